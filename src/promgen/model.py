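"""Character-level SMILES recurrent language model (NumPy GRU).

A compact generative model in the REINVENT mold: an embedding layer, one or
more GRU layers and a softmax output over the token vocabulary, trained by
teacher forcing to minimise the negative log-likelihood (NLL, in nats) of
SMILES token sequences with the Adam optimizer. Everything -- forward pass,
backpropagation through time, Adam, seeded ancestral sampling -- is
implemented directly on NumPy arrays, which keeps the model dependency-light
and bit-reproducible on one CPU at the desk scales this package targets.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, ``fit`` for pretraining, fitted attributes with trailing
underscores, ``get_params``/``set_params`` inherited from ``BaseEstimator``.
Transfer learning is exposed as :meth:`SmilesRnnGenerator.fine_tune`, which
continues training on a focused compound set (optionally re-randomising each
SMILES spelling every epoch as augmentation) and snapshots per-epoch
checkpoints.
"""

from __future__ import annotations

import copy
import json
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._seeds import derive_seed
from .chem import randomize_smiles
from .vocab import TokenVocabulary

__all__ = ["SmilesRnnGenerator"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _log_softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


class _Adam:
    """Plain Adam over a flat dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SmilesRnnGenerator(BaseEstimator):
    """GRU language model over SMILES tokens with seeded sampling.

    Parameters
    ----------
    embedding_dim, hidden_size, n_layers : network shape.
    learning_rate, batch_size, n_epochs : Adam pretraining schedule.
    max_len : hard cap on token-sequence length, both for training inputs
        and for ancestral sampling; sampled sequences that hit the cap
        without emitting EOS are returned unterminated (they are counted
        invalid downstream).
    clip_norm : global gradient-norm clip; 0 disables.
    dtype : "float32" (default) or "float64" (used by gradient checks).
    random_state : master seed; initialisation, shuffling and augmentation
        use named child seeds derived from it.

    Attributes (after :meth:`fit`)
    ------------------------------
    vocab_ : frozen :class:`TokenVocabulary` built from the pretraining corpus.
    params_ : dict of weight arrays.
    trace_ : list of ``{"epoch", "phase", "mean_nll"}`` rows, one per epoch.
    epoch_ : total completed training epochs (pretraining + fine-tuning).
    """

    def __init__(
        self,
        embedding_dim: int = 48,
        hidden_size: int = 96,
        n_layers: int = 1,
        learning_rate: float = 1e-3,
        batch_size: int = 128,
        n_epochs: int = 12,
        max_len: int = 120,
        clip_norm: float = 5.0,
        dtype: str = "float32",
        random_state: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.max_len = max_len
        self.clip_norm = clip_norm
        self.dtype = dtype
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64

    def initialize(self, corpus: Sequence[str]) -> "SmilesRnnGenerator":
        """Build the vocabulary from ``corpus`` and initialise weights."""
        self.vocab_ = TokenVocabulary.from_corpus(corpus)
        rng = np.random.default_rng(derive_seed(self.random_state, "init"))
        V, E, H, L = len(self.vocab_), self.embedding_dim, self.hidden_size, self.n_layers
        dt = self._np_dtype()
        s = 1.0 / np.sqrt(H)

        def u(*shape):
            return rng.uniform(-s, s, size=shape).astype(dt)

        p: dict[str, np.ndarray] = {"E": u(V, E), "Wo": u(H, V), "bo": np.zeros(V, dt)}
        for l in range(L):
            in_dim = E if l == 0 else H
            p[f"Wx{l}"] = u(in_dim, 3 * H)
            p[f"Uh{l}"] = u(H, 3 * H)
            p[f"bx{l}"] = np.zeros(3 * H, dt)
            p[f"bh{l}"] = np.zeros(3 * H, dt)
        self.params_ = p
        self.opt_ = _Adam(p, self.learning_rate)
        self.trace_: list[dict] = []
        self.epoch_ = 0
        return self

    # ------------------------------------------------------------- forward/bwd

    def _encode_batch(self, smiles: Sequence[str]) -> np.ndarray:
        seqs = [self.vocab_.encode(s) for s in smiles]
        longest = max(len(s) for s in seqs)
        if longest > self.max_len + 2:
            raise ValueError(
                f"sequence of {longest} tokens exceeds max_len={self.max_len}"
            )
        pad = self.vocab_.pad_id
        out = np.full((len(seqs), longest), pad, dtype=np.int64)
        for i, s in enumerate(seqs):
            out[i, : len(s)] = s
        return out

    def _forward(self, X: np.ndarray, want_cache: bool):
        """Teacher-forced forward over input ids X (B,T). Returns
        (log_probs (B,T,V), caches)."""
        p = self.params_
        H = self.hidden_size
        B, T = X.shape
        layer_in = p["E"][X]  # (B,T,E)
        caches = []
        for l in range(self.n_layers):
            GX = layer_in.reshape(B * T, -1) @ p[f"Wx{l}"] + p[f"bx{l}"]
            GX = GX.reshape(B, T, 3 * H)
            h = np.zeros((B, H), dtype=GX.dtype)
            Hout = np.empty((B, T, H), dtype=GX.dtype)
            steps = []
            for t in range(T):
                gh = h @ p[f"Uh{l}"] + p[f"bh{l}"]
                z = _sigmoid(GX[:, t, :H] + gh[:, :H])
                r = _sigmoid(GX[:, t, H : 2 * H] + gh[:, H : 2 * H])
                ghn = gh[:, 2 * H :]
                n = np.tanh(GX[:, t, 2 * H :] + r * ghn)
                h_new = (1.0 - z) * n + z * h
                if want_cache:
                    steps.append((h, z, r, n, ghn))
                Hout[:, t] = h_new
                h = h_new
            caches.append((layer_in, steps, Hout))
            layer_in = Hout
        logits = layer_in.reshape(B * T, H) @ p["Wo"] + p["bo"]
        logp = _log_softmax(logits).reshape(B, T, -1)
        return logp, caches

    def _nll_from_logp(self, logp, Y, mask):
        """Per-sequence NLL (nats): -sum of target log-probs over mask."""
        B, T, _ = logp.shape
        tok_lp = np.take_along_axis(logp, Y[:, :, None], axis=2)[:, :, 0]
        return -(tok_lp * mask).sum(axis=1, dtype=np.float64)

    def _backward(self, X, Y, mask, logp, caches):
        p = self.params_
        H = self.hidden_size
        B, T, V = logp.shape
        probs = np.exp(logp)
        dlogits = probs
        np.put_along_axis(
            dlogits, Y[:, :, None], np.take_along_axis(dlogits, Y[:, :, None], 2) - 1.0, 2
        )
        dlogits *= mask[:, :, None] / B
        dlogits = dlogits.astype(p["Wo"].dtype)
        grads = {}
        top = caches[-1][2]  # (B,T,H)
        grads["Wo"] = top.reshape(B * T, H).T @ dlogits.reshape(B * T, V)
        grads["bo"] = dlogits.sum(axis=(0, 1))
        dHout = (dlogits.reshape(B * T, V) @ p["Wo"].T).reshape(B, T, H)
        for l in range(self.n_layers - 1, -1, -1):
            layer_in, steps, _ = caches[l]
            Uh = p[f"Uh{l}"]
            dGX = np.empty((B, T, 3 * H), dtype=Uh.dtype)
            dUh = np.zeros_like(Uh)
            dbh = np.zeros(3 * H, dtype=Uh.dtype)
            dh_carry = np.zeros((B, H), dtype=Uh.dtype)
            dgh = np.empty((B, 3 * H), dtype=Uh.dtype)
            for t in range(T - 1, -1, -1):
                dh = dHout[:, t] + dh_carry
                h_prev, z, r, n, ghn = steps[t]
                dn = dh * (1.0 - z) * (1.0 - n * n)
                dz = dh * (h_prev - n) * z * (1.0 - z)
                dr = dn * ghn * r * (1.0 - r)
                dGX[:, t, :H] = dz
                dGX[:, t, H : 2 * H] = dr
                dGX[:, t, 2 * H :] = dn
                dgh[:, :H] = dz
                dgh[:, H : 2 * H] = dr
                dgh[:, 2 * H :] = dn * r
                dUh += h_prev.T @ dgh
                dbh += dgh.sum(axis=0)
                dh_carry = dh * z + dgh @ Uh.T
            in_dim = layer_in.shape[2]
            flat_in = layer_in.reshape(B * T, in_dim)
            flat_dGX = dGX.reshape(B * T, 3 * H)
            grads[f"Wx{l}"] = flat_in.T @ flat_dGX
            grads[f"bx{l}"] = flat_dGX.sum(axis=0)
            grads[f"Uh{l}"] = dUh
            grads[f"bh{l}"] = dbh
            dHout = (flat_dGX @ p[f"Wx{l}"].T).reshape(B, T, in_dim)
        dE = np.zeros_like(p["E"])
        np.add.at(dE, X, dHout)
        grads["E"] = dE
        return grads

    def _clip(self, grads: dict) -> None:
        if not self.clip_norm:
            return
        total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
        if total > self.clip_norm:
            scale = self.clip_norm / total
            for g in grads.values():
                g *= scale

    def _train_batch(self, smiles: Sequence[str]) -> np.ndarray:
        """One optimisation step on a batch; returns per-sequence NLLs."""
        seq = self._encode_batch(smiles)
        X, Y = seq[:, :-1], seq[:, 1:]
        mask = (Y != self.vocab_.pad_id).astype(self.params_["Wo"].dtype)
        logp, caches = self._forward(X, want_cache=True)
        nll = self._nll_from_logp(logp, Y, mask)
        grads = self._backward(X, Y, mask, logp, caches)
        self._clip(grads)
        self.opt_.step(self.params_, grads)
        return nll

    def _run_epochs(self, smiles: list[str], n_epochs: int, phase: str,
                    randomize: bool, seed: int,
                    checkpoint_epochs=(), checkpoints=None) -> None:
        for local_epoch in range(n_epochs):
            rng = np.random.default_rng(derive_seed(seed, f"{phase}:{local_epoch}"))
            if randomize:
                batch_pool = [randomize_smiles(s, rng) for s in smiles]
            else:
                batch_pool = smiles
            order = rng.permutation(len(batch_pool))
            nlls = []
            for start in range(0, len(order), self.batch_size):
                batch = [batch_pool[i] for i in order[start : start + self.batch_size]]
                nlls.append(self._train_batch(batch))
            self.epoch_ += 1
            self.trace_.append(
                {
                    "epoch": self.epoch_,
                    "phase": phase,
                    "mean_nll": float(np.concatenate(nlls).mean()),
                }
            )
            if checkpoints is not None and self.epoch_ in checkpoint_epochs:
                checkpoints[self.epoch_] = self.snapshot()

    # ---------------------------------------------------------------- training

    def fit(self, X: Sequence[str], y=None) -> "SmilesRnnGenerator":
        """Pretrain on a corpus of canonical SMILES (the whole universe)."""
        corpus = list(X)
        if len(corpus) < 1:
            raise ValueError("empty pretraining corpus")
        self.initialize(corpus)
        self._run_epochs(
            corpus, self.n_epochs, phase="pretrain", randomize=False,
            seed=derive_seed(self.random_state, "pretrain"),
        )
        return self

    def fine_tune(
        self,
        train_smiles: Sequence[str],
        n_epochs: int,
        randomize: bool = True,
        seed: int | None = None,
        checkpoint_epochs: Iterable[int] = (),
    ) -> dict[int, "SmilesRnnGenerator"]:
        """Continue training on a focused set (transfer learning).

        With ``randomize=True`` every SMILES is re-spelled with a fresh
        random atom order each epoch (augmentation against overfitting).
        The vocabulary stays frozen; training strings with unseen tokens
        raise :class:`~promgen.vocab.UnknownTokenError`.

        Returns a dict of epoch -> model snapshot for the requested
        ``checkpoint_epochs`` (epoch numbers count fine-tuning epochs,
        0 = the state before any fine-tuning).
        """
        self._check_fitted()
        train = list(train_smiles)
        for s in train:  # fail loudly before mutating any state
            self.vocab_.encode(s)
        seed = self.random_state if seed is None else seed
        start = self.epoch_
        wanted = {start + e for e in checkpoint_epochs}
        checkpoints: dict[int, SmilesRnnGenerator] = {}
        if start in wanted:
            checkpoints[start] = self.snapshot()
        self._run_epochs(
            train, n_epochs, phase="finetune", randomize=randomize,
            seed=derive_seed(seed, "finetune"),
            checkpoint_epochs=wanted, checkpoints=checkpoints,
        )
        return {e - start: ck for e, ck in checkpoints.items()}

    # --------------------------------------------------------------- inference

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not initialised; call fit() first")

    def sequence_nll(self, X: Sequence[str] | str, chunk: int = 1024) -> np.ndarray:
        """NLL in nats of each canonical SMILES: -sum log p(token | prefix),
        over all tokens after BOS up to and including EOS."""
        self._check_fitted()
        single = isinstance(X, str)
        smiles = [X] if single else list(X)
        out = np.empty(len(smiles), dtype=np.float64)
        for start in range(0, len(smiles), chunk):
            part = smiles[start : start + chunk]
            seq = self._encode_batch(part)
            Xb, Yb = seq[:, :-1], seq[:, 1:]
            mask = (Yb != self.vocab_.pad_id).astype(np.float64)
            logp, _ = self._forward(Xb, want_cache=False)
            out[start : start + len(part)] = self._nll_from_logp(logp, Yb, mask)
        return out if not single else out[0]

    def score_samples(self, X: Sequence[str]) -> np.ndarray:
        """Log-likelihood per string (= negative :meth:`sequence_nll`)."""
        return -self.sequence_nll(X)

    def sample(self, n: int, seed: int) -> list[str]:
        """Draw ``n`` raw strings by seeded ancestral sampling.

        Deterministic: identical (weights, n, seed) give the identical list,
        order included, so differences between checkpoints sampled with the
        same seed are attributable to the weights alone. Strings are
        returned unfiltered; sequences that hit ``max_len`` without EOS come
        back unterminated.
        """
        self._check_fitted()
        if n == 0:
            return []
        p = self.params_
        H, L = self.hidden_size, self.n_layers
        rng = np.random.default_rng(seed)
        eos, V = self.vocab_.eos_id, len(self.vocab_)
        alive = np.arange(n)
        ids = np.full(n, self.vocab_.bos_id, dtype=np.int64)
        h = [np.zeros((n, H), dtype=p["Wo"].dtype) for _ in range(L)]
        tokens: list[list[int]] = [[] for _ in range(n)]
        for _ in range(self.max_len):
            x = p["E"][ids]
            for l in range(L):
                gx = x @ p[f"Wx{l}"] + p[f"bx{l}"]
                gh = h[l] @ p[f"Uh{l}"] + p[f"bh{l}"]
                z = _sigmoid(gx[:, :H] + gh[:, :H])
                r = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
                nn = np.tanh(gx[:, 2 * H :] + r * gh[:, 2 * H :])
                h[l] = (1.0 - z) * nn + z * h[l]
                x = h[l]
            probs = _softmax(x @ p["Wo"] + p["bo"])
            u = rng.random(len(alive))
            nxt = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
            np.clip(nxt, 0, V - 1, out=nxt)
            for row, tok in zip(alive, nxt):
                tokens[row].append(int(tok))
            cont = nxt != eos
            if not cont.any():
                break
            alive = alive[cont]
            ids = nxt[cont]
            h = [hl[cont] for hl in h]
        return [self.vocab_.decode(t) for t in tokens]

    # ------------------------------------------------------------- persistence

    def snapshot(self) -> "SmilesRnnGenerator":
        """Deep in-memory copy (an immutable per-epoch checkpoint)."""
        return copy.deepcopy(self)

    def save(self, path) -> None:
        """Write a self-describing checkpoint archive (weights + optimizer
        moments + vocabulary + hyperparameters + epoch counter)."""
        self._check_fitted()
        meta = {
            "params": self.get_params(),
            "vocab": self.vocab_.to_dict(),
            "epoch": self.epoch_,
            "adam_t": self.opt_.t,
            "trace": self.trace_,
        }
        arrays = {f"p_{k}": v for k, v in self.params_.items()}
        arrays.update({f"m_{k}": v for k, v in self.opt_.m.items()})
        arrays.update({f"v_{k}": v for k, v in self.opt_.v.items()})
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SmilesRnnGenerator":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(**meta["params"])
            model.vocab_ = TokenVocabulary.from_dict(meta["vocab"])
            model.params_ = {k[2:]: data[k].copy() for k in data.files if k.startswith("p_")}
            model.opt_ = _Adam(model.params_, model.learning_rate)
            model.opt_.t = meta["adam_t"]
            model.opt_.m = {k[2:]: data[k].copy() for k in data.files if k.startswith("m_")}
            model.opt_.v = {k[2:]: data[k].copy() for k in data.files if k.startswith("v_")}
            model.epoch_ = meta["epoch"]
            model.trace_ = meta["trace"]
        return model
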