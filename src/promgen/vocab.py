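"""SMILES tokenisation and the token vocabulary of the language model.

Tokens follow standard SMILES language-model practice: bracket atom
expressions ``[...]`` are single tokens, the two-letter halogens ``Cl`` and
``Br`` are single tokens, ``%nn`` ring closures are single tokens, and
every other character is its own token. The scheme is reversible:
joining the tokens reproduces the input string exactly.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np

__all__ = ["TokenVocabulary", "UnknownTokenError", "smiles_tokens"]

_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")

PAD, BOS, EOS = "<pad>", "^", "$"


class UnknownTokenError(KeyError):
    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:
        return f"token {self.token!r} is not in the vocabulary"


def smiles_tokens(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; lossless (``''.join`` inverts)."""
    return _TOKEN_RE.findall(smiles)


class TokenVocabulary:
    """Bijective token <-> index mapping with reserved PAD/BOS/EOS slots.

    PAD is index 0, BOS 1, EOS 2; corpus tokens follow in sorted order so
    that vocabulary construction is deterministic.
    """

    def __init__(self, tokens: Sequence[str]):
        specials = [PAD, BOS, EOS]
        body = [t for t in tokens if t not in specials]
        if len(set(body)) != len(body):
            raise ValueError("duplicate tokens in vocabulary")
        self.tokens: list[str] = specials + list(body)
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_corpus(
        cls, corpus: Iterable[str], extra_tokens: Sequence[str] = tuple("123456789")
    ) -> "TokenVocabulary":
        """Build from every token in ``corpus``.

        ``extra_tokens`` defaults to all ring-closure digits: randomized
        (non-canonical) spellings of corpus molecules can open more ring
        numbers than any canonical string uses, and the vocabulary is frozen
        before augmentation starts.
        """
        seen: set[str] = set(extra_tokens)
        for smi in corpus:
            seen.update(smiles_tokens(smi))
        return cls(sorted(seen))

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    def encode(self, smiles: str) -> np.ndarray:
        """Token ids ``[BOS, t1..tk, EOS]``; raises on out-of-vocabulary tokens."""
        ids = [self.bos_id]
        for tok in smiles_tokens(smiles):
            idx = self.index.get(tok)
            if idx is None:
                raise UnknownTokenError(tok)
            ids.append(idx)
        ids.append(self.eos_id)
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids: Iterable[int]) -> str:
        """Join tokens, stopping at EOS and skipping PAD/BOS."""
        out = []
        for i in ids:
            if i == self.eos_id:
                break
            if i in (self.pad_id, self.bos_id):
                continue
            out.append(self.tokens[i])
        return "".join(out)

    def to_dict(self) -> dict:
        return {"tokens": self.tokens}

    @classmethod
    def from_dict(cls, d: dict) -> "TokenVocabulary":
        vocab = cls.__new__(cls)
        vocab.tokens = list(d["tokens"])
        vocab.index = {t: i for i, t in enumerate(vocab.tokens)}
        return vocab
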