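"""Per-epoch evaluation of sampled batches against the curated sets.

Four analyses, each applied to the unique valid canonical SMILES sampled
from a model checkpoint, mirror the standard readouts for transfer-learning
a molecular generator toward a focused compound class:

* NLL tracking  -- quartiles of per-compound sequence NLL for each curated
  set at each checkpoint;
* retrieval     -- how many known compounds of each set are reproduced
  exactly (by canonical SMILES);
* neighbors     -- ECFP6 Tanimoto >= 0.6 fingerprint neighbors of each set
  among the *novel* generated molecules (exact reproductions excluded),
  counted as (generated, known) pairs and normalised per known compound;
* scaffolds     -- Bemis-Murcko scaffold overlap between generated molecules
  and each set, including test-set scaffolds absent from the training set.

A gradient-boosted promiscuity classifier (ECFP6 features, XGBoost) adds a
supervised readout: the fraction of generated compounds predicted to be
multi-target at each checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import DataStructs
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import matthews_corrcoef, recall_score, roc_auc_score
from xgboost import XGBClassifier

from .chem import bm_scaffold, canonicalize, ecfp6_matrix, ecfp6_rdkit
from .curation import CuratedSets

__all__ = [
    "SampleBatch",
    "reduce_batch",
    "nll_summary",
    "retrieval",
    "neighbors",
    "scaffold_sets",
    "scaffold_analysis",
    "PromiscuityClassifier",
    "ClassifierBundle",
    "train_classifier",
    "classify_generated",
]

SET_NAMES = ("multi_train", "multi_test", "single_test", "none_test")


@dataclass
class SampleBatch:
    """One checkpoint's raw sample reduced to unique valid canonical SMILES."""

    epoch: int
    n_raw: int
    n_valid: int
    unique: frozenset[str]
    reproduced: dict[str, frozenset[str]]  # per curated set
    novel: frozenset[str]  # unique minus every known compound


def reduce_batch(
    raw: Sequence[str], known_sets: Mapping[str, Sequence[str]], epoch: int = 0
) -> SampleBatch:
    """Canonicalize raw strings, drop failures, deduplicate, flag knowns."""
    canon = [canonicalize(s) for s in raw]
    valid = [c for c in canon if c is not None]
    unique = frozenset(valid)
    reproduced = {
        name: frozenset(unique & set(members)) for name, members in known_sets.items()
    }
    all_known: set[str] = set()
    for members in known_sets.values():
        all_known.update(members)
    return SampleBatch(
        epoch=epoch,
        n_raw=len(raw),
        n_valid=len(valid),
        unique=unique,
        reproduced=reproduced,
        novel=frozenset(unique - all_known),
    )


def nll_summary(checkpoints: Mapping[int, object], sets: CuratedSets) -> pd.DataFrame:
    """Quartiles (q25/median/q75, nats) of canonical-SMILES NLL per epoch x set.

    Set members the frozen vocabulary cannot tokenize are excluded and
    counted in the ``n_excluded`` column.
    """
    rows = []
    for epoch in sorted(checkpoints):
        model = checkpoints[epoch]
        for name, members in sets.set_items().items():
            kept, excluded = [], 0
            for smi in members.values():
                try:
                    model.vocab_.encode(smi)
                    kept.append(smi)
                except KeyError:
                    excluded += 1
            nll = model.sequence_nll(kept) if kept else np.asarray([], dtype=float)
            q25, med, q75 = (
                np.percentile(nll, [25, 50, 75]) if nll.size else (np.nan,) * 3
            )
            rows.append(
                {
                    "epoch": epoch, "set": name, "n": int(nll.size),
                    "n_excluded": excluded,
                    "q25": q25, "median": med, "q75": q75,
                }
            )
    return pd.DataFrame(rows)


def retrieval(batch: SampleBatch, sets: CuratedSets) -> pd.DataFrame:
    """Exact reproduction count and percentage per curated set."""
    rows = []
    for name, members in sets.set_items().items():
        count = len(batch.unique & set(members.values()))
        rows.append(
            {
                "epoch": batch.epoch, "set": name, "n_set": len(members),
                "retrieved": count,
                "pct": 100.0 * count / len(members) if members else np.nan,
            }
        )
    return pd.DataFrame(rows)


def neighbors(
    batch: SampleBatch, sets: CuratedSets, threshold: float = 0.6
) -> pd.DataFrame:
    """Fingerprint-neighbor counts of each set among novel generated molecules.

    A (generated, known) pair is a neighbor pair when ECFP6 Tanimoto
    similarity is at least ``threshold`` (inclusive). Exact reproductions of
    any known compound are excluded beforehand (``batch.novel``). Reported
    per set: absolute pair count, pairs per known compound, and the number
    of distinct generated molecules with at least one neighbor in the set.
    """
    gen = sorted(batch.novel)
    gen_fps = [ecfp6_rdkit(s) for s in gen]
    rows = []
    for name, members in sets.set_items().items():
        known = sorted(set(members.values()))
        known_fps = [ecfp6_rdkit(k) for k in known]
        pair_count = 0
        gen_with_neighbor = 0
        for fp in gen_fps:
            if not known_fps:
                continue
            sims = np.asarray(DataStructs.BulkTanimotoSimilarity(fp, known_fps))
            hits = int(np.count_nonzero(sims >= threshold))
            pair_count += hits
            if hits:
                gen_with_neighbor += 1
        rows.append(
            {
                "epoch": batch.epoch, "set": name, "n_set": len(known),
                "pairs": pair_count,
                "pairs_per_known": pair_count / len(known) if known else np.nan,
                "generated_with_neighbor": gen_with_neighbor,
            }
        )
    return pd.DataFrame(rows)


def scaffold_sets(sets: CuratedSets) -> dict[str, frozenset[str]]:
    """Unique non-empty Bemis-Murcko scaffolds per curated set."""
    out = {}
    for name, members in sets.set_items().items():
        scaffolds = {bm_scaffold(s) for s in members.values()}
        out[name] = frozenset(scaffolds - {""})
    return out


def scaffold_analysis(
    batches: Mapping[int, SampleBatch], sets: CuratedSets
) -> pd.DataFrame:
    """Scaffold retrieval per epoch x set, plus novel-test-scaffold recovery.

    ``novel_test_retrieved`` (reported on multi_test rows) counts multi-test
    scaffolds that are absent from the multi-train scaffold set yet present
    among scaffolds of generated compounds -- evidence of generalisation
    beyond the training frameworks.
    """
    known_scaffolds = scaffold_sets(sets)
    novel_test = known_scaffolds["multi_test"] - known_scaffolds["multi_train"]
    rows = []
    for epoch in sorted(batches):
        batch = batches[epoch]
        gen_scaffolds = {bm_scaffold(s) for s in batch.unique} - {""}
        for name, scaffolds in known_scaffolds.items():
            retrieved = gen_scaffolds & scaffolds
            row = {
                "epoch": epoch, "set": name, "n_scaffolds": len(scaffolds),
                "retrieved": len(retrieved),
                "fraction": len(retrieved) / len(scaffolds) if scaffolds else np.nan,
            }
            if name == "multi_test":
                row["n_novel_test"] = len(novel_test)
                row["novel_test_retrieved"] = len(gen_scaffolds & novel_test)
            rows.append(row)
    return pd.DataFrame(rows)


class PromiscuityClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted tree classifier for multi-target compounds.

    Operates directly on SMILES: molecules are featurised as ECFP6/2048
    fingerprints (the same representation as the similarity analysis) and
    classified with XGBoost. Positive class = multi-target.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int = 6,
        learning_rate: float = 0.1,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X: Sequence[str], y) -> "PromiscuityClassifier":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both positive and negative examples")
        self.model_ = XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
            n_jobs=1,
            eval_metric="logloss",
        )
        self.model_.fit(ecfp6_matrix(list(X)), y)
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        return self.model_.predict_proba(ecfp6_matrix(list(X)))

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class ClassifierBundle:
    classifier: PromiscuityClassifier
    metrics: dict = field(default_factory=dict)


def train_classifier(
    sets: CuratedSets,
    n_negative_per_class: int,
    seed: int,
    **xgb_params,
) -> ClassifierBundle:
    """Train the promiscuity classifier and evaluate it on held-out compounds.

    Positives: the multi-target training set. Negatives: equally sized random
    subsets of the single- and no-target sets. Held-out evaluation uses the
    multi-target test set (positives) plus all remaining single/no-target
    compounds (negatives); reported metrics are ROC AUC, Matthews
    correlation coefficient and recall at a 0.5 probability threshold.
    """
    rng = np.random.default_rng(seed)
    pos_train = sorted(sets.multi_train.values())
    neg_pools = {
        "single_test": sorted(sets.single_test.values()),
        "none_test": sorted(sets.none_test.values()),
    }
    neg_train: list[str] = []
    held_neg: list[str] = []
    for pool in neg_pools.values():
        k = min(n_negative_per_class, len(pool))
        picked = set(rng.choice(len(pool), size=k, replace=False).tolist())
        neg_train.extend(pool[i] for i in sorted(picked))
        held_neg.extend(pool[i] for i in range(len(pool)) if i not in picked)
    X_train = pos_train + neg_train
    y_train = [1] * len(pos_train) + [0] * len(neg_train)
    clf = PromiscuityClassifier(random_state=seed % (2**31), **xgb_params)
    clf.fit(X_train, y_train)

    held_pos = sorted(sets.multi_test.values())
    X_test = held_pos + held_neg
    y_test = np.asarray([1] * len(held_pos) + [0] * len(held_neg))
    metrics: dict = {"n_train": len(X_train), "n_test": len(X_test)}
    if len(np.unique(y_test)) == 2:
        proba = clf.predict_proba(X_test)[:, 1]
        pred = (proba >= 0.5).astype(int)
        metrics.update(
            roc_auc=float(roc_auc_score(y_test, proba)),
            mcc=float(matthews_corrcoef(y_test, pred)),
            recall=float(recall_score(y_test, pred)),
        )
    return ClassifierBundle(classifier=clf, metrics=metrics)


def classify_generated(
    bundle: ClassifierBundle, batches: Mapping[int, SampleBatch]
) -> pd.DataFrame:
    """Fraction of unique valid generated compounds predicted multi-target.

    Empty batches report NaN (no prediction), not zero.
    """
    rows = []
    for epoch in sorted(batches):
        unique = sorted(batches[epoch].unique)
        if not unique:
            frac = np.nan
        else:
            frac = float(np.mean(bundle.classifier.predict(unique)))
        rows.append(
            {"epoch": epoch, "n_generated": len(unique), "fraction_multi": frac}
        )
    return pd.DataFrame(rows)
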