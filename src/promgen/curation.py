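"""High-confidence curation of assay outcomes into promiscuity classes.

The pipeline mirrors standard practice for mining qualitative screening
data: (1) drop whole assays whose hit rate exceeds an artifact threshold
(frequent-hitter assays inflate apparent promiscuity), (2) collapse
remaining records to one consensus outcome per (compound, target) and
discard compounds with conflicting annotations, (3) assign each compound to
a promiscuity class by counting distinct targets:

* ``multi_target``  -- confirmed active against >= 5 distinct targets;
* ``single_target`` -- active against exactly 1 target and confirmed
  inactive against >= 4 others;
* ``no_target``     -- no activity, inactive against >= 5 targets;
* anything else is ``unassigned`` and dropped.

Thresholds are configurable; the defaults above are the conventional
high-confidence choices. "Hit rate higher than 2%" is read strictly:
an assay at exactly 2% is retained.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import canonicalize
from .universe import AssayRecord

__all__ = [
    "CompoundClass",
    "ActivityProfile",
    "CuratedSets",
    "ClassThresholds",
    "filter_assays_by_hit_rate",
    "build_profiles",
    "assign_class",
    "split_sets",
    "apply_exclusion_list",
    "curate",
]


class CompoundClass(str, Enum):
    multi_target = "multi_target"
    single_target = "single_target"
    no_target = "no_target"
    unassigned = "unassigned"


@dataclass(frozen=True)
class ActivityProfile:
    """Per-compound consensus activity across targets."""

    compound_id: str
    targets_active: frozenset[str]
    targets_inactive: frozenset[str]
    inconsistent_targets: frozenset[str]

    def __post_init__(self) -> None:
        if self.targets_active & self.targets_inactive:
            raise ValueError("active and inactive target sets must be disjoint")
        if self.inconsistent_targets & (self.targets_active | self.targets_inactive):
            raise ValueError("inconsistent targets must be disjoint from consensus sets")


@dataclass(frozen=True)
class ClassThresholds:
    """Distinct-target counts required for each class."""

    multi_min_active: int = 5
    single_min_inactive: int = 4
    none_min_inactive: int = 5


@dataclass
class CuratedSets:
    """The four labeled compound collections used downstream.

    Each set maps compound_id -> canonical SMILES; the four sets are
    pairwise disjoint by compound id. ``audit`` records the counts removed
    or assigned at each curation step.
    """

    multi_train: dict[str, str]
    multi_test: dict[str, str]
    single_test: dict[str, str]
    none_test: dict[str, str]
    audit: dict = field(default_factory=dict)

    def set_items(self) -> dict[str, dict[str, str]]:
        return {
            "multi_train": self.multi_train,
            "multi_test": self.multi_test,
            "single_test": self.single_test,
            "none_test": self.none_test,
        }

    def smiles(self, name: str) -> list[str]:
        return list(self.set_items()[name].values())


class DataIntegrityError(ValueError):
    """Contradictory duplicate rows within one assay."""


def filter_assays_by_hit_rate(
    records: Sequence[AssayRecord], max_hit_rate: float = 0.02
) -> tuple[list[AssayRecord], dict]:
    """Drop every record of any assay whose hit rate strictly exceeds the cutoff.

    Hit rate is the fraction of a given assay's records with outcome
    ``active``. Returns the surviving records plus an audit dict with the
    removed assay ids and record counts.
    """
    if not records:
        raise ValueError("no assay records given")
    totals: dict[str, int] = defaultdict(int)
    actives: dict[str, int] = defaultdict(int)
    for r in records:
        totals[r.assay_id] += 1
        if r.outcome == "active":
            actives[r.assay_id] += 1
    removed = {a for a in totals if actives[a] / totals[a] > max_hit_rate}
    kept = [r for r in records if r.assay_id not in removed]
    audit = {
        "max_hit_rate": max_hit_rate,
        "assays_total": len(totals),
        "assays_removed": sorted(removed),
        "records_removed": len(records) - len(kept),
    }
    return kept, audit


def build_profiles(records: Sequence[AssayRecord]) -> list[ActivityProfile]:
    """Collapse records to per-(compound, target) consensus outcomes.

    Agreeing outcomes yield a consensus active/inactive target; conflicting
    outcomes across assays park the target in ``inconsistent_targets``.
    Duplicate rows with the same (assay, compound, target) but different
    outcomes are contradictory within a single assay and raise
    :class:`DataIntegrityError`.
    """
    by_row: dict[tuple[str, str, str], str] = {}
    outcomes: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for r in records:
        key = (r.assay_id, r.compound_id, r.target_id)
        prev = by_row.get(key)
        if prev is not None and prev != r.outcome:
            raise DataIntegrityError(
                f"conflicting duplicate rows for assay={r.assay_id} "
                f"compound={r.compound_id} target={r.target_id}"
            )
        by_row[key] = r.outcome
        outcomes[r.compound_id][r.target_id].add(r.outcome)
    profiles = []
    for cid in sorted(outcomes):
        act, inact, incons = set(), set(), set()
        for tid, seen in outcomes[cid].items():
            if len(seen) > 1:
                incons.add(tid)
            elif "active" in seen:
                act.add(tid)
            else:
                inact.add(tid)
        profiles.append(
            ActivityProfile(cid, frozenset(act), frozenset(inact), frozenset(incons))
        )
    return profiles


def assign_class(
    profile: ActivityProfile,
    thresholds: ClassThresholds = ClassThresholds(),
    drop_if_inconsistent: bool = True,
) -> CompoundClass:
    """Apply the distinct-target counting rules to one activity profile."""
    if drop_if_inconsistent and profile.inconsistent_targets:
        return CompoundClass.unassigned
    n_act = len(profile.targets_active)
    n_inact = len(profile.targets_inactive)
    if n_act >= thresholds.multi_min_active:
        return CompoundClass.multi_target
    if n_act == 1 and n_inact >= thresholds.single_min_inactive:
        return CompoundClass.single_target
    if n_act == 0 and n_inact >= thresholds.none_min_inactive:
        return CompoundClass.no_target
    return CompoundClass.unassigned


def split_sets(
    classified: Mapping[str, tuple[CompoundClass, str]],
    n_train: int,
    seed: int,
) -> CuratedSets:
    """Split classified compounds into train/test collections.

    ``classified`` maps compound_id -> (class, canonical SMILES). A uniform
    random sample of ``n_train`` multi-target compounds becomes the
    fine-tuning training set; the remaining multi-target compounds and all
    single-target compounds are test sets, and the no-target test set is
    downsampled to the single-target test set's size when larger (matching
    the equally-sized control-set convention). Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[CompoundClass, list[tuple[str, str]]] = defaultdict(list)
    for cid in sorted(classified):
        cls, smi = classified[cid]
        by_class[cls].append((cid, smi))
    multi = by_class[CompoundClass.multi_target]
    if n_train >= len(multi):
        raise ValueError(
            f"n_train={n_train} must be smaller than the number of "
            f"multi-target compounds ({len(multi)})"
        )
    order = rng.permutation(len(multi))
    train_idx = set(order[:n_train].tolist())
    multi_train = dict(multi[i] for i in sorted(train_idx))
    multi_test = dict(multi[i] for i in range(len(multi)) if i not in train_idx)
    single_test = dict(by_class[CompoundClass.single_target])
    none_all = by_class[CompoundClass.no_target]
    if len(none_all) > len(single_test):
        pick = rng.choice(len(none_all), size=len(single_test), replace=False)
        none_test = dict(none_all[i] for i in sorted(pick.tolist()))
    else:
        none_test = dict(none_all)
    audit = {
        "n_train": n_train,
        "counts": {
            "multi_train": len(multi_train),
            "multi_test": len(multi_test),
            "single_test": len(single_test),
            "none_test": len(none_test),
            "no_target_downsampled_from": len(none_all),
            "unassigned": len(by_class[CompoundClass.unassigned]),
        },
    }
    return CuratedSets(multi_train, multi_test, single_test, none_test, audit)


def apply_exclusion_list(
    compounds: Mapping[str, str], exclusion: Iterable[str]
) -> tuple[dict[str, str], list[str]]:
    """Remove compounds whose structure is on an exclusion list.

    The hook where liability filters (pan-assay interference, aggregation
    alerts, medicinal-chemistry rules) plug in as a precomputed list of
    SMILES; entries are canonicalized before matching so spelling variants
    still match. Returns (kept, removed compound ids).
    """
    excl = {canonicalize(s) for s in exclusion} - {None}
    kept, removed = {}, []
    for cid, smi in compounds.items():
        if canonicalize(smi) in excl:
            removed.append(cid)
        else:
            kept[cid] = smi
    return kept, removed


def curate(
    records: Sequence[AssayRecord],
    smiles_by_id: Mapping[str, str],
    *,
    max_hit_rate: float = 0.02,
    thresholds: ClassThresholds = ClassThresholds(),
    n_train: int,
    seed: int,
    exclusion: Iterable[str] = (),
) -> CuratedSets:
    """Full curation: hit-rate filter, consensus, class rules, exclusions, split.

    ``smiles_by_id`` supplies each compound's structure; compounds with
    records but no structure (or an invalid one) are dropped and audited.
    """
    kept_records, filter_audit = filter_assays_by_hit_rate(records, max_hit_rate)
    profiles = build_profiles(kept_records)
    classified: dict[str, tuple[CompoundClass, str]] = {}
    n_dropped_inconsistent = 0
    n_missing_structure = 0
    for p in profiles:
        cls = assign_class(p, thresholds)
        if p.inconsistent_targets:
            n_dropped_inconsistent += 1
        smi = smiles_by_id.get(p.compound_id)
        canon = canonicalize(smi) if smi is not None else None
        if canon is None:
            n_missing_structure += 1
            continue
        classified[p.compound_id] = (cls, canon)
    if exclusion:
        as_map = {cid: smi for cid, (c, smi) in classified.items()}
        kept, removed = apply_exclusion_list(as_map, exclusion)
        classified = {cid: classified[cid] for cid in kept}
        excluded_ids = removed
    else:
        excluded_ids = []
    sets = split_sets(classified, n_train=n_train, seed=seed)
    sets.audit.update(
        {
            "hit_rate_filter": filter_audit,
            "profiles": len(profiles),
            "dropped_inconsistent": n_dropped_inconsistent,
            "missing_or_invalid_structure": n_missing_structure,
            "excluded_by_list": excluded_ids,
            "order_of_operations": [
                "hit_rate_filter", "consensus_profiles", "class_rules",
                "exclusion_list", "train_test_split",
            ],
        }
    )
    return sets


def classify_profiles(
    profiles: Iterable[ActivityProfile],
    thresholds: ClassThresholds = ClassThresholds(),
) -> dict[str, CompoundClass]:
    """Convenience: class per compound id for a batch of profiles."""
    return {p.compound_id: assign_class(p, thresholds) for p in profiles}
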