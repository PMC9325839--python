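"""Synthetic screening universe with a planted structure-promiscuity signal.

Real multi-target (promiscuous) compound sets come from large public
screening collections; at desk scale this module stands in for that
extraction. It assembles valid molecules by linking ring/chain fragments
with single bonds and plants a structural signal: compounds of the
``multi`` class contain at least one "promiscuity motif" fragment that
never occurs in the ``single`` or ``none`` classes. Assay records are then
emitted so that the curation rules (consensus outcomes, activity-count
thresholds) recover the planted classes.

Design notes
------------
* Fragments are written so that plain string concatenation yields valid
  SMILES: each fragment's first atom accepts one incoming bond and its last
  atom one outgoing bond. Ring-closure digits are remapped per slot so up
  to four ring fragments can be chained without digit collisions.
* Because concatenation never creates new rings, a ring motif occurs as a
  substructure if and only if its fragment was used -- motif exclusivity is
  structural, and is additionally verified with RDKit substructure matches.
* Activity counts per class straddle the curation thresholds (>=5 active
  targets for multi; 1 active + >=4 inactive for single; 0 active + >=5
  inactive for none), while total inactive records keep every per-target
  assay's hit rate safely below the 2% artifact filter.
* Optional "artifact" assays with ~50% hit rate are appended; the hit-rate
  filter is expected to remove them before consensus building.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import canonicalize

__all__ = [
    "FragmentLibrary",
    "UniverseConfig",
    "SyntheticCompound",
    "AssayRecord",
    "Universe",
    "NoSignalWarning",
    "default_library",
    "build_universe",
    "inject_noise",
    "write_smiles_file",
    "read_smiles_file",
    "write_assay_csv",
    "read_assay_csv",
]

CLASSES = ("multi", "single", "none")


class ConfigurationError(ValueError):
    """Invalid fragment library or universe configuration."""


class GenerationError(RuntimeError):
    """The requested class sizes cannot be reached from the fragment space."""


class NoSignalWarning(UserWarning):
    """Emitted when the universe is built without promiscuity motifs."""


@dataclass(frozen=True)
class FragmentLibrary:
    """Fragment SMILES pieces compounds are assembled from.

    ``promiscuity_motifs`` are reserved for the multi-target class;
    ``common_fragments`` are shared by all classes. ``linker_rules`` is the
    set of allowed fragment counts per compound (single-bond chain
    attachment, first-to-last atom).
    """

    promiscuity_motifs: tuple[str, ...]
    common_fragments: tuple[str, ...]
    linker_rules: tuple[int, ...] = (2, 3, 4)

    def __post_init__(self) -> None:
        for smi in (*self.promiscuity_motifs, *self.common_fragments):
            if Chem.MolFromSmiles(smi) is None:
                raise ConfigurationError(f"invalid fragment SMILES: {smi!r}")
            if any(ch in smi for ch in "3456789%"):
                raise ConfigurationError(
                    f"fragment {smi!r} may only use ring-closure digits 1-2"
                )
        motif_canon = {canonicalize(s) for s in self.promiscuity_motifs}
        common_canon = {canonicalize(s) for s in self.common_fragments}
        overlap = motif_canon & common_canon
        if overlap:
            raise ConfigurationError(f"motifs overlap common fragments: {overlap}")
        if max(self.linker_rules, default=0) > 4 or min(self.linker_rules, default=1) < 1:
            raise ConfigurationError("linker_rules must be within 1..4 fragments")


def default_library() -> FragmentLibrary:
    """Default fragment library: 4 S/O-heterocycle motifs + 14 common pieces.

    The motifs are the only source of furan, thiophene, thiazole and
    thiolane rings, so their substructures cannot arise in motif-free
    compounds.
    """
    return FragmentLibrary(
        promiscuity_motifs=(
            "c1ccoc1",   # furan
            "c1ccsc1",   # thiophene
            "c1ncsc1",   # 1,3-thiazole (C-attached)
            "C1CCSC1",   # thiolane
        ),
        common_fragments=(
            "c1ccccc1",  # benzene
            "c1ccncc1",  # pyridine
            "c1cncnc1",  # pyrimidine
            "C1CCCCC1",  # cyclohexane
            "C1CCCC1",   # cyclopentane
            "C1CCNCC1",  # piperidine
            "C1CCNC1",   # pyrrolidine
            "C1CC1",     # cyclopropane
            "CC",
            "CCC",
            "CO",
            "CN",
            "C(=O)N",
            "C=C",
        ),
    )


@dataclass(frozen=True)
class UniverseConfig:
    """Parameters of the synthetic screening universe.

    Class sizes default to the real-data imbalance (multi rarest) scaled to
    desk size. Activity-count ranges straddle the curation thresholds while
    keeping per-assay hit rates well below the 2% artifact cutoff.
    """

    n_multi: int
    n_single: int
    n_none: int
    seed: int
    n_targets: int = 40
    library: FragmentLibrary = field(default_factory=default_library)
    k_weights_multi: tuple[float, ...] = (0.4, 0.4, 0.2)
    k_weights_other: tuple[float, ...] = (0.15, 0.45, 0.4)
    multi_active: tuple[int, int] = (5, 8)
    multi_inactive: tuple[int, int] = (10, 16)
    single_active: int = 1
    single_inactive: tuple[int, int] = (25, 35)
    none_inactive: tuple[int, int] = (25, 35)
    n_artifact_assays: int = 2
    artifact_assay_size: int = 150
    artifact_hit_rate: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_multi, self.n_single, self.n_none) < 10:
            raise ConfigurationError("class sizes must each be >= 10")
        if self.seed is None or self.seed < 0:
            raise ConfigurationError("a non-negative seed is required")
        need = max(
            self.multi_active[1] + self.multi_inactive[1],
            self.single_active + self.single_inactive[1],
            self.none_inactive[1],
        )
        if self.n_targets < need:
            raise ConfigurationError(
                f"n_targets={self.n_targets} too small for activity ranges (need >= {need})"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["library"] = dataclasses.asdict(self.library)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "UniverseConfig":
        d = dict(d)
        lib = d.get("library")
        if isinstance(lib, dict):
            d["library"] = FragmentLibrary(
                promiscuity_motifs=tuple(lib["promiscuity_motifs"]),
                common_fragments=tuple(lib["common_fragments"]),
                linker_rules=tuple(lib.get("linker_rules", (2, 3, 4))),
            )
        for key in (
            "k_weights_multi", "k_weights_other", "multi_active",
            "multi_inactive", "single_inactive", "none_inactive",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticCompound:
    compound_id: str
    smiles: str  # canonical
    planted_class: str  # "multi" | "single" | "none"
    motif_ids: tuple[int, ...]  # indices into library.promiscuity_motifs


class AssayRecord(NamedTuple):
    assay_id: str
    compound_id: str
    target_id: str
    outcome: str  # "active" | "inactive"


class Universe(NamedTuple):
    compounds: list[SyntheticCompound]
    records: list[AssayRecord]


# ----------------------------------------------------------------------------
# Assembly

_DIGIT_MAPS = [str.maketrans("12", pair) for pair in ("12", "34", "56", "78")]


def _assemble(fragments: Sequence[str]) -> str:
    """Concatenate fragments into one SMILES, remapping ring digits per slot."""
    return "".join(frag.translate(_DIGIT_MAPS[i]) for i, frag in enumerate(fragments))


def _sample_compound(
    rng: np.random.Generator,
    library: FragmentLibrary,
    k_weights: Sequence[float],
    with_motif: bool,
) -> tuple[str, tuple[int, ...]] | None:
    ks = np.asarray(library.linker_rules[: len(k_weights)])
    k = int(rng.choice(ks, p=np.asarray(k_weights) / np.sum(k_weights)))
    idx = rng.integers(0, len(library.common_fragments), size=k)
    parts = [library.common_fragments[i] for i in idx]
    motif_ids: tuple[int, ...] = ()
    if with_motif:
        slot = int(rng.integers(0, k))
        m = int(rng.integers(0, len(library.promiscuity_motifs)))
        parts[slot] = library.promiscuity_motifs[m]
        motif_ids = (m,)
    smi = canonicalize(_assemble(parts))
    if smi is None:
        return None
    return smi, motif_ids


def _build_class(
    rng: np.random.Generator,
    config: UniverseConfig,
    cls: str,
    n: int,
    seen: set[str],
    motif_mols,
) -> list[SyntheticCompound]:
    k_weights = config.k_weights_multi if cls == "multi" else config.k_weights_other
    with_motif = cls == "multi" and len(config.library.promiscuity_motifs) > 0
    out: list[SyntheticCompound] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not assemble {n} unique '{cls}' compounds from the "
                f"fragment space (got {len(out)} after {attempts} attempts)"
            )
        drawn = _sample_compound(rng, config.library, k_weights, with_motif)
        if drawn is None:
            continue
        smi, motif_ids = drawn
        if smi in seen:
            continue
        if not with_motif and motif_mols:
            mol = Chem.MolFromSmiles(smi)
            if any(mol.HasSubstructMatch(m) for m in motif_mols):
                continue  # keep motifs exclusive to the multi class
        seen.add(smi)
        out.append(
            SyntheticCompound(
                compound_id=f"{cls[0].upper()}{len(out):05d}",
                smiles=smi,
                planted_class=cls,
                motif_ids=motif_ids,
            )
        )
    return out


def _emit_records(
    rng: np.random.Generator,
    config: UniverseConfig,
    compound: SyntheticCompound,
    active_load: np.ndarray,
) -> list[AssayRecord]:
    cls = compound.planted_class
    if cls == "multi":
        n_act = int(rng.integers(config.multi_active[0], config.multi_active[1] + 1))
        n_inact = int(rng.integers(config.multi_inactive[0], config.multi_inactive[1] + 1))
    elif cls == "single":
        n_act = config.single_active
        n_inact = int(rng.integers(config.single_inactive[0], config.single_inactive[1] + 1))
    else:
        n_act = 0
        n_inact = int(rng.integers(config.none_inactive[0], config.none_inactive[1] + 1))
    # Active targets are dealt to the least-loaded assays (random tie-break)
    # so per-assay hit rates stay tightly around the universe mean instead of
    # fluctuating across the artifact-filter cutoff.
    order = np.lexsort((rng.random(config.n_targets), active_load))
    act_targets = order[:n_act]
    active_load[act_targets] += 1
    remaining = np.setdiff1d(np.arange(config.n_targets), act_targets)
    inact_targets = rng.choice(remaining, size=n_inact, replace=False)
    records = []
    for t in act_targets:
        records.append(
            AssayRecord(f"A{t:02d}", compound.compound_id, f"T{t:02d}", "active")
        )
    for t in inact_targets:
        records.append(
            AssayRecord(f"A{t:02d}", compound.compound_id, f"T{t:02d}", "inactive")
        )
    return records


def _artifact_records(
    rng: np.random.Generator, config: UniverseConfig, compounds: Sequence[SyntheticCompound]
) -> list[AssayRecord]:
    """High hit-rate junk assays the 2% filter is expected to discard."""
    records: list[AssayRecord] = []
    n_comp = len(compounds)
    for a in range(config.n_artifact_assays):
        size = min(config.artifact_assay_size, n_comp)
        picked = rng.choice(n_comp, size=size, replace=False)
        for i in picked:
            t = int(rng.integers(0, config.n_targets))
            outcome = "active" if rng.random() < config.artifact_hit_rate else "inactive"
            records.append(
                AssayRecord(
                    assay_id=f"XA{a:02d}",
                    compound_id=compounds[i].compound_id,
                    target_id=f"T{t:02d}",
                    outcome=outcome,
                )
            )
    return records


def build_universe(config: UniverseConfig) -> Universe:
    """Assemble the synthetic compound classes and their assay records.

    Deterministic given ``config`` (including its seed). Emits a
    :class:`NoSignalWarning` when the library carries no promiscuity motifs,
    in which case downstream fine-tuning has no structural signal to learn.
    """
    if len(config.library.promiscuity_motifs) == 0:
        warnings.warn(
            "fragment library has no promiscuity motifs: the multi-target class "
            "carries no planted structural signal",
            NoSignalWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    motif_mols = [Chem.MolFromSmiles(s) for s in config.library.promiscuity_motifs]
    seen: set[str] = set()
    compounds: list[SyntheticCompound] = []
    for cls, n in zip(CLASSES, (config.n_multi, config.n_single, config.n_none)):
        compounds.extend(_build_class(rng, config, cls, n, seen, motif_mols))
    records: list[AssayRecord] = []
    active_load = np.zeros(config.n_targets, dtype=np.int64)
    for comp in compounds:
        records.extend(_emit_records(rng, config, comp, active_load))
    records.extend(_artifact_records(rng, config, compounds))
    return Universe(compounds=compounds, records=records)


def inject_noise(
    records: Sequence[AssayRecord], flip_rate: float, seed: int
) -> list[AssayRecord]:
    """Independently flip each record's outcome with probability ``flip_rate``.

    Reproducible from ``seed``: the i-th record is flipped iff the i-th
    uniform draw of ``numpy.random.default_rng(seed)`` falls below the rate.
    """
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError(f"flip_rate must be in [0, 1], got {flip_rate}")
    rng = np.random.default_rng(seed)
    flips = rng.random(len(records)) < flip_rate
    flipped = {"active": "inactive", "inactive": "active"}
    return [
        r._replace(outcome=flipped[r.outcome]) if flip else r
        for r, flip in zip(records, flips)
    ]


# ----------------------------------------------------------------------------
# I/O

def write_smiles_file(path, compounds: Iterable[SyntheticCompound] | Iterable[tuple[str, str]]) -> None:
    """Write one ``SMILES<TAB>compound_id`` line per compound."""
    with open(path, "w") as fh:
        for item in compounds:
            if isinstance(item, SyntheticCompound):
                fh.write(f"{item.smiles}\t{item.compound_id}\n")
            else:
                smi, cid = item
                fh.write(f"{smi}\t{cid}\n")


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read ``SMILES<TAB>compound_id`` lines; id defaults to the line number."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            out.append((parts[0], parts[1] if len(parts) > 1 else f"L{i}"))
    return out


def write_assay_csv(path, records: Sequence[AssayRecord]) -> None:
    pd.DataFrame(records, columns=AssayRecord._fields).to_csv(path, index=False)


def read_assay_csv(path) -> list[AssayRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = set(AssayRecord._fields) - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns: {sorted(missing)}")
    return [AssayRecord(*row) for row in df[list(AssayRecord._fields)].itertuples(index=False)]
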