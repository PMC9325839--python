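"""Molecular primitives: canonicalisation, SMILES randomisation, ECFP6
fingerprints, Tanimoto similarity and Bemis-Murcko scaffolds.

All structure handling is delegated to RDKit. Fingerprints are Morgan
circular fingerprints of radius 3 (bond diameter 6) hashed to a fixed
2048-bit vector, the standard "ECFP6/2048" setup for 2D similarity work.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

# Sampled batches contain many syntactically broken strings; parsing them is
# expected and must not spam stderr.
RDLogger.DisableLog("rdApp.error")

N_BITS = 2048
_morgan = GetMorganGenerator(radius=3, fpSize=N_BITS)

__all__ = [
    "N_BITS",
    "canonicalize",
    "canonicalize_many",
    "randomize_smiles",
    "ecfp6",
    "ecfp6_matrix",
    "ecfp6_rdkit",
    "tanimoto",
    "bm_scaffold",
]


def canonicalize(smiles: str) -> str | None:
    """Return the canonical SMILES, or ``None`` for an unparseable string.

    Never raises on invalid input so it can run over raw sampled batches;
    idempotent on valid input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def canonicalize_many(smiles: Iterable[str]) -> list[str | None]:
    """Vectorised :func:`canonicalize`; preserves order, ``None`` for failures."""
    return [canonicalize(s) for s in smiles]


def randomize_smiles(smiles: str, rng: np.random.Generator) -> str:
    """Return a random alternative SMILES spelling of the same molecule.

    The atom order is permuted and the string rewritten without
    canonicalisation, the usual data-augmentation trick for SMILES language
    models. ``canonicalize(randomize_smiles(s)) == canonicalize(s)`` always.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot randomize invalid SMILES: {smiles!r}")
    order = rng.permutation(mol.GetNumAtoms()).tolist()
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False)


def ecfp6_rdkit(smiles: str):
    """ECFP6/2048 as an RDKit ``ExplicitBitVect`` (fast bulk similarity path)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint invalid SMILES: {smiles!r}")
    return _morgan.GetFingerprint(mol)


def ecfp6(smiles: str) -> np.ndarray:
    """ECFP6/2048 fingerprint as a boolean numpy vector of length 2048."""
    fp = ecfp6_rdkit(smiles)
    arr = np.zeros(N_BITS, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr.astype(bool)


def ecfp6_matrix(smiles: Sequence[str]) -> np.ndarray:
    """Stack fingerprints for many molecules into an ``(n, 2048)`` bool matrix."""
    out = np.zeros((len(smiles), N_BITS), dtype=bool)
    for i, s in enumerate(smiles):
        out[i] = ecfp6(s)
    return out


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| between two bit vectors.

    Defined as 0.0 when both vectors are all-zero. Symmetric by construction.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def bm_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold (rings + linkers, side chains removed) as
    canonical SMILES; the empty string for acyclic molecules.

    Atom and bond types are retained (non-generic framework). Idempotent:
    the scaffold of a scaffold is itself.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot extract scaffold from invalid SMILES: {smiles!r}")
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(core)
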