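"""Topological fingerprints and Tanimoto drug–drug similarity (K1).

Drugs are compared through RDKit's path-based (topological) hashed
fingerprint; pairwise similarity is the Tanimoto coefficient
|A ∩ B| / |A ∪ B| over the fingerprint bit sets.  The resulting drug–drug
matrix K1 is the source of the drug similarity vectors fed to the CNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .core import Drug, SimilarityMatrix

__all__ = [
    "Fingerprint",
    "compute_fingerprint",
    "tanimoto",
    "drug_similarity_matrix",
]

DEFAULT_N_BITS = 2048
# RDKit topological fingerprint defaults: linear paths of 1..7 bonds.
MIN_PATH = 1
MAX_PATH = 7

RDLogger.DisableLog("rdApp.*")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint of a molecular graph."""

    bits: np.ndarray = field(repr=False)
    n_bits: int

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1 or bits.size != self.n_bits:
            raise ValueError("fingerprint bits must be a vector of length n_bits")

    @property
    def on_bits(self) -> int:
        return int(self.bits.sum())


def _parse_smiles(smiles: str, context: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" ({context})" if context else ""
        raise ValueError(f"unparseable SMILES {smiles!r}{where}")
    return mol


def compute_fingerprint(smiles: str, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    """Hash the linear atom paths of a molecule into an ``n_bits`` bit vector.

    Deterministic: the same molecular graph (regardless of SMILES atom
    ordering) always yields the same bits.
    """
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    mol = _parse_smiles(smiles)
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=MIN_PATH, maxPath=MAX_PATH, fpSize=n_bits
    )
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return Fingerprint(bits=bits, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two fingerprints.

    Two all-zero fingerprints are defined as identical (similarity 1.0);
    a warning is emitted because 0/0 is otherwise undefined.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}"
        )
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        warnings.warn(
            "Tanimoto of two all-zero fingerprints defined as 1.0",
            stacklevel=2,
        )
        return 1.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union


def drug_similarity_matrix(
    drugs: list[Drug], n_bits: int = DEFAULT_N_BITS
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix K1 over a drug roster.

    Only the upper triangle is computed; the diagonal is exactly 1.
    """
    if not drugs:
        raise ValueError("need at least one drug")
    fps = []
    for d in drugs:
        try:
            fps.append(compute_fingerprint(d.smiles, n_bits=n_bits))
        except ValueError as exc:
            raise ValueError(f"drug {d.drug_id!r}: {exc}") from exc
    n = len(drugs)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(tuple(d.drug_id for d in drugs), values)
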