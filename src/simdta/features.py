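"""Outer-product pair inputs built from similarity columns.

Each drug–target pair (i, j) is represented by the outer product
k_i1 ⊗ k_j2 of the drug's Tanimoto similarity column and the target's
normalized Smith–Waterman similarity column.  Because k_ii = 1, row i of
the grid reproduces the target similarity vector verbatim (and column j the
drug vector), so the grid carries both the bimodal interaction terms and
the raw unimodal profiles.

Similarity vectors are always defined against the *training* roster: in
cross-validation on a single dataset the similarity matrices are computed
once over all entities (every entity appears in training folds under the
fold-coverage constraint), while unseen case-study drugs or targets get
vectors against the training roster only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem, seqsim
from .core import Drug, SimilarityMatrix, Target
from .data import AffinityDataset, PairRecord

__all__ = [
    "SimilarityVector",
    "PairInput",
    "outer_product",
    "similarity_vector_for_drug",
    "similarity_vector_for_target",
    "build_pair_inputs",
    "pair_grid_array",
    "write_pair_grid",
]


@dataclass(frozen=True)
class SimilarityVector:
    """Similarities of one query entity against a reference roster."""

    values: np.ndarray = field(repr=False)
    roster_ids: tuple = ()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "roster_ids", tuple(self.roster_ids))
        if vals.ndim != 1 or vals.size != len(self.roster_ids):
            raise ValueError("values length must match roster_ids")
        if vals.size == 0:
            raise ValueError("similarity vector must be nonempty")
        if vals.min() < -1e-10 or vals.max() > 1 + 1e-10:
            raise ValueError("similarity values must lie in [0, 1]")


@dataclass(frozen=True)
class PairInput:
    """The n_d x n_t outer-product grid for one drug–target pair."""

    grid: np.ndarray = field(repr=False)
    drug_roster_ids: tuple = ()
    target_roster_ids: tuple = ()

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "drug_roster_ids", tuple(self.drug_roster_ids))
        object.__setattr__(self, "target_roster_ids", tuple(self.target_roster_ids))
        if grid.shape != (len(self.drug_roster_ids), len(self.target_roster_ids)):
            raise ValueError("grid shape must match roster lengths")


def outer_product(dv: SimilarityVector, tv: SimilarityVector) -> PairInput:
    """k1 ⊗ k2: grid[a, b] = dv[a] * tv[b]."""
    return PairInput(
        np.outer(dv.values, tv.values), dv.roster_ids, tv.roster_ids
    )


def similarity_vector_for_drug(
    query: Drug, roster: list[Drug], n_bits: int = chem.DEFAULT_N_BITS
) -> SimilarityVector:
    """Tanimoto similarities of ``query`` against each roster drug.

    Works identically for roster members (own position holds 1.0) and for
    unseen case-study compounds.
    """
    if not roster:
        raise ValueError("roster must be nonempty")
    try:
        qfp = chem.compute_fingerprint(query.smiles, n_bits=n_bits)
    except ValueError as exc:
        raise ValueError(f"drug {query.drug_id!r}: {exc}") from exc
    vals = np.empty(len(roster))
    for k, d in enumerate(roster):
        fp = chem.compute_fingerprint(d.smiles, n_bits=n_bits)
        vals[k] = chem.tanimoto(qfp, fp)
    return SimilarityVector(vals, tuple(d.drug_id for d in roster))


def similarity_vector_for_target(
    query: Target,
    roster: list[Target],
    scoring: seqsim.AlignmentScoring | None = None,
) -> SimilarityVector:
    """Normalized-SW similarities of ``query`` against each roster target."""
    if not roster:
        raise ValueError("roster must be nonempty")
    scoring = scoring or seqsim.default_scoring()
    vals = np.empty(len(roster))
    for k, t in enumerate(roster):
        vals[k] = seqsim.normalized_sw(query.sequence, t.sequence, scoring)
    return SimilarityVector(vals, tuple(t.target_id for t in roster))


def _check_rosters(ds: AffinityDataset, k1: SimilarityMatrix, k2: SimilarityMatrix):
    if k1.entity_ids != ds.drug_ids:
        raise ValueError("K1 roster does not match dataset drug roster")
    if k2.entity_ids != ds.target_ids:
        raise ValueError("K2 roster does not match dataset target roster")


def build_pair_inputs(
    ds: AffinityDataset,
    pairs: list[PairRecord],
    k1: SimilarityMatrix,
    k2: SimilarityMatrix,
) -> list[tuple[PairInput, float]]:
    """One (grid, affinity) training example per pair record."""
    _check_rosters(ds, k1, k2)
    out = []
    for p in pairs:
        grid = np.outer(k1.values[:, p.drug_index], k2.values[:, p.target_index])
        out.append(
            (PairInput(grid, ds.drug_ids, ds.target_ids), p.affinity)
        )
    return out


def pair_grid_array(
    ds: AffinityDataset,
    pairs: list[PairRecord],
    k1: SimilarityMatrix,
    k2: SimilarityMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (n, n_d, n_t) grid array and (n,) affinity vector.

    Equivalent to :func:`build_pair_inputs` but materialized as the dense
    arrays the estimator consumes.
    """
    _check_rosters(ds, k1, k2)
    n = len(pairs)
    X = np.empty((n, ds.n_drugs, ds.n_targets))
    y = np.empty(n)
    for m, p in enumerate(pairs):
        X[m] = np.outer(k1.values[:, p.drug_index], k2.values[:, p.target_index])
        y[m] = p.affinity
    return X, y


def write_pair_grid(pair: PairInput, path) -> None:
    """Dump one grid as dense whitespace-separated text (for inspection)."""
    np.savetxt(path, pair.grid, fmt="%.10g")
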