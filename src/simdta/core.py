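"""Core containers shared across the similarity, data and feature layers.

The package models a drug–target affinity study as three pieces: a roster of
drugs (SMILES), a roster of protein targets (amino-acid sequences), and a
partially observed affinity matrix over their Cartesian product.  Similarity
matrices over either roster are square, symmetric, unit-diagonal and bounded
in [0, 1]; those invariants are enforced at construction time so downstream
code can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Drug", "Target", "SimilarityMatrix", "read_similarity_csv"]


@dataclass(frozen=True)
class Drug:
    """A compound: stable identifier plus its SMILES string."""

    drug_id: str
    smiles: str


@dataclass(frozen=True)
class Target:
    """A protein target: stable identifier plus its amino-acid sequence."""

    target_id: str
    sequence: str


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix with unit diagonal over one roster.

    Parameters
    ----------
    entity_ids : tuple of str
        Ordered identifiers of the entities the rows/columns refer to.
    values : ndarray of shape (n, n)
        Pairwise similarities in [0, 1].
    """

    entity_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        ids = tuple(self.entity_ids)
        object.__setattr__(self, "entity_ids", ids)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValueError("similarity matrix entity ids must be unique")
        if vals.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {vals.shape} does not match "
                f"{n} entity ids"
            )
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-10):
            raise ValueError("similarity matrix diagonal must be 1.0")
        if vals.min() < -1e-10 or vals.max() > 1.0 + 1e-10:
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def column(self, entity_id: str) -> np.ndarray:
        """Similarity vector of one entity against the whole roster."""
        try:
            idx = self.entity_ids.index(entity_id)
        except ValueError:
            raise KeyError(f"unknown entity id {entity_id!r}") from None
        return self.values[:, idx].copy()

    def to_csv(self, path) -> None:
        """Write the full symmetric matrix as CSV with ids on both margins."""
        df = pd.DataFrame(
            self.values, index=list(self.entity_ids), columns=list(self.entity_ids)
        )
        df.to_csv(path, index_label="id")


def read_similarity_csv(path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("similarity CSV row and column ids differ")
    return SimilarityMatrix(tuple(df.index), df.to_numpy(dtype=float))
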