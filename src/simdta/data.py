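"""Dataset model, affinity-scale transforms, missingness and file I/O.

An :class:`AffinityDataset` couples a drug roster, a target roster and a
drugs x targets affinity matrix with an explicit observed mask.  Affinity
values live on a declared scale:

``Kd_nM``
    raw dissociation constants in nanomolar (lower = stronger binding);
``pKd``
    -log10(Kd / 1e9), so higher = stronger binding;
``KIBA_raw``
    integrated Kd/Ki/IC50 bioactivity scores (lower = stronger);
``KIBA_transformed``
    KIBA scores negated and shifted so the minimum is 0 and higher =
    stronger, the orientation used for model training.

Transforms are never applied implicitly by the loader; callers convert
explicitly with :func:`kd_to_pkd` / :func:`transform_kiba`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import Drug, SimilarityMatrix, Target

__all__ = [
    "SCALES",
    "AffinityDataset",
    "PairRecord",
    "kd_to_pkd",
    "transform_kiba",
    "impute_missing_affinity",
    "impute_dataset",
    "load_dataset",
    "write_dataset",
    "read_drug_table",
    "read_targets_fasta",
    "observed_pairs",
]

SCALES = ("Kd_nM", "pKd", "KIBA_raw", "KIBA_transformed")

MISSING_TOKENS = {"", ".", "NA"}


@dataclass(frozen=True)
class PairRecord:
    """One observed drug–target affinity measurement (dataset indices)."""

    drug_index: int
    target_index: int
    affinity: float


@dataclass(frozen=True)
class AffinityDataset:
    drugs: tuple
    targets: tuple
    y: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    scale: str = "pKd"

    def __post_init__(self):
        drugs = tuple(self.drugs)
        targets = tuple(self.targets)
        object.__setattr__(self, "drugs", drugs)
        object.__setattr__(self, "targets", targets)
        y = np.asarray(self.y, dtype=float)
        obs = np.asarray(self.observed, dtype=bool)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "observed", obs)
        if self.scale not in SCALES:
            raise ValueError(f"unknown affinity scale {self.scale!r}")
        shape = (len(drugs), len(targets))
        if y.shape != shape or obs.shape != shape:
            raise ValueError(
                f"y {y.shape} and observed {obs.shape} must both be {shape}"
            )
        d_ids = [d.drug_id for d in drugs]
        t_ids = [t.target_id for t in targets]
        if len(set(d_ids)) != len(d_ids):
            raise ValueError("duplicate drug ids")
        if len(set(t_ids)) != len(t_ids):
            raise ValueError("duplicate target ids")
        if not obs.any():
            raise ValueError("dataset has no observed affinities")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def density(self) -> float:
        """Fraction of drug–target cells with an observed affinity."""
        return float(self.observed.sum()) / self.observed.size

    @property
    def drug_ids(self) -> tuple:
        return tuple(d.drug_id for d in self.drugs)

    @property
    def target_ids(self) -> tuple:
        return tuple(t.target_id for t in self.targets)

    def with_scale(self, y: np.ndarray, scale: str) -> "AffinityDataset":
        return replace(self, y=y, scale=scale)


def kd_to_pkd(kd):
    """Convert Kd in nM to pKd = -log10(Kd / 1e9).

    10,000 nM maps to 5.0; 1 nM maps to 9.0.  Accepts scalars or arrays.
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("Kd must be positive (nM)")
    out = -np.log10(kd / 1e9)
    return float(out) if out.ndim == 0 else out


def transform_kiba(scores):
    """Reorient raw KIBA scores so higher means stronger binding.

    Three steps: negate every score, find the minimum of the negatives,
    and add its absolute value to all.  The minimum output is exactly 0
    and the ordering is reversed (low raw KIBA -> high transformed value).
    The shift is a property of the score set being transformed, so any
    threshold stated on the raw scale moves with the shift.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("transform_kiba needs at least one score")
    neg = -arr
    return neg + abs(neg.min())


def impute_missing_affinity(affinities, weights) -> float:
    """Similarity-weighted mean of a drug's observed affinities.

    ``weights`` are the normalized Smith–Waterman similarities between the
    target whose cell is missing and the targets with observed affinities
    for this drug.  Falls back to the plain mean (with a warning) if every
    weight is zero.
    """
    a = np.asarray(affinities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one observed affinity")
    if a.shape != w.shape:
        raise ValueError("affinities and weights must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        warnings.warn("all similarity weights zero; using unweighted mean",
                      stacklevel=2)
        return float(a.mean())
    return float((w * a).sum() / total)


def impute_dataset(ds: AffinityDataset, k2: SimilarityMatrix) -> AffinityDataset:
    """Fill every missing cell with the weighted average of that drug's
    observed affinities, weighted by target–target similarity.

    Provided as an optional preprocessing utility; model training itself
    uses observed pairs only.  Drugs with no observation at all stay
    missing.
    """
    if k2.entity_ids != ds.target_ids:
        raise ValueError("K2 roster does not match dataset targets")
    y = ds.y.copy()
    obs = ds.observed.copy()
    for i in range(ds.n_drugs):
        row_obs = np.flatnonzero(ds.observed[i])
        if row_obs.size == 0:
            continue
        for j in np.flatnonzero(~ds.observed[i]):
            y[i, j] = impute_missing_affinity(
                ds.y[i, row_obs], k2.values[j, row_obs]
            )
            obs[i, j] = True
    return replace(ds, y=y, observed=obs)


def observed_pairs(ds: AffinityDataset) -> list[PairRecord]:
    """One record per observed cell, row-major (drug-major) order."""
    rows, cols = np.nonzero(ds.observed)
    return [
        PairRecord(int(i), int(j), float(ds.y[i, j])) for i, j in zip(rows, cols)
    ]


def read_drug_table(path) -> list[Drug]:
    """Read a drug table (TSV or CSV) with columns ``drug_id``, ``smiles``."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "drug_id" not in cols or "smiles" not in cols:
        raise ValueError(
            f"{path}: drug table must have 'drug_id' and 'smiles' columns, "
            f"got {list(df.columns)}"
        )
    drugs = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        did = getattr(row, cols["drug_id"]) if hasattr(row, cols["drug_id"]) else row[0]
        smi = getattr(row, cols["smiles"]) if hasattr(row, cols["smiles"]) else row[1]
        if pd.isna(did) or pd.isna(smi):
            raise ValueError(f"{path} row {row_no}: empty drug_id or smiles")
        drugs.append(Drug(str(did).strip(), str(smi).strip()))
    ids = [d.drug_id for d in drugs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate drug ids {dup}")
    return drugs


def read_targets_fasta(path) -> list[Target]:
    targets = [
        Target(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not targets:
        raise ValueError(f"{path}: no FASTA records found")
    ids = [t.target_id for t in targets]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate target ids {dup}")
    return targets


def _read_affinity_csv(path, drug_ids, target_ids):
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(i).strip() for i in df.index]
    col_ids = [str(c).strip() for c in df.columns]
    if set(row_ids) != set(drug_ids):
        raise ValueError(
            f"{path}: affinity matrix row ids do not match the drug roster"
        )
    if set(col_ids) != set(target_ids):
        raise ValueError(
            f"{path}: affinity matrix column ids do not match the target roster"
        )
    df.index = row_ids
    df.columns = col_ids
    df = df.loc[list(drug_ids), list(target_ids)]
    y = np.zeros(df.shape)
    obs = np.zeros(df.shape, dtype=bool)
    for i, did in enumerate(drug_ids):
        for j, tid in enumerate(target_ids):
            cell = df.iat[i, j].strip()
            if cell in MISSING_TOKENS:
                y[i, j] = np.nan
                continue
            try:
                y[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric affinity {cell!r} at "
                    f"drug {did!r} / target {tid!r}"
                ) from None
            obs[i, j] = True
    return y, obs


def load_dataset(drug_table_path, fasta_path, affinity_csv_path,
                 scale: str = "pKd") -> AffinityDataset:
    """Assemble an :class:`AffinityDataset` from the three canonical files.

    The affinity CSV has target ids on the first row and drug ids in the
    first column; empty cells (also ``.`` and ``NA``) are missing.  The
    declared ``scale`` is recorded verbatim — no transform is applied.
    """
    drugs = read_drug_table(drug_table_path)
    targets = read_targets_fasta(fasta_path)
    y, obs = _read_affinity_csv(
        affinity_csv_path, [d.drug_id for d in drugs], [t.target_id for t in targets]
    )
    return AffinityDataset(tuple(drugs), tuple(targets), y, obs, scale)


def write_dataset(ds: AffinityDataset, out_dir) -> dict:
    """Write the three canonical files; returns the paths written.

    Values are written with Python's shortest round-trip float repr so a
    write/read cycle is bit-identical for finite inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drug_path = out / "drugs.tsv"
    fasta_path = out / "targets.fasta"
    aff_path = out / "affinities.csv"
    with open(drug_path, "w") as fh:
        fh.write("drug_id\tsmiles\n")
        for d in ds.drugs:
            fh.write(f"{d.drug_id}\t{d.smiles}\n")
    with open(fasta_path, "w") as fh:
        for t in ds.targets:
            fh.write(f">{t.target_id}\n")
            seq = t.sequence
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")
    with open(aff_path, "w") as fh:
        fh.write("drug_id," + ",".join(ds.target_ids) + "\n")
        for i, did in enumerate(ds.drug_ids):
            cells = [
                repr(float(ds.y[i, j])) if ds.observed[i, j] else ""
                for j in range(ds.n_targets)
            ]
            fh.write(did + "," + ",".join(cells) + "\n")
    return {"drugs": drug_path, "targets": fasta_path, "affinities": aff_path}
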