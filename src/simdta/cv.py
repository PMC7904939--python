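"""Coverage-constrained k-fold cross-validation over observed pairs.

Folds partition the observed drug–target pairs, with the extra constraint
that every target's observations span at least ``min_folds_per_target``
distinct folds (2 for threefold CV, 4 for fivefold), so no target is seen
only in training or only in testing.  Targets with fewer observations than
the constraint simply span all the folds they can.

Construction: for each target (visited in seeded random order) its pairs
are dealt round-robin into a random fold ordering, which satisfies the
coverage constraint by construction; a rebalancing pass then moves pairs
out of overfull folds whenever the move cannot reduce any target's fold
spread (the pair's target must occupy the source fold more than once).
The whole procedure is deterministic under the seed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chem, seqsim
from .data import AffinityDataset, PairRecord, observed_pairs
from .features import pair_grid_array
from .metrics import MetricReport, evaluate, summarize_reports
from .model import ModelConfig, SimCNNRegressor

__all__ = ["FoldAssignment", "build_folds", "run_cv",
           "write_folds_csv", "read_folds_csv"]


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of_pair: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self):
        folds = np.asarray(self.fold_of_pair, dtype=int)
        object.__setattr__(self, "fold_of_pair", folds)
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if folds.min(initial=0) < 0 or folds.max(initial=0) >= self.k:
            raise ValueError("fold labels out of range")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_pair == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_pair != fold)


def default_min_folds(k: int) -> int:
    # 2 for threefold, 4 for fivefold; k-1 generalizes both
    return k - 1


def build_folds(
    pairs: list[PairRecord],
    k: int,
    min_folds_per_target: int | None = None,
    seed: int = 0,
) -> FoldAssignment:
    """Assign each observed pair to one of k folds under the target-coverage
    constraint; deterministic given the seed."""
    n = len(pairs)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot build {k} folds from {n} pairs")
    if min_folds_per_target is None:
        min_folds_per_target = default_min_folds(k)
    if min_folds_per_target > k:
        raise ValueError("min_folds_per_target cannot exceed k")
    rng = np.random.default_rng(seed)

    by_target: dict[int, list[int]] = {}
    for idx, p in enumerate(pairs):
        by_target.setdefault(p.target_index, []).append(idx)

    assignment = np.full(n, -1, dtype=int)
    targets = sorted(by_target)
    rng.shuffle(targets)
    for t in targets:
        idxs = np.array(by_target[t])
        rng.shuffle(idxs)
        fold_order = rng.permutation(k)
        for pos, idx in enumerate(idxs):
            assignment[idx] = fold_order[pos % k]

    _rebalance(assignment, pairs, k, rng)
    return FoldAssignment(k, assignment, seed)


def _rebalance(assignment, pairs, k, rng):
    """Move pairs from overfull to underfull folds without ever reducing a
    target's fold spread (only pairs whose target occupies the source fold
    at least twice may move)."""
    n = len(pairs)
    target_of = np.array([p.target_index for p in pairs])
    for _ in range(4 * k):  # a few passes suffice; bounded for determinism
        sizes = np.bincount(assignment, minlength=k)
        lo, hi = sizes.argmin(), sizes.argmax()
        if sizes[hi] - sizes[lo] <= 1:
            return
        moved = False
        candidates = np.flatnonzero(assignment == hi)
        rng.shuffle(candidates)
        for idx in candidates:
            t = target_of[idx]
            in_src = np.sum((assignment == hi) & (target_of == t))
            if in_src >= 2:
                assignment[idx] = lo
                moved = True
                break
        if not moved:
            return


def target_fold_spread(pairs: list[PairRecord], fa: FoldAssignment) -> dict:
    """Number of distinct folds each target's observations occupy."""
    spread: dict[int, set] = {}
    for idx, p in enumerate(pairs):
        spread.setdefault(p.target_index, set()).add(int(fa.fold_of_pair[idx]))
    return {t: len(s) for t, s in spread.items()}


def write_folds_csv(ds: AffinityDataset, pairs, fa: FoldAssignment, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["drug_id", "target_id", "fold"])
        for idx, p in enumerate(pairs):
            w.writerow([
                ds.drugs[p.drug_index].drug_id,
                ds.targets[p.target_index].target_id,
                int(fa.fold_of_pair[idx]),
            ])


def read_folds_csv(ds: AffinityDataset, pairs, path) -> FoldAssignment:
    lookup = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lookup[(row["drug_id"], row["target_id"])] = int(row["fold"])
    assignment = np.empty(len(pairs), dtype=int)
    for idx, p in enumerate(pairs):
        key = (ds.drugs[p.drug_index].drug_id, ds.targets[p.target_index].target_id)
        if key not in lookup:
            raise ValueError(f"fold file missing pair {key}")
        assignment[idx] = lookup[key]
    return FoldAssignment(int(assignment.max()) + 1, assignment)


def run_cv(
    ds: AffinityDataset,
    k: int,
    cfg: ModelConfig | None = None,
    threshold: float | None = None,
    positive_is_high: bool = True,
    seed: int = 0,
    scoring: seqsim.AlignmentScoring | None = None,
    n_bits: int = chem.DEFAULT_N_BITS,
    min_folds_per_target: int | None = None,
):
    """k-fold CV of the CNN on one dataset.

    Similarity matrices are computed once over the full rosters (every
    entity appears in training folds under the coverage constraint).  Each
    fold trains on the out-of-fold pairs and is evaluated on the held-out
    fold.  Returns ``(reports, summary, fold_assignment)`` where summary
    holds per-metric mean and standard error across folds.
    """
    from dataclasses import asdict, replace

    cfg = cfg or ModelConfig()
    if threshold is None:
        threshold = 12.1 if ds.scale == "KIBA_transformed" else 7.0
    pairs = observed_pairs(ds)
    if len(pairs) < k:
        raise ValueError("fewer observed pairs than folds")
    k1 = chem.drug_similarity_matrix(list(ds.drugs), n_bits=n_bits)
    k2 = seqsim.target_similarity_matrix(list(ds.targets), scoring=scoring)
    X, y = pair_grid_array(ds, pairs, k1, k2)
    fa = build_folds(pairs, k, min_folds_per_target=min_folds_per_target, seed=seed)

    reports: list[MetricReport] = []
    for fold in range(k):
        tr = fa.train_indices(fold)
        te = fa.test_indices(fold)
        if te.size == 0:
            warnings.warn(f"fold {fold} is empty; skipped", stacklevel=2)
            continue
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        est = SimCNNRegressor(**asdict(fold_cfg)).fit(X[tr], y[tr])
        yhat = est.predict(X[te])
        reports.append(evaluate(y[te], yhat, threshold, positive_is_high))
    return reports, summarize_reports(reports), fa
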