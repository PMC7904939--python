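"""Regression evaluation statistics: MSE, concordance index, r_m², AUPR.

The concordance index (CI) is the probability that, for two randomly drawn
pairs with different measured affinities, the predictions are ordered the
same way:

    CI = (1/Z) * sum_{y_i > y_j} h(yhat_i - yhat_j)

with h(x) = 1, 0.5, 0 for x > 0, x = 0, x < 0 and Z the number of strictly
ordered label pairs (label ties contribute to neither side — the standard
survival-analysis convention).

The modified squared correlation r_m² = r² * (1 - sqrt(|r² - r0²|)) compares
the least-squares fit of predictions on observations with intercept (r²,
i.e. the squared Pearson correlation) against the fit through the origin
(r0²).  Observed values sit on the abscissa, predictions on the ordinate,
and the absolute value guards the root when r0² exceeds r²; models with
r_m² > 0.5 on test data are conventionally deemed acceptable.

AUPR binarizes affinities at a threshold (pKd 7.0 for Kd-derived data,
12.1 on the transformed KIBA scale) and integrates the precision–recall
curve step-wise (average precision); tied prediction scores share one PR
point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

__all__ = [
    "MetricReport",
    "mse",
    "concordance_index",
    "rm_squared",
    "aupr",
    "evaluate",
    "summarize_reports",
    "write_reports_csv",
    "write_summary_json",
    "PKD_THRESHOLD",
    "KIBA_THRESHOLD",
]

PKD_THRESHOLD = 7.0
KIBA_THRESHOLD = 12.1


@dataclass(frozen=True)
class MetricReport:
    """The four evaluation statistics for one scored pair set."""

    mse: float
    ci: float
    rm2: float
    aupr: float  # NaN when the binarized labels are single-class
    n: int


def _check_xy(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return y, yhat


def mse(y, yhat) -> float:
    """Mean squared error."""
    y, yhat = _check_xy(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def concordance_index(y, yhat) -> float:
    """Pairwise concordance of predicted vs measured ordering (in [0, 1])."""
    y, yhat = _check_xy(y, yhat)
    if y.size < 2:
        raise ValueError("concordance index needs at least two pairs")
    dy = y[:, None] - y[None, :]
    dyh = yhat[:, None] - yhat[None, :]
    ordered = dy > 0  # ordered label pairs (i, j) with y_i > y_j
    z = int(ordered.sum())
    if z == 0:
        raise ValueError("all affinity labels tied; concordance undefined")
    h = np.where(dyh > 0, 1.0, np.where(dyh == 0, 0.5, 0.0))
    return float(h[ordered].sum() / z)


def rm_squared(y, yhat) -> float:
    """Modified squared correlation r² * (1 - sqrt(|r² - r0²|))."""
    y, yhat = _check_xy(y, yhat)
    if y.size < 3:
        raise ValueError("r_m^2 needs at least three pairs")
    sst = float(((yhat - yhat.mean()) ** 2).sum())
    if sst == 0 or np.allclose(y, y.mean()):
        raise ValueError("zero variance; r_m^2 undefined")
    r = np.corrcoef(y, yhat)[0, 1]
    r2 = float(r * r)
    # through-origin fit of predictions (ordinate) on observations (abscissa)
    k = float((y * yhat).sum() / (y * y).sum())
    ss_res0 = float(((yhat - k * y) ** 2).sum())
    r0_2 = 1.0 - ss_res0 / sst
    return r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))


def aupr(y, yhat, threshold: float, positive_is_high: bool = True) -> float:
    """Area under the precision–recall curve after binarizing ``y``.

    A pair is positive when its affinity is >= threshold (or <= threshold
    when ``positive_is_high`` is false, for raw-Kd-like scales); predictions
    are ranked on the matching orientation.
    """
    y, yhat = _check_xy(y, yhat)
    if positive_is_high:
        labels = y >= threshold
        scores = yhat
    else:
        labels = y <= threshold
        scores = -yhat
    if labels.all() or not labels.any():
        raise ValueError(
            "binarized labels are single-class; AUPR undefined"
        )
    return float(average_precision_score(labels, scores))


def evaluate(y, yhat, threshold: float, positive_is_high: bool = True) -> MetricReport:
    """All four statistics for one (measured, predicted) pair set.

    AUPR is reported as NaN (with a warning) when the binarized labels are
    single-class, e.g. a small CV fold with no strong binder; r_m² likewise
    when either vector is constant.
    """
    y, yhat = _check_xy(y, yhat)
    try:
        pr = aupr(y, yhat, threshold, positive_is_high)
    except ValueError as exc:
        warnings.warn(f"AUPR skipped: {exc}", stacklevel=2)
        pr = float("nan")
    try:
        rm2 = rm_squared(y, yhat)
    except ValueError as exc:
        warnings.warn(f"r_m^2 skipped: {exc}", stacklevel=2)
        rm2 = float("nan")
    return MetricReport(
        mse=mse(y, yhat),
        ci=concordance_index(y, yhat),
        rm2=rm2,
        aupr=pr,
        n=int(y.size),
    )


def summarize_reports(reports: list[MetricReport]) -> dict:
    """Mean and standard error of each metric over CV folds (NaN-aware)."""
    out = {}
    for name in ("mse", "ci", "rm2", "aupr"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[name] = {"mean": float("nan"), "se": float("nan"), "k": 0}
            continue
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[name] = {"mean": float(vals.mean()), "se": se, "k": int(vals.size)}
    return out


def write_reports_csv(reports: list[MetricReport], path) -> None:
    """One row per fold per metric, long format."""
    rows = []
    for fold, r in enumerate(reports):
        for name, value in asdict(r).items():
            if name == "n":
                continue
            rows.append({"fold": fold, "metric": name, "value": value, "n": r.n})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, allow_nan=True)
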