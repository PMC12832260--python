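"""Parameter-recovery indices and cross-iteration quantile trimming.

The error-based indices use the n-divisor (population) convention for the
error SD, which yields the exact decomposition ``rmse^2 = bias^2 + see^2``.
Pearson r is computed on raw values and flagged undefined (NaN) when either
vector has zero variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "RecoveryIndices",
    "INDEX_NAMES",
    "compute_indices",
    "trim_bounds",
    "trim_iterations",
    "trimmed_mean",
    "summarize",
]

INDEX_NAMES = ("r", "bias", "rmse", "mae", "see")


@dataclass(frozen=True)
class RecoveryIndices:
    """Agreement between true and estimated values of one parameter.

    ``r`` is NaN when undefined (zero variance in either vector); the four
    error-based indices are always defined for finite inputs.
    """

    r: float
    bias: float
    rmse: float
    mae: float
    see: float
    parameter: str = ""
    n_used: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def compute_indices(true_values, est_values, parameter: str = "") -> RecoveryIndices:
    """Compute r, bias, RMSE, MAE and SEE between paired vectors."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(est_values, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError(f"true and estimated vectors must be equal-length 1-D, got {t.shape} vs {e.shape}")
    if t.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(e))):
        raise ValueError("inputs must be finite")
    err = e - t
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.abs(err).mean())
    see = float(err.std())  # n-divisor: rmse^2 = bias^2 + see^2 exactly
    if t.std() == 0 or e.std() == 0:
        r = math.nan
    else:
        r = float(np.corrcoef(t, e)[0, 1])
    return RecoveryIndices(r=r, bias=bias, rmse=rmse, mae=mae, see=see,
                           parameter=parameter, n_used=t.size)


def trim_bounds(values, alpha: float = 0.025) -> Tuple[float, float]:
    """Nearest-rank trimming thresholds: the values at 1-based ranks
    ``floor(alpha*n) + 1`` and ``n - floor(alpha*n)`` of the finite entries."""
    if not 0.0 <= alpha < 0.5:
        raise ValueError(f"alpha must lie in [0, 0.5), got {alpha}")
    v = np.asarray(values, dtype=float)
    vf = np.sort(v[np.isfinite(v)])
    if vf.size == 0:
        raise ValueError("no finite values to trim")
    k = int(math.floor(alpha * vf.size))
    return float(vf[k]), float(vf[vf.size - 1 - k])


def trim_iterations(values, alpha: float = 0.025, bounds: Optional[Tuple[float, float]] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Drop each tail's ``floor(alpha * n)`` most extreme values.

    Values strictly outside the nearest-rank thresholds of
    :func:`trim_bounds` are removed, so at most ``ceil(alpha*n)`` values go
    per tail; passing the same precomputed ``bounds`` again removes nothing
    (trimming is idempotent under fixed thresholds).  NaNs are always
    removed.  Returns ``(retained_values, keep_mask)`` with the mask
    aligned to the input.
    """
    if not 0.0 <= alpha < 0.5:
        raise ValueError(f"alpha must lie in [0, 0.5), got {alpha}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no finite values to trim")
    mask = finite.copy()
    if alpha > 0 or bounds is not None:
        lo, hi = bounds if bounds is not None else trim_bounds(v, alpha)
        mask &= (v >= lo) & (v <= hi)
    return v[mask], mask


def trimmed_mean(values, alpha: float = 0.025) -> float:
    retained, _ = trim_iterations(values, alpha)
    return float(retained.mean())


def summarize(
    records: pd.DataFrame,
    factors: Sequence[str] = ("method", "model", "c", "aip", "tss", "n"),
    parameters: Sequence[str] = ("a", "b", "theta"),
    alpha: float = 0.025,
) -> pd.DataFrame:
    """Factor-level mean recovery indices after per-cell trimming.

    ``records`` is the long-format iteration table (one row per iteration x
    model x method x parameter, columns for the scenario factors and the
    five indices).  For each parameter, factor and factor level, every
    index is trimmed across the matching records and averaged; a marginal
    ``Total`` row per parameter repeats the computation over all records.
    Cells with no finite values are reported as NaN with ``n_retained = 0``
    rather than dropped.
    """
    missing = [col for col in list(parameters and ["parameter"]) + list(INDEX_NAMES) if col not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns: {missing}")
    rows = []
    for param in parameters:
        sub = records[records["parameter"] == param]
        for factor in factors:
            if factor not in records.columns:
                raise ValueError(f"unknown factor column {factor!r}")
            for level, group in sub.groupby(factor, sort=True):
                rows.append(_summary_row(param, factor, level, group, alpha))
        rows.append(_summary_row(param, "Total", "-", sub, alpha))
    return pd.DataFrame(rows)


def _summary_row(param, factor, level, group: pd.DataFrame, alpha: float) -> dict:
    row = {"parameter": param, "factor": factor, "level": level, "n_total": len(group)}
    n_ret = 0
    for index in INDEX_NAMES:
        vals = group[index].to_numpy(dtype=float)
        if vals.size == 0 or not np.isfinite(vals).any():
            row[index] = math.nan
        else:
            retained, mask = trim_iterations(vals, alpha)
            row[index] = float(retained.mean())
            n_ret = max(n_ret, int(mask.sum()))
    row["n_retained"] = n_ret
    return row
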