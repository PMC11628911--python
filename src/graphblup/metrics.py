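"""Prediction-accuracy metrics for cross-validated genomic prediction.

APC (Pearson correlation), NRMSE (RMSE over the sample SD of the
observed test values), MAAPE (mean arctan absolute percentage error,
bounded in [0, pi/2]), and Best20 (percentage of the truly best
top-fraction lines recovered among the predicted top fraction).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

__all__ = ["pearson", "nrmse", "maape", "best20"]


def pearson(y, yhat) -> float:
    """Sample Pearson correlation; NaN (with a warning) if either side is constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(y) == 0 or np.std(yhat) == 0:
        warnings.warn("zero variance: Pearson correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(y, yhat).statistic)


def nrmse(y, yhat) -> float:
    """RMSE normalised by the sample (ddof=1) standard deviation of y."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("zero variance in observed values")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / sd)


def maape(y, yhat) -> float:
    """Mean arctan(|relative error|); a zero observation contributes pi/2."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ape = np.abs((y - yhat) / y)
    terms = np.arctan(ape)
    # y == 0: arctan(inf) = pi/2 unless the prediction is also exactly 0
    zero = y == 0
    terms[zero & (yhat != 0)] = math.pi / 2
    terms[zero & (yhat == 0)] = 0.0
    return float(terms.mean())


def best20(y, yhat, top_fraction: float = 0.20, direction: str = "larger_is_better") -> float:
    """Percentage of the truly best ceil(fraction*m) lines found in the
    predicted best set of the same size."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 values for a non-trivial top fraction")
    m = math.ceil(top_fraction * y.size)
    sign = -1.0 if direction == "larger_is_better" else 1.0
    if direction not in ("larger_is_better", "smaller_is_better"):
        raise ValueError(f"unknown direction {direction!r}")
    top_obs = set(np.argsort(sign * y, kind="stable")[:m].tolist())
    top_pred = set(np.argsort(sign * yhat, kind="stable")[:m].tolist())
    return 100.0 * len(top_obs & top_pred) / m
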