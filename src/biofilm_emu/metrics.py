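"""Validation metrics for held-out emulator performance."""
from __future__ import annotations

import numpy as np


def _check(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 values")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean squared error."""
    y_true, y_pred = _check(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def variance_explained(y_true, y_pred) -> float:
    """Percentage of variance explained, 100 * (1 - SSE / SST).

    Penalizes bias as well as scatter; can be negative for predictions
    worse than the mean.
    """
    y_true, y_pred = _check(y_true, y_pred)
    sst = np.sum((y_true - y_true.mean()) ** 2)
    if sst == 0:
        raise ValueError("y_true has zero variance; variance explained undefined")
    sse = np.sum((y_true - y_pred) ** 2)
    return float(100.0 * (1.0 - sse / sst))


def squared_correlation(y_true, y_pred) -> float:
    """100 * r^2, the correlation-based variant of variance explained."""
    y_true, y_pred = _check(y_true, y_pred)
    if y_true.std() == 0 or y_pred.std() == 0:
        raise ValueError("zero-variance input to correlation")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    return float(100.0 * r**2)


def interval_coverage(y_true, lower, upper) -> float:
    """Fraction of observations inside [lower, upper]."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    lower = np.asarray(lower, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    return float(np.mean((y_true >= lower) & (y_true <= upper)))
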