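"""Quadratic feature expansion for the Poisson count emulator.

The exponential-mean of the count model is quadratic in the raw
covariates: log lambda_k = sum_{i<=j} beta_{ij} x_ik x_jk with x_0 = 1, so
for p raw covariates the basis has 1 + p + p(p+1)/2 columns (intercept,
linear, squared and pairwise-interaction terms).  For the six detachment
covariates (time, particle count, shear rate, EPS composition, height,
mass) that is 28 columns.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def quadratic_labels(p: int) -> list[tuple[int, int]]:
    """Column labels (i, j), i <= j, with index 0 the constant term.

    Order: (0,0), (0,1) ... (0,p), (1,1), (1,2) ... (p,p).
    """
    labels = [(0, j) for j in range(p + 1)]
    for i in range(1, p + 1):
        for j in range(i, p + 1):
            labels.append((i, j))
    return labels


@dataclass
class QuadraticBasis:
    """Expanded design matrix for the quadratic log-linear count model."""

    x: np.ndarray  # raw inputs, n x p
    matrix: np.ndarray  # expanded, n x q
    labels: list[tuple[int, int]]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def build_quadratic_features(x: np.ndarray) -> QuadraticBasis:
    """Expand raw inputs into the quadratic basis.

    Parameters
    ----------
    x : ndarray, shape (n, p)
        Raw covariate rows; must be finite.

    Returns
    -------
    QuadraticBasis
        With ``matrix`` of shape (n, 1 + p + p(p+1)/2) in the fixed label
        order; the (0, 0) column is identically 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 1:
        raise ValueError("need at least one input row")
    bad = ~np.isfinite(x)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"non-finite input in row {row}")
    n, p = x.shape
    labels = quadratic_labels(p)
    xe = np.hstack([np.ones((n, 1)), x])  # x_0 = 1
    cols = [xe[:, i] * xe[:, j] for i, j in labels]
    return QuadraticBasis(x=x, matrix=np.column_stack(cols), labels=labels)
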