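"""Latin hypercube designs over the simulator parameter space."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .config import PARAM_NAMES, default_ranges


@dataclass
class DesignMatrix:
    """An n-point design over the seven simulator parameters.

    ``points`` holds one column per parameter in canonical order; each
    column of a Latin hypercube has exactly one sample per equal-width
    stratum of its [low, high] range.
    """

    points: pd.DataFrame
    ranges: dict[str, tuple[float, float]]
    seed: int

    @property
    def n(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    @staticmethod
    def read_csv(path, ranges=None, seed: int = -1) -> "DesignMatrix":
        points = pd.read_csv(path)
        if ranges is None:
            ranges = {
                c: (points[c].min(), points[c].max()) for c in points.columns
            }
        return DesignMatrix(points=points, ranges=dict(ranges), seed=seed)


def latin_hypercube_design(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> DesignMatrix:
    """Draw an n-point Latin hypercube design.

    Each parameter range is split into n equal-width strata and exactly one
    point is sampled uniformly within each stratum, with strata randomly
    matched across parameters.

    Parameters
    ----------
    n : int
        Number of design points (>= 1).
    ranges : dict, optional
        Mapping parameter name -> (low, high).  Defaults to +/-50% of the
        reference simulator values.  Any mapping defines the parameter set
        and column order, so designs over other spaces are possible.
    seed : int
        Seed for the scrambled-stratum sampler; fixed seed gives an
        identical design.
    """
    if n < 1:
        raise ValueError("number of design points n must be >= 1")
    if ranges is None:
        ranges = default_ranges()
    names = list(ranges)
    for name in names:
        low, high = ranges[name]
        if not low < high:
            raise ValueError(
                f"inverted or empty range for parameter {name!r}: "
                f"[{low}, {high}]"
            )
    sampler = qmc.LatinHypercube(d=len(names), seed=np.random.default_rng(seed))
    unit = sampler.random(n)
    lows = np.array([ranges[name][0] for name in names])
    highs = np.array([ranges[name][1] for name in names])
    points = pd.DataFrame(qmc.scale(unit, lows, highs), columns=names)
    return DesignMatrix(points=points, ranges=dict(ranges), seed=seed)


def stratum_indices(column: np.ndarray, low: float, high: float) -> np.ndarray:
    """Equal-width stratum index of each sample (0 .. n-1).

    For a valid Latin hypercube column the returned multiset is exactly
    {0, ..., n-1}.
    """
    column = np.asarray(column, dtype=float)
    n = len(column)
    idx = np.floor((column - low) / (high - low) * n).astype(int)
    return np.clip(idx, 0, n - 1)
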