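"""Preprocessing shared by both emulators: min-max scaling and time binning."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MinMaxScaler:
    """Columnwise map x' = (x - x_min) / (x_max - x_min) onto [0, 1].

    The training minima/maxima are stored so test points are scaled with
    the same affine transform (values outside the training range map
    outside [0, 1], which is intended).
    """

    mins: np.ndarray
    maxs: np.ndarray
    names: list[str] | None = None

    @classmethod
    def fit(cls, X, names: list[str] | None = None) -> "MinMaxScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mins, maxs = X.min(axis=0), X.max(axis=0)
        constant = np.flatnonzero(maxs <= mins)
        if constant.size:
            j = int(constant[0])
            label = names[j] if names else f"column {j}"
            raise ValueError(
                f"constant column {label!r}: min == max, cannot min-max scale"
            )
        return cls(mins=mins, maxs=maxs, names=names)

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mins) / (self.maxs - self.mins)

    def inverse_transform(self, Xn) -> np.ndarray:
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        return Xn * (self.maxs - self.mins) + self.mins

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "names": self.names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        return cls(
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            names=d.get("names"),
        )


def normalize_inputs(X, names: list[str] | None = None):
    """Fit-and-apply min-max scaling; returns (X_scaled, scaler)."""
    scaler = MinMaxScaler.fit(X, names=names)
    return scaler.transform(X), scaler


def average_slices(
    series,
    ratio: int | None = None,
    slice_dt: float = 2000.0,
    bin_dt: float = 10000.0,
    kind: str = "mean",
    allow_ragged: bool = False,
) -> np.ndarray:
    """Condense a fine time series into coarse bins.

    Continuous channels (``kind="mean"``) are averaged within each bin;
    the event-count channel (``kind="sum"``) is summed so bins stay on an
    integer events-per-bin scale suitable for a Poisson likelihood.

    Parameters
    ----------
    series : 1-D array
    ratio : int, optional
        Slices per bin; derived from ``bin_dt / slice_dt`` when omitted.
    allow_ragged : bool
        If True a trailing partial bin is truncated; otherwise a
        non-divisible length is an error (silent truncation hides data
        loss).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if ratio is None:
        r = bin_dt / slice_dt
        if abs(r - round(r)) > 1e-9 or r < 1:
            raise ValueError(
                f"bin_dt={bin_dt} is not an integer multiple of slice_dt={slice_dt}"
            )
        ratio = int(round(r))
    if kind not in ("mean", "sum"):
        raise ValueError("kind must be 'mean' or 'sum'")
    n = len(series)
    if n % ratio != 0:
        if not allow_ragged:
            raise ValueError(
                f"series length {n} not divisible by bin ratio {ratio}; "
                "pass allow_ragged=True to truncate the trailing partial bin"
            )
        series = series[: (n // ratio) * ratio]
    binned = series.reshape(-1, ratio)
    return binned.sum(axis=1) if kind == "sum" else binned.mean(axis=1)


def average_replicates(runs: list[pd.DataFrame], round_counts: bool = True) -> pd.DataFrame:
    """Average replicate time series of one design point columnwise.

    Counts (`noe`) are rounded to the nearest integer after averaging so
    the result keeps Poisson (integer) support.
    """
    if not runs:
        raise ValueError("no replicates to average")
    stacked = pd.concat(runs).groupby(level=0).mean()
    if round_counts and "noe" in stacked:
        stacked["noe"] = np.rint(stacked["noe"])
    return stacked
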