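"""Mean biofilm height from particle snapshots.

The simulation box base (the z = 0 plane) is partitioned into N_x x N_y
equal blocks.  A base block is "occupied" when at least one particle
center projects into it; its column height is the maximum particle z in
the column, and vacant blocks contribute height 0.  The mean height is the
discrete area-weighted average

    h_bar = (1 / (L_x L_y)) * sum_blocks h(block) * dx * dy
          = mean over all N_x N_y blocks of h(block).
"""
from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .config import GridSpec


@dataclass
class ParticleSnapshot:
    """Particle center positions (um) at one instant."""

    positions: np.ndarray  # (n, 3) x, y, z
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)


def write_snapshot(snapshot: ParticleSnapshot, grid: GridSpec, path) -> None:
    """Write particle centers as ``snapshot.csv`` with a grid-spec YAML sidecar."""
    import pandas as pd
    import yaml

    path = Path(path)
    pd.DataFrame(snapshot.positions, columns=["x_um", "y_um", "z_um"]).to_csv(
        path, index=False
    )
    sidecar = asdict(grid) | {"time_s": snapshot.time}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_snapshot(path) -> tuple[ParticleSnapshot, GridSpec]:
    """Read a snapshot CSV and its grid-spec sidecar back."""
    import pandas as pd
    import yaml

    path = Path(path)
    df = pd.read_csv(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    time = meta.pop("time_s", 0.0)
    snap = ParticleSnapshot(
        positions=df[["x_um", "y_um", "z_um"]].to_numpy(), time=time
    )
    return snap, GridSpec(**meta)


def compute_biofilm_height(
    snapshot: ParticleSnapshot,
    grid: GridSpec,
    occupied_only: bool = False,
) -> float:
    """Area-weighted mean biofilm height (um).

    Parameters
    ----------
    snapshot : ParticleSnapshot
        Particle centers; all must lie inside the grid box.
    grid : GridSpec
        Box dimensions and base-block counts.
    occupied_only : bool
        If True, average over occupied columns only instead of all base
        blocks (the alternative convention; vacant-as-zero is the default).

    Returns
    -------
    float
        0.0 (with a warning) for an empty snapshot.
    """
    pos = snapshot.positions
    if len(pos) == 0:
        warnings.warn("empty particle snapshot; mean height is 0", stacklevel=2)
        return 0.0
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    if (
        (x < 0).any() or (x > grid.L_x).any()
        or (y < 0).any() or (y > grid.L_y).any()
        or (z < 0).any() or (z > grid.L_z).any()
    ):
        raise ValueError("particle center outside the simulation box")
    ix = np.minimum((x / grid.block_dx).astype(int), grid.N_x - 1)
    iy = np.minimum((y / grid.block_dy).astype(int), grid.N_y - 1)
    heights = np.zeros((grid.N_x, grid.N_y))
    np.maximum.at(heights, (ix, iy), z)
    if occupied_only:
        occupied = np.zeros((grid.N_x, grid.N_y), dtype=bool)
        occupied[ix, iy] = True
        return float(heights[occupied].mean())
    return float(heights.mean())
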