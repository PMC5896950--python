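"""Synthetic stand-in for the individual-based biofilm simulator.

The original training data come from an expensive NUFEB/LAMMPS
individual-based simulation of a heterotrophic biofilm sheared by fluid
flow; those runs were never deposited.  This module generates datasets
with the same statistical structure the two emulators assume:

* a Latin hypercube design over the seven simulator parameters,
* smooth morphology covariates (height, mass, EPS composition, particle
  count) whose decay rate increases with shear rate, plus replicate noise,
* shear-event counts drawn Poisson with a log-quadratic mean in (time,
  particles, shear rate, EPS, height, mass),
* log detached-cluster volumes generated by the exact linear-Gaussian
  state-space process the DLM emulator fits,
* optional particle snapshots for the biofilm-height operator.

Every random stream is fanned out from a single seed via
``numpy.random.SeedSequence`` so each component can be regenerated
independently and the full dataset is byte-identical under a fixed seed.
The generated ground truth is recorded for parameter-recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import build_quadratic_features
from .config import (
    DLM_INPUT_NAMES,
    PARAM_NAMES,
    POISSON_COVARIATE_RANGES,
    POISSON_INPUT_NAMES,
    GeneratorConfig,
    GridSpec,
    TrajectoryConfig,
    default_true_poisson_coeffs,
)
from .design import DesignMatrix, latin_hypercube_design
from .height import ParticleSnapshot

RUN_COLUMNS = ["time_s", "noe", "volume", "height", "mass", "eps", "particles"]


@dataclass
class SimulatorParams:
    """One point in the seven-dimensional simulator parameter space."""

    K_s_HET: float
    mu_m_HET: float
    Y_HET: float
    gamma: float
    K_n: float
    gamma_n: float
    K_e: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"simulator parameter {name} must be > 0")

    @classmethod
    def from_row(cls, row) -> "SimulatorParams":
        return cls(**{name: float(row[name]) for name in PARAM_NAMES})


@dataclass
class GroundTruth:
    """Generative parameters recorded for recovery tests."""

    poisson_coeffs: np.ndarray
    dlm_psi: np.ndarray
    dlm_phi_y: np.ndarray
    dlm_phi_beta: np.ndarray
    dlm_m0: np.ndarray
    dlm_beta_path: np.ndarray  # (T+1) x p, index 0 = beta_0
    F_true: np.ndarray  # n_points x 8, normalized inputs incl. noe
    noe_expected: np.ndarray  # per-run expected events per bin
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "poisson_coeffs": self.poisson_coeffs.tolist(),
            "dlm_psi": self.dlm_psi.tolist(),
            "dlm_phi_y": self.dlm_phi_y.tolist(),
            "dlm_phi_beta": self.dlm_phi_beta.tolist(),
            "dlm_m0": self.dlm_m0.tolist(),
            "dlm_beta_path": self.dlm_beta_path.tolist(),
            "F_true": self.F_true.tolist(),
            "noe_expected": self.noe_expected.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            poisson_coeffs=np.array(d["poisson_coeffs"]),
            dlm_psi=np.array(d["dlm_psi"]),
            dlm_phi_y=np.array(d["dlm_phi_y"]),
            dlm_phi_beta=np.array(d["dlm_phi_beta"]),
            dlm_m0=np.array(d["dlm_m0"]),
            dlm_beta_path=np.array(d["dlm_beta_path"]),
            F_true=np.array(d["F_true"]),
            noe_expected=np.array(d["noe_expected"]),
            seed=int(d["seed"]),
        )


def simulate_covariate_trajectories(
    params: SimulatorParams,
    T_slices: int,
    seed=None,
    cfg: TrajectoryConfig | None = None,
    slice_dt: float = 2000.0,
    noise_sigma: float | None = None,
) -> pd.DataFrame:
    """Morphology covariate series for one replicate.

    Height rises while growth dominates and then declines; mass, EPS and
    particle count hold a plateau and then decay logistically, faster at
    higher shear rate.  ``noise_sigma=0`` gives the noiseless curves.

    Returns a DataFrame with columns time_s, height, mass, eps, particles.
    """
    if T_slices < 2:
        raise ValueError("need at least 2 time slices")
    cfg = cfg or TrajectoryConfig()
    if params.gamma <= 0:
        raise ValueError("shear rate gamma must be positive")
    sigma = cfg.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(seed)
    t = slice_dt * np.arange(1, T_slices + 1)
    tau = t / (slice_dt * T_slices)
    rel = params.gamma / cfg.gamma_ref
    height = cfg.height_H0 * (1 + cfg.height_a * tau) * np.exp(-cfg.height_b0 * rel * tau)

    def logistic_decay(X0, s0, tau0):
        return X0 / (1.0 + np.exp(s0 * rel * (tau - tau0)))

    out = pd.DataFrame(
        {
            "time_s": t,
            "height": height,
            "mass": logistic_decay(cfg.mass_X0, cfg.mass_s0, cfg.mass_tau0),
            "eps": logistic_decay(cfg.eps_X0, cfg.eps_s0, cfg.eps_tau0),
            "particles": logistic_decay(
                cfg.particles_X0, cfg.particles_s0, cfg.particles_tau0
            ),
        }
    )
    if sigma > 0:
        for col in ("height", "mass", "eps", "particles"):
            out[col] = out[col].to_numpy() * np.exp(
                sigma * rng.standard_normal(T_slices)
            )
    return out


def scale_poisson_covariates(cov: pd.DataFrame, gamma: float) -> np.ndarray:
    """Raw covariate rows (time, particles, gamma, eps, height, mass) on [0,1].

    Uses the fixed reference ranges of the study design (not data minima)
    so the true coefficient vector has a stable meaning.
    """
    cols = {}
    values = {
        "time": cov["time_s"].to_numpy(),
        "particles": cov["particles"].to_numpy(),
        "gamma": np.full(len(cov), gamma),
        "eps": cov["eps"].to_numpy(),
        "height": cov["height"].to_numpy(),
        "mass": cov["mass"].to_numpy(),
    }
    for name in POISSON_INPUT_NAMES:
        low, high = POISSON_COVARIATE_RANGES[name]
        cols[name] = (values[name] - low) / (high - low)
    return np.column_stack([cols[name] for name in POISSON_INPUT_NAMES])


def simulate_counts(
    covariates: np.ndarray,
    true_B: np.ndarray,
    seed=None,
    shear_on: np.ndarray | None = None,
) -> np.ndarray:
    """Poisson event counts with log-quadratic mean.

    Parameters
    ----------
    covariates : ndarray (n, 6)
        Scaled covariate rows (time, particles, gamma, eps, height, mass).
    true_B : ndarray (28,)
        Coefficients on the quadratic basis of the covariates.
    shear_on : bool array, optional
        Slices where shear flow is active; counts are zero elsewhere.
    """
    basis = build_quadratic_features(covariates)
    true_B = np.asarray(true_B, dtype=float)
    if true_B.shape != (basis.n_features,):
        raise ValueError(
            f"true_B has length {true_B.size}, expected {basis.n_features} "
            "(quadratic basis of 6 covariates)"
        )
    log_lam = basis.matrix @ true_B
    if np.max(log_lam) > 50:
        raise ValueError(
            "Poisson mean exp(x.B) overflows; rescale the coefficients"
        )
    lam = np.exp(log_lam)
    if shear_on is not None:
        lam = np.where(shear_on, lam, 0.0)
    rng = np.random.default_rng(seed)
    return rng.poisson(lam)


def simulate_volumes(
    F: np.ndarray,
    dlm_G: np.ndarray,
    dlm_V: np.ndarray,
    dlm_W: np.ndarray,
    T: int,
    seed=None,
    m0: np.ndarray | None = None,
    C0: np.ndarray | None = None,
):
    """Forward-simulate the linear-Gaussian state-space pair.

    Observation Y_t = F beta_t + v_t, v_t ~ N(0, V); evolution
    beta_t = G beta_{t-1} + w_t, w_t ~ N(0, W); beta_0 ~ N(m0, C0).

    Returns
    -------
    Y : ndarray (m, T)
    beta_path : ndarray (T+1, p), row 0 is beta_0.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    m, p = F.shape
    G = np.asarray(dlm_G, dtype=float)
    if G.ndim == 1:
        G = np.diag(G)
    V = np.asarray(dlm_V, dtype=float)
    if V.ndim == 1:
        V = np.diag(V)
    W = np.asarray(dlm_W, dtype=float)
    if W.ndim == 1:
        W = np.diag(W)
    for name, M_, dim in (("V", V, m), ("W", W, p)):
        if M_.shape != (dim, dim):
            raise ValueError(f"{name} must be {dim}x{dim}")
        if (np.diag(M_) < 0).any():
            raise ValueError(f"negative variance entry in {name}")
    if G.shape != (p, p):
        raise ValueError(f"G must be {p}x{p}")
    m0 = np.zeros(p) if m0 is None else np.asarray(m0, dtype=float)
    C0 = np.eye(p) if C0 is None else np.asarray(C0, dtype=float)
    rng = np.random.default_rng(seed)

    def chol_psd(M):
        # Cholesky factor tolerant of zero (degenerate) variances
        w_, U = np.linalg.eigh((M + M.T) / 2)
        return U * np.sqrt(np.clip(w_, 0.0, None))

    L0, LV, LW = chol_psd(C0), chol_psd(V), chol_psd(W)
    beta = np.empty((T + 1, p))
    beta[0] = m0 + L0 @ rng.standard_normal(p)
    Y = np.empty((m, T))
    for t in range(1, T + 1):
        beta[t] = G @ beta[t - 1] + LW @ rng.standard_normal(p)
        Y[:, t - 1] = F @ beta[t] + LV @ rng.standard_normal(m)
    return Y, beta


def sample_particle_snapshot(
    n_particles: int,
    grid: GridSpec | None = None,
    seed=None,
    height_scale: float = 20.0,
    time: float = 0.0,
) -> ParticleSnapshot:
    """Random particle cloud for exercising the height operator."""
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, grid.L_x, n_particles)
    y = rng.uniform(0, grid.L_y, n_particles)
    z = np.minimum(rng.exponential(height_scale, n_particles), grid.L_z)
    return ParticleSnapshot(positions=np.column_stack([x, y, z]), time=time)


@dataclass
class SyntheticDataset:
    """A full synthetic study: design, replicate runs, ground truth."""

    design: DesignMatrix
    runs: dict[tuple[int, int], pd.DataFrame]  # (point, replicate) -> series
    truth: GroundTruth
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def replicates(self, point: int) -> list[pd.DataFrame]:
        return [
            df for (i, _r), df in sorted(self.runs.items()) if i == point
        ]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.design.to_csv(outdir / "design.csv")
        for (i, r), df in sorted(self.runs.items()):
            df.to_csv(outdir / f"run_{i}_rep_{r}.csv", index=False)
        self.truth.to_json(outdir / "truth.json")

    @classmethod
    def read(cls, indir, config: GeneratorConfig | None = None) -> "SyntheticDataset":
        indir = Path(indir)
        config = config or GeneratorConfig()
        design = DesignMatrix.read_csv(indir / "design.csv", ranges=config.ranges)
        runs = {}
        for f in sorted(indir.glob("run_*_rep_*.csv")):
            stem = f.stem.split("_")
            runs[(int(stem[1]), int(stem[3]))] = pd.read_csv(f)
        truth = GroundTruth.from_json(indir / "truth.json")
        return cls(design=design, runs=runs, truth=truth, config=config)


def generate_dataset(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    true_B: np.ndarray | None = None,
) -> SyntheticDataset:
    """Generate a complete synthetic study under one global seed."""
    cfg = config or GeneratorConfig()
    if true_B is None:
        true_B = default_true_poisson_coeffs()
    ss = np.random.SeedSequence(seed)
    s_design, s_traj, s_counts, s_vol = ss.spawn(4)
    design_seed = int(np.random.default_rng(s_design).integers(2**31))
    design = latin_hypercube_design(cfg.n_points, cfg.ranges, seed=design_seed)

    n, T = cfg.n_points, cfg.n_slices
    shear_on = np.arange(T) >= cfg.growth_slices
    traj_rngs = [np.random.default_rng(s) for s in s_traj.spawn(n * cfg.n_reps)]
    count_rngs = [np.random.default_rng(s) for s in s_counts.spawn(n * cfg.n_reps)]
    vol_rng = np.random.default_rng(s_vol)

    # expected (noiseless) event intensity per run, for the DLM noe column
    noe_expected = np.empty(n)
    lam0_by_run = []
    for i in range(n):
        params = SimulatorParams.from_row(design.points.iloc[i])
        cov0 = simulate_covariate_trajectories(
            params, T, cfg=cfg.trajectories, slice_dt=cfg.slice_dt, noise_sigma=0.0
        )
        X0 = scale_poisson_covariates(cov0, params.gamma)
        lam0 = np.exp(build_quadratic_features(X0).matrix @ true_B)
        lam0 = np.where(shear_on, lam0, 0.0)
        lam0_by_run.append(lam0)
        per_bin = lam0[cfg.growth_slices :].reshape(cfg.n_bins, cfg.bin_ratio)
        noe_expected[i] = per_bin.sum(axis=1).mean()

    # true DLM inputs: range-normalized parameters + normalized expected noe
    dt = cfg.dlm_truth
    lows = np.array([cfg.ranges[nm][0] for nm in DLM_INPUT_NAMES[:-1]])
    highs = np.array([cfg.ranges[nm][1] for nm in DLM_INPUT_NAMES[:-1]])
    P = design.points[list(DLM_INPUT_NAMES[:-1])].to_numpy()
    F_true = np.column_stack(
        [
            (P - lows) / (highs - lows),
            (noe_expected - noe_expected.min())
            / max(float(np.ptp(noe_expected)), 1e-12),
        ]
    )
    p = F_true.shape[1]
    psi = np.asarray(dt.psi, dtype=float)
    phi_y = np.full(n, dt.phi_y)
    phi_beta = np.full(p, dt.phi_beta)
    vol_seed = int(vol_rng.integers(2**31))
    Y_panel, beta_path = simulate_volumes(
        F_true,
        psi,
        1.0 / phi_y,
        1.0 / phi_beta,
        cfg.n_bins,
        seed=vol_seed,
        m0=np.asarray(dt.m0, dtype=float),
        C0=dt.c0_scale * np.eye(p),
    )

    runs: dict[tuple[int, int], pd.DataFrame] = {}
    for i in range(n):
        params = SimulatorParams.from_row(design.points.iloc[i])
        # per-slice target volume: growth-phase floor, then the bin's value
        v_slice = np.full(T, dt.volume_floor)
        v_slice[cfg.growth_slices :] = np.repeat(
            np.exp(Y_panel[i]), cfg.bin_ratio
        )
        for r in range(cfg.n_reps):
            k = i * cfg.n_reps + r
            cov = simulate_covariate_trajectories(
                params,
                T,
                seed=traj_rngs[k],
                cfg=cfg.trajectories,
                slice_dt=cfg.slice_dt,
            )
            X = scale_poisson_covariates(cov, params.gamma)
            noe = simulate_counts(
                X, true_B, seed=count_rngs[k], shear_on=shear_on
            )
            volume = v_slice * np.exp(
                dt.volume_noise_sigma * vol_rng.standard_normal(T)
            )
            df = cov.copy()
            df.insert(1, "noe", noe)
            df.insert(2, "volume", volume)
            runs[(i, r)] = df[RUN_COLUMNS]

    truth = GroundTruth(
        poisson_coeffs=np.asarray(true_B, dtype=float),
        dlm_psi=psi,
        dlm_phi_y=phi_y,
        dlm_phi_beta=phi_beta,
        dlm_m0=np.asarray(dt.m0, dtype=float),
        dlm_beta_path=beta_path,
        F_true=F_true,
        noe_expected=noe_expected,
        seed=seed,
    )
    return SyntheticDataset(design=design, runs=runs, truth=truth, config=cfg)
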