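"""Reference parameter values and study-design constants.

The individual-based (NUFEB/LAMMPS) biofilm simulator that produced the
original training data exposes seven physical parameters: three growth
parameters for the heterotrophic functional group (substrate affinity
``K_s_HET``, maximum specific growth rate ``mu_m_HET``, growth yield
``Y_HET``), the applied hydrodynamic shear rate ``gamma``, two
discrete-element collision coefficients (``K_n``, ``gamma_n``) and the EPS
stiffness per unit EPS mass (``K_e``).  Experimental designs vary each
parameter within +/-50% of its reference value.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical column order used in every design matrix and CSV header.
PARAM_NAMES: tuple[str, ...] = (
    "K_s_HET",
    "mu_m_HET",
    "Y_HET",
    "gamma",
    "K_n",
    "gamma_n",
    "K_e",
)

#: Reference (standard) values of the seven simulator parameters.
#: Units: kg m^-3, h^-1, gCOD/gCOD, s^-1, N m^-1, s^-1, s^-2.
PARAM_DEFAULTS: dict[str, float] = {
    "K_s_HET": 3.5e-5,
    "mu_m_HET": 1.0,
    "Y_HET": 0.61,
    "gamma": 0.25,
    "K_n": 1e-4,
    "gamma_n": 1e-5,
    "K_e": 5e9,
}

#: Column order of the DLM regression matrix F: the seven simulator
#: parameters plus the (expected) number of shear events per run.
DLM_INPUT_NAMES: tuple[str, ...] = (
    "mu_m_HET",
    "K_s_HET",
    "Y_HET",
    "gamma",
    "K_n",
    "gamma_n",
    "K_e",
    "noe",
)

#: Covariates entering the Poisson quadratic basis, in fixed order.
POISSON_INPUT_NAMES: tuple[str, ...] = (
    "time",
    "particles",
    "gamma",
    "eps",
    "height",
    "mass",
)


def default_ranges(frac: float = 0.5) -> dict[str, tuple[float, float]]:
    """Per-parameter [low, high] ranges at +/- ``frac`` of the reference values."""
    return {
        name: (value * (1.0 - frac), value * (1.0 + frac))
        for name, value in PARAM_DEFAULTS.items()
    }


@dataclass(frozen=True)
class GridSpec:
    """Simulation box dimensions (um) and Cartesian block counts."""

    L_x: float = 200.0
    L_y: float = 40.0
    L_z: float = 100.0
    N_x: int = 30
    N_y: int = 12
    N_z: int = 30

    def __post_init__(self) -> None:
        for name in ("L_x", "L_y", "L_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"box dimension {name} must be positive")
        for name in ("N_x", "N_y", "N_z"):
            if getattr(self, name) < 1:
                raise ValueError(f"block count {name} must be >= 1")

    @property
    def block_dx(self) -> float:
        return self.L_x / self.N_x

    @property
    def block_dy(self) -> float:
        return self.L_y / self.N_y


@dataclass
class TrajectoryConfig:
    """Closed-form covariate trajectory family.

    Time is scaled to tau = t / t_total in [0, 1].  Biofilm height follows
    H0 * (1 + a*tau) * exp(-b(gamma)*tau): an early rise while growth
    outpaces erosion, then decline.  Mass, EPS-particle count and total
    particle count follow logistic decays X0 / (1 + exp(s(gamma)*(tau -
    tau0))): a plateau during early growth, then shear-driven loss.  Both
    decay rates scale linearly with shear rate, b(gamma) = b0 * gamma /
    gamma_ref, so higher shear strips the biofilm faster.  Replicate noise
    is multiplicative lognormal, exp(sigma * Z) i.i.d. per time slice.
    """

    gamma_ref: float = 0.25  # s^-1, reference shear rate
    height_H0: float = 15.0  # um
    height_a: float = 6.0
    height_b0: float = 3.0
    mass_X0: float = 1.2e-10  # kg
    mass_s0: float = 5.5
    mass_tau0: float = 0.40
    eps_X0: float = 600.0  # EPS particle count
    eps_s0: float = 7.0
    eps_tau0: float = 0.30
    particles_X0: float = 2000.0
    particles_s0: float = 6.0
    particles_tau0: float = 0.35
    noise_sigma: float = 0.05  # lognormal replicate noise scale


#: Fixed reference ranges used to scale Poisson covariates to [0, 1] inside
#: the generator (so the true coefficient vector keeps exp() tame).
POISSON_COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "time": (0.0, 240000.0),
    "particles": (0.0, 2400.0),
    "gamma": (0.10, 0.40),
    "eps": (0.0, 720.0),
    "height": (0.0, 25.0),
    "mass": (0.0, 1.5e-10),
}


def default_true_poisson_coeffs() -> np.ndarray:
    """True quadratic-basis coefficients used by the count generator.

    Defined on the 28-term quadratic basis over the [0,1]-scaled covariates
    (time, particles, gamma, eps, height, mass).  Chosen once to give event
    counts that rise to a mid-window peak and increase with shear rate,
    with per-10000 s bin counts of order 1-60.
    """
    from .basis import quadratic_labels

    labels = quadratic_labels(6)
    coeffs = dict.fromkeys(labels, 0.0)
    # indices (1-based within the raw covariates): 1 time, 2 particles,
    # 3 gamma, 4 eps, 5 height, 6 mass
    coeffs[(0, 0)] = -0.8  # intercept
    coeffs[(0, 1)] = 6.0  # rises with time ...
    coeffs[(1, 1)] = -5.0  # ... then declines (peak near tau ~ 0.6)
    coeffs[(0, 3)] = 2.0  # more shear, more events
    coeffs[(1, 3)] = 1.2  # shear effect strengthens over time
    coeffs[(3, 3)] = -0.5
    coeffs[(0, 2)] = 0.8  # larger biofilms shed more
    coeffs[(0, 4)] = -0.6  # EPS binds the biofilm together
    coeffs[(0, 5)] = 0.5
    return np.array([coeffs[lab] for lab in labels])


@dataclass
class DLMTruthConfig:
    """True dynamic-linear-model parameters for the volume generator.

    States are the 8 time-varying regression coefficients on
    (mu_m_HET, K_s_HET, Y_HET, gamma, K_n, gamma_n, K_e, noe), each an
    AR(1) with coefficient psi_j.  Weights on Y_HET, gamma, K_e and noe
    dominate so the detached volume is mainly driven by growth yield,
    shear, EPS stiffness and the event count.
    """

    psi: tuple[float, ...] = (0.9, 0.85, 0.8, 0.9, 0.7, 0.6, 0.95, 0.9)
    phi_y: float = 50.0  # observation precision (log-volume sd ~ 0.14)
    phi_beta: float = 25.0  # evolution precision (innovation sd 0.2)
    m0: tuple[float, ...] = (0.1, 0.1, 1.2, 1.5, 0.1, 0.3, 1.0, 2.0)
    c0_scale: float = 0.25
    volume_floor: float = 1e-6  # growth-phase detached volume (normalized)
    volume_noise_sigma: float = 0.03  # within-bin slice-level noise


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic study.

    Defaults reproduce the original study design: a 140-point Latin
    hypercube over +/-50% of the reference parameter values, 5 replicates
    per point, output recorded every 2000 s for 120 slices (a 40000 s
    growth phase followed by a 200000 s shear window), then averaged into
    10000 s bins over the shear window.
    """

    n_points: int = 140
    n_reps: int = 5
    n_slices: int = 120
    slice_dt: float = 2000.0  # s
    growth_slices: int = 20  # slices before shear flow is switched on
    bin_dt: float = 10000.0  # s
    range_frac: float = 0.5
    trajectories: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    dlm_truth: DLMTruthConfig = field(default_factory=DLMTruthConfig)

    @property
    def ranges(self) -> dict[str, tuple[float, float]]:
        return default_ranges(self.range_frac)

    @property
    def shear_slices(self) -> int:
        return self.n_slices - self.growth_slices

    @property
    def bin_ratio(self) -> int:
        ratio = self.bin_dt / self.slice_dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("bin_dt must be an integer multiple of slice_dt")
        return int(round(ratio))

    @property
    def n_bins(self) -> int:
        return self.shear_slices // self.bin_ratio
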