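"""End-to-end orchestration: data -> preprocess -> emulators -> validation.

The full analysis mirrors the original study design: generate (or load) a
designed ensemble of replicate simulator runs; average the replicates and
treat them as deterministic; keep the shear window and condense it into
10,000 s bins; split the design points into training and held-out test
sets; fit the Poisson count emulator on the training rows; fit the DLM
volume emulator on the training log-volume panel; chain the two by
feeding the Poisson emulator's predicted event counts into the DLM's
test-input rows; validate both on the held-out points; and run the
time-resolved Sobol sensitivity analysis on the fitted volume surface.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import build_quadratic_features
from .config import DLM_INPUT_NAMES, POISSON_INPUT_NAMES, GeneratorConfig
from .dlm import DLMSpec, VolumePredictive, gibbs_sample, predict_volumes
from .metrics import interval_coverage, rmse, squared_correlation, variance_explained
from .poisson import PoissonPrior, metropolis_sample, predict_counts
from .preprocess import MinMaxScaler, average_replicates, average_slices
from .sobol import sensitivity_over_time
from .synthetic import SyntheticDataset, generate_dataset

log = logging.getLogger("biofilm_emu")


@dataclass
class ChainSettings:
    n_iter: int
    burn_in: int
    thin: int


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end analysis, YAML round-trippable."""

    seed: int = 0
    n_points: int = 140
    n_reps: int = 5
    n_train: int = 130
    n_test: int = 10
    poisson: ChainSettings = field(
        default_factory=lambda: ChainSettings(60_000, 1_000, 10)
    )
    dlm: ChainSettings = field(default_factory=lambda: ChainSettings(20_000, 1_000, 10))
    sensitivity_N: int = 10_000
    sensitivity_bins: list[int] | None = None
    prior_mean: float = 0.5  # Poisson prior mean (inert under flat precision)
    obs_noise: str = "harmonic"  # new-unit observation noise policy
    static_noe: bool = True  # run-mean noe column in F (time-invariant F)
    allow_ragged: bool = False
    quiet: bool = False

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n_points:
            raise ValueError(
                f"n_train + n_test = {self.n_train + self.n_test} "
                f"must equal n_points = {self.n_points}"
            )

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(n_points=self.n_points, n_reps=self.n_reps)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("poisson", "dlm"):
            if isinstance(d.get(key), dict):
                d[key] = ChainSettings(**d[key])
        return cls(**d)


def split_train_test(n_runs: int, n_train: int, n_test: int, seed=None):
    """Disjoint, exhaustive, seed-reproducible random index partition."""
    if n_train + n_test != n_runs:
        raise ValueError(
            f"n_train + n_test = {n_train + n_test} must equal n_runs = {n_runs}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    perm = rng.permutation(n_runs)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class ValidationReport:
    """Held-out performance of both emulators plus chaining diagnostics."""

    poisson_rmse: float
    poisson_var_explained: float
    poisson_rho_sq: float
    poisson_coverage: float
    dlm_rmse: float
    dlm_var_explained: float
    dlm_rho_sq: float
    dlm_coverage: float
    n_train: int
    n_test: int
    n_bins: int
    seed: int
    poisson_acceptance: float
    trajectories: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            k: (round(v, 10) if isinstance(v, float) else v)
            for k, v in dataclasses.asdict(self).items()
            if k != "trajectories"
        }
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _binned_tables(dataset: SyntheticDataset, cfg: GeneratorConfig, allow_ragged=False):
    """Replicate-averaged, shear-window 10,000 s binned table per design point."""
    ratio = cfg.bin_ratio
    tables = []
    for i in range(cfg.n_points):
        avg = average_replicates(dataset.replicates(i))
        shear = avg.iloc[cfg.growth_slices :]
        if (shear["volume"] <= 0).any():
            raise ValueError(f"non-positive detached volume in run {i}")
        binned = {
            "time_s": average_slices(
                shear["time_s"], ratio, kind="mean", allow_ragged=allow_ragged
            ),
            "noe": average_slices(
                shear["noe"], ratio, kind="sum", allow_ragged=allow_ragged
            ),
            "volume": average_slices(
                shear["volume"], ratio, kind="mean", allow_ragged=allow_ragged
            ),
        }
        for col in ("height", "mass", "eps", "particles"):
            binned[col] = average_slices(
                shear[col], ratio, kind="mean", allow_ragged=allow_ragged
            )
        df = pd.DataFrame(binned)
        df["noe"] = np.rint(df["noe"])  # replicate-averaged counts, integer support
        df["log_volume"] = np.log(df["volume"])
        tables.append(df)
    return tables


def _poisson_rows(tables, design, idx):
    rows = []
    for i in idx:
        df = tables[i]
        gamma = float(design.points.iloc[i]["gamma"])
        rows.append(
            np.column_stack(
                [
                    df["time_s"],
                    df["particles"],
                    np.full(len(df), gamma),
                    df["eps"],
                    df["height"],
                    df["mass"],
                ]
            )
        )
    X = np.vstack(rows)
    y = np.concatenate([tables[i]["noe"].to_numpy() for i in idx])
    return X, y


@dataclass
class PipelineResult:
    report: ValidationReport
    dataset: SyntheticDataset
    train_idx: np.ndarray
    test_idx: np.ndarray
    poisson_posterior: object
    poisson_scaler: MinMaxScaler
    dlm_posterior: object
    dlm_scaler: MinMaxScaler
    dlm_predictive: VolumePredictive
    sensitivity: pd.DataFrame
    F_train: np.ndarray
    F_test: np.ndarray
    Y_train: np.ndarray
    Y_test: np.ndarray


def run_pipeline(
    config: PipelineConfig,
    dataset: SyntheticDataset | None = None,
    outdir=None,
) -> PipelineResult:
    """Execute the full chained analysis; every stage seeds from config.seed."""
    if config.quiet:
        log.setLevel(logging.WARNING)
    ss = np.random.SeedSequence(config.seed)
    (s_data, s_split, s_pois, s_pois_pred, s_dlm, s_dlm_pred, s_sens) = ss.spawn(7)

    gen_cfg = config.generator_config()
    if dataset is None:
        log.info("stage simulate: %d points x %d reps", config.n_points, config.n_reps)
        dataset = generate_dataset(
            gen_cfg, seed=int(np.random.default_rng(s_data).integers(2**31))
        )
    log.info("stage preprocess: averaging replicates, binning shear window")
    tables = _binned_tables(dataset, gen_cfg, allow_ragged=config.allow_ragged)
    n_bins = len(tables[0])

    train_idx, test_idx = split_train_test(
        config.n_points,
        config.n_train,
        config.n_test,
        seed=np.random.default_rng(s_split),
    )
    log.info("stage split: %d train / %d test", len(train_idx), len(test_idx))

    # ---- Poisson count emulator -------------------------------------------
    X_train_raw, y_train = _poisson_rows(tables, dataset.design, train_idx)
    X_test_raw, y_test = _poisson_rows(tables, dataset.design, test_idx)
    pois_scaler = MinMaxScaler.fit(X_train_raw, names=list(POISSON_INPUT_NAMES))
    basis_train = build_quadratic_features(pois_scaler.transform(X_train_raw))
    prior = PoissonPrior.flat(basis_train.n_features, mean=config.prior_mean)
    log.info(
        "stage fit-poisson: n=%d rows, %d basis terms, %d iterations",
        len(y_train),
        basis_train.n_features,
        config.poisson.n_iter,
    )
    pois_post = metropolis_sample(
        basis_train,
        y_train,
        prior,
        n_iter=config.poisson.n_iter,
        burn_in=config.poisson.burn_in,
        thin=config.poisson.thin,
        seed=int(np.random.default_rng(s_pois).integers(2**31)),
    )
    basis_test = build_quadratic_features(pois_scaler.transform(X_test_raw))
    pois_pred = predict_counts(
        pois_post,
        basis_test,
        seed=int(np.random.default_rng(s_pois_pred).integers(2**31)),
    )

    # ---- DLM volume emulator ----------------------------------------------
    params7 = list(DLM_INPUT_NAMES[:-1])
    P = dataset.design.points[params7].to_numpy()
    noe_bins = np.stack(
        [tables[i]["noe"].to_numpy() for i in range(config.n_points)]
    )  # (n_points, n_bins)
    noe_mean = noe_bins.mean(axis=1)
    F_raw = np.column_stack([P, noe_mean])
    if config.static_noe:
        dlm_scaler = MinMaxScaler.fit(F_raw[train_idx], names=list(DLM_INPUT_NAMES))
        F_train = dlm_scaler.transform(F_raw[train_idx])
    else:
        # time-varying F: the noe column is the run's binned count at bin t;
        # the scaler pools all training (run, bin) rows
        pooled = np.vstack(
            [
                np.column_stack([P[train_idx], noe_bins[train_idx, t]])
                for t in range(n_bins)
            ]
        )
        dlm_scaler = MinMaxScaler.fit(pooled, names=list(DLM_INPUT_NAMES))
        F_train = np.stack(
            [
                dlm_scaler.transform(
                    np.column_stack([P[train_idx], noe_bins[train_idx, t]])
                )
                for t in range(n_bins)
            ]
        )
    Y_train = np.vstack([tables[i]["log_volume"].to_numpy() for i in train_idx])
    Y_test = np.vstack([tables[i]["log_volume"].to_numpy() for i in test_idx])
    spec = DLMSpec(F=F_train)
    log.info(
        "stage fit-dlm: panel %d x %d, %d iterations",
        *Y_train.shape,
        config.dlm.n_iter,
    )
    dlm_post = gibbs_sample(
        spec,
        Y_train,
        n_iter=config.dlm.n_iter,
        burn_in=config.dlm.burn_in,
        thin=config.dlm.thin,
        seed=int(np.random.default_rng(s_dlm).integers(2**31)),
    )

    # chain: test noe column comes from the Poisson emulator's predictions
    lam_mean = pois_pred.lambda_mean.reshape(len(test_idx), n_bins)
    if config.static_noe:
        F_test = dlm_scaler.transform(
            np.column_stack([P[test_idx], lam_mean.mean(axis=1)])
        )
    else:
        F_test = np.stack(
            [
                dlm_scaler.transform(
                    np.column_stack([P[test_idx], lam_mean[:, t]])
                )
                for t in range(n_bins)
            ]
        )
    log.info("stage predict: chained noe -> DLM test predictions")
    dlm_pred = predict_volumes(
        dlm_post,
        F_test,
        seed=int(np.random.default_rng(s_dlm_pred).integers(2**31)),
        obs_noise=config.obs_noise,
    )

    # ---- validation --------------------------------------------------------
    report = ValidationReport(
        poisson_rmse=rmse(y_test, pois_pred.lambda_mean),
        poisson_var_explained=variance_explained(y_test, pois_pred.lambda_mean),
        poisson_rho_sq=squared_correlation(y_test, pois_pred.lambda_mean),
        poisson_coverage=interval_coverage(y_test, pois_pred.lower, pois_pred.upper),
        dlm_rmse=rmse(Y_test.ravel(), dlm_pred.mean.ravel()),
        dlm_var_explained=variance_explained(Y_test.ravel(), dlm_pred.mean.ravel()),
        dlm_rho_sq=squared_correlation(Y_test.ravel(), dlm_pred.mean.ravel()),
        dlm_coverage=interval_coverage(
            Y_test.ravel(), dlm_pred.lower.ravel(), dlm_pred.upper.ravel()
        ),
        n_train=len(train_idx),
        n_test=len(test_idx),
        n_bins=n_bins,
        seed=config.seed,
        poisson_acceptance=pois_post.acceptance_rate,
        trajectories=_trajectory_table(
            tables, dataset.design, test_idx, dlm_pred, pois_pred, n_bins
        ),
    )
    log.info(
        "validation: poisson varexp %.1f%%, dlm varexp %.1f%%",
        report.poisson_var_explained,
        report.dlm_var_explained,
    )

    # ---- sensitivity -------------------------------------------------------
    ranges = [
        (float(F_raw[train_idx, j].min()), float(F_raw[train_idx, j].max()))
        for j in range(F_raw.shape[1])
    ]
    log.info("stage sensitivity: N=%d over %d bins", config.sensitivity_N, n_bins)
    sens = sensitivity_over_time(
        dlm_post,
        dlm_scaler,
        ranges,
        N=config.sensitivity_N,
        seed=int(np.random.default_rng(s_sens).integers(2**31)),
        names=list(DLM_INPUT_NAMES),
        bins=config.sensitivity_bins,
    )

    result = PipelineResult(
        report=report,
        dataset=dataset,
        train_idx=train_idx,
        test_idx=test_idx,
        poisson_posterior=pois_post,
        poisson_scaler=pois_scaler,
        dlm_posterior=dlm_post,
        dlm_scaler=dlm_scaler,
        dlm_predictive=dlm_pred,
        sensitivity=sens,
        F_train=F_train,
        F_test=F_test,
        Y_train=Y_train,
        Y_test=Y_test,
    )
    if outdir is not None:
        write_artifacts(result, config, outdir)
    return result


def _trajectory_table(tables, design, test_idx, dlm_pred, pois_pred, n_bins):
    """Simulated vs predicted series per held-out run (with 95% bands)."""
    rows = []
    lam = pois_pred.lambda_mean.reshape(len(test_idx), n_bins)
    lo_c = pois_pred.lower.reshape(len(test_idx), n_bins)
    hi_c = pois_pred.upper.reshape(len(test_idx), n_bins)
    for k, i in enumerate(test_idx):
        df = tables[i]
        rows.append(
            pd.DataFrame(
                {
                    "run": i,
                    "gamma": float(design.points.iloc[i]["gamma"]),
                    "time_s": df["time_s"],
                    "noe_sim": df["noe"],
                    "noe_pred": lam[k],
                    "noe_lo95": lo_c[k],
                    "noe_hi95": hi_c[k],
                    "log_volume_sim": df["log_volume"],
                    "log_volume_pred": dlm_pred.mean[k],
                    "log_volume_lo95": dlm_pred.lower[k],
                    "log_volume_hi95": dlm_pred.upper[k],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_artifacts(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    """Write every stage artifact as CSV/JSON/YAML under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    result.dataset.design.to_csv(out / "design.csv")
    pd.DataFrame(result.Y_train).to_csv(out / "Y_panel.csv", index=False)
    F_out = result.F_train if result.F_train.ndim == 2 else result.F_train.mean(axis=0)
    pd.DataFrame(F_out, columns=list(DLM_INPUT_NAMES)).to_csv(
        out / "F.csv", index=False
    )
    pois = result.poisson_posterior
    pd.DataFrame(
        pois.draws, columns=[f"b_{i}_{j}" for i, j in pois.labels]
    ).to_csv(out / "poisson_chain.csv", index=False)
    ci = pois.credible_interval()
    summary = {
        "mean": pois.mean().tolist(),
        "sd": pois.sd().tolist(),
        "ci_2.5": ci[0].tolist(),
        "ci_97.5": ci[1].tolist(),
        "acceptance_rate": pois.acceptance_rate,
        "n_iter": pois.n_iter,
        "burn_in": pois.burn_in,
        "thin": pois.thin,
    }
    (out / "poisson_summary.json").write_text(json.dumps(summary, indent=1))
    dlm = result.dlm_posterior
    pd.DataFrame(dlm.psi_draws).to_csv(out / "psi.csv", index=False)
    pd.DataFrame(dlm.phi_y_draws).to_csv(out / "phi_y.csv", index=False)
    pd.DataFrame(dlm.phi_beta_draws).to_csv(out / "phi_beta.csv", index=False)
    result.report.trajectories.to_csv(out / "predictive.csv", index=False)
    dlm_rows = []
    for k in range(result.dlm_predictive.mean.shape[0]):
        dlm_rows.append(
            pd.DataFrame(
                {
                    "run": result.test_idx[k],
                    "time_bin": np.arange(1, result.dlm_predictive.mean.shape[1] + 1),
                    "mean": result.dlm_predictive.mean[k],
                    "lo95": result.dlm_predictive.lower[k],
                    "hi95": result.dlm_predictive.upper[k],
                }
            )
        )
    pd.concat(dlm_rows, ignore_index=True).to_csv(
        out / "dlm_predictive.csv", index=False
    )
    result.sensitivity.to_csv(out / "sobol_indices.csv", index=False)
    result.report.to_json(out / "report.json")
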