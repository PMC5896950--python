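# Methods

`biofilm_emu` builds cheap Bayesian surrogates for an individual-based
simulation of a heterotrophic biofilm sheared by fluid flow. The simulator
resolves bacterial growth, EPS mechanics and hydrodynamics at the
single-cell scale and takes hours per run; the surrogates predict its two
detachment outputs — the number of shear (detachment) events per time bin
and the volume of detached clusters — in seconds, as functions of seven
physical parameters and time. This note records the models, the synthetic
data-generating process used in place of the (undeposited) simulator
output, and the numerical and design choices a maintainer would want
explained.

## The count emulator: Bayesian Poisson regression

Event counts per 10,000 s bin are modelled as

    y_k ~ Poisson(lambda_k),   log lambda_k = sum_{i<=j} beta_ij x_ik x_jk,

a full quadratic (intercept, linear, squared and pairwise terms; 28
coefficients) in six covariates: time, total particle count, shear rate
gamma, EPS composition (number of EPS particles), biofilm mean height and
biofilm mass. All covariates are min–max scaled to [0, 1] using training
minima/maxima before expansion, which keeps `exp()` numerically tame and
gives the coefficients a common scale. Priors are independent normals; the
default is the flat limit (precision 0, nominal mean 0.5), under which the
posterior is proportional to the likelihood.

The posterior has no conjugate form, so sampling is Gaussian random-walk
Metropolis: the chain starts at the maximum-likelihood estimate (computed
in-package by damped Newton iteration), the proposal covariance is the
inverse Fisher information at the MLE scaled by 2.38/sqrt(q), and a global
scale factor adapts toward 23% acceptance during burn-in only (frozen
afterwards, so the retained chain is a valid Markov chain). Desk-scale
defaults are 60,000 iterations, burn-in 1,000, thinning 10; the original
study's 6,000,000/1,000/1,000 settings remain available through the chain
configuration. Predictions at new covariate rows are Poisson draws with
rate `exp(x . B_s)` per retained draw `B_s`; intervals are empirical
2.5/97.5 percentiles of the count draws, so they include both parameter
and Poisson noise.

Degenerate inputs: all-zero counts are accepted, with the fitted rate
floored at 1e-8 instead of letting the intercept diverge; proposals whose
linear predictor would overflow `exp` get log-posterior −inf (rejected),
never NaN; collinear basis columns are reported as an error at the MLE
stage because the proposal needs the inverse Fisher matrix.

## The volume emulator: Bayesian dynamic linear model

Log detached volume for the m training runs forms a panel Y (m × T bins)
modelled by the linear-Gaussian state-space pair

    Y_t = F beta_t + v_t,  v_t ~ N(0, V),    V = diag(1/phi_y,i)
    beta_t = G beta_{t-1} + w_t,  w_t ~ N(0, W),  W = diag(1/phi_beta,j)
    beta_0 ~ N(m0, C0),   G = diag(psi_1..psi_p)

with one F row per run: the seven simulator parameters plus the run's
event count (noe), all min–max scaled on the training set. F is
time-invariant by default: the noe column is the run's mean binned count
(a time-varying-F mode exists but is off by default, matching the
assumption that the regression matrix is constant). Priors: psi_j ~
N(psi0, tau0), precisions Gamma(shape, rate); the defaults psi0=0, tau0=1,
alpha_y=3, b_y=0.01, alpha_beta=3, b_beta=1, m0=0, C0=I are the original
study's. The shape–rate convention was chosen because it makes the
printed hyperparameters physically plausible (prior mean observation
precision 300, i.e. log-volume noise sd ≈ 0.06); a `gamma_scale` switch
reinterprets b as a scale for anyone preferring the other convention.

Inference is a systematic-scan Gibbs sampler:

1. **States** by forward-filtering backward-sampling (FFBS). The forward
   pass is a Kalman filter run in information form: with diagonal V the
   Woodbury identity turns the m × m predictive-covariance solve into
   p × p algebra, so the per-step cost is O(mp² + p³) — the difference
   between minutes and hours at m = 130. The covariance-form recursion is
   kept as the general path (used when V has zeros or matrices are
   non-diagonal) and both are tested against dense joint-Gaussian
   conditioning. beta_0 is sampled as an extra latent with prior
   N(m0, C0).
2. **psi_j** from its normal full conditional: precision 1/tau0 +
   phi_beta,j * sum_t beta_{j,t-1}^2, mean (psi0/tau0 + phi_beta,j *
   sum_t beta_{j,t-1} beta_{j,t}) / precision. tau0 = 0 is honoured as
   the dogmatic prior (psi_j = psi0 exactly).
3. **Precisions** from gamma conditionals, shape alpha + T/2 and rate
   b + SS/2 with SS the observation (per run) or evolution (per state)
   residual sum of squares.

Desk defaults: 20,000 iterations, burn-in 1,000, thinning 10. Predictions
for a new run use each retained state path: Y*_t = F* beta_t^(s) plus
observation noise at the draw's harmonic-mean training precision (the
model gives a new run its own phi; the harmonic mean is the variance-side
average and is the default policy; a fresh prior draw or no noise are
selectable).

Numerical choices: all covariances are symmetrized after every update;
sampling from possibly-singular conditionals (exact when W = 0) uses a
Cholesky factor when possible and otherwise an eigendecomposition with
eigenvalues below 1e-12 of the spectral radius clipped to zero, so
degenerate directions are reproduced exactly rather than jittered.

## Chaining and validation

The pipeline averages the replicates of each design point (counts rounded
back to integers so the Poisson likelihood keeps integer support), keeps
the shear window, condenses 2,000 s slices into 10,000 s bins (continuous
channels averaged, counts summed), and splits design points into training
and held-out test sets (130/10 at full scale). The count emulator is fit
on training rows; its posterior-mean rates on the test rows provide the
noe column of the test F rows for the volume emulator — the two surrogates
are chained exactly as they would be in use, where the true test noe is
unknown. Held-out performance is reported as RMSE, percentage of variance
explained 100·(1 − SSE/SST) (the headline figure, because it penalizes
bias), the squared-correlation variant 100·r² (reported alongside, since
"variance explained" is sometimes used in that sense), and 95%
predictive-interval coverage.

## Sensitivity analysis

Time-resolved Sobol indices of the emulated log volume: for each time bin
the evaluator maps the eight raw inputs through the training scaler and
the posterior-mean DLM surface F(x)·E[beta_t]. The posterior mean is used
because Sobol indices of a stochastic evaluator would conflate Monte-Carlo
noise with input variance; a mode that averages over posterior state draws
exists (equivalent for this linear-in-beta surface). Estimators are the
Saltelli (2010) first-order and Jansen total-effect forms on plain
uniform Monte-Carlo matrices A, B, A_B^(i) — N(k+2) evaluations for k = 8
inputs — with outputs centred by the overall mean before estimation (a
standard, unbiased variance reduction). Raw estimates (which may be
slightly negative) are reported alongside [0,1]-clipped values. Input
ranges default to the ±50% design ranges, and the noe range to the
training counts' min–max.

## The synthetic data generator

No simulator output was deposited, so the generator manufactures datasets
with the statistical structure the emulators assume, plus known ground
truth for recovery tests. It emulates:

* the **design**: a Latin hypercube (one sample per equal-width stratum
  per parameter) over ±50% of the reference parameter values; defaults
  140 points × 5 replicates;
* the **recording scheme**: 120 slices of 2,000 s — a 40,000 s growth
  phase (20 slices) then a 200,000 s shear window (100 slices) — binned
  to 20 bins of 10,000 s over the shear window. (The alternative
  24-bin reading, which would include the growth phase, is available via
  configuration.)
* **morphology covariates** as smooth parametric curves with replicate
  noise: height H0(1 + a·tau)exp(−b(gamma)·tau) (early rise, later
  decline; peak near the end of the growth phase at the reference shear
  rate), and logistic decays X0/(1 + exp(s(gamma)(tau − tau0))) for mass,
  EPS and particle count (plateau, then shear-driven loss). Both decay
  rates scale linearly with gamma, so higher shear strips the biofilm
  faster — the qualitative behaviour reported for the simulator.
  Replicate noise is multiplicative lognormal (sigma = 0.05) per slice.
* **counts** drawn Poisson with the model's own log-quadratic mean; the
  true 28-coefficient vector (recorded in `truth.json`) rises to a
  mid-window peak, increases with shear rate and yields bin counts of
  order 1–60, the scale of the study's figures;
* **log volumes** generated by exact forward simulation of the DLM
  state-space pair itself, with dominant true weights on yield, shear
  rate, EPS stiffness and noe so the generative sensitivity ranking
  matches the reported one; per-slice volumes are the bin value with
  small multiplicative noise, and a positive floor (1e-6) covers the
  growth phase.

One global seed fans out to per-stream child seeds (design, trajectories,
counts, volumes), so each component is independently regenerable and the
written CSVs are byte-identical across runs.

What the generator does **not** emulate — and hence what passing tests do
not show about real simulator data: mechanistic coupling between the
covariates and the counts (in NUFEB the height *causes* detachment
propensity; here both are driven by the same smooth curves), spatial
structure beyond the height operator, non-Poisson dispersion of event
counts, non-Gaussian or heteroscedastic volume noise, and any model
misspecification: the emulators are fit to data drawn from their own
model class, so validation numbers are upper bounds on real-data
performance.

## Validation experiment sizes

The pre-registered experiments (`biofilm_emu.validation.experiments`) use
desk-scale problem sizes chosen so the whole battery runs on one CPU in
well under half an hour: 50 random state-space instances (m, p, T ≤ 4)
against dense-Gaussian conditioning; quadrature comparisons for 1- and
2-coefficient count models (n = 200); 100-repetition coverage experiments
(n = 600 counts; 20×3×20 DLM panels); precision recovery on T = 200
panels over 20 seeds (at T = 20 the posterior mean of a precision is
intrinsically 20–30% high — Jensen curvature of 1/x over ~10 degrees of
freedom plus latent-state absorption — so a short panel tests the Bayes
estimator, not the implementation); 5,000 FFBS draws against dense
smoothing; Sobol estimators at N = 10,000 against analytic and quadrature
decompositions; and an end-to-end fixture study of 20 design points × 3
replicates with a 16/4 split, desk chain settings and sensitivity
N = 2,000, rerun twice to confirm byte-identical determinism.

## Known limitations

* The Metropolis proposal is a single full-vector block; for the 28-term
  basis this mixes adequately at desk scale but component-blocked or
  gradient-based samplers would mix faster at the original study's chain
  lengths.
* F is time-invariant by default (run-mean noe). The time-varying mode
  (noe column per bin, chained per-bin predicted rates for test runs) is
  implemented and checked against the dense-Gaussian oracle, but the
  default follows the constant-F assumption of the original analysis.
* The DLM assumes diagonal G, V, W and a shared state path across runs;
  run-specific state paths (a hierarchical extension) are out of scope.
* Sobol indices are first-order and total only; no second-order indices,
  and no quasi-random (Sobol'-sequence) sampling by default, to match the
  plain uniform sampling the analysis specifies.
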