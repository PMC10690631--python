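# Methods

## Task and scene model

`gravicept` models a manual-interception experiment in which an observer
lies supine and presses a button to intercept a ball (diameter s = 0.07 m)
dropping vertically from 9.72 m above the ground toward a ring held
0.775 m above the ground, roughly 0.5 m above the observer's eyes. The
ball disappears 0.40 m below the ring. All lengths are real-world metres
(`SceneGeometry`); the drop distance is D = 9.72 − 0.775 = 8.945 m.

Twelve kinematic conditions cross three signed downward accelerations
a ∈ {−9.8, 0, +9.8} m/s² with four motion durations
T ∈ {0.8, 0.9, 1.0, 1.1} s. Downward is the positive axis, so the
"decelerating" profile has a = −9.8 applied to the downward speed. For
every condition the onset speed solves D = v₀T + ½aT², which makes the
mean speed D/T identical across accelerations at fixed T. Closed-form
state propagation (`state_at`) is checked in tests against midpoint-rule
numerical integration at 0.1 ms steps.

Retinal variables use the eye-to-ball distance d_eye (ball-to-ring
distance plus the 0.5 m eye-to-ring offset): θ = 2·atan(s/(2·d_eye))
exactly, with the analytic derivative θ̇ = s·v/(d_eye² + s²/4). The exact
arctan is kept for traces because it costs nothing; the small-angle form
is reserved for the known-size predictor below, where it is part of the
model definition. The eye height (ring − 0.5 m) is an inference from the
scene description; it affects only the retinal traces, not the
predictors, which are referenced to the interception point.

## Arrival-time predictors

**Gravity-prior predictors.** The hypothesis is that at some engagement
time t_e after motion onset the observer extrapolates the remaining fall
*as if* the ball were gravitationally accelerated from its current state.
Given the true state (remaining distance d, speed v) at t_e, the
predicted arrival is t_e + τ with τ the positive root of
d = vτ + ½gτ² (the negative root is unphysical). A grid of engagement
times 0–600 ms every 50 ms yields thirteen predictors. For
gravity-congruent motion the extrapolation coincides with the truth, so
every gravity predictor returns T exactly; for constant-velocity and
decelerating motion the predictions are too early, increasingly so for
earlier engagement and for stronger incongruence (decelerating <
constant-velocity < true duration at every grid point). Past-arrival
engagement times degenerate to the true duration. The closed form is
tested against a numerical integration oracle that switches the
acceleration to g at t_e (agreement well under 0.5 ms).

**Known-size (KS) optical predictor.** The interceptive action is
triggered when the retinal dilation rate crosses a threshold calibrated
from the ball's known size: θ̇_th = s/(v̄·T_ca²), where T_ca = 150 ms is
the motor delay of the button press and v̄ is the mean target speed over
the 100 ms window 150–250 ms before arrival (for the linear speed
profiles used here, the window average equals the speed at the window
midpoint, T − 200 ms). The model evaluates θ̇(t) = s·v(t)/d(t)² in the
small-angle form with d the ball-to-ring distance, finds the earliest
crossing by bracketed root-finding (`scipy.optimize.brentq`), and
predicts the response at crossing + T_ca. For constant-velocity motion
this is exact: the crossing sits exactly T_ca before arrival. Referencing
d to the interception point rather than the eye, and using the
small-angle form, are deliberate: this reconstruction reproduces the
reference predictor values (exactly for constant velocity, within a few
ms elsewhere); an eye-referenced distance does not. Predictor tables are
kept at full precision; rounding to whole ms is display-only.

## Synthetic response generator

The generator is the hierarchical twin of the analysis model. Per subject
i a correlated random intercept/slope pair (b₀ᵢ, b₁ᵢ) is drawn from a
bivariate normal; per condition j the latent mean response is

    β₀ + b₀ᵢ + (β₁ + b₁ᵢ)·P_j + ε_ij,   ε_ij ~ N(0, σ_cond),

and each of the 20 trials adds N(0, σ_trial). The driving predictor is
P_j = (1 − w)·gravity(t_e) + w·optical, so `w_optical` > 0 injects a
genuine optical contribution for sensitivity experiments; the default is
w = 0. Defaults mirror the reference population estimates: β₀ = −8.8 ms,
β₁ = 0.99, sd(b₀) = 68.08 ms, sd(b₁) = 0.02, cor = −0.5, engagement
450 ms, 32 subjects × 12 conditions × 20 trials. The two noise scales
(σ_cond = 20 ms, σ_trial = 60 ms) are chosen so that per-condition trial
SDs (~60 ms) and the residual SD of the regression on the 384
condition means (≈ √(20² + 60²/20) ≈ 24 ms) are simultaneously
realistic. Trials are laid out in a seeded uniform permutation of 20
copies of the 12 conditions (240 per subject); no pseudorandomization
constraints are imposed because none are specified for the task being
emulated. The generator is stationary — no learning or feedback effects —
and bit-reproducible under a fixed seed.

Timing error is TE = RT − 1000·T (negative = anticipated). Outlier
filtering is a single pass per subject × condition cell: trials with
|TE − mean| > 2·SD (n−1 denominator) are flagged; zero-variance cells
keep everything. Aggregation over kept trials yields the 384-row
subject × condition summary table (mean RT, mean TE, std TE, n).

What the generator does **not** emulate: condition-dependent precision.
Trial noise is homoscedastic, so the generative std TE is flat across
conditions, whereas real interception data show precision degrading from
gravity-congruent to decelerating targets. The generative accuracy
pattern (|mean TE| ordered congruent < constant-velocity < decelerating,
growing with duration for the incongruent conditions) follows from the
predictor geometry and is asserted on the latent means, where it holds
exactly. Passing tests therefore validate the accuracy structure and the
estimation machinery, not any claim about precision mechanisms, motor
noise structure, eye movements, or sequential adaptation.

## Descriptive statistics

Accuracy (mean TE) and precision (std TE) are each submitted to a
balanced two-way within-subject ANOVA (acceleration × duration) with
Greenhouse–Geisser correction. Sums of squares use the standard balanced
decomposition with effect-specific subject-interaction error terms. The
GG epsilon is estimated per effect as ε = tr(M)²/(q·tr(M²)), with
M = K S K′, S the sample covariance of the subject × cell matrix, K the
effect's orthonormal contrast matrix (normalized Helmert factors,
Kronecker-combined) and q the effect's degrees of freedom; ε is clipped
to [1/q, 1] and both F degrees of freedom are multiplied by it. The
implementation is in-package because the available library implementation
warns that its own two-way epsilon may be inaccurate when both factors
have more than two levels; F and uncorrected p are nevertheless verified
against that library exactly, and the two-level case against the paired-t
equivalence F = t².

## Bayesian mixed regression

The analysis model for the 384 condition means is

    rt_ij = (β₀ + b₀ᵢ) + (β₁ + b₁ᵢ)·P_j [+ β₂·O_j] + e_ij,

with correlated subject random effects (b₀ᵢ, b₁ᵢ) ~ N(0, Σ) and
e_ij ~ N(0, σ²). The first predictor (a gravity column) carries fixed +
random effects; the optical predictor, when present, enters as a fixed
effect only. Priors: Normal(0, 1) on each fixed slope (sensible because
the slope is ms/ms, hence dimensionless); Student-t(3, median(y), s_y)
on the intercept and half-Student-t(3, 0, s_y) on the random-effect SDs
and σ, with s_y = max(2.5·mad_sd(y), 10) — the conventional
weakly-informative defaults for this model family (a config knob);
uniform on the correlation (LKJ(1) for a 2×2 correlation matrix).

**Sampling.** The subject random effects are marginalised analytically:
with a balanced design every subject shares the 12×2 random-effect
design Z, so the marginal likelihood is a product of multivariate
normals with common covariance V = ZΣZ′ + σ²I, evaluated with one
Cholesky per parameter value. The remaining 7–8 hyperparameters are
sampled with emcee's affine-invariant ensemble in unconstrained
coordinates (log SDs, atanh correlation, with Jacobians), using
differential-evolution moves. The ensemble is deliberately wide (128
walkers, 1200 steps, 500 burn-in by default): DE moves mix dramatically
better with many walkers, the batched likelihood makes walkers nearly
free, and the default run achieves split-Rhat ≤ 1.01 and bulk ESS in the
thousands on the 4000 retained draws (4 pseudo-chains of 1000, formed
from disjoint walker groups). A fit flags `converged = False` whenever
max Rhat ≥ 1.01. Initialisation is a cloud around per-subject
least-squares moments; a hard box on the unconstrained coordinates and a
PSD fallback in the likelihood keep wild ensemble proposals finite. A
floor of 1e−8 on σ lets exactly noise-free data (used in degenerate
recovery tests) remain well-posed.

**Posterior quantities.** For each retained draw the subject random
effects are drawn exactly from their conditional Gaussian posterior
b_i | y, θ (mean ΣZ′V⁻¹r_i, covariance Σ − ΣZ′V⁻¹ZΣ, PSD-safe square
root via eigendecomposition). This yields per-draw fitted values,
pointwise log-likelihoods (hence PSIS-LOO via arviz), posterior
predictive replicates, and the Bayesian R² computed per draw as
Var(fitted)/(Var(fitted) + σ²_draw). The expected error variance is the
posterior mean of σ². The engagement-time scan fits one model per grid
point (offsetting the sampler seed per point) and reports the R²/σ²
profile and the best time (highest R²; on well-specified synthetic data
the σ² minimum coincides). Model comparison uses PSIS-LOO: the ELPD
difference and its SE from the pointwise ELPD contributions; a
difference is declared significant when it exceeds 4 and exceeds its SE.
Pareto-k values above 0.7 trigger a warning.

**Cross-checks.** Posterior point estimates are verified in tests against
a likelihood-based mixed model (statsmodels MixedLM) on the same data,
and the sampler against degenerate (noise-free), pure-noise, and
scaling-equivariance constructions.

## Problem sizes and numerical choices

- Predictor tables and kinematics are closed-form; tolerances against the
  printed reference tables are ±3 ms for gravity cells (their own
  rounding jitter against exact recomputation is 1–3 ms) and ±5 ms for
  the optical column (±2 ms for constant velocity).
- Multi-replicate experiments (engagement-time recovery over 10 seeds on
  the 300–600 ms half-grid; LOO specificity/sensitivity over 5 seeds per
  scenario) use a reduced ensemble (64 walkers, 700–900 steps), chosen
  because the scan and comparison decisions depend on posterior means of
  R²/σ²/ELPD, which are stable at that length even when the strict
  Rhat < 1.01 gate is not yet met; single-model inference uses the full
  defaults.
- Ties in the scan resolve to the earlier engagement time; `brentq`
  brackets are [0, T − 1 ns]; the outlier filter is single-pass.

## Known limitations

- Homoscedastic trial noise (see above): no precision ordering across
  conditions, so std-TE ANOVAs on synthetic data test only the null
  machinery.
- The ensemble sampler's pseudo-chains are walker groups of one ensemble,
  not independent chains; Rhat is therefore a mixing diagnostic rather
  than a strict multi-start convergence proof.
- The real participant dataset is not publicly deposited, so the fitted
  population estimates serve as generative defaults; the package makes no
  claim to reproduce the original posterior numerics, ANOVA F values, or
  discard counts.
- No 3D rendering, stereo disparity, drag, or alternative optical models
  (τ-only, λ-threshold) are implemented.
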