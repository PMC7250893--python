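# Methods

This note documents the statistical machinery implemented in `spatedm`, the
conventions it fixes where the underlying methods leave choices open, what the
synthetic-data generator does and does not emulate, and the problem sizes used
in the validation suite.

## Survey statistics

All survey inputs are long-format CPUE tables (catch per unit effort,
individuals per hauling hour) indexed by `(quarter_step, subarea, class)`.
The time grid is biquarterly: only the first and third quarters of each year
are sampled, and `quarter_step` is a 0-based consecutive index over the
interleaved Q1/Q3 sequence. All lags and embeddings count in these steps.

Before any statistic is computed, two retention rules apply, grids first:

1. subareas whose CPUE is zero at every surveyed time step are removed (the
   species never inhabited them; zeros *within* otherwise occupied subareas
   are data and are kept);
2. quarter steps surveyed in fewer than `min_grids` (default 10) subareas are
   removed, because spatial statistics over a handful of grid cells are
   biased.

Fewer than 30 retained steps triggers a warning: state-space methods on
shorter series are unreliable.

Per quarter step the package computes:

* **Population spatial variability** `CV_q = sigma_q / mu_q`, the coefficient
  of variation of total CPUE (summed over classes) across subareas.
* **Age diversity** `Shannon_q = -sum_a p_qa ln p_qa`, the Shannon entropy of
  the age-class composition of the quarter's total CPUE (summed over
  subareas). Zero shares contribute nothing.
* **Total abundance** `CPUE_q`, the grand sum over subareas and classes.

Conventions fixed for reproducibility: the *sample* standard deviation
(denominator n−1) everywhere, and natural logarithms for the Shannon index
and the Taylor fit. Quarters where a statistic is undefined (zero mean, all
zeros, fewer than two subareas) become NaN slots on the full grid and are
logged; keeping the grid intact lets lagged embeddings see the gaps.

**Preprocessing** before any state-space analysis: an OLS regression of the
series on the time index removes a linear trend when the slope is significant
(two-sided p < 0.05); the series is then z-scored (mean 0, sample SD 1).
Detrending precedes normalisation; since z-scoring is applied last, the
order does not affect the downstream analyses.

**Taylor's power law** is fitted as `log V = log a + b log M` by OLS over
quarters, using the spatial mean `M` and sample variance `V` of total CPUE
over subareas; quarters need `M > 0`, `V > 0` and at least three subareas.
Under this law the spatial CV scales as `a' M^(b/2−1)`, so the fitted
exponent classifies the CV–abundance relationship: negative for `b < 2`,
positive for `b > 2`, neutral at `b = 2` (tie tolerance 1e−6).

## State-space reconstruction

**Embedding.** `lag_embed` builds state vectors from lagged coordinates of
one series (`<X(t), X(t−τ), …>`) or from several series at specified lags.
Rows containing any missing coordinate are dropped; each retained row is
aligned with the target's next-step value. Distances are Euclidean.

**Simplex projection** forecasts each state's next value from its `E+1`
nearest neighbours (weights `exp(−d/d_nearest)`, normalised), leave-one-out:
the target's own row is excluded from its neighbour search. A floor of
1e−12 on the nearest distance keeps duplicate states from dividing by zero
(they receive near-delta weights). The optimal embedding dimension `E*`
maximises the Pearson skill ρ over `E ∈ {1..10}`; ties break toward the
smaller dimension, and a reconstruction whose best skill is below 0.1 is
flagged low-skill. Leave-one-out rather than split-half evaluation is used
throughout because ~50-point series cannot afford a holdout; only the
target's own row is excluded, not temporal neighbours, so skill on strongly
autocorrelated series is slightly optimistic — a known, documented bias that
affects all candidate dimensions equally.

**S-map.** At each target state `x(t*)` the solver fits a locally weighted
linear map from the library (all other rows with a next-step target) to the
next-step target, with weights `w(d) = exp(−θ d / d̄)` where `d̄` is the mean
distance from `x(t*)` to the library. The weighted system `B = A·C` (weighted
coordinates plus weighted intercept column) is solved by SVD least squares;
singular values below 1e−10 of the largest are truncated, which stabilises
near-collinear weighted designs on short series. The prediction is
`C_0 + Σ_j C_j x_j(t*)`; the per-step coefficient of coordinate `j` estimates
the Jacobian element ∂x_i(t+1)/∂x_j(t), i.e. the time-varying influence of
variable `j` on the target. At `θ = 0` the weights are uniform and each
step's solve reduces exactly to ordinary least squares on its library — the
model is then a vector autoregression. θ is tuned over `{0..8}` by
leave-one-out skill; ties break toward the smaller θ. Significance of a
model is a one-sided Student t-test on ρ
(`t = ρ sqrt((n−2)/(1−ρ²))`, df = n−2), gated at p < 0.10 for attribution
models and p < 0.05 inside the CCM convergence test.

## Convergent cross mapping

To test "cause → effect" the *effect* series is the library variable: its
shadow manifold (univariate embedding at its own `E*`) predicts the
contemporaneous cause values via simplex-style neighbour weighting, and the
skill `ρ(L)` is tracked as the library grows from `L_min = E*` to the full
row count. (With an E-dimensional embedding only `n−E+1` complete vectors
exist, so "the entire time series" as the maximal library means all
embedding rows.)

Libraries are uniform random subsamples without replacement, drawn freshly
per `(replicate, L)`. Each replicate's curve faces two one-sided tests at
α = 0.05: Kendall's τ for a monotone increase of ρ with L, and a Student
t-test for `ρ(L_max) > 0`. A link is declared significant when at least 95%
of 200 replicates pass both. Lagged causality is scanned by aligning
`cause(t−lag)` with the manifold at `t` for lags 0..8 (quarterly) or 0..4
(yearly); the retained lag maximises the mean `ρ(L_max)` among significant
lags, and "n.s." is reported when none is significant.

The library-size grid is `L_grid_size` evenly spaced integers (default 15).
On short series (~50 steps) the package's own analyses use a dense grid
(`L_grid_size = 40`, i.e. nearly every size): the per-replicate Kendall test
draws its power from the number of grid points, and skill curves that
converge quickly and then saturate otherwise fail the monotonicity test in a
substantial fraction of replicates even for strong links. The strict
95%-pass rule is conservative by construction; its type-I rate on
independent AR(1) pairs is far below nominal (see the validation suite).

## Attribution of influences

After CCM, the attractor for the target (spatial variability) is
reconstructed multivariately: the target plus the top `E*−1` significant
causes ranked by cross-map skill (ties: higher skill, then smaller best lag,
then name). All coordinates enter **contemporaneously** (lag 0): CCM lags
identify causality and its delay, but the prediction model maps the
variables' current states to the target's next value. Embedding CCM-lagged copies of causes instead was
tried and rejected: conditioned on the target's own lag-0 coordinate, a
lagged cause coordinate degenerates into a mean-reversion proxy whose
coefficient sign is unidentifiable, and cross-map skill does not decay with
lag (the shadow manifold spans lagged coordinates), so "best lag by ρ"
wanders. With fewer significant causes than `E*−1`, the suboptimal dimension
`k+1` is used; with none, the recorded verdict is "no causal variables" (the
sprat-type outcome) rather than an exception.

Mean influences (time-averages of per-step coefficients) are reported only
for models passing the p < 0.10 gate. Sensitivity re-embeddings fit all
alternative `(E*−1)`-subsets of significant causes (single-variable swaps in
rank order when more than `max_sensitivity_models = 20` subsets exist).

The fishing-mortality analysis runs on annual averages (fishing mortality is
reported yearly): a CCM lag scan with lags 0..4 per target (age diversity,
abundance, spatial CV), then one bivariate S-map per significant lag with
the fishing term at that lag, and the fishing influence averaged —
sign-preserving — over all significant lags to damp short-series
variability. At 25 yearly points this analysis has little power (a low-power
warning fires below 20 points); the validation suite therefore exercises the
mechanism at 50 years.

## Synthetic data

Two generator families provide every input with known truth.

**Coupled systems** (`gen_coupled_system`): coupled logistic maps
(`x_j(t) = x_j(t−1)(r_j − r_j x_j(t−1) − Σ a_ij x_i(t−d_ij))`, admissible
parameters keep trajectories in (0,1) without clipping), linear VARs with
Gaussian noise, and forced drivers; adjacency, delays and noise are declared
up front and exported for scoring. 200 burn-in steps are discarded.
Observation noise is additive Gaussian scaled to the series SD.

**Survey scenarios** (`gen_survey`): an age-structured stock surveyed twice
a year over a 1-D habitat axis of `n_subareas` cells (defaults: 25 years,
40 subareas, 6 age classes — the scale of the motivating surveys).
Internally the stock is tracked in half-year cohort classes with recruitment
every survey occasion (log-AR(1) anomalies, marginal SD 0.6, persistence
0.5), so the dynamics carry no Q1/Q3 parity artifacts; classes are reported
as yearly ages. Mortality is `M + F_y · sel(age)` with logistic selectivity;
the oldest class is a plus-group. Each class prefers a Gaussian habitat band;
realized occupancy can carry inertia (a fraction of last step's field,
cohorts keeping their location as they age). CPUE is density × catchability
× lognormal mean-one noise (σ = 0.3, a standard figure for trawl catches).
The emitted truth record holds latent abundance, Shannon diversity, the
latent spatial CV, and a first-moment approximation of the CV expected under
observation noise (the concavity of the square root makes realized CVs run a
few percent below this approximation where noise dominates, so fidelity
tests compare CV and entropy on noise-free replicas and abundance — which is
exactly unbiased — on noisy ones).

*Aggregation control.* The habitat width scales as `(N/N_ref)^γ`. For a
Gaussian occupancy bump of width `w` on `S` cells with spacing `dh`, the
spatial variance of occupancy shares is `A/w − 1/S²` with
`A = dh/(2√π S)`, giving `d log V / d log N = 2 − γ/(1−q)`,
`q = 2√π w/(S·dh)`; inverting at the baseline width calibrates γ for a
target Taylor exponent (`SurveyScenario.taylor_regime`). The 50-replicate
mean fitted exponents land within ~0.06 of targets 1.5 and 2.5.

*Hypothesis-1 scenario* (`SurveyScenario.age_truncation`): fishing ramps
from 0.1 to 1.4 yr⁻¹ with persistent management-like variation, selectively
on older ages, progressively truncating the age structure. The causal link
to spatial variability is structural: the occupied habitat width responds
positively to an exponentially weighted history of age diversity (a diverse
stock occupies more habitat), and negatively to a persistent AR(1)
temperature anomaly (warming contracts the band). Diversity therefore drives
the *next* step's spatial CV with a genuinely negative partial derivative,
while temperature provides an independent driver so that the diversity–CV
relationship is not collinear with the target's own dynamics. The effect
size (width response 1.5 per entropy unit) is chosen so the designed
mechanism dominates observation noise — this is a validation scenario, not a
calibrated North Sea model.

What the generator does **not** emulate: 2-D geography and oceanography,
survey gear/vessel effects, length-based growth (the length view is a fixed
age→length binning), density-dependent mortality, or species interactions.
Passing tests demonstrate that the pipeline recovers known structure under
these idealised conditions; they do not certify performance on real surveys,
where drivers are confounded and effect sizes are smaller.

## Validation problem sizes

The test suite validates, with all randomness seeded: analytic identities
(exact); θ=0 reduction to per-library OLS (50 random state matrices, 1e−8);
brute-force neighbour-search equivalence (n = 200, 1e−12); Jacobian recovery
on `x(t+1) = 0.5x + 0.3y + ε` (n = 500, ±0.1); CCM power on coupling-0.3
logistic pairs (50 datasets, n = 200, 200 replicates, 8-point L-grid,
≥ 80%); type-I on independent AR(1) pairs (100 datasets, n = 50, ≤ 10%);
modal lag recovery under a 3-step delay (50 datasets); Taylor regimes 1.5
and 2.5 (50 replicates each, 50 quarters × 40 subareas, ±0.2); and the
end-to-end hypothesis-1 pipeline (50 replicate runs, negative age-diversity
coefficient in ≥ 90%). `scripts/acceptance.py` recomputes the same
quantities at reduced replicate counts so a full report takes a few minutes.

## Known limitations

* Leave-one-out skill without an exclusion radius slightly inflates ρ on
  autocorrelated series (affects all models equally; rankings are stable).
* The 95%-pass convergence rule is conservative; weak true links on short
  series are often reported "n.s." — consistent with the sparse significant
  entries such analyses report on real data.
* Attribution assumes the significant causes span the attractor; when key
  drivers are unobserved the S-map fit is poor and the gate (p ≥ 0.10)
  correctly withholds influences, but cannot flag *which* driver is missing.
* The yearly fishing analysis at 25 points is underpowered by construction;
  its results should be read as exploratory.
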