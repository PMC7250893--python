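# spatedm

Causal analysis of fish population spatial variability from trawl-survey
CPUE, built on empirical dynamic modeling (EDM).

Exploited fish stocks do not just shrink — they redistribute. The spatial
variability of a population, measured as the coefficient of variation (CV)
of catch per unit effort (CPUE) across survey grid cells, responds to the
completeness of the age structure, to abundance, and to the environment,
but these drivers are interdependent and weakly coupled, so correlation and
regression give ambiguous answers. This package implements the
nonlinear-dynamics alternative: treat the biquarterly survey series as
observations of one dynamical system, reconstruct its attractor from lagged
coordinates, and ask causal questions of the reconstruction.

It provides, as a tested reusable pipeline:

* **Survey statistics** — spatial CV of CPUE over subareas
  (`CV_q = σ_q/μ_q`), Shannon age diversity
  (`−Σ_a p_qa ln p_qa`), total abundance, the survey filtering rules
  (always-zero subareas removed; quarters with < 10 grids removed), and
  Taylor's power law `V = aM^b`, whose exponent classifies the
  CV–abundance relationship (`CV ∝ M^(b/2−1)`: negative below `b = 2`,
  positive above).
* **EDM from scratch** — lagged-coordinate embedding, simplex projection
  (selects the embedding dimension `E*`), and the S-map: locally weighted
  linear maps with weights `exp(−θd/d̄)` whose per-time-step coefficients
  estimate Jacobian elements, i.e. time-varying interaction strengths.
* **Convergent cross mapping (CCM)** — "cause → effect" holds when the
  effect's shadow manifold predicts the cause and the skill ρ(L) converges
  with library size: a one-sided Kendall τ test for monotone increase plus
  a one-sided t-test on ρ(L_max), both at α = 0.05, passed by ≥ 95% of 200
  random-library replicates; lags 0–8 are scanned and the best significant
  lag retained.
* **Attribution** — multivariate S-map on the target plus its top `E*−1`
  CCM-determined causes, θ tuned over 0–8, influences reported for models
  with p < 0.10; sensitivity re-embeddings over alternative cause subsets;
  a yearly fishing-mortality analysis (lags ≤ 4, influences averaged over
  all significant lagged terms).
* **Synthetic data with known truth** — coupled logistic/VAR systems for
  validating CCM and S-map, and an age-structured spatial survey simulator
  (25 years × Q1/Q3 × 40 subareas × 6 ages, lognormal observation noise)
  with scenario presets for fishing-induced age truncation and for
  targeted Taylor exponents.

See `docs/methods.md` for the full statistical conventions and the
generator's mechanics.

## Worked example

Generate an age-truncation scenario — ramping, old-age-selective fishing
erodes age diversity while, by construction, a diverse age structure
occupies more habitat (lower spatial CV) — and ask the pipeline whether it
recovers that negative influence:

```python
import numpy as np
from spatedm import (RunConfig, SurveyScenario, gen_survey, filter_survey,
                     spatial_cv, age_diversity, preprocess, lag_scan,
                     select_embedding, estimate_influence, select_E)

real = gen_survey(SurveyScenario.age_truncation(rng_seed=3))
cv = preprocess(spatial_cv(filter_survey(real.length_table)))
sh = preprocess(age_diversity(filter_survey(real.age_table)))

cfg = RunConfig(n_ccm_replicates=100, L_grid_size=40, lag_max_quarterly=4)
rng = np.random.default_rng(0)
scan = lag_scan(cv, sh, cfg.lag_max_quarterly, cfg, rng,
                cause_name="age_diversity", effect_name="spatial_cv")
print("age_diversity -> spatial_cv:", scan.verdict)

E_star = select_E(cv.values, cfg.E_max).E_star
sel = select_embedding("spatial_cv", [scan], E_star)
att = estimate_influence(sel.embedding,
                         {"spatial_cv": cv, "age_diversity": sh}, cfg)
print(f"S-map: theta={att.model.theta:g} rho={att.model.rho:.3f} "
      f"p={att.model.p_value:.2g}")
print(f"mean influence of age diversity on spatial CV: "
      f"{att.mean_influence['age_diversity']:+.3f}")
```

```
age_diversity -> spatial_cv: rho=0.8695 (lag 2)
S-map: theta=1 rho=0.884 p=2.1e-17
mean influence of age diversity on spatial CV: -0.294
```

Reading the output: cross mapping from the spatial-CV manifold predicts age
diversity with skill 0.87 and converges with library size in 100 of 100
replicates, so age diversity is a causal driver. The S-map reconstruction
(nonlinearity θ = 1, skill 0.88) then quantifies the influence: the
time-averaged coefficient is −0.29 — higher age diversity lowers the next
step's spatial variability, matching the mechanism built into the scenario.

The same flow is available from the shell:

```sh
spatedm --outdir demo --seed 3 simulate --scenario age-truncation
spatedm --outdir demo taylor --length-table demo/survey_length.csv
# a=7.0630 b=1.2795 r2=0.1553 n=50 direction=negative
```

Here `b < 2`: the population diffuses as it grows, so its spatial CV falls
with abundance. Subcommands `metrics`, `ccm`, `smap` and `report` expose
the intermediate stages and write the summary CSVs (per-variable cross-map
table, influence table, per-step coefficient series, Taylor fits).

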