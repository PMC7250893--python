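"""Synthetic inputs with known causal structure.

Two generator families:

* :func:`gen_coupled_system` — small coupled dynamical systems (coupled
  logistic maps, linear vector autoregressions, forced drivers) whose
  adjacency, delays and noise are declared up front, used to validate
  simplex projection, CCM and S-map against ground truth.

* :func:`gen_survey` — an age-structured population surveyed on a spatial
  grid twice a year (Q1/Q3), emulating trawl-survey CPUE tables.  Each age
  class prefers a distinct habitat band, yearly recruitment is lognormal,
  fishing removes old ages selectively, and CPUE carries lognormal
  observation noise.  The emitted truth record holds the latent per-step
  spatial CV, age diversity and abundance, so pipeline estimates can be
  scored against what the generator actually did.

Aggregation tendency (the Taylor exponent ``b``) is controlled through
behaviour, not bookkeeping: the habitat-preference width shrinks with
abundance for ``b > 2`` (crowding into favoured habitat) and widens for
``b < 2`` (spillover into marginal habitat).  See
:meth:`SurveyScenario.taylor_regime` for the width-exponent calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EnvSeries, SurveyTable, quarter_step_grid
from .errors import ParameterError

__all__ = [
    "CoupledSystemTruth",
    "SurveyScenario",
    "SurveyRealization",
    "gen_coupled_system",
    "gen_survey",
    "gen_taylor_table",
]

logger = logging.getLogger(__name__)

_BURN_IN = 200
MAP_TYPES = ("logistic-coupling", "linear-VAR", "forced-driver")


@dataclass
class CoupledSystemTruth:
    """Declared causal structure of a coupled system.

    ``adjacency[i, j]`` is the strength with which variable ``i`` forces
    variable ``j``; ``delays[i, j]`` is the corresponding delay in steps
    (the value of ``j`` at time ``t`` depends on ``i`` at ``t - delay``).
    Logistic variables follow ``x_j(t) = x_j(t-1) * (r_j - r_j x_j(t-1)
    - sum_i a_ij x_i(t - d_ij))`` and stay in (0, 1) without clipping for
    admissible parameters; linear-VAR variables follow
    ``x_j(t) = sum_i a_ij x_i(t - d_ij) + noise``.
    """

    names: tuple[str, ...]
    map_type: str
    adjacency: np.ndarray
    delays: np.ndarray | None = None
    noise_sd: float = 0.0  # process noise
    obs_noise_sd: float = 0.0  # additive noise on the emitted series, in SD units
    growth_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.names)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.shape != (k, k):
            raise ParameterError("adjacency must be k x k")
        if self.map_type not in MAP_TYPES:
            raise ParameterError(f"unknown map_type {self.map_type!r}")
        if self.delays is None:
            d = np.ones((k, k), dtype=int)
            if self.map_type == "linear-VAR":
                np.fill_diagonal(d, 1)
            self.delays = d
        else:
            self.delays = np.asarray(self.delays, dtype=int)
            if self.delays.shape != (k, k):
                raise ParameterError("delays must be k x k")
            if (self.delays < 0).any():
                raise ParameterError("delays must be >= 0")
        if self.map_type != "linear-VAR":
            if self.growth_rates is None:
                self.growth_rates = np.full(k, 3.7)
            else:
                self.growth_rates = np.asarray(self.growth_rates, dtype=float)
            if np.diag(self.adjacency).any():
                raise ParameterError("logistic self-coupling is set by growth_rates")
            if (self.delays[self.adjacency != 0] == 0).any():
                self._check_acyclic_instantaneous()
        elif (np.asarray(self.delays)[self.adjacency != 0] == 0).any():
            raise ParameterError("linear-VAR edges need delay >= 1")

    def _check_acyclic_instantaneous(self) -> None:
        inst = (self.adjacency != 0) & (self.delays == 0)
        order, _ = _topo_order(inst)
        if order is None:
            raise ParameterError("delay-0 couplings form a cycle")


def _topo_order(edges: np.ndarray):
    """Kahn topological sort of a boolean edge matrix (i -> j)."""
    k = edges.shape[0]
    indeg = edges.sum(axis=0)
    order, ready = [], [j for j in range(k) if indeg[j] == 0]
    indeg = indeg.copy()
    while ready:
        u = ready.pop()
        order.append(u)
        for v in np.nonzero(edges[u])[0]:
            indeg[v] -= 1
            if indeg[v] == 0:
                ready.append(int(v))
    if len(order) < k:
        return None, None
    return order, indeg


def _offending_edge(truth: CoupledSystemTruth, j: int) -> str:
    col = np.abs(truth.adjacency[:, j])
    if col.any():
        i = int(np.argmax(col))
        return f"{truth.names[i]} -> {truth.names[j]} (strength {truth.adjacency[i, j]:g})"
    return f"self-dynamics of {truth.names[j]}"


def gen_coupled_system(
    truth: CoupledSystemTruth, n: int, seed: int | np.random.Generator
) -> dict[str, np.ndarray]:
    """Realise ``n`` post-burn-in steps of the declared system."""
    if n < 50:
        raise ParameterError("n must be >= 50")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(truth.names)
    total = n + _BURN_IN
    a, d = truth.adjacency, truth.delays
    max_d = int(d.max(initial=1))
    x = np.empty((total, k))

    if truth.map_type == "linear-VAR":
        x[: max_d + 1] = rng.normal(0, max(truth.noise_sd, 1e-3), size=(max_d + 1, k))
        noise = rng.normal(0, truth.noise_sd, size=(total, k))
        for t in range(max_d + 1, total):
            for j in range(k):
                x[t, j] = sum(
                    a[i, j] * x[t - d[i, j], i] for i in range(k) if a[i, j] != 0
                ) + noise[t, j]
            if np.abs(x[t]).max() > 1e6:
                j = int(np.argmax(np.abs(x[t])))
                raise ParameterError(
                    f"divergent trajectory via {_offending_edge(truth, j)}"
                )
    else:
        r = truth.growth_rates
        inst = (a != 0) & (d == 0)
        order, _ = _topo_order(inst)
        x[: max_d + 1] = rng.uniform(0.2, 0.8, size=(max_d + 1, k))
        pnoise = (
            rng.normal(0, truth.noise_sd, size=(total, k))
            if truth.noise_sd > 0
            else None
        )
        start = max(max_d, 1)
        for t in range(start, total):
            for j in order:
                drive = sum(
                    a[i, j] * x[t - d[i, j], i]
                    for i in range(k)
                    if a[i, j] != 0
                )
                prev = x[t - 1, j]
                val = prev * (r[j] - r[j] * prev - drive)
                if pnoise is not None:
                    val += pnoise[t, j] * val * (1 - val)
                if not (0.0 < val < 1.0):
                    raise ParameterError(
                        f"trajectory left (0,1) via {_offending_edge(truth, j)}"
                    )
                x[t, j] = val

    out = x[_BURN_IN:]
    series = {}
    for j, name in enumerate(truth.names):
        col = out[:, j].copy()
        if truth.obs_noise_sd > 0:
            col = col + rng.normal(0, truth.obs_noise_sd * col.std(), size=n)
        series[name] = col
    return series


# ---------------------------------------------------------------------------
# age-structured spatial survey
# ---------------------------------------------------------------------------


@dataclass
class SurveyScenario:
    """Parameters of the age-structured spatial survey simulator.

    Defaults emulate the study conditions the pipeline is meant for: a
    25-year biquarterly (Q1/Q3) survey over 40 subareas with six age
    classes, lognormal yearly recruitment, age-selective fishing, and
    lognormal observation noise (sigma 0.3) on CPUE.
    """

    n_years: int = 25
    start_year: int = 1991
    n_subareas: int = 40
    n_ages: int = 6
    recruitment_mean: float = 1000.0
    recruitment_sigma: float = 0.6  # lognormal sd of yearly recruitment (log scale)
    recruitment_phi: float = 0.5  # AR(1) persistence of log-recruitment anomalies
    natural_mortality: float = 0.3  # per year
    fishing_mortality: float | np.ndarray = 0.2  # per year, scalar or per-year array
    fishing_age50: float = 2.5  # logistic selectivity midpoint (age)
    fishing_sel_slope: float = 1.5
    pref_centers: np.ndarray | None = None  # habitat centre per age, in [0, 1]
    pref_width: float = 0.12
    occupancy_inertia: float = 0.0  # fraction of last step's spatial field retained
    width_diversity_coeff: float = 0.0  # diverse age structure widens occupancy (lagged)
    diversity_memory: float = 0.5  # EWMA weight on older diversity in the width driver
    width_abundance_exponent: float = 0.0  # gamma: width ~ (N / N_ref)^gamma
    temp_base: float = 8.0  # deg C
    temp_trend: float = 0.0  # deg C per year
    temp_seasonal_amp: float = 2.0  # Q3 minus Q1, deg C
    temp_anomaly_sd: float = 0.6  # SD of the AR(1) interannual temperature anomaly
    temp_anomaly_phi: float = 0.7  # persistence of the anomaly across steps
    temp_heterogeneity: float = 0.5  # spatial SD of the temperature field
    temp_shift_per_degree: float = 0.0  # habitat-centre displacement per degree anomaly
    width_temp_coeff: float = 0.0  # warm anomaly contracts habitat width (raises CV)
    catchability: float = 1.0
    obs_noise_sigma: float = 0.3  # lognormal sd on each CPUE cell
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pref_centers is None:
            self.pref_centers = np.linspace(0.15, 0.85, self.n_ages)
        else:
            self.pref_centers = np.asarray(self.pref_centers, dtype=float)
        for name in (
            "recruitment_mean", "recruitment_sigma", "natural_mortality",
            "pref_width", "temp_heterogeneity", "catchability", "obs_noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        f = np.asarray(self.fishing_mortality, dtype=float)
        if (f < 0).any():
            raise ParameterError("fishing mortality must be >= 0")

    def fishing_schedule(self) -> np.ndarray:
        f = np.asarray(self.fishing_mortality, dtype=float)
        if f.ndim == 0:
            return np.full(self.n_years, float(f))
        if f.size != self.n_years:
            raise ParameterError("fishing_mortality must be scalar or per-year")
        return f

    def half_ages(self) -> np.ndarray:
        """Midpoint ages of the internal half-year cohort classes."""
        return (np.arange(2 * self.n_ages) + 0.5) / 2.0

    def selectivity(self) -> np.ndarray:
        """Logistic fishing selectivity over the half-year classes."""
        return 1.0 / (
            1.0 + np.exp(-self.fishing_sel_slope * (self.half_ages() - self.fishing_age50))
        )

    def half_centers(self) -> np.ndarray:
        """Habitat centres interpolated onto the half-year classes."""
        yearly = np.arange(self.n_ages) + 0.5
        return np.interp(self.half_ages(), yearly, self.pref_centers)

    def equilibrium_abundance(self) -> float:
        """Deterministic total abundance under mean recruitment and mean F.

        Recruitment enters every survey occasion (half-year), at half the
        yearly mean.
        """
        z = self.natural_mortality + self.fishing_schedule().mean() * self.selectivity()
        surv = np.concatenate([[1.0], np.exp(-np.cumsum(z[:-1] / 2.0))])
        return float(0.5 * self.recruitment_mean * surv.sum())

    @classmethod
    def age_truncation(cls, rng_seed: int = 0, **overrides) -> "SurveyScenario":
        """Heavy, ramping, old-age-selective fishing: the age structure is
        progressively truncated, so age diversity falls and — because each
        age class holds a distinct habitat band — spatial variability rises.
        """
        n_years = int(overrides.pop("n_years", 25))
        # exploitation ramps up with persistent management-driven
        # year-to-year variation around the trend
        f_rng = np.random.default_rng((rng_seed, 0xF15))
        f_sched = np.linspace(0.1, 1.4, n_years) * np.exp(
            0.25 * _ar1(n_years, phi=0.6, sd=0.8, rng=f_rng)
        )
        defaults = dict(
            n_years=n_years,
            fishing_mortality=f_sched,
            fishing_age50=1.5,
            fishing_sel_slope=2.0,
            recruitment_sigma=0.6,
            recruitment_phi=0.7,
            pref_width=0.10,
            occupancy_inertia=0.5,
            width_diversity_coeff=1.5,
            width_temp_coeff=0.4,
            obs_noise_sigma=0.3,
            rng_seed=rng_seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def taylor_regime(cls, b: float, rng_seed: int = 0, **overrides) -> "SurveyScenario":
        """Single-stock scenario whose fitted Taylor exponent targets ``b``.

        The habitat width scales as ``(N / N_ref)^gamma``.  For a Gaussian
        occupancy bump of width ``w`` sampled on ``S`` cells of spacing
        ``dh``, the spatial variance of occupancy shares is
        ``A/w - 1/S^2`` with ``A = dh / (2 sqrt(pi) S)``, so
        ``d log V / d log N = 2 - gamma / (1 - q)`` with
        ``q = 2 sqrt(pi) w / (S dh)``; inverting at the baseline width
        gives ``gamma = (2 - b) (1 - q)``.
        """
        n_subareas = int(overrides.pop("n_subareas", 40))
        pref_width = float(overrides.pop("pref_width", 0.12))
        dh = 1.0 / (n_subareas - 1)
        q = 2.0 * np.sqrt(np.pi) * pref_width / (n_subareas * dh)
        gamma = (2.0 - b) * (1.0 - q)
        defaults = dict(
            n_subareas=n_subareas,
            n_ages=1,
            pref_centers=np.array([0.5]),
            pref_width=pref_width,
            width_abundance_exponent=gamma,
            recruitment_sigma=0.8,
            fishing_mortality=0.2,
            natural_mortality=0.3,
            obs_noise_sigma=0.2,
            rng_seed=rng_seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SurveyRealization:
    """Everything one scenario run emits: tables, drivers, and the truth."""

    age_table: SurveyTable
    length_table: SurveyTable
    env: dict[str, EnvSeries]
    truth: dict


def _length_class_of_age(ages: np.ndarray) -> np.ndarray:
    # von-Bertalanffy-flavoured age->length map binned to 5 cm classes
    L = 100.0 * (1.0 - np.exp(-0.25 * (ages + 1.0)))
    return (L // 5).astype(int) * 5


def gen_survey(scenario: SurveyScenario) -> SurveyRealization:
    """Run the scenario and emit age/length CPUE tables, environmental
    series, and the truth record.

    The truth record holds, per quarter step: latent total abundance,
    latent age diversity (Shannon over the age composition), the latent
    spatial CV of density, and its expectation after observation noise
    (``spatial_cv``); plus the scenario's aggregation exponent.
    """
    sc = scenario
    rng = np.random.default_rng(sc.rng_seed)
    S, A = sc.n_subareas, sc.n_ages
    H = 2 * A  # internal half-year cohort classes; reported as yearly classes
    n_steps = 2 * sc.n_years
    h = np.linspace(0.0, 1.0, S)
    F = sc.fishing_schedule()
    sel = sc.selectivity()
    centers0 = sc.half_centers()
    n_ref = max(sc.equilibrium_abundance(), 1e-12)
    sig_o = sc.obs_noise_sigma
    v_obs = np.exp(sig_o**2) - 1.0  # relative variance of the noise factor

    # deterministic start at mean-recruitment equilibrium
    z0 = sc.natural_mortality + F[0] * sel
    N = 0.5 * sc.recruitment_mean * np.concatenate(
        [[1.0], np.exp(-np.cumsum(z0[:-1] / 2.0))]
    )

    grid = quarter_step_grid(sc.start_year, sc.start_year + sc.n_years - 1)
    records = []
    truth_rows = []
    temp_mean = np.empty(n_steps)
    temp_cv = np.empty(n_steps)
    # persistent interannual temperature anomaly, shared by the habitat-width
    # response and the emitted temperature series
    anomaly = _ar1(n_steps, phi=sc.temp_anomaly_phi, sd=sc.temp_anomaly_sd, rng=rng)
    # persistent (environmentally forced) log-recruitment anomalies with
    # marginal SD recruitment_sigma, exponentiated mean-one; recruitment
    # arrives every survey occasion so the dynamics carry no Q1/Q3 parity
    phi_step = np.sqrt(max(sc.recruitment_phi, 0.0))
    log_rec = _ar1(
        n_steps,
        phi=phi_step,
        sd=sc.recruitment_sigma * np.sqrt(max(1.0 - phi_step**2, 1e-12)),
        rng=rng,
    )
    recruitment = 0.5 * sc.recruitment_mean * np.exp(log_rec - sc.recruitment_sigma**2 / 2.0)

    occupancy = None  # (H, S) spatial field per half-year class
    # exponentially weighted history of latent diversity: the habitat-width
    # response integrates the recent age structure, not just the last step
    diversity_state = None
    for step in range(n_steps):
        year_idx, quarter = divmod(step, 2)
        if step > 0:
            # advance cohorts one half-year class (oldest is a plus-group)
            old = N
            N = np.concatenate([[0.0], old[:-1]])
            if H > 1:
                N[-1] += old[-1]
            N[0] = recruitment[step]
        # half-year survival at annual rates M + F * selectivity
        z = sc.natural_mortality + F[year_idx] * sel
        N = N * np.exp(-z / 2.0)

        # temperature field
        t_anom = (
            sc.temp_trend * year_idx
            + (sc.temp_seasonal_amp if quarter == 1 else 0.0)
            + anomaly[step]
        )
        T = sc.temp_base + t_anom + sc.temp_heterogeneity * rng.standard_normal(S)
        temp_mean[step] = T.mean()
        temp_cv[step] = T.std(ddof=1) / T.mean() if T.mean() != 0 else np.nan

        # latent age diversity over the reported (yearly) classes
        n_tot = N.sum()
        N_year = N.reshape(A, 2).sum(axis=1)
        p_age = N_year / n_tot if n_tot > 0 else np.full(A, np.nan)
        pa = p_age[p_age > 0]
        shannon = float(-(pa * np.log(pa)).sum()) if n_tot > 0 else np.nan

        # spatial allocation: warm anomalies contract the occupied habitat
        # band (width_temp_coeff > 0); a diverse age structure occupies more
        # habitat on the next survey occasion (width_diversity_coeff > 0)
        width = (
            sc.pref_width
            * (max(n_tot, 1e-12) / n_ref) ** sc.width_abundance_exponent
            * np.exp(-sc.width_temp_coeff * anomaly[step])
        )
        if sc.width_diversity_coeff != 0.0 and diversity_state is not None:
            width *= np.exp(
                sc.width_diversity_coeff * (diversity_state - 0.6 * np.log(max(A, 2)))
            )
        centers = centers0 + sc.temp_shift_per_degree * t_anom
        g = np.exp(-((h[None, :] - centers[:, None]) ** 2) / (2.0 * width**2))
        g_sum = g.sum(axis=1, keepdims=True)
        if (g_sum == 0).any():
            raise ParameterError("habitat preference collapsed outside the grid")
        pref = g / g_sum  # (H, S)
        if occupancy is None:
            occupancy = pref.copy()
        else:
            # cohorts carry their field into the next class, then relax
            # toward the class-preferred habitat
            shifted = np.vstack([pref[:1], occupancy[:-1]])
            if H > 1:
                shifted[-1] = 0.5 * (shifted[-1] + occupancy[-1])
            occupancy = sc.occupancy_inertia * shifted + (1 - sc.occupancy_inertia) * pref
            occupancy /= occupancy.sum(axis=1, keepdims=True)
        density = N[:, None] * occupancy  # (H, S)

        # latent spatial statistics of total density
        tot_s = density.sum(axis=0) * sc.catchability
        mu = tot_s.mean()
        latent_var = tot_s.var(ddof=1)
        latent_cv = np.sqrt(latent_var) / mu if mu > 0 else np.nan
        obs_var = latent_var + v_obs * np.mean(tot_s**2)
        obs_cv = np.sqrt(obs_var) / mu if mu > 0 else np.nan
        if np.isfinite(shannon):
            diversity_state = (
                shannon
                if diversity_state is None
                else sc.diversity_memory * diversity_state
                + (1 - sc.diversity_memory) * shannon
            )

        truth_rows.append(
            dict(
                quarter_step=step,
                abundance=float(n_tot * sc.catchability),
                shannon=shannon,
                spatial_cv_latent=float(latent_cv),
                spatial_cv=float(obs_cv),
            )
        )

        # observed CPUE per reported (yearly) class with lognormal noise
        density_year = density.reshape(A, 2, S).sum(axis=1)
        noise = np.exp(sig_o * rng.standard_normal((A, S)) - sig_o**2 / 2.0)
        cpue = sc.catchability * density_year * noise
        yr = sc.start_year + year_idx
        q_label = 1 if quarter == 0 else 3
        for a_idx in range(A):
            for s_idx in range(S):
                records.append(
                    (step, yr, q_label, f"G{s_idx:02d}", a_idx, cpue[a_idx, s_idx])
                )

    df = pd.DataFrame(
        records, columns=["quarter_step", "year", "quarter", "subarea", "class_id", "cpue"]
    )
    if df["cpue"].sum() == 0:
        logger.warning("gen_survey[extinction]: scenario produced an all-zero table")
    age_table = SurveyTable(records=df, class_kind="age", grid=grid)

    ldf = df.copy()
    ldf["class_id"] = _length_class_of_age(ldf["class_id"].to_numpy())
    ldf = ldf.groupby(
        ["quarter_step", "year", "quarter", "subarea", "class_id"], as_index=False
    )["cpue"].sum()
    length_table = SurveyTable(records=ldf, class_kind="length", grid=grid)

    years = grid["year"].to_numpy()
    quarters = grid["quarter"].to_numpy()
    climate = _ar1(n_steps, phi=0.8, sd=1.0, rng=rng)
    env = {
        "temperature": EnvSeries(
            "temperature", temp_mean, "spatial_mean_temperature", years, quarters
        ),
        "temperature_cv": EnvSeries(
            "temperature_cv", temp_cv, "spatial_cv_temperature", years, quarters
        ),
        "climate_index": EnvSeries(
            "climate_index", climate, "climate_index", years, quarters
        ),
        "fishing_mortality": EnvSeries(
            "fishing_mortality",
            F,
            "fishing_mortality_yearly",
            np.arange(sc.start_year, sc.start_year + sc.n_years),
            None,
        ),
    }
    # implied Taylor exponent of the width-scaling mechanism at baseline width
    dh = 1.0 / (S - 1)
    q_geom = 2.0 * np.sqrt(np.pi) * sc.pref_width / (S * dh)
    truth = {
        "per_step": pd.DataFrame(truth_rows),
        "width_abundance_exponent": sc.width_abundance_exponent,
        "taylor_b_target": 2.0 - sc.width_abundance_exponent / max(1.0 - q_geom, 1e-6),
        "scenario": sc,
    }
    return SurveyRealization(
        age_table=age_table, length_table=length_table, env=env, truth=truth
    )


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0, sd / np.sqrt(1 - phi**2))
    eps = rng.normal(0, sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def gen_taylor_table(
    b: float,
    a: float = 0.05,
    n_quarters: int = 50,
    n_subareas: int = 40,
    sigma_logV: float = 0.1,
    sigma_logM: float = 0.8,
    seed: int | np.random.Generator = 0,
    start_year: int = 1991,
) -> SurveyTable:
    """Survey table sampled directly from Taylor's law ``V = a M^b``.

    Per quarter a spatial mean ``M`` is drawn lognormally, the variance is
    set to ``a M^b`` with lognormal noise on ``log V``, and subarea CPUEs
    are drawn from the lognormal distribution with those two moments.
    Used as the analytic reference for Taylor-fit recovery.  The default
    scale ``a`` keeps spatial CVs moderate, where the sample variance of a
    lognormal field is effectively unbiased; very heavy-tailed settings
    depress the fitted slope at large ``M``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_years = (n_quarters + 1) // 2
    grid = quarter_step_grid(start_year, start_year + n_years - 1)
    records = []
    for step in range(n_quarters):
        M = 10.0 * np.exp(sigma_logM * rng.standard_normal())
        V = a * M**b * np.exp(sigma_logV * rng.standard_normal())
        s2 = np.log1p(V / M**2)
        mu_log = np.log(M) - s2 / 2.0
        cpue = np.exp(mu_log + np.sqrt(s2) * rng.standard_normal(n_subareas))
        yr = grid.loc[step, "year"]
        q = grid.loc[step, "quarter"]
        for s_idx in range(n_subareas):
            records.append((step, yr, q, f"G{s_idx:02d}", 0, cpue[s_idx]))
    df = pd.DataFrame(
        records, columns=["quarter_step", "year", "quarter", "subarea", "class_id", "cpue"]
    )
    return SurveyTable(records=df, class_kind="length", grid=grid)
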