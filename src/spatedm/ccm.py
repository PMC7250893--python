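"""Convergent cross mapping (CCM) with the convergence-test protocol.

To test "cause -> effect", the EFFECT series is the library variable: its
shadow manifold (lagged-coordinate embedding at the effect's optimal
dimension ``E*``) is used to predict the contemporaneous cause values.  If
the cause truly forces the effect, its states are imprinted on the
effect's dynamics and the cross-map skill ``rho(L)`` (Pearson correlation
between predicted and observed cause) converges — improves — as the
library size ``L`` grows from ``L_min = E*`` to the full library.

Convergence is declared per replicate when BOTH
(1) ``rho(L)`` increases monotonically with ``L`` (one-sided Kendall tau
test) and (2) ``rho(L_max) > 0`` (one-sided Student t-test) are
significant at ``alpha = 0.05``.  The analysis is repeated with fresh
random library subsamples (default 200 replicates); the causal link is
declared significant when at least 95% of replicates pass.

Lagged causation is scanned by aligning ``cause(t - lag)`` with the
effect's manifold at ``t`` (positive lag = cause precedes the effect's
response); the retained lag maximises the mean ``rho(L_max)`` among
significant lags, and "n.s." is reported when no lag is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .config import RunConfig
from .containers import QuarterSeries
from .edm import (
    EmbeddingSpec,
    _neighbor_predict,
    _pearson,
    lag_embed,
    rho_pvalue,
    select_E,
)
from .errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    InsufficientGridError,
)

__all__ = [
    "CCMResult",
    "LagScanResult",
    "cross_map",
    "convergence_test",
    "ccm_with_replicates",
    "lag_scan",
]

logger = logging.getLogger(__name__)


def _as_values(series) -> np.ndarray:
    if isinstance(series, QuarterSeries):
        return np.asarray(series.values, float)
    return np.asarray(series, dtype=float)


def shift_cause(cause: np.ndarray, lag: int) -> np.ndarray:
    """Align ``cause(t - lag)`` onto index ``t`` (NaN-pad the head)."""
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if lag == 0:
        return cause.copy()
    out = np.full_like(cause, np.nan, dtype=float)
    out[lag:] = cause[: cause.size - lag]
    return out


class _CrossMapProblem:
    """Effect-manifold embedding with an aligned (possibly lagged) cause.

    Precomputes the all-pairs distance matrix once so that replicate
    library subsamples are cheap.
    """

    def __init__(self, effect: np.ndarray, cause: np.ndarray, E: int, tau: int = 1):
        if effect.shape != cause.shape:
            raise ValueError("effect and cause must share the time grid")
        sm = lag_embed(effect, EmbeddingSpec.univariate("effect", E, tau))
        ok = np.isfinite(cause[sm.valid_steps])
        self.rows = sm.rows[ok]
        self.cause = cause[sm.valid_steps][ok]
        self.steps = sm.valid_steps[ok]
        self.E = E
        if self.rows.shape[0] < E + 2:
            raise InsufficientDataError("too few states with an aligned cause value")
        if np.nanstd(self.cause) == 0:
            raise DegenerateSeriesError("constant cause: cross-map rho undefined")
        self.D = cdist(self.rows, self.rows)

    @property
    def n_states(self) -> int:
        return self.rows.shape[0]

    def rho(self, lib: np.ndarray) -> float:
        """Cross-map skill using the given library row indices.

        Every state is a prediction target; when a target belongs to the
        library its own row is excluded from its neighbour search.
        """
        d = self.D[:, lib].copy()
        self_col = np.searchsorted(lib, np.arange(self.n_states))
        in_lib = (self_col < lib.size) & (lib[np.minimum(self_col, lib.size - 1)] == np.arange(self.n_states))
        rows_in_lib = np.nonzero(in_lib)[0]
        d[rows_in_lib, self_col[rows_in_lib]] = np.inf
        pred = _neighbor_predict(d, self.cause[lib], self.E + 1)
        return _pearson(pred, self.cause)


def cross_map(
    effect,
    cause,
    E: int,
    L: int,
    rng: np.random.Generator,
    lag: int = 0,
    tau: int = 1,
) -> float:
    """Single cross-map estimate at library size ``L``.

    Draws a uniform random size-``L`` subsample (without replacement) of
    the effect's embedding rows as library and predicts the contemporaneous
    (lag-shifted) cause at every state via simplex-style neighbour
    weighting; returns the Pearson skill.
    """
    eff = _as_values(effect)
    cau = shift_cause(_as_values(cause), lag)
    prob = _CrossMapProblem(eff, cau, E, tau)
    if L < E:
        raise InsufficientDataError(f"library size {L} < embedding dimension {E}")
    if L > prob.n_states:
        raise InsufficientDataError(f"library size {L} exceeds {prob.n_states} states")
    lib = np.sort(rng.choice(prob.n_states, size=L, replace=False))
    return prob.rho(lib)


def convergence_test(
    L_grid: np.ndarray,
    rho_by_L: np.ndarray,
    n_pred: int,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Dual convergence criteria for one replicate's skill curve.

    Returns ``(kendall_p, ttest_p, pass)`` where the Kendall test asks for
    a monotone increase of ``rho`` with ``L`` (one-sided) and the t-test
    asks ``rho(L_max) > 0`` (one-sided, df = n_pred - 2); the replicate
    passes when both p-values are below ``alpha``.
    """
    L_grid = np.asarray(L_grid, float)
    rho_by_L = np.asarray(rho_by_L, float)
    ok = np.isfinite(rho_by_L)
    if ok.sum() < 3:
        raise InsufficientGridError("convergence test needs >= 3 library sizes")
    kt = stats.kendalltau(L_grid[ok], rho_by_L[ok], alternative="greater")
    kendall_p = float(kt.pvalue)
    ttest_p = rho_pvalue(float(rho_by_L[ok][-1]), n_pred)
    passed = bool(kendall_p < alpha and np.isfinite(ttest_p) and ttest_p < alpha)
    return kendall_p, ttest_p, passed


@dataclass
class CCMResult:
    """Replicate-averaged cross-map outcome for one (cause, lag)."""

    cause_name: str
    effect_name: str
    lag: int
    E_star_library: int
    L_grid: np.ndarray
    rho_by_L: np.ndarray  # mean over replicates
    rho_Lmax: float  # mean skill at the full library
    kendall_p: float  # median per-replicate p
    ttest_p: float  # median per-replicate p
    pass_fraction: float
    significant: bool
    n_replicates: int
    n_states: int


def _library_grid(L_min: int, L_max: int, size: int) -> np.ndarray:
    if L_max < L_min:
        raise InsufficientDataError(f"L_max={L_max} < L_min={L_min}")
    return np.unique(np.linspace(L_min, L_max, min(size, L_max - L_min + 1)).round().astype(int))


def ccm_with_replicates(
    effect,
    cause,
    lag: int,
    config: RunConfig,
    rng: np.random.Generator,
    cause_name: str = "cause",
    effect_name: str = "effect",
    E_star: int | None = None,
) -> CCMResult:
    """Full CCM analysis at one lag: replicate library subsampling plus
    the dual convergence test, summarised by the 95%-pass rule.

    ``E_star`` (the effect/library variable's optimal embedding dimension)
    is selected by simplex projection when not supplied.
    """
    eff = _as_values(effect)
    cau = shift_cause(_as_values(cause), lag)
    if E_star is None:
        E_star = select_E(eff, config.E_max).E_star
    prob = _CrossMapProblem(eff, cau, E_star, tau=1)
    L_min, L_max = E_star, prob.n_states
    L_grid = _library_grid(L_min, L_max, config.L_grid_size)
    if L_grid.size < 3:
        raise InsufficientGridError("library range supports fewer than 3 sizes")

    n_rep = config.n_ccm_replicates
    rhos = np.empty((n_rep, L_grid.size))
    kps = np.empty(n_rep)
    tps = np.empty(n_rep)
    passes = np.empty(n_rep, dtype=bool)
    for r in range(n_rep):
        for i, L in enumerate(L_grid):
            lib = np.sort(rng.choice(prob.n_states, size=int(L), replace=False))
            rhos[r, i] = prob.rho(lib)
        kps[r], tps[r], passes[r] = convergence_test(
            L_grid, rhos[r], prob.n_states, config.alpha_ccm
        )

    pass_fraction = float(passes.mean())
    return CCMResult(
        cause_name=cause_name,
        effect_name=effect_name,
        lag=lag,
        E_star_library=E_star,
        L_grid=L_grid,
        rho_by_L=np.nanmean(rhos, axis=0),
        rho_Lmax=float(np.nanmean(rhos[:, -1])),
        kendall_p=float(np.median(kps)),
        ttest_p=float(np.median(tps)),
        pass_fraction=pass_fraction,
        significant=pass_fraction >= config.ccm_pass_fraction,
        n_replicates=n_rep,
        n_states=prob.n_states,
    )


@dataclass
class LagScanResult:
    """All per-lag CCM results plus the retained best lag (or "n.s.")."""

    cause_name: str
    effect_name: str
    results: list[CCMResult]
    best: CCMResult | None  # None => no significant lag

    @property
    def significant(self) -> bool:
        return self.best is not None

    @property
    def verdict(self) -> str:
        if self.best is None:
            return "n.s."
        return f"rho={self.best.rho_Lmax:.4f} (lag {self.best.lag})"


def lag_scan(
    effect,
    cause,
    lag_max: int,
    config: RunConfig,
    rng: np.random.Generator,
    cause_name: str = "cause",
    effect_name: str = "effect",
) -> LagScanResult:
    """Scan lags 0..lag_max and retain the skill-maximising significant lag.

    Lags that leave too few aligned states are skipped with a log entry.
    The library embedding dimension is selected once from the effect
    series (it does not depend on the lag).
    """
    eff = _as_values(effect)
    E_star = select_E(eff, config.E_max).E_star
    results: list[CCMResult] = []
    for lag in range(lag_max + 1):
        try:
            results.append(
                ccm_with_replicates(
                    eff, cause, lag, config, rng,
                    cause_name=cause_name, effect_name=effect_name, E_star=E_star,
                )
            )
        except (InsufficientDataError, InsufficientGridError) as exc:
            logger.info("lag_scan[skipped]: %s -> %s lag=%d (%s)",
                        cause_name, effect_name, lag, exc)
    significant = [r for r in results if r.significant]
    best = max(significant, key=lambda r: r.rho_Lmax) if significant else None
    if best is None:
        logger.info("lag_scan[n.s.]: %s -> %s", cause_name, effect_name)
    return LagScanResult(cause_name=cause_name, effect_name=effect_name,
                         results=results, best=best)
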