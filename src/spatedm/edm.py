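"""State-space reconstruction primitives.

Implements the three building blocks of empirical dynamic modeling (EDM):

* lagged-coordinate embedding of one or several time series into a state
  matrix (Takens-style shadow-manifold reconstruction),
* simplex projection — nearest-neighbour one-step-ahead forecasting, used
  to select the optimal embedding dimension ``E*``,
* the S-map solver — sequential locally weighted linear regression whose
  per-time-step coefficients estimate the Jacobian elements of the latent
  update map, i.e. time-varying interaction strengths.

All distances are Euclidean in embedding space.  Forecast skill is the
Pearson correlation ``rho`` between leave-one-out predictions and
observations; its significance is a one-sided Student t-test
``t = rho * sqrt((n-2)/(1-rho^2))`` with ``n-2`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateGeometryError,
    DegenerateSeriesError,
    InsufficientDataError,
)

__all__ = [
    "EmbeddingSpec",
    "StateMatrix",
    "SimplexResult",
    "SelectEResult",
    "SMapModel",
    "lag_embed",
    "simplex_forecast",
    "select_E",
    "smap_solve",
    "tune_theta",
    "rho_pvalue",
]

#: floor on the nearest-neighbour distance so duplicate states get
#: near-delta weights instead of a division by zero
_D_FLOOR = 1e-12

#: singular values below this fraction of the largest one are truncated
#: in the S-map SVD solve (near-collinear weighted designs on short series)
_SVD_RCOND = 1e-10


def rho_pvalue(rho: float, n: int) -> float:
    """One-sided p-value for H1: rho > 0 (Student t with n-2 df)."""
    if n < 3 or not np.isfinite(rho):
        return float("nan")
    if rho >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(stats.t.sf(t, df=n - 2))


@dataclass(frozen=True)
class EmbeddingSpec:
    """Which coordinates span the reconstructed state space.

    ``variables`` is an ordered list of ``(series_name, lag)`` pairs; the
    coordinate ``j`` of the state at time ``t`` is ``series[name][t - lag]``.
    For a univariate embedding the lags are ``0, tau, ..., (E-1)*tau``.
    """

    variables: tuple[tuple[str, int], ...]
    tau: int = 1
    E_star: int | None = None

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if any(lag < 0 for _, lag in self.variables):
            raise ValueError("lags must be >= 0")
        if not self.variables:
            raise ValueError("embedding needs at least one coordinate")

    @property
    def E(self) -> int:
        return len(self.variables)

    @classmethod
    def univariate(cls, name: str, E: int, tau: int = 1) -> "EmbeddingSpec":
        return cls(tuple((name, j * tau) for j in range(E)), tau=tau)


@dataclass
class StateMatrix:
    """Complete embedding rows with their aligned next-step targets.

    ``rows[k]`` is the state vector at time ``valid_steps[k]``; ``target[k]``
    is the target series one step later (NaN when that step has no
    observation, e.g. the final row).  Rows with any missing coordinate are
    never retained.
    """

    rows: np.ndarray  # (m, E)
    target: np.ndarray  # (m,)
    valid_steps: np.ndarray  # (m,) time indices
    spec: EmbeddingSpec

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def E(self) -> int:
        return self.rows.shape[1]

    def modeling_view(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rows restricted to those with a finite next-step target."""
        ok = np.isfinite(self.target)
        return self.rows[ok], self.target[ok], self.valid_steps[ok]


def lag_embed(
    series: dict[str, np.ndarray] | np.ndarray,
    spec: EmbeddingSpec,
    target: str | np.ndarray | None = None,
) -> StateMatrix:
    """Build a :class:`StateMatrix` from one or several aligned series.

    Parameters
    ----------
    series:
        Either a single array (univariate embedding; every spec variable
        must then refer to the same name) or a mapping of name -> array, all
        on a shared time grid.  NaN marks a missing observation.
    spec:
        The coordinates to use.
    target:
        The series whose next-step value is predicted.  Defaults to the
        first embedding variable.
    """
    if isinstance(series, np.ndarray):
        names = {name for name, _ in spec.variables}
        series = {name: series for name in names}
    n = len(next(iter(series.values())))
    for name, arr in series.items():
        if len(arr) != n:
            raise ValueError(f"series {name!r} is not on the shared grid")

    if target is None:
        target = spec.variables[0][0]
    tgt = series[target] if isinstance(target, str) else np.asarray(target, float)

    coords = np.full((n, spec.E), np.nan)
    for j, (name, lag) in enumerate(spec.variables):
        arr = np.asarray(series[name], dtype=float)
        if lag == 0:
            coords[:, j] = arr
        else:
            coords[lag:, j] = arr[: n - lag]

    y = np.full(n, np.nan)
    y[: n - 1] = tgt[1:]

    keep = np.all(np.isfinite(coords), axis=1)
    rows = coords[keep]
    if rows.shape[0] < 2:
        raise InsufficientDataError(
            f"only {rows.shape[0]} complete state rows for E={spec.E}"
        )
    return StateMatrix(
        rows=rows,
        target=y[keep],
        valid_steps=np.nonzero(keep)[0],
        spec=spec,
    )


# ---------------------------------------------------------------------------
# simplex projection
# ---------------------------------------------------------------------------


@dataclass
class SimplexResult:
    E: int
    rho: float
    predictions: np.ndarray
    observed: np.ndarray
    steps: np.ndarray


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _neighbor_predict(
    dist: np.ndarray, lib_values: np.ndarray, k: int
) -> np.ndarray:
    """Simplex-style prediction from a (targets x library) distance matrix.

    Distances set to +inf are excluded (weight 0); a target whose neighbour
    set is entirely invalid yields NaN.
    """
    k = min(k, dist.shape[1])
    idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
    d = np.take_along_axis(dist, idx, axis=1)
    order = np.argsort(d, axis=1)
    d = np.take_along_axis(d, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    d_nearest = np.maximum(d[:, :1], _D_FLOOR)
    with np.errstate(invalid="ignore", over="ignore"):
        w = np.exp(-d / d_nearest)
    w[~np.isfinite(w)] = 0.0
    w[np.isinf(d)] = 0.0
    wsum = w.sum(axis=1)
    vals = lib_values[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = (w * vals).sum(axis=1) / wsum
    pred[wsum == 0] = np.nan
    return pred


def simplex_forecast(
    series: np.ndarray, E: int, tau: int = 1, name: str = "x"
) -> SimplexResult:
    """Leave-one-out one-step-ahead simplex projection.

    Each state's next value is predicted from its ``E+1`` nearest
    neighbours (its own row excluded) with weights
    ``exp(-d / d_nearest)`` normalised to sum to one.
    """
    series = np.asarray(series, dtype=float)
    finite = series[np.isfinite(series)]
    if finite.size and np.nanstd(finite) == 0:
        raise DegenerateSeriesError("constant series: simplex rho undefined")
    sm = lag_embed(series, EmbeddingSpec.univariate(name, E, tau))
    X, y, steps = sm.modeling_view()
    if X.shape[0] < E + 2:
        raise InsufficientDataError("too few predictable states")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    pred = _neighbor_predict(D, y, E + 1)
    rho = _pearson(pred, y)
    if not np.isfinite(rho):
        raise DegenerateSeriesError("forecast correlation undefined")
    return SimplexResult(E=E, rho=rho, predictions=pred, observed=y, steps=steps)


@dataclass
class SelectEResult:
    E_star: int
    rho_by_E: np.ndarray  # indexed E-1 .. E_max-1; NaN where not computable
    low_skill: bool  # max rho < 0.1: reconstruction is unreliable

    @property
    def rho_star(self) -> float:
        return float(self.rho_by_E[self.E_star - 1])


def select_E(series: np.ndarray, E_max: int = 10, tau: int = 1) -> SelectEResult:
    """Optimal embedding dimension by simplex forecast skill.

    ``E*`` maximises rho over ``E in {1..E_max}``; ties break toward the
    smaller dimension.  Dimensions that leave too few complete rows are
    skipped.
    """
    if E_max < 1:
        raise ValueError("E_max must be >= 1")
    rhos = np.full(E_max, np.nan)
    for E in range(1, E_max + 1):
        try:
            rhos[E - 1] = simplex_forecast(series, E, tau).rho
        except InsufficientDataError:
            break
    if not np.any(np.isfinite(rhos)):
        raise InsufficientDataError("no embedding dimension is estimable")
    best = int(np.nanargmax(rhos)) + 1  # nanargmax returns the first maximum
    return SelectEResult(E_star=best, rho_by_E=rhos, low_skill=np.nanmax(rhos) < 0.1)


# ---------------------------------------------------------------------------
# S-map
# ---------------------------------------------------------------------------


@dataclass
class SMapModel:
    """Locally weighted linear model fitted at every predictable state.

    ``coefficients[k]`` is ``(C_0, C_1, ..., C_E)`` for the state at
    ``steps[k]``: the intercept followed by one coefficient per embedding
    coordinate, so the one-step prediction is
    ``C_0 + sum_j C_j * x_j(t)``.  With ``theta = 0`` every row equals the
    global least-squares solution and the model reduces to a vector
    autoregression.
    """

    theta: float
    coefficients: np.ndarray  # (m, E+1)
    predictions: np.ndarray  # (m,)
    observed: np.ndarray  # (m,)
    steps: np.ndarray  # (m,)
    rho: float
    p_value: float
    d_bar: np.ndarray  # (m,) mean library distance per target state
    spec: EmbeddingSpec | None = None
    weights: np.ndarray | None = None  # (m, m-1) per-step audit weights

    @property
    def n_pred(self) -> int:
        return int(self.steps.size)

    def mean_coefficients(self) -> np.ndarray:
        """Time-average of (C_0 .. C_E) over predictable steps."""
        return self.coefficients.mean(axis=0)


def smap_solve(
    states: StateMatrix, theta: float, store_weights: bool = False
) -> SMapModel:
    """Fit the S-map at every predictable state of ``states``.

    For each target state ``x(t*)`` the library is every other row with a
    finite next-step target; weights are ``w(d) = exp(-theta * d / d_bar)``
    where ``d_bar`` is the mean distance from ``x(t*)`` to the library.
    The weighted linear system ``B = A . C`` (weighted targets vs weighted
    coordinates plus intercept) is solved by SVD least squares with small
    singular values truncated.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    X, y, steps = states.modeling_view()
    m, E = X.shape
    if m < E + 2:
        raise InsufficientDataError(f"S-map needs >= E+2 predictable rows, got {m}")

    D = cdist(X, X)
    coef = np.empty((m, E + 1))
    pred = np.empty(m)
    d_bar = np.empty(m)
    weights = np.empty((m, m - 1)) if store_weights else None

    others = ~np.eye(m, dtype=bool)
    for i in range(m):
        lib = others[i]
        d = D[i, lib]
        db = d.mean()
        if db <= 0:
            raise DegenerateGeometryError("all library states coincide (d_bar = 0)")
        d_bar[i] = db
        w = np.exp(-theta * d / db)
        if weights is not None:
            weights[i] = w
        A = np.empty((m - 1, E + 1))
        A[:, 0] = w
        A[:, 1:] = w[:, None] * X[lib]
        B = w * y[lib]
        c, *_ = np.linalg.lstsq(A, B, rcond=_SVD_RCOND)
        coef[i] = c
        pred[i] = c[0] + X[i] @ c[1:]

    rho = _pearson(pred, y)
    return SMapModel(
        theta=float(theta),
        coefficients=coef,
        predictions=pred,
        observed=y,
        steps=steps,
        rho=rho,
        p_value=rho_pvalue(rho, m),
        d_bar=d_bar,
        spec=states.spec,
        weights=weights,
    )


def tune_theta(
    states: StateMatrix, theta_grid=(0, 1, 2, 3, 4, 5, 6, 7, 8)
) -> SMapModel:
    """S-map model with the skill-maximising theta; ties toward smaller theta."""
    best: SMapModel | None = None
    for theta in theta_grid:
        model = smap_solve(states, float(theta))
        if best is None or (
            np.isfinite(model.rho) and (not np.isfinite(best.rho) or model.rho > best.rho)
        ):
            best = model
    assert best is not None
    return best
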