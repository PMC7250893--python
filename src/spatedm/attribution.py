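"""Multivariate S-map attribution of spatial-variability dynamics.

After CCM has identified which candidate drivers (age diversity,
abundance, environmental series, ...) causally force the target — the
population spatial variability — this module reconstructs the attractor
with a multivariate embedding built from the target plus its strongest
``E* - 1`` causes (each at its best CCM lag), fits the S-map over the
theta grid, and reads the per-time-step coefficient of each cause as its
time-varying influence strength on the target.  Sensitivity re-embeddings
over alternative cause combinations probe the robustness of the signs,
and the yearly fishing-mortality analysis applies the same machinery to
targets {age diversity, abundance, spatial CV} on annually averaged data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .ccm import LagScanResult, lag_scan
from .config import RunConfig
from .containers import QuarterSeries
from .edm import EmbeddingSpec, SMapModel, lag_embed, tune_theta
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "AttributionResult",
    "FishingAnalysisResult",
    "select_embedding",
    "estimate_influence",
    "sensitivity_combinations",
    "fishing_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class AttributionResult:
    """One attractor reconstruction and its S-map influence estimates.

    ``mean_influence`` maps each embedded cause to the time-average of its
    per-step S-map coefficient; it is populated only when the model is
    significant (one-sided t-test on rho at the configured alpha), matching
    the reporting rule that influence strengths are interpretable only for
    significant reconstructions.
    """

    target_name: str
    embedding: EmbeddingSpec | None
    model: SMapModel | None
    significant: bool
    mean_influence: dict[str, float] = field(default_factory=dict)
    alternates: list["AttributionResult"] = field(default_factory=list)
    verdict: str = "ok"  # "ok" | "no-causal-variables"

    @property
    def cause_names(self) -> list[str]:
        if self.embedding is None:
            return []
        return [name for name, _ in self.embedding.variables[1:]]


def _rank_key(scan: LagScanResult):
    best = scan.best
    return (-best.rho_Lmax, best.lag, scan.cause_name)


def select_embedding(
    target_name: str,
    ccm_results: list[LagScanResult],
    E_star: int,
) -> AttributionResult:
    """Choose the multivariate embedding from CCM-determined causes.

    The embedding pairs the target (lag 0) with the top ``E* - 1``
    significant causes ranked by cross-map skill.  All coordinates are
    contemporaneous: cross-map lags identify causality and its delay,
    but the attractor is reconstructed from the variables' current
    states (the prediction model uses ``x_j(t*)``), so each cause
    enters at lag 0.  With only ``k < E* - 1`` significant causes the
    suboptimal dimension ``k + 1`` is used; with none, the outcome is
    the recorded verdict "no-causal-variables" (the attractor cannot be
    reconstructed from the examined variables), not an exception.

    Ties rank by higher skill, then smaller CCM lag, then name.
    """
    significant = [s for s in ccm_results if s.significant]
    if any(s.cause_name == target_name for s in significant):
        raise ValidationError("the target cannot be one of its own causes")
    if not significant:
        logger.info("select_embedding[no-causal-variables]: %s", target_name)
        return AttributionResult(
            target_name=target_name, embedding=None, model=None,
            significant=False, verdict="no-causal-variables",
        )
    ranked = sorted(significant, key=_rank_key)
    chosen = ranked[: max(E_star - 1, 1)]
    variables = [(target_name, 0)] + [(s.cause_name, 0) for s in chosen]
    return AttributionResult(
        target_name=target_name,
        embedding=EmbeddingSpec(tuple(variables), E_star=E_star),
        model=None,
        significant=False,
    )


def estimate_influence(
    embedding: EmbeddingSpec,
    series: dict[str, np.ndarray | QuarterSeries],
    config: RunConfig,
) -> AttributionResult:
    """Fit the S-map on the multivariate embedding and extract influences.

    theta is tuned over ``config.theta_grid``; the per-step coefficient of
    each cause coordinate on the next-step target is retained in full, and
    its time average is reported when the model passes the significance
    gate (one-sided p < ``config.alpha_smap`` on rho).
    """
    target_name = embedding.variables[0][0]
    if any(name == target_name for name, _ in embedding.variables[1:]):
        raise ValidationError(
            "the target series may appear only once, as the lag-0 coordinate"
        )
    arrays = {
        name: (s.values if isinstance(s, QuarterSeries) else np.asarray(s, float))
        for name, s in series.items()
    }
    states = lag_embed(arrays, embedding, target=target_name)
    model = tune_theta(states, config.theta_grid)
    significant = bool(np.isfinite(model.p_value) and model.p_value < config.alpha_smap)
    mean_influence: dict[str, float] = {}
    if significant:
        means = model.mean_coefficients()  # (C_0, C_target, C_cause1, ...)
        for j, (name, _lag) in enumerate(embedding.variables):
            if name == target_name:
                continue
            mean_influence[name] = float(means[1 + j])
    return AttributionResult(
        target_name=target_name,
        embedding=embedding,
        model=model,
        significant=significant,
        mean_influence=mean_influence,
    )


def sensitivity_combinations(
    target_name: str,
    ccm_results: list[LagScanResult],
    E_star: int,
    series: dict[str, np.ndarray | QuarterSeries],
    config: RunConfig,
) -> list[AttributionResult]:
    """Re-embed with alternative cause combinations (robustness check).

    Only runs when the significant causes outnumber ``E* - 1``.  All
    alternative ``(E*-1)``-subsets are fitted when there are at most
    ``config.max_sensitivity_models`` of them; otherwise single-variable
    swaps of the top-ranked set are used, in rank order.
    """
    significant = sorted((s for s in ccm_results if s.significant), key=_rank_key)
    k = E_star - 1
    if len(significant) <= k:
        return []
    primary = tuple(s.cause_name for s in significant[:k])

    subsets = [c for c in combinations([s.cause_name for s in significant], k)
               if tuple(c) != primary]
    if len(subsets) > config.max_sensitivity_models:
        subsets = []
        for out_name in primary:
            for s in significant[k:]:
                cand = tuple(n if n != out_name else s.cause_name for n in primary)
                if cand not in subsets:
                    subsets.append(cand)
        subsets = subsets[: config.max_sensitivity_models]

    results = []
    for names in subsets:
        variables = [(target_name, 0)] + [(n, 0) for n in names]
        spec = EmbeddingSpec(tuple(variables), E_star=E_star)
        try:
            results.append(estimate_influence(spec, series, config))
        except InsufficientDataError as exc:
            logger.info("sensitivity[skipped]: %s (%s)", names, exc)
    return results


@dataclass
class FishingAnalysisResult:
    """Yearly fishing-mortality influence on one target series."""

    target_name: str
    scan: LagScanResult
    per_lag: dict[int, AttributionResult]  # one S-map per significant lag
    mean_influence: float | None  # averaged over all significant lags


def fishing_analysis(
    targets: dict[str, QuarterSeries],
    fishing: QuarterSeries,
    config: RunConfig,
    rng: np.random.Generator,
) -> dict[str, FishingAnalysisResult]:
    """Causal effect of fishing mortality on yearly target series.

    All inputs must already be on the yearly grid (annual averages of the
    biquarterly series; fishing mortality is reported annually).  For each
    target a CCM lag scan with lags 0..``config.lag_max_yearly`` is run;
    an S-map (target + fishing at that lag) is fitted at every significant
    lag, and the fishing influence is averaged — sign-preserving — over all
    significant lags to damp short-series variability.
    """
    if fishing.grid != "yearly":
        raise ValidationError("fishing mortality must be a yearly series")
    n_years = fishing.n_finite
    if n_years < 20:
        logger.warning(
            "fishing_analysis[low_power]: only %d yearly points; results may be unstable",
            n_years,
        )
    out: dict[str, FishingAnalysisResult] = {}
    for name, target in targets.items():
        if target.grid != "yearly":
            raise ValidationError(f"target {name!r} must be on the yearly grid")
        scan = lag_scan(
            target, fishing, config.lag_max_yearly, config, rng,
            cause_name=fishing.name, effect_name=name,
        )
        per_lag: dict[int, AttributionResult] = {}
        influences = []
        for res in scan.results:
            if not res.significant:
                continue
            spec = EmbeddingSpec(((name, 0), (fishing.name, res.lag)))
            try:
                att = estimate_influence(
                    spec, {name: target, fishing.name: fishing}, config
                )
            except InsufficientDataError as exc:
                logger.info("fishing_analysis[skipped]: %s lag=%d (%s)", name, res.lag, exc)
                continue
            per_lag[res.lag] = att
            if att.significant:
                influences.append(att.mean_influence[fishing.name])
        mean_influence = float(np.mean(influences)) if influences else None
        out[name] = FishingAnalysisResult(
            target_name=name, scan=scan, per_lag=per_lag, mean_influence=mean_influence
        )
    return out
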