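"""Multivariate S-map attribution: embedding selection, influence signs,
sensitivity re-embeddings and the yearly fishing analysis."""

import numpy as np
import pytest

from spatedm.attribution import (
    estimate_influence,
    fishing_analysis,
    select_embedding,
    sensitivity_combinations,
)
from spatedm.ccm import CCMResult, LagScanResult
from spatedm.config import RunConfig
from spatedm.containers import QuarterSeries
from spatedm.edm import EmbeddingSpec
from spatedm.errors import ValidationError
from spatedm.metrics import (
    age_diversity,
    filter_survey,
    preprocess,
    spatial_cv,
    to_yearly,
)
from spatedm.synthetic import (
    CoupledSystemTruth,
    SurveyScenario,
    _ar1,
    gen_coupled_system,
    gen_survey,
)


def fake_scan(cause, rho, lag=0, significant=True, E=3):
    res = CCMResult(
        cause_name=cause, effect_name="spatial_cv", lag=lag, E_star_library=E,
        L_grid=np.array([3, 20, 40]), rho_by_L=np.array([0.2, 0.5, rho]),
        rho_Lmax=rho, kendall_p=0.01, ttest_p=0.001,
        pass_fraction=0.99 if significant else 0.2,
        significant=significant, n_replicates=100, n_states=40,
    )
    return LagScanResult(cause_name=cause, effect_name="spatial_cv",
                         results=[res], best=res if significant else None)


class TestSelectEmbedding:
    def test_top_causes_by_skill(self):
        scans = [fake_scan(c, r) for c, r in
                 [("a", 0.5), ("b", 0.9), ("c", 0.7), ("d", 0.6), ("e", 0.3)]]
        sel = select_embedding("spatial_cv", scans, E_star=4)
        assert sel.embedding.variables == (
            ("spatial_cv", 0), ("b", 0), ("c", 0), ("d", 0))

    def test_suboptimal_dimension_when_few_causes(self):
        scans = [fake_scan(c, r) for c, r in [("a", 0.5), ("b", 0.9), ("c", 0.7)]]
        sel = select_embedding("spatial_cv", scans, E_star=7)
        # 3 causes < E*-1 = 6: suboptimal E = k+1 = 4 coordinates
        assert sel.embedding.E == 4

    def test_no_causal_variables_verdict(self):
        scans = [fake_scan("a", 0.5, significant=False)]
        sel = select_embedding("spatial_cv", scans, E_star=3)
        assert sel.verdict == "no-causal-variables"
        assert sel.embedding is None

    def test_target_as_cause_rejected(self):
        with pytest.raises(ValidationError):
            select_embedding("spatial_cv", [fake_scan("spatial_cv", 0.9)], 3)


class TestEstimateInfluence:
    def test_target_duplicated_is_precondition_violation(self):
        spec = EmbeddingSpec((("y", 0), ("y", 0)))
        with pytest.raises(ValidationError):
            estimate_influence(spec, {"y": np.random.default_rng(0).standard_normal(50)},
                               RunConfig())

    def test_linear_var_coefficients_recovered(self):
        truth = CoupledSystemTruth(
            names=("x", "y", "z"),
            map_type="linear-VAR",
            adjacency=np.array([[0.5, 0, 0], [0.3, 0, 0], [-0.4, 0, 0]]),
            noise_sd=1.0,
        )
        s = gen_coupled_system(truth, 400, 21)
        att = estimate_influence(
            EmbeddingSpec((("x", 0), ("y", 0), ("z", 0))), s, RunConfig()
        )
        assert att.significant
        assert att.model.theta == 0 or att.model.rho - 0.02 < 1  # theta free
        assert att.mean_influence["y"] == pytest.approx(0.3, abs=0.1)
        assert att.mean_influence["z"] == pytest.approx(-0.4, abs=0.1)

    def test_gate_blocks_mean_influence(self, rng):
        # independent noise: model should not report influences
        s = {"y": rng.standard_normal(40), "x": rng.standard_normal(40)}
        att = estimate_influence(EmbeddingSpec((("y", 0), ("x", 0))), s, RunConfig())
        if not att.significant:
            assert att.mean_influence == {}

    def test_signed_ground_truth_recovered(self):
        """Generators with a negative diversity->CV influence yield a
        negative mean coefficient (known-cause embedding, many seeds)."""
        neg = 0
        n_rep = 12
        for seed in range(n_rep):
            real = gen_survey(SurveyScenario.age_truncation(rng_seed=seed))
            cv = preprocess(spatial_cv(filter_survey(real.length_table)))
            sh = preprocess(age_diversity(filter_survey(real.age_table)))
            att = estimate_influence(
                EmbeddingSpec((("spatial_cv", 0), ("age_diversity", 0))),
                {"spatial_cv": cv.values, "age_diversity": sh.values},
                RunConfig(),
            )
            if att.significant and att.mean_influence["age_diversity"] < 0:
                neg += 1
        assert neg >= 0.9 * n_rep


class TestSensitivity:
    def series_set(self, rng, names):
        base = rng.standard_normal(80)
        out = {"spatial_cv": base}
        for i, n in enumerate(names):
            out[n] = 0.5 * np.roll(base, 1) + rng.standard_normal(80)
        return out

    def test_combinatorics(self, rng):
        scans = [fake_scan(c, r) for c, r in
                 [("a", 0.9), ("b", 0.8), ("c", 0.7), ("d", 0.6), ("e", 0.5)]]
        series = self.series_set(rng, "abcde")
        alts = sensitivity_combinations("spatial_cv", scans, 4, series, RunConfig())
        # C(5,3) = 10 subsets minus the primary one
        assert len(alts) == 9

    def test_exact_fit_gives_empty_list(self, rng):
        scans = [fake_scan(c, r) for c, r in [("a", 0.9), ("b", 0.8)]]
        series = self.series_set(rng, "ab")
        assert sensitivity_combinations("spatial_cv", scans, 3, series, RunConfig()) == []

    def test_swap_cap_respected(self, rng):
        scans = [fake_scan(f"v{i}", 0.9 - 0.05 * i) for i in range(8)]
        series = self.series_set(rng, [f"v{i}" for i in range(8)])
        cfg = RunConfig(max_sensitivity_models=5)
        alts = sensitivity_combinations("spatial_cv", scans, 4, series, cfg)
        assert len(alts) <= 5


class TestFishingAnalysis:
    def yearly(self, series):
        return preprocess(to_yearly(series))

    def test_quarterly_input_rejected(self, rng):
        q = QuarterSeries(name="x", values=rng.standard_normal(20),
                          years=np.repeat(np.arange(2000, 2010), 2),
                          quarters=np.tile([1, 3], 10))
        f = QuarterSeries(name="F", values=rng.standard_normal(10),
                          years=np.arange(2000, 2010))
        with pytest.raises(ValidationError):
            fishing_analysis({"t": q}, f, RunConfig(), rng)
        with pytest.raises(ValidationError):
            fishing_analysis({"t": f.with_values(f.values)}, q, RunConfig(), rng)

    def test_truncation_mechanism_negative_influence(self):
        """Strongly varying F truncating the age structure: the averaged
        fishing -> age-diversity influence is negative across datasets."""
        cfg = RunConfig(n_ccm_replicates=100, L_grid_size=40)
        vals = []
        for seed in range(8):
            f_rng = np.random.default_rng((seed, 0xF15))
            ny = 50
            F = 0.8 * np.exp(0.5 * _ar1(ny, phi=0.4, sd=np.sqrt(1 - 0.16), rng=f_rng))
            sc = SurveyScenario(
                rng_seed=seed, n_years=ny, fishing_mortality=F,
                fishing_age50=1.5, fishing_sel_slope=2.5,
                recruitment_sigma=0.3, recruitment_phi=0.5,
            )
            real = gen_survey(sc)
            sh_y = self.yearly(age_diversity(filter_survey(real.age_table)))
            f = preprocess(real.env["fishing_mortality"].to_quarter_series())
            out = fishing_analysis({"age_diversity": sh_y}, f, cfg,
                                   np.random.default_rng(seed))
            if out["age_diversity"].mean_influence is not None:
                vals.append(out["age_diversity"].mean_influence)
        assert len(vals) >= 4
        assert np.mean(vals) < 0

    def test_independent_fishing_mostly_ns(self, rng):
        cfg = RunConfig(n_ccm_replicates=50, L_grid_size=10)
        n_sig = 0
        n_rep = 6
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            years = np.arange(1990, 2040)
            t = QuarterSeries(name="t", values=r.standard_normal(50), years=years)
            f = QuarterSeries(name="F", values=r.standard_normal(50), years=years)
            out = fishing_analysis({"t": preprocess(t)}, preprocess(f), cfg, r)
            n_sig += out["t"].scan.significant
        assert n_sig <= 1
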