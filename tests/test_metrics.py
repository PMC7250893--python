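"""Survey metrics: filtering, spatial CV, Shannon, abundance, Taylor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatedm.errors import (
    DegenerateSeriesError,
    InsufficientDataError,
)
from spatedm.metrics import (
    TaylorFit,
    age_diversity,
    cv_abundance_direction,
    filter_survey,
    fit_taylor,
    preprocess,
    spatial_cv,
    to_yearly,
    total_abundance,
)
from spatedm.synthetic import gen_taylor_table

from conftest import make_survey


def survey_one_quarter(cpues, class_kind="length"):
    rows = [(2000, 1, f"G{i}", 0, v) for i, v in enumerate(cpues)]
    return make_survey(rows, class_kind)


class TestFilterSurvey:
    def test_always_zero_subarea_removed(self):
        rows = []
        for q in (1, 3):
            for s in ("A", "B", "Z"):
                rows.append((2000, q, s, 0, 0.0 if s == "Z" else 2.0))
        out = filter_survey(make_survey(rows), min_grids=2)
        assert "Z" not in out.subareas

    def test_thin_quarter_removed(self):
        rows = [(2000, 1, f"G{i}", 0, 1.0) for i in range(9)]
        rows += [(2000, 3, f"G{i}", 0, 1.0) for i in range(12)]
        out = filter_survey(make_survey(rows), min_grids=10)
        assert out.surveyed_steps.tolist() == [1]

    def test_clean_table_unchanged(self):
        rows = [(2000, q, f"G{i}", 0, 1.0 + i) for q in (1, 3) for i in range(12)]
        table = make_survey(rows)
        out = filter_survey(table, min_grids=10)
        assert out.equals(table)

    def test_zeros_within_quarters_are_kept(self):
        # a subarea with some zero quarters (but not all) stays
        rows = [(2000, 1, "A", 0, 0.0), (2000, 3, "A", 0, 5.0),
                (2000, 1, "B", 0, 1.0), (2000, 3, "B", 0, 1.0)]
        out = filter_survey(make_survey(rows), min_grids=2)
        assert set(out.subareas) == {"A", "B"}


class TestSpatialCV:
    def test_equal_cpues_give_zero(self):
        cv = spatial_cv(survey_one_quarter([10.0, 10, 10, 10]))
        assert cv.values[0] == pytest.approx(0.0)

    def test_two_subareas_hand_value(self):
        # sigma = sqrt(2), mu = 2 -> CV = 0.70711 (sample SD)
        cv = spatial_cv(survey_one_quarter([1.0, 3.0]))
        assert cv.values[0] == pytest.approx(0.70711, abs=1e-5)

    @settings(max_examples=25, deadline=None)
    @given(k=st.floats(0.01, 100), seed=st.integers(0, 100))
    def test_scale_invariance(self, k, seed):
        vals = np.random.default_rng(seed).uniform(0.1, 5.0, 8)
        a = spatial_cv(survey_one_quarter(vals)).values[0]
        b = spatial_cv(survey_one_quarter(k * vals)).values[0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_mean_quarter_excluded(self):
        table = survey_one_quarter([0.0, 0.0, 0.0])
        cv = spatial_cv(table)
        assert np.isnan(cv.values[0])

    def test_moments_stored(self):
        cv = spatial_cv(survey_one_quarter([1.0, 3.0]))
        assert cv.mu[0] == pytest.approx(2.0)
        assert cv.sigma[0] == pytest.approx(np.sqrt(2.0))


class TestAgeDiversity:
    def make_age_table(self, cpue_by_age):
        rows = [(2000, 1, "A", a, v) for a, v in enumerate(cpue_by_age)]
        return make_survey(rows, "age")

    def test_uniform_four_classes(self):
        sh = age_diversity(self.make_age_table([5.0, 5, 5, 5]))
        assert sh.values[0] == pytest.approx(np.log(4), abs=1e-9)

    def test_single_class_zero(self):
        sh = age_diversity(self.make_age_table([0.0, 7.0, 0.0]))
        assert sh.values[0] == pytest.approx(0.0)

    def test_hand_computed_entropy(self):
        sh = age_diversity(self.make_age_table([2.0, 1.0, 1.0]))
        assert sh.values[0] == pytest.approx(1.03972, abs=1e-5)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.0, 50.0), min_size=2, max_size=8))
    def test_bounds(self, cpues):
        if sum(cpues) <= 0:
            return
        sh = age_diversity(self.make_age_table(cpues)).values[0]
        assert -1e-9 <= sh <= np.log(len(cpues)) + 1e-9

    def test_needs_age_table(self, toy_survey):
        with pytest.raises(ValueError):
            age_diversity(toy_survey)


class TestAbundance:
    def test_simple_sum(self):
        rows = [(2000, 1, s, c, 1.0) for s in ("A", "B") for c in (0, 1)]
        ab = total_abundance(make_survey(rows))
        assert ab.values[0] == pytest.approx(4.0)

    def test_order_invariance(self, rng):
        rows = [(2000, q, f"G{i}", c, float(rng.uniform(0, 5)))
                for q in (1, 3) for i in range(4) for c in (0, 1)]
        a = total_abundance(make_survey(rows))
        perm = rng.permutation(len(rows))
        b = total_abundance(make_survey([rows[i] for i in perm]))
        np.testing.assert_allclose(a.values, b.values)

    def test_disjoint_subarea_additivity(self, rng):
        rows_a = [(2000, 1, f"A{i}", 0, float(rng.uniform(0, 5))) for i in range(4)]
        rows_b = [(2000, 1, f"B{i}", 0, float(rng.uniform(0, 5))) for i in range(4)]
        total = total_abundance(make_survey(rows_a + rows_b)).values[0]
        parts = (total_abundance(make_survey(rows_a)).values[0]
                 + total_abundance(make_survey(rows_b)).values[0])
        assert total == pytest.approx(parts)


def qs(values, name="x"):
    from spatedm.containers import QuarterSeries
    n = len(values)
    years = np.repeat(np.arange(2000, 2000 + (n + 1) // 2), 2)[:n]
    quarters = np.tile([1, 3], (n + 1) // 2)[:n]
    return QuarterSeries(name=name, values=np.asarray(values, float),
                         years=years, quarters=quarters)


class TestPreprocess:
    def test_white_noise_normalised_only(self, rng):
        s = preprocess(qs(rng.standard_normal(60)))
        assert not s.detrended
        v = s.values
        assert abs(v.mean()) < 1e-9
        assert abs(v.std(ddof=1) - 1) < 1e-9

    def test_ramp_detrended(self, rng):
        s = preprocess(qs(np.arange(60.0) + rng.normal(0, 0.5, 60)))
        assert s.detrended
        t = np.arange(60.0)
        assert abs(np.corrcoef(s.values, t)[0, 1]) < 0.05

    def test_exact_line_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            preprocess(qs(np.arange(30.0)))

    def test_nan_steps_preserved(self, rng):
        v = rng.standard_normal(40)
        v[5] = np.nan
        s = preprocess(qs(v))
        assert np.isnan(s.values[5])
        assert np.isfinite(np.delete(s.values, 5)).all()


class TestToYearly:
    def test_quarter_mean(self):
        s = to_yearly(qs([1.0, 3.0]))
        assert s.grid == "yearly"
        assert s.values.tolist() == [2.0]

    def test_single_quarter_year(self):
        s = to_yearly(qs([5.0, np.nan]))
        assert s.values.tolist() == [5.0]

    def test_constant_series(self):
        s = to_yearly(qs([2.0] * 10))
        assert np.all(s.values == 2.0)


class TestTaylor:
    def test_poisson_like_slope_one(self, rng):
        rows = []
        for step in range(50):
            year, q = 2000 + step // 2, 1 if step % 2 == 0 else 3
            lam = float(rng.uniform(2, 50))
            counts = rng.poisson(lam, 40)
            rows += [(year, q, f"G{i}", 0, float(c)) for i, c in enumerate(counts)]
        fit = fit_taylor(make_survey(rows))
        assert fit.b == pytest.approx(1.0, abs=0.15)

    def test_imposed_exponent_recovered(self):
        fit = fit_taylor(gen_taylor_table(b=2.5, n_quarters=50, n_subareas=40, seed=9))
        assert fit.b == pytest.approx(2.5, abs=0.15)
        assert fit.r_squared > 0.9

    def test_scaled_pattern_gives_two(self, rng):
        pattern = rng.uniform(1, 5, 20)
        rows = []
        for step, scale in enumerate([1.0, 2.0, 5.0, 10.0]):
            year, q = 2000 + step // 2, 1 if step % 2 == 0 else 3
            rows += [(year, q, f"G{i}", 0, float(scale * p))
                     for i, p in enumerate(pattern)]
        fit = fit_taylor(make_survey(rows))
        assert fit.b == pytest.approx(2.0, abs=1e-9)

    def test_insufficient_quarters(self):
        with pytest.raises(InsufficientDataError):
            fit_taylor(survey_one_quarter([1.0, 2.0, 3.0]))


class TestCvDirection:
    @pytest.mark.parametrize(
        "b,expected",
        [(1.5, "negative"), (2.5, "positive"), (2.0, "neutral")],
    )
    def test_direction_rule(self, b, expected):
        import pandas as pd
        fit = TaylorFit(a=1.0, b=b, r_squared=1.0, points=pd.DataFrame())
        assert cv_abundance_direction(fit) == expected

    def test_direction_matches_empirical_regression(self):
        """Fitted b on either side of 2 implies the sign of the empirical
        log CV vs log M slope."""
        from scipy import stats as sps
        for b in (1.5, 2.5):
            table = gen_taylor_table(b=b, n_quarters=50, n_subareas=40, seed=4)
            fit = fit_taylor(table)
            totals = table.totals_by_subarea().groupby("quarter_step")["cpue"]
            M = totals.mean()
            CV = totals.std(ddof=1) / M
            slope = sps.linregress(np.log(M), np.log(CV)).slope
            direction = cv_abundance_direction(fit)
            assert direction == ("negative" if slope < 0 else "positive")
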