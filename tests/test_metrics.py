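import math

import numpy as np
import pytest

import _oracle as oracle
from methaneval import PairedSeries
from methaneval.errors import DegenerateInputError, InsufficientDataError
from methaneval.metrics import (
    ccc_from_components,
    concordance,
    evaluate,
    mean_bias_pct,
    mean_so_ratio,
    model_efficiency,
    moments,
    mspe_partition,
    regression_fit,
)


def series(o, s):
    o = np.asarray(o, dtype=float)
    return PairedSeries(o=o, s=np.asarray(s, dtype=float),
                        group=np.zeros(len(o), dtype=bool), variable="dmi")


TOY = ([2.0, 4.0, 6.0], [1.0, 4.0, 7.0])


class TestMoments:
    def test_toy_hand_values(self):
        m = moments(series(*TOY))
        assert m.mean_o == 4.0 and m.mean_s == 4.0
        assert m.sd_o**2 == pytest.approx(8.0 / 3.0, rel=1e-12)
        assert m.sd_s**2 == pytest.approx(6.0, rel=1e-12)
        assert m.cov_os == pytest.approx(4.0, rel=1e-12)
        assert m.r == pytest.approx(1.0, abs=1e-12)

    def test_identity_series(self, identity_series):
        m = moments(identity_series)
        assert m.r == pytest.approx(1.0, abs=1e-12)
        assert m.sd_o == m.sd_s

    def test_constant_s_flagged_nan_r(self):
        m = moments(series([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))
        assert m.sd_s == 0.0 and math.isnan(m.r)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            moments(series([1.0], [1.0]))

    def test_sample_convention_flag(self):
        m0 = moments(series(*TOY), ddof=0)
        m1 = moments(series(*TOY), ddof=1)
        assert m1.sd_o**2 == pytest.approx(m0.sd_o**2 * 3 / 2, rel=1e-12)
        assert m1.r == pytest.approx(m0.r, abs=1e-12)


class TestMeanSORatio:
    def test_toy(self):
        msor, cv = mean_so_ratio(series(*TOY))
        assert msor == pytest.approx(8.0 / 9.0, rel=1e-12)
        assert cv == pytest.approx(oracle.cv_so_pct(*TOY), rel=1e-12)
        assert cv == pytest.approx(31.87, abs=0.01)

    def test_identity(self, identity_series):
        msor, cv = mean_so_ratio(identity_series)
        assert msor == 1.0 and cv == 0.0

    def test_scaling(self):
        o = [2.0, 4.0, 6.0]
        msor, cv = mean_so_ratio(series(o, [4.0, 8.0, 12.0]))
        assert msor == pytest.approx(2.0, rel=1e-12)
        assert cv == pytest.approx(0.0, abs=1e-12)


class TestMeanBias:
    def test_underestimation_is_negative(self):
        # group means close to the published all-diet methane means
        p = series([159.0] * 3, [110.0] * 3)
        mb = mean_bias_pct(p)
        assert mb < 0
        assert abs(mb - (-30.5)) <= 0.5

    def test_identity_zero(self, identity_series):
        assert mean_bias_pct(identity_series) == 0.0

    def test_toy_equal_means(self):
        assert mean_bias_pct(series(*TOY)) == pytest.approx(0.0, abs=1e-12)


class TestRegression:
    def test_toy_moment(self):
        slope, se, r2, p1, p0 = regression_fit(series(*TOY), mode="moment")
        assert slope == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_toy_origin(self):
        slope, *_ = regression_fit(series(*TOY), mode="origin")
        assert slope == pytest.approx(60.0 / 66.0, rel=1e-12)

    def test_identity_slope_one(self, identity_series):
        slope, se, r2, p1, p0 = regression_fit(identity_series)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert p1 == 1.0

    def test_constant_s_degenerate(self):
        with pytest.raises(DegenerateInputError):
            regression_fit(series([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            regression_fit(series(*TOY), mode="banana")

    def test_slope_tests_against_scipy(self):
        rng = np.random.default_rng(3)
        o = rng.uniform(2, 8, size=12)
        s = 0.7 * o + rng.normal(0, 0.4, size=12)
        p = series(o, np.abs(s) + 0.1)
        slope, se, r2, p1, p0 = regression_fit(p)
        from scipy import stats
        lr = stats.linregress(p.s, p.o)
        assert slope == pytest.approx(lr.slope, rel=1e-10)
        assert se == pytest.approx(lr.stderr, rel=1e-10)
        assert p0 == pytest.approx(lr.pvalue, rel=1e-10)


class TestModelEfficiency:
    def test_toy(self):
        assert model_efficiency(series(*TOY)) == pytest.approx(0.75, rel=1e-12)

    def test_identity_is_one(self, identity_series):
        assert model_efficiency(identity_series) == 1.0

    def test_mean_predictor_is_zero(self):
        o = [2.0, 4.0, 6.0]
        assert model_efficiency(series(o, [4.0, 4.0, 4.0])) == pytest.approx(0.0, abs=1e-12)

    def test_constant_observed_error(self):
        with pytest.raises(DegenerateInputError):
            model_efficiency(series([3.0, 3.0, 3.0], [1.0, 2.0, 3.0]))


class TestMspePartition:
    def test_toy(self):
        mspe, bias, slope, random, p_bias, perfect = mspe_partition(series(*TOY))
        assert mspe == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert bias == pytest.approx(0.0, abs=1e-9)
        assert slope == pytest.approx(100.0, rel=1e-12)
        assert random == pytest.approx(0.0, abs=1e-9)
        assert not perfect

    def test_identity_perfect_flag(self, identity_series):
        mspe, bias, slope, random, p_bias, perfect = mspe_partition(identity_series)
        assert mspe == 0.0 and perfect
        assert (bias, slope, random) == (0.0, 0.0, 0.0)

    def test_partition_sums_to_100(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(3, 25)
            o = rng.uniform(1, 10, size=n)
            s = rng.uniform(1, 10, size=n)
            mspe, bias, slope, random, *_ = mspe_partition(series(o, s))
            assert bias + slope + random == pytest.approx(100.0, abs=1e-9)

    def test_p_bias_matches_paired_ttest(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        o = rng.uniform(2, 8, 15)
        s = o * 0.8 + rng.normal(0, 0.3, 15)
        p = series(o, np.abs(s) + 0.05)
        *_, p_bias, _ = mspe_partition(p)
        assert p_bias == pytest.approx(stats.ttest_rel(p.o, p.s).pvalue, rel=1e-12)


class TestConcordance:
    def test_toy(self):
        ccc, ca, r = concordance(series(*TOY))
        assert ccc == pytest.approx(24.0 / 26.0, rel=1e-12)
        assert ca == pytest.approx(24.0 / 26.0, rel=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_identity(self, identity_series):
        ccc, ca, r = concordance(identity_series)
        assert (ccc, ca, r) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            concordance(series([1.0, 2.0, 3.0], [4.0, 4.0, 4.0]))

    def test_published_component_products(self):
        # the three reconstructible printed columns
        assert round(ccc_from_components(0.923, 0.941), 3) == 0.869
        assert round(ccc_from_components(0.316, 0.960), 3) == 0.303
        assert round(ccc_from_components(0.330, 0.235), 3) == 0.078

    def test_component_range_checks(self):
        with pytest.raises(ValueError):
            ccc_from_components(1.5, 0.5)
        with pytest.raises(ValueError):
            ccc_from_components(0.5, 1.5)


class TestEvaluate:
    def test_toy_metric_set(self):
        ms = evaluate(series(*TOY))
        assert ms.msor == pytest.approx(8.0 / 9.0, rel=1e-10)
        assert ms.slope == pytest.approx(2.0 / 3.0, rel=1e-10)
        assert ms.mb_pct == pytest.approx(0.0, abs=1e-10)
        assert ms.me == pytest.approx(0.75, rel=1e-10)
        assert ms.mspe == pytest.approx(2.0 / 3.0, rel=1e-10)
        assert ms.ccc == pytest.approx(24.0 / 26.0, rel=1e-10)

    def test_identity_perfect_scores(self, identity_series):
        ms = evaluate(identity_series)
        assert ms.msor == 1.0
        assert ms.mb_pct == 0.0
        assert ms.slope == pytest.approx(1.0, abs=1e-12)
        assert ms.r2 == pytest.approx(1.0, abs=1e-12)
        assert ms.me == 1.0
        assert ms.mspe == 0.0 and ms.perfect_fit
        assert ms.ccc == pytest.approx(1.0) and ms.ca == pytest.approx(1.0)
        assert ms.p_slope_vs_1 == 1.0 and ms.p_bias == 1.0

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            evaluate(series([1.0, 2.0], [1.0, 2.0]))

    def test_internal_identities_on_synthetic(self, synthetic_records, diets):
        from methaneval import to_paired
        for variable in ("dmi", "ch4"):
            ms = evaluate(to_paired(synthetic_records, variable, diets))
            assert ms.bias_pct + ms.slope_pct + ms.random_pct == pytest.approx(100.0, abs=1e-9)
            assert ms.ccc == pytest.approx(ms.ca * ms.r, abs=1e-12)
            assert abs(ms.ccc) <= abs(ms.r) <= 1.0
            assert 0 < ms.ca <= 1.0
            assert ms.me <= ms.r2


class TestOracleEquivalence:
    """Every statistic must match the independent loop-based formulas."""

    def test_200_random_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(3, 31))
            o = rng.uniform(0.5, 20.0, size=n)
            s = rng.uniform(0.5, 20.0, size=n)
            p = series(o, s)
            olist, slist = list(o), list(s)
            ms = evaluate(p)
            assert ms.msor == pytest.approx(oracle.msor(olist, slist), abs=1e-10)
            assert ms.cv_so_pct == pytest.approx(oracle.cv_so_pct(olist, slist), abs=1e-10)
            assert ms.mb_pct == pytest.approx(oracle.mean_bias_pct(olist, slist), abs=1e-10)
            assert ms.slope == pytest.approx(oracle.slope_moment(olist, slist), abs=1e-10)
            assert ms.r2 == pytest.approx(oracle.r2(olist, slist), abs=1e-10)
            assert ms.me == pytest.approx(oracle.model_efficiency(olist, slist), abs=1e-10)
            assert ms.mspe == pytest.approx(oracle.mspe(olist, slist), abs=1e-10)
            eb, es, er = oracle.mspe_partition_pct(olist, slist)
            assert ms.bias_pct == pytest.approx(eb, abs=1e-9)
            assert ms.slope_pct == pytest.approx(es, abs=1e-9)
            assert ms.random_pct == pytest.approx(er, abs=1e-9)
            assert ms.ccc == pytest.approx(oracle.ccc(olist, slist), abs=1e-10)
            assert ms.ca == pytest.approx(oracle.ca(olist, slist), abs=1e-10)
            assert ms.r == pytest.approx(oracle.pearson(olist, slist), abs=1e-10)
            slope_o, *_ = regression_fit(p, mode="origin")
            assert slope_o == pytest.approx(oracle.slope_origin(olist, slist), abs=1e-10)
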