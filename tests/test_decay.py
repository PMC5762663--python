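import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oceandecay.decay import (
    DAYS_PER_YEAR,
    LogDecayFit,
    PairSamples,
    build_pairs,
    fit_logdecay,
    fit_loglog,
    group_decay_analysis,
    halving_time,
    initial_similarity,
)
from oceandecay.pairwise import PairwiseMatrix


def make_pairs(t, s):
    t = np.asarray(t, float)
    labels = [("a", f"b{i}") for i in range(t.size)]
    return PairSamples(np.asarray(s, float), t, labels)


class TestBuildPairs:
    def test_pair_count_and_dropping(self):
        labels = ["a", "b", "c", "d"]
        rng = np.random.default_rng(0)
        S = PairwiseMatrix.from_condensed(rng.random(6), labels, kind="similarity")
        tvals = rng.random(6) * 100 + 1
        T = PairwiseMatrix.from_condensed(tvals, labels, kind="distance")
        pairs = build_pairs(S, T)
        assert pairs.n_pairs == 6 and pairs.n_dropped == 0
        tvals2 = tvals.copy()
        tvals2[2] = np.nan  # one unreachable pair
        T2 = PairwiseMatrix.from_condensed(tvals2, labels, kind="distance")
        pairs2 = build_pairs(S, T2)
        assert pairs2.n_pairs == 5 and pairs2.n_dropped == 1

    def test_mismatched_stations_rejected(self):
        S = PairwiseMatrix.from_condensed([0.5], ["a", "b"], kind="similarity")
        T = PairwiseMatrix.from_condensed([3.0], ["a", "c"], kind="distance")
        with pytest.raises(ValueError, match="different station"):
            build_pairs(S, T)

    def test_all_missing_rejected(self):
        S = PairwiseMatrix.from_condensed([0.5], ["a", "b"], kind="similarity")
        T = PairwiseMatrix.from_condensed([np.nan], ["a", "b"], kind="distance")
        with pytest.raises(ValueError, match="no valid"):
            build_pairs(S, T)


class TestLogLogFit:
    def test_exact_power_law(self):
        t = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        fit = fit_loglog(make_pairs(t, 1.0 / t))
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_similarity_zero_slope(self):
        fit = fit_loglog(make_pairs([1, 10, 100], [0.3, 0.3, 0.3]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_similarity_excluded_and_counted(self):
        fit = fit_loglog(make_pairs([1, 10, 100, 1000], [0.5, 0.2, 0.1, 0.0]))
        assert fit.n_zero_excluded == 1 and fit.n_pairs == 3

    def test_slope_recovery_under_noise(self):
        """Known b = -0.3 recovered on average over 20 seeds."""
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.exp(rng.uniform(0, 7, 80))
            s = np.exp(-0.3 * np.log(t) + rng.normal(0, 0.2, 80))
            slopes.append(fit_loglog(make_pairs(t, s)).slope)
        assert np.mean(slopes) == pytest.approx(-0.3, abs=0.03)


class TestLogDecayFit:
    def test_exact_line(self):
        t = np.array([10.0, 100.0, 1000.0, 5000.0])
        s = -0.05 * np.log(t) + 0.6
        fit = fit_logdecay(make_pairs(t, s))
        assert fit.slope == pytest.approx(-0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(0.6, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        t = np.exp(rng.uniform(0, 8, 50))
        s = rng.random(50)
        fit = fit_logdecay(make_pairs(t, s))
        X = np.column_stack([np.ones(50), np.log(t)])
        beta = np.linalg.solve(X.T @ X, X.T @ s)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_two_point_closed_form(self):
        t = np.array([10.0, 1000.0, 10.0])  # third repeats to reach n=3
        s = np.array([0.8, 0.2, 0.8])
        fit = fit_logdecay(make_pairs(t, s))
        expected_slope = (0.2 - 0.8) / (np.log(1000.0) - np.log(10.0))
        assert fit.slope == pytest.approx(expected_slope, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_logdecay(make_pairs([1.0, 2.0], [0.5, 0.4]))


class TestInitialSimilarity:
    def test_mean_within_reference_window(self):
        pairs = make_pairs([50, 90, 500], [0.5, 0.54, 0.1])
        s0, fallback = initial_similarity(pairs)
        assert s0 == pytest.approx(0.52) and not fallback

    def test_single_qualifying_pair(self):
        pairs = make_pairs([80, 500, 900], [0.4, 0.2, 0.1])
        s0, fallback = initial_similarity(pairs)
        assert s0 == pytest.approx(0.4) and not fallback

    def test_fallback_to_ten_smallest(self):
        t = np.arange(200.0, 200.0 + 15)
        s = np.linspace(0.9, 0.2, 15)
        s0, fallback = initial_similarity(make_pairs(t, s))
        assert fallback
        assert s0 == pytest.approx(s[:10].mean())


class TestHalvingTime:
    def test_closed_form_example(self):
        fit = LogDecayFit(slope=-0.05, intercept=0.6, r_squared=1, p_value=0, n_pairs=9)
        days, years = halving_time(fit, s0=0.6)
        assert days == pytest.approx(np.exp(6.0), rel=1e-12)  # ~403.43
        assert years == pytest.approx(days / 365.25)

    def test_exponent_zero_gives_one_day(self):
        fit = LogDecayFit(slope=-0.1, intercept=0.2, r_squared=1, p_value=0, n_pairs=9)
        days, _ = halving_time(fit, s0=0.4)  # S0/2 == int
        assert days == pytest.approx(1.0)

    def test_no_decay_rejected(self):
        fit = LogDecayFit(slope=0.01, intercept=0.2, r_squared=1, p_value=0, n_pairs=9)
        with pytest.raises(ValueError, match="no decay"):
            halving_time(fit, s0=0.4)

    def test_consistent_with_published_prokaryote_row(self):
        """Implied intercept from (c, S0, HT) round-trips within 1%."""
        c, s0, ht_years = -0.0232, 0.52, 5094.0
        ht_days = ht_years * DAYS_PER_YEAR
        implied_int = s0 / 2.0 - c * np.log(ht_days)
        assert implied_int == pytest.approx(0.595, abs=0.005)
        fit = LogDecayFit(slope=c, intercept=implied_int, r_squared=1, p_value=0, n_pairs=9)
        _, years = halving_time(fit, s0)
        assert years == pytest.approx(ht_years, rel=0.01)

    @settings(max_examples=60, derandomize=True)
    @given(
        c=st.floats(-0.1, -0.005),
        s0=st.floats(0.1, 0.9),
        dint=st.floats(0.01, 0.3),
    )
    def test_monotonicity_in_slope_and_s0(self, c, s0, dint):
        """|c| steeper -> shorter t_H; a curve anchored through a larger S0
        at the reference time halves later."""
        intercept = s0 + dint  # keep S0/2 - int negative -> finite decay time
        base = LogDecayFit(slope=c, intercept=intercept, r_squared=1, p_value=0, n_pairs=9)
        steeper = LogDecayFit(slope=c * 1.5, intercept=intercept, r_squared=1, p_value=0, n_pairs=9)
        t_base, _ = halving_time(base, s0)
        t_steep, _ = halving_time(steeper, s0)
        assert t_steep <= t_base
        # anchor the fitted line through (t0=100 d, S0): int = S0 - c ln 100
        def anchored(s0v):
            fit = LogDecayFit(
                slope=c, intercept=s0v - c * np.log(100.0),
                r_squared=1, p_value=0, n_pairs=9,
            )
            return halving_time(fit, s0v)[0]

        assert anchored(min(s0 + 0.05, 1.0)) >= anchored(s0)

    def test_time_unit_invariance(self):
        """Fitting in years shifts the intercept but not c or t_H."""
        rng = np.random.default_rng(2)
        t_days = np.exp(rng.uniform(3, 9, 60))
        s = np.clip(-0.04 * np.log(t_days) + 0.7 + rng.normal(0, 0.02, 60), 0, 1)
        fit_days = fit_logdecay(make_pairs(t_days, s))
        fit_years = fit_logdecay(make_pairs(t_days / DAYS_PER_YEAR, s))
        assert fit_years.slope == pytest.approx(fit_days.slope, abs=1e-10)
        assert fit_years.intercept == pytest.approx(
            fit_days.intercept + fit_days.slope * np.log(DAYS_PER_YEAR), abs=1e-9
        )
        s0 = 0.6
        th_days, _ = halving_time(fit_days, s0)
        th_from_years, _ = halving_time(fit_years, s0)
        assert th_from_years * DAYS_PER_YEAR == pytest.approx(th_days, rel=1e-9)


class TestGroupAnalysis:
    def test_identical_communities_have_no_decay(self):
        labels = [f"s{i}" for i in range(6)]
        S = PairwiseMatrix(np.ones((6, 6)), labels, kind="similarity")
        rng = np.random.default_rng(3)
        T = PairwiseMatrix.from_condensed(
            np.exp(rng.uniform(2, 8, 15)), labels, kind="distance"
        )
        logdecay, loglog = group_decay_analysis(S, T)
        assert logdecay.slope == pytest.approx(0.0, abs=1e-12)
        assert logdecay.halving_days is None
        with pytest.raises(ValueError, match="no decay"):
            halving_time(logdecay, 1.0)

    def test_steeper_decay_shorter_halving_time(self):
        rng = np.random.default_rng(4)
        labels = [f"s{i}" for i in range(20)]
        t = np.exp(rng.uniform(2.5, 8, 190))
        T = PairwiseMatrix.from_condensed(t, labels, kind="distance")
        results = []
        for c in (-0.02, -0.06):
            s = np.clip(c * np.log(t) + 0.6 + rng.normal(0, 0.01, t.size), 0, 1)
            S = PairwiseMatrix.from_condensed(s, labels, kind="similarity")
            logdecay, _ = group_decay_analysis(S, T)
            results.append(logdecay)
        assert results[1].halving_days < results[0].halving_days
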