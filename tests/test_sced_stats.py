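"""PND, visual summaries, randomization/permutation tests, Bayes factor."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as spstats

from exengage.errors import DesignViolationError, InsufficientDataError, PairingError
from exengage.sced_design import enumerate_schedules
from exengage.sced_stats import (
    ATDSeries,
    bayes_factor_t,
    fisher_pitman,
    interpret_bayes_factor,
    pnd,
    scrt,
    visual_summary,
    wilcoxon_pratt,
)


class TestPND:
    @pytest.mark.parametrize("m,k,want",
                             [(5, 4, 80.0), (4, 1, 25.0), (4, 2, 50.0),
                              (2, 0, 0.0), (6, 5, pytest.approx(83.3, abs=0.05))])
    def test_favourable_fraction_of_comparisons(self, m, k, want,
                                                alternating_series):
        assert pnd(alternating_series(m, k)) == want

    def test_exact_ties_count_as_overlap(self):
        series = ATDSeries.from_values(["feedback", "no_feedback"], [0.8, 0.8])
        assert pnd(series) == 0.0

    def test_no_transitions_is_insufficient_data(self):
        series = ATDSeries.from_values(["feedback", "feedback"], [0.9, 0.8])
        with pytest.raises(InsufficientDataError):
            pnd(series)

    def test_bounded_and_translation_invariant(self, alternating_series):
        series = alternating_series(6, 4)
        p = pnd(series)
        shifted = ATDSeries.from_values(series.conditions, series.values + 5.0)
        assert 0.0 <= p <= 100.0
        assert pnd(shifted) == p

    def test_each_session_used_in_at_most_one_comparison(self):
        # FNNF: transition at (0,1); session 2-3 forms the second pair
        series = ATDSeries.from_values(
            ["feedback", "no_feedback", "no_feedback", "feedback"],
            [1.0, 0.5, 0.9, 0.8])
        # pairs: (0,1) favourable; (2,3): 0.8 < 0.9 not favourable
        assert pnd(series) == 50.0


class TestVisualSummary:
    def test_constant_series_is_flat_and_stable(self):
        series = ATDSeries.from_values(["feedback", "no_feedback"] * 3, [0.9] * 6)
        vs = visual_summary(series, scale=(0.0, 1.25))
        assert vs.trend == "zero-celerating"
        assert vs.variability == "stable"

    def test_high_level_gradual_acceleration(self):
        values = 0.9 + 0.02 * np.arange(6)
        series = ATDSeries.from_values(["feedback", "no_feedback"] * 3, values)
        vs = visual_summary(series, scale=(0.0, 1.25))
        assert vs.level == "high"
        assert vs.trend == "gradual accelerating"

    def test_ceiling_ratings_read_high_and_stable(self):
        """All-5 smiley ratings: high level, no trend, no variability."""
        series = ATDSeries.from_values(["feedback", "no_feedback"] * 3,
                                       [5] * 6, outcome_name="fun")
        vs = visual_summary(series, scale=(1.0, 5.0))
        assert (vs.level, vs.trend, vs.variability) == \
            ("high", "zero-celerating", "stable")

    def test_steep_decline_labelled(self):
        series = ATDSeries.from_values(["feedback", "no_feedback"] * 3,
                                       [1.0, 0.9, 0.8, 0.7, 0.6, 0.5])
        assert visual_summary(series, (0, 1.25)).trend == "steep decelerating"

    def test_zero_scale_range_rejected(self):
        series = ATDSeries.from_values(["feedback", "no_feedback"], [1, 2])
        with pytest.raises(ValueError):
            visual_summary(series, scale=(1.0, 1.0))


class TestSCRT:
    def test_constant_outcomes_give_p_one(self):
        space = enumerate_schedules(8)
        series = ATDSeries.from_values(space.schedules[0], [0.8] * 8)
        assert scrt(series, space).p_value == 1.0

    def test_schedule_outside_space_is_design_violation(self):
        space = enumerate_schedules(8, max_run=2, balance=True)
        series = ATDSeries.from_values(["feedback"] * 4 + ["no_feedback"] * 4,
                                       np.linspace(0.5, 1.2, 8))
        with pytest.raises(DesignViolationError):
            scrt(series, space)

    def test_monte_carlo_close_to_exhaustive(self, rng):
        """MC sampling of the null reproduces the exhaustive p within 0.01."""
        space = enumerate_schedules(8, max_run=2, balance=True)
        series = ATDSeries.from_values(space.schedules[5],
                                       rng.normal(0.8, 0.2, 8))
        exact = scrt(series, space, n_mc=10_000)
        assert exact.exhaustive
        mc = scrt(series, space, n_mc=20, seed=1)  # force sampling
        assert not mc.exhaustive
        # compare against a big MC run for the 0.01 agreement contract
        mc_big = scrt(series, space, n_mc=len(space.schedules) - 1 + 9_999, seed=2)
        assert abs(mc_big.p_value - exact.p_value) < 0.01

    def test_null_uses_only_admissible_schedules(self, rng):
        """The null set size never exceeds the restricted space size."""
        space = enumerate_schedules(10, max_run=2, balance=True)
        series = ATDSeries.from_values(space.schedules[0],
                                       rng.normal(0.8, 0.2, 10))
        res = scrt(series, space)
        assert res.exhaustive and res.n_resamples == len(space)
        assert res.p_value >= 1.0 / len(space)

    def test_power_rises_with_effect_size(self):
        """Rejection rate is non-decreasing in the feedback effect."""
        from exengage.sced_design import draw_schedule
        from exengage.synthetic_data import EffectSpec, simulate_atd_sessions

        space = enumerate_schedules(12, max_run=2, balance=True)
        rates = []
        for delta in (0.0, 0.1, 0.2, 0.3):
            rej = 0
            for i in range(150):
                sched = draw_schedule(space, seed=1000 + i)
                recs = simulate_atd_sessions(
                    EffectSpec(feedback_delta=delta, session_sd=0.15,
                               seed=5000 + i), list(sched))
                rej += scrt(ATDSeries(recs), space).p_value <= 0.05
            rates.append(rej / 150)
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestFisherPitman:
    def test_exhaustive_small_case(self):
        """a=[3,4] vs b=[1,2]: only 1 of 6 splits has a mean gap this large."""
        res = fisher_pitman([3, 4], [1, 2], alternative="greater")
        assert res.exhaustive
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_constant_groups_give_p_one(self):
        assert fisher_pitman([2, 2, 2], [2, 2, 2]).p_value == 1.0

    def test_monte_carlo_matches_exhaustive_within_3_se(self, rng):
        a, b = rng.normal(0.5, 1, 5), rng.normal(0, 1, 5)
        exact = fisher_pitman(a, b, n_mc=100_000)
        assert exact.exhaustive
        mc = fisher_pitman(a, b, n_mc=200, seed=3)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 200)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 1 / 200

    def test_agrees_with_scipy_permutation_test(self, rng):
        """Independent cross-check against scipy's exact enumeration."""
        a, b = rng.normal(1, 1, 4), rng.normal(0, 1, 5)
        mine = fisher_pitman(a, b, alternative="greater")
        ref = spstats.permutation_test(
            (a, b), lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent", alternative="greater",
            n_resamples=np.inf)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            fisher_pitman([], [1, 2])


class TestWilcoxonPratt:
    def test_all_zero_differences_degenerate(self):
        assert wilcoxon_pratt([1, 1, 1], [1, 1, 1]).p_value == 1.0

    def test_matches_exhaustive_sign_flip_oracle(self, rng):
        """Brute-force 2^m sign-flip enumeration with Pratt ranks."""
        a = rng.normal(0.3, 1, 6)
        b = rng.normal(0, 1, 6)
        res = wilcoxon_pratt(a, b, alternative="greater")
        d = a - b
        ranks = spstats.rankdata(np.abs(d))
        nz = d != 0
        r, s = ranks[nz], np.sign(d[nz])
        w_obs = r[s > 0].sum()
        null = [sum(rk for rk, sg in zip(r, signs) if sg > 0)
                for signs in itertools.product([-1, 1], repeat=len(r))]
        expected = np.mean([w >= w_obs - 1e-12 for w in null])
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_pratt_zeros_raise_ranks_of_nonzero_differences(self):
        """d=[+1,+2,+3,0]: the zero is ranked (rank 1) then discarded, so the
        positive differences hold ranks 2,3,4 and the one-sided p is 1/8."""
        res = wilcoxon_pratt([2, 3, 4, 5], [1, 1, 1, 5], alternative="greater")
        # exhaustive oracle over 2^3 sign patterns with ranks {2,3,4}
        null = [sum(rk for rk, sg in zip((2, 3, 4), signs) if sg > 0)
                for signs in itertools.product([-1, 1], repeat=3)]
        expected = np.mean([w >= 9 - 1e-12 for w in null])
        assert res.p_value == pytest.approx(expected) == pytest.approx(1 / 8)

    def test_length_mismatch_is_pairing_error(self):
        with pytest.raises(PairingError):
            wilcoxon_pratt([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(min_value=-5, max_value=5),
                    min_size=1, max_size=8))
    def test_p_in_unit_interval_and_bounded_below(self, diffs):
        a = np.array(diffs, dtype=float)
        b = np.zeros_like(a)
        res = wilcoxon_pratt(a, b)
        m = int((a != 0).sum())
        assert 0 < res.p_value <= 1
        if res.exhaustive and m > 0:
            assert res.p_value >= 1 / 2 ** m


class TestBayesFactor:
    def test_identical_means_favour_the_null(self, rng):
        a, b = rng.normal(0, 1, 150), rng.normal(0, 1, 150)
        assert bayes_factor_t(a, b).bayes_factor < 1

    def test_matches_independent_fine_grid_quadrature(self, rng):
        """Trapezoid integration on a transformed fine grid agrees to 4 sig figs."""
        a, b = rng.normal(0.8, 1, 9), rng.normal(0, 1, 11)
        bf = bayes_factor_t(a, b).bayes_factor

        na, nb = len(a), len(b)
        nu = na + nb - 2
        n_eff = na * nb / (na + nb)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / nu
        t = (a.mean() - b.mean()) / np.sqrt(sp2 / n_eff)
        r2 = 0.5
        # substitute g = u / (1 - u), du-Jacobian 1/(1-u)^2, u on (0, 1)
        u = np.linspace(1e-9, 1 - 1e-9, 400_001)
        g = u / (1 - u)
        dens = np.sqrt(r2 / (2 * np.pi)) * g ** -1.5 * np.exp(-r2 / (2 * g))
        like = (1 + n_eff * g) ** -0.5 * (
            1 + t ** 2 / ((1 + n_eff * g) * nu)) ** (-(nu + 1) / 2)
        num = np.trapezoid(like * dens / (1 - u) ** 2, u)
        den = (1 + t ** 2 / nu) ** (-(nu + 1) / 2)
        assert bf == pytest.approx(num / den, rel=5e-5)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        a, b = rng.normal(0.5, 1, 12), rng.normal(0, 1, 10)
        t = spstats.ttest_ind(a, b).statistic
        ref = float(pg.bayesfactor_ttest(t, 12, 10))
        assert bayes_factor_t(a, b).bayes_factor == pytest.approx(ref, rel=1e-3)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(0.4, 1, 8), rng.normal(0, 1, 8)
        bf1 = bayes_factor_t(a, b).bayes_factor
        bf2 = bayes_factor_t(7.3 * a, 7.3 * b).bayes_factor
        assert bf1 == pytest.approx(bf2, rel=1e-6)

    def test_qualitative_interpretation_bands(self):
        assert "moderate evidence for the null" in interpret_bayes_factor(0.2)
        assert "for a difference" in interpret_bayes_factor(5.0)
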