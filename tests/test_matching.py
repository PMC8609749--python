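"""Tests of the propensity fit and the greedy caliper matcher."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import psmsim as ps
from psmsim.matching import (
    MatchOptions,
    PropensityFit,
    fit_propensity_xy,
    match,
    match_with_replacement_family,
)
from psmsim.synthetic import WEAK_BETA

from _oracles import brute_force_match


def toy_fit(logit_ps, caliper):
    lp = np.asarray(logit_ps, dtype=float)
    return PropensityFit(
        ps=expit(lp),
        logit_ps=lp,
        coefficients=np.full(7, np.nan),
        converged=True,
        caliper_width=caliper,
    )


class TestFitPropensity:
    def test_null_model_recovers_treated_fraction(self, rng):
        X = ps.draw_covariates(20_000, rng)
        T = (rng.uniform(size=20_000) < 0.4).astype(int)
        fit = fit_propensity_xy(X, T)
        assert fit.converged
        assert expit(fit.coefficients[0]) == pytest.approx(T.mean(), abs=0.01)
        assert fit.coefficients[1:] == pytest.approx(np.zeros(6), abs=0.05)

    def test_parameter_recovery_large_n(self, weak05_logistic):
        rng = np.random.default_rng(31)
        X = ps.draw_covariates(100_000, rng)
        pT = ps.treatment_probabilities(X, weak05_logistic.beta0, WEAK_BETA)
        T = (rng.uniform(size=len(pT)) < pT).astype(int)
        fit = fit_propensity_xy(X, T)
        assert fit.converged
        assert fit.coefficients[1:] == pytest.approx(WEAK_BETA, abs=0.05)

    def test_degenerate_all_treated_flagged(self):
        X = ps.draw_covariates(50, 3)
        fit = fit_propensity_xy(X, np.ones(50))
        assert not fit.converged

    def test_caliper_attached(self, cohort):
        fit = ps.fit_propensity(cohort)
        assert fit.caliper_width == pytest.approx(
            0.2 * np.std(fit.logit_ps, ddof=1)
        )


class TestComputeCaliper:
    def test_triple_with_unit_sd(self):
        assert ps.compute_caliper(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.2)

    def test_constant_logit_ps(self):
        assert ps.compute_caliper(np.zeros(5)) == 0.0


class TestMatchToyExamples:
    """Hand-enumerated cases on a 4-unit cohort."""

    def test_narrow_caliper_discards_treated(self):
        # only one of the two required controls is within the caliper
        fit = toy_fit([0.0, 0.05, 0.30, 0.50], caliper=0.2)
        t = np.array([1, 0, 0, 0])
        sample = match(fit, t, MatchOptions(with_replacement=True, ratio_K=2))
        assert sample.n_treated_matched == 0
        assert sample.discarded_treated == [0]

    def test_wide_caliper_selects_two_nearest(self):
        fit = toy_fit([0.0, 0.05, 0.30, 0.50], caliper=0.6)
        t = np.array([1, 0, 0, 0])
        sample = match(fit, t, MatchOptions(with_replacement=True, ratio_K=2))
        (s,) = sample.sets
        assert s.control_indices == (1, 2)
        assert s.control_weight == pytest.approx(0.5)

    def test_without_replacement_exclusivity(self):
        # two treated, a single control in both calipers: only one set forms
        fit = toy_fit([0.0, 0.02, 0.01], caliper=0.1)
        t = np.array([1, 1, 0])
        sample = match(fit, t, MatchOptions(with_replacement=False, ratio_K=1, order_seed=5))
        assert sample.n_treated_matched == 1
        assert list(sample.usage_count.values()) == [1]
        assert len(sample.discarded_treated) == 1

    def test_tie_broken_by_lower_index(self):
        # controls at indices 1 and 2 are equidistant from the treated unit
        fit = toy_fit([0.0, 0.1, -0.1], caliper=0.5)
        t = np.array([1, 0, 0])
        sample = match(fit, t, MatchOptions(with_replacement=True, ratio_K=1))
        assert sample.sets[0].control_indices == (1,)

    def test_empty_groups(self):
        fit = toy_fit([0.1, 0.2], caliper=0.2)
        sample = match(fit, np.array([1, 1]), MatchOptions(True, 1))
        assert sample.n_treated_matched == 0
        assert sample.n_treated_total == 2


@st.composite
def small_cohorts(draw):
    n = draw(st.integers(min_value=2, max_value=8))
    # coarse grid of logit values to force exact ties
    lp = draw(
        st.lists(
            st.sampled_from([-0.2, -0.1, 0.0, 0.1, 0.2, 0.3]), min_size=n, max_size=n
        )
    )
    t = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    K = draw(st.integers(1, 3))
    wr = draw(st.booleans())
    partial = draw(st.booleans())
    seed = draw(st.integers(0, 100))
    return np.array(lp), np.array(t), K, wr, partial, seed


class TestMatchOracleEquivalence:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(small_cohorts())
    def test_agrees_with_exhaustive_matcher(self, case):
        lp, t, K, wr, partial, seed = case
        caliper = 0.15
        fit = toy_fit(lp, caliper)
        sample = match(
            fit,
            t,
            MatchOptions(
                with_replacement=wr, ratio_K=K, order_seed=seed, partial_sets=partial
            ),
        )
        oracle_sets, oracle_discarded = brute_force_match(
            lp, t, caliper, K, wr, seed, partial_sets=partial
        )
        got = {s.treated_index: list(s.control_indices) for s in sample.sets}
        assert got == oracle_sets
        assert sorted(sample.discarded_treated) == sorted(oracle_discarded)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(small_cohorts())
    def test_invariants_hold(self, case):
        lp, t, K, wr, partial, seed = case
        fit = toy_fit(lp, 0.15)
        sample = match(
            fit,
            t,
            MatchOptions(
                with_replacement=wr, ratio_K=K, order_seed=seed, partial_sets=partial
            ),
        )
        for s in sample.sets:
            assert 1 <= len(set(s.control_indices)) == s.m <= K
            if not partial:
                assert s.m == K
            for c in s.control_indices:
                assert abs(lp[c] - lp[s.treated_index]) <= 0.15 + 1e-12
        if not wr:
            assert all(v == 1 for v in sample.usage_count.values())
        assert sum(sample.usage_count.values()) == sum(s.m for s in sample.sets)
        assert sample.n_treated_full == sum(1 for s in sample.sets if s.m == K)


class TestReplacementProperties:
    def test_k1_with_replacement_is_order_independent(self, cohort):
        fit = ps.fit_propensity(cohort)
        samples = [
            match(fit, cohort.T, MatchOptions(True, 1, order_seed=s)) for s in (0, 1, 2)
        ]
        reference = {s.treated_index: s.control_indices for s in samples[0].sets}
        for other in samples[1:]:
            assert {s.treated_index: s.control_indices for s in other.sets} == reference

    @pytest.mark.parametrize("partial", [False, True])
    def test_family_fast_path_equals_direct_match(self, cohort, partial):
        fit = ps.fit_propensity(cohort)
        family = match_with_replacement_family(
            fit, cohort.T, [1, 2, 3, 4, 5], partial_sets=partial
        )
        for K in (1, 2, 3, 4, 5):
            direct = match(
                fit,
                cohort.T,
                MatchOptions(True, K, order_seed=77, partial_sets=partial),
            )
            assert family[K].sets == direct.sets
            assert family[K].usage_count == direct.usage_count
            assert family[K].discarded_treated == direct.discarded_treated
            assert family[K].n_treated_full == direct.n_treated_full


class TestMatchedSampleSummaries:
    def test_proportion_matched_treated(self):
        fit = toy_fit(np.linspace(-1, 1, 20), caliper=0.5)
        t = np.zeros(20, dtype=int)
        t[:10] = 1
        sample = match(fit, t, MatchOptions(True, 1))
        assert ps.proportion_matched_treated(sample) == sample.n_treated_matched / 10

    def test_prc_counts_reused_controls(self):
        fit = toy_fit([0.0, 0.1, 0.01, 0.02], caliper=0.5)
        t = np.array([1, 1, 0, 0])
        wr = match(fit, t, MatchOptions(True, 2))
        assert ps.proportion_resampled_controls(wr) == pytest.approx(1.0)
        nr = match(fit, t, MatchOptions(False, 1, order_seed=4))
        assert ps.proportion_resampled_controls(nr) == 0.0

    def test_unit_weights_sum(self, cohort):
        fit = ps.fit_propensity(cohort)
        sample = match(fit, cohort.T, MatchOptions(True, 3))
        w = sample.unit_weights(cohort.n, cohort.T.astype(bool))
        # each set contributes weight 1 on the treated side and 1 in total
        # across its controls
        t = cohort.T.astype(bool)
        assert w[t].sum() == pytest.approx(sample.n_sets)
        assert w[~t].sum() == pytest.approx(sample.n_sets)

    def test_tidy_export(self, cohort):
        fit = ps.fit_propensity(cohort)
        sample = match(fit, cohort.T, MatchOptions(True, 2))
        frame = sample.to_frame()
        assert set(frame.columns) == {"set_id", "role", "unit_index", "weight"}
        assert (frame.groupby("set_id").size() == 3).all()
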