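"""Log-rank statistics, Dunnett adjustment, combination function, closed testing."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hyp

import seamtrial as st
from seamtrial.exceptions import MonotoneInformationError, ValidationError
from seamtrial.testing import _comparison_logrank, _pmax_equicorrelated


def brute_force_logrank(times, events, group):
    """Independent oracle: explicit risk-set enumeration at each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, bool)
    u = v = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & group).sum()
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u, v


small_dataset = hyp.integers(2, 20).flatmap(
    lambda n: hyp.tuples(
        hyp.lists(hyp.integers(1, 8), min_size=n, max_size=n),  # tied times
        hyp.lists(hyp.booleans(), min_size=n, max_size=n),
        hyp.lists(hyp.booleans(), min_size=n, max_size=n),
    )
)


class TestLogrank:
    def test_hand_computed_two_subjects(self):
        stat = st.logrank_uv([1.0, 2.0], [1, 0], [True, False])
        assert stat.u == pytest.approx(0.5)
        assert stat.v == pytest.approx(0.25)

    def test_antisymmetry_under_group_exchange(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(1, 30)
        events = rng.uniform(size=30) < 0.7
        group = rng.uniform(size=30) < 0.5
        if group.all() or (~group).all():
            group[0] = not group[0]
        s1 = st.logrank_uv(times, events, group)
        s2 = st.logrank_uv(times, events, ~group)
        assert s1.u == pytest.approx(-s2.u, abs=1e-12)
        assert s1.v == pytest.approx(s2.v, abs=1e-12)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(small_dataset)
    def test_matches_brute_force_oracle(self, data):
        times, events, group = data
        group = np.asarray(group)
        if group.all() or (~group).all():
            return
        stat = st.logrank_uv(times, events, group)
        u, v = brute_force_logrank(times, events, group)
        assert stat.u == pytest.approx(u, abs=1e-10)
        assert stat.v == pytest.approx(v, abs=1e-10)

    def test_matches_lifelines(self):
        """Cross-check the standardized statistic against an established library."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 60
            times = np.round(rng.exponential(10, n), 1) + 0.1
            events = rng.uniform(size=n) < 0.8
            group = rng.uniform(size=n) < 0.5
            if group.all() or (~group).all():
                continue
            stat = st.logrank_uv(times, events, group)
            ll = logrank_test(
                times[group], times[~group], events[group], events[~group]
            )
            assert stat.z**2 == pytest.approx(ll.test_statistic, rel=1e-8)

    def test_no_events(self):
        stat = st.logrank_uv([1.0, 2.0], [0, 0], [True, False])
        assert (stat.u, stat.v) == (0.0, 0.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            st.logrank_uv([1.0, 2.0], [1, 1], [True, True])


class TestStagewise:
    def test_zero_information_stage1(self):
        sw = st.stagewise_z(st.LogrankStat(0.0, 0.0), st.LogrankStat(2.0, 4.0))
        assert sw.z1 == 0.0
        assert sw.z2 == pytest.approx(1.0)

    def test_arithmetic(self):
        sw = st.stagewise_z(st.LogrankStat(0.5, 0.25), st.LogrankStat(2.5, 1.25))
        assert sw.z1 == pytest.approx(1.0)
        assert sw.z2 == pytest.approx(2.0)

    def test_degenerate_increment(self):
        sw = st.stagewise_z(st.LogrankStat(1.0, 2.0), st.LogrankStat(1.0, 2.0))
        assert sw.z2 == 0.0

    def test_monotone_information_error(self):
        with pytest.raises(MonotoneInformationError):
            st.stagewise_z(st.LogrankStat(1.0, 2.0), st.LogrankStat(1.0, 1.0))

    def test_independent_increments_on_null_trials(self, null_design):
        """corr(Z1, Z2) of the selected comparison is ~0 across null replicates."""
        cfg = replace(null_design, threshold_delta=-np.inf)
        z1s, z2s = [], []
        for seed in range(300):
            tr = st.simulate_trial(cfg, 0.16, -1.37, 1.53, seed=seed)
            (sel,) = tr.decision.selected_arms
            interim = _comparison_logrank(
                tr, sel, tr.ia_calendar_week, tr.surrogate_mature_at_ia
            )
            final = _comparison_logrank(
                tr, sel, np.full(tr.n_subjects, cfg.followup_weeks), tr.in_analysis_set
            )
            sw = st.stagewise_z(interim, final)
            z1s.append(sw.z1)
            z2s.append(sw.z2)
        corr = np.corrcoef(z1s, z2s)[0, 1]
        assert abs(corr) < 3 / np.sqrt(300)


class TestDunnett:
    def test_single_comparison_reduces_to_unadjusted(self):
        assert st.dunnett_adjusted_p([1.6449]) == pytest.approx(0.05, abs=1e-4)

    def test_monte_carlo_oracle(self):
        """Frozen oracle: P(max >= 1.96), k=3, rho=0.5, from a 2e7-draw
        Monte-Carlo simulation (estimate 0.0627104, SE 5.4e-5)."""
        p = st.dunnett_adjusted_p([1.96, 1.0, 0.5])
        assert p == pytest.approx(0.0627104, abs=3 * 5.4e-5)

    def test_quadrature_matches_scipy_mvn(self):
        from scipy.stats import multivariate_normal

        for k in (2, 3, 4):
            for rho in (0.3, 0.5):
                for t in (-0.5, 1.0, 2.3):
                    corr = np.full((k, k), rho)
                    np.fill_diagonal(corr, 1.0)
                    ref = multivariate_normal.cdf(
                        np.full(k, t), mean=np.zeros(k), cov=corr, abseps=1e-8
                    )
                    assert _pmax_equicorrelated(t, k, rho) == pytest.approx(ref, abs=1e-6)

    def test_general_correlation_path(self):
        """Non-equicorrelated matrices route through the multivariate normal CDF."""
        from scipy.stats import multivariate_normal

        corr = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        z = [1.5, 0.7, 0.2]
        expected = 1 - multivariate_normal.cdf(
            np.full(3, 1.5), mean=np.zeros(3), cov=corr, abseps=1e-8
        )
        assert st.dunnett_adjusted_p(z, corr) == pytest.approx(expected, abs=1e-5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hyp.lists(hyp.floats(-3, 3), min_size=1, max_size=4))
    def test_adjusted_at_least_unadjusted(self, zs):
        from scipy.special import ndtr

        p_adj = st.dunnett_adjusted_p(zs)
        assert p_adj >= (1 - ndtr(max(zs))) - 1e-12

    def test_critical_value_against_monte_carlo(self):
        """97.5th percentile of max of trivariate equicorrelated normals."""
        crit = st.dunnett_critical_value(3, 0.025)
        rng = np.random.default_rng(42)
        n = 4_000_000
        x0 = rng.standard_normal(n)
        m = np.sqrt(0.5) * x0 + np.sqrt(0.5) * rng.standard_normal(n)
        for _ in range(2):
            m = np.maximum(m, np.sqrt(0.5) * x0 + np.sqrt(0.5) * rng.standard_normal(n))
        assert crit == pytest.approx(np.quantile(m, 0.975), abs=0.005)

    def test_bad_correlation(self):
        with pytest.raises(ValidationError):
            st.dunnett_adjusted_p([1.0, 2.0], np.eye(3))


class TestCombination:
    def test_degenerate_weight_returns_p1(self):
        for p2 in (0.001, 0.4, 0.999):
            assert st.inverse_normal_combination(0.07, p2, 1.0, 0.0) == pytest.approx(
                0.07, abs=1e-12
            )

    def test_equal_weights_frozen_value(self):
        """C(0.05, 0.05) with equal weights: 1 - Phi(sqrt(2) * 1.64485...)."""
        c = st.inverse_normal_combination(0.05, 0.05, np.sqrt(0.5), np.sqrt(0.5))
        assert c == pytest.approx(0.01000463, abs=1e-6)

    def test_monotone_in_both_arguments(self):
        grid = np.linspace(0.01, 0.99, 50)
        w = np.sqrt(0.5)
        vals = np.array(
            [[st.inverse_normal_combination(p1, p2, w, w) for p2 in grid] for p1 in grid]
        )
        assert (np.diff(vals, axis=0) >= -1e-12).all()
        assert (np.diff(vals, axis=1) >= -1e-12).all()

    def test_weight_constraint_enforced(self):
        with pytest.raises(ValidationError):
            st.inverse_normal_combination(0.05, 0.05, 0.8, 0.8)

    def test_sample_fraction_weights_are_unit_norm(self, scenario1_design):
        w1, w2 = scenario1_design.stage_weights()
        assert w1**2 + w2**2 == pytest.approx(1.0, abs=1e-15)
        assert w1 == pytest.approx(np.sqrt(40 / 288))
        assert w2 == pytest.approx(np.sqrt(248 / 288))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(hyp.integers(1, 10_000), hyp.integers(1, 10_000))
    def test_weight_identity_any_sizes(self, n1, n2):
        w1 = np.sqrt(n1 / (n1 + n2))
        w2 = np.sqrt(n2 / (n1 + n2))
        assert abs(w1**2 + w2**2 - 1.0) < 1e-12


class TestClosedTesting:
    W = (np.sqrt(40 / 288), np.sqrt(248 / 288))

    def test_hand_enumeration_selected_arm_only(self):
        """Strong stage-1 and stage-2 evidence rejects the selected arm and,
        because every other elementary hypothesis lacks stage-2 data, only it."""
        z1 = np.array([2.8, 2.9, 3.0])
        z2 = np.array([0.0, 0.0, 4.0])
        res = st.closed_testing(z1, z2, {3}, alpha=0.025, weights=self.W)
        np.testing.assert_array_equal(res.rejected, [False, False, True])
        assert len(res.details) == 7
        # independent hand computation of every intersection containing H3
        from scipy.special import ndtr, ndtri
        from scipy.stats import multivariate_normal

        w1, w2 = self.W
        for det in res.details:
            S = sorted(det.subset)
            k = len(S)
            corr = np.full((k, k), 0.5)
            np.fill_diagonal(corr, 1.0)
            p1 = 1 - multivariate_normal.cdf(
                np.full(k, z1[np.array(S) - 1].max()), mean=np.zeros(k), cov=corr, abseps=1e-8
            )
            p2 = 1 - ndtr(4.0) if 3 in S else 1 - 1e-15
            c = 1 - ndtr(w1 * ndtri(1 - p1) + w2 * ndtri(1 - p2))
            assert det.combined == pytest.approx(max(c, 1e-15), rel=1e-4, abs=1e-9)
            assert (det.combined < 0.025) == (3 in S)

    def test_futility_rejects_nothing(self):
        res = st.closed_testing([3.0, 3.0, 3.0], [3.0, 3.0, 3.0], set(), weights=self.W)
        assert not res.any_rejected()
        assert res.details == ()

    def test_monotone_in_stage2_evidence(self):
        z1 = np.array([0.5, 1.0, 1.8])
        rejected_sets = []
        for z2_sel in np.linspace(0.0, 6.0, 25):
            z2 = np.array([0.0, 0.0, z2_sel])
            res = st.closed_testing(z1, z2, {3}, alpha=0.025, weights=self.W)
            rejected_sets.append(res.rejected.sum())
        assert (np.diff(rejected_sets) >= 0).all()

    def test_unselected_arms_cannot_be_rejected(self):
        z1 = np.full(3, 10.0)
        z2 = np.full(3, 10.0)
        res = st.closed_testing(z1, z2, {2}, alpha=0.025, weights=self.W)
        np.testing.assert_array_equal(res.rejected, [False, True, False])

    def test_closure_consonance_structural(self):
        """H_i rejected exactly when every intersection containing i passes."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            z1 = rng.normal(1.0, 1.5, size=3)
            z2 = np.zeros(3)
            sel = int(rng.integers(1, 4))
            z2[sel - 1] = rng.normal(2.0, 1.5)
            res = st.closed_testing(z1, z2, {sel}, alpha=0.025, weights=self.W)
            for i in range(1, 4):
                should = all(
                    det.combined < 0.025 for det in res.details if i in det.subset
                )
                assert res.rejected[i - 1] == should

    def test_selected_out_of_range(self):
        with pytest.raises(ValidationError):
            st.closed_testing([1.0, 1.0], [1.0, 1.0], {5}, weights=self.W)


class TestSingleStageDunnett:
    def test_k1_reduces_to_z_threshold(self):
        from scipy.special import ndtri

        c = ndtri(1 - 0.025)
        assert st.single_stage_dunnett_test([c + 0.01], 0.025)[0]
        assert not st.single_stage_dunnett_test([c - 0.01], 0.025)[0]

    def test_huge_statistics_all_rejected(self):
        assert st.single_stage_dunnett_test([10.0, 10.0, 10.0], 0.025).all()

    def test_marginal_cases_use_family_critical_value(self):
        crit = st.dunnett_critical_value(3, 0.025)
        out = st.single_stage_dunnett_test([crit + 0.01, crit - 0.01, 0.0], 0.025)
        np.testing.assert_array_equal(out, [True, False, False])
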