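import numpy as np
import pytest
from scipy import stats

from renalrisk.risk_metrics import (
    CensoringDistribution,
    auc_t,
    bootstrap_se,
    horizon_classify,
    pcf,
    pcf_curve,
    pnf,
    prediction_error,
    risk_distribution_summary,
)
from tests.conftest import uncensored_instance


def _uncensored_outcomes(is_case, horizon=1.0):
    """Outcomes with all weights 1: cases before, controls after the horizon."""
    times = np.where(is_case, 0.5, 2.0)
    events = np.where(is_case, 1, 0)
    return horizon_classify(times, events, horizon)


class TestHorizonClassify:
    def test_no_censoring_simple_dichotomy(self):
        out = _uncensored_outcomes(np.array([True, True, False, False]))
        assert out.is_case.tolist() == [True, True, False, False]
        assert np.allclose(out.weight, 1.0)

    def test_censored_before_horizon_is_ambiguous(self):
        out = horizon_classify([0.5, 2.0], [0, 0], horizon=1.0)
        assert out.status[0] == "ambiguous"
        assert out.weight[0] == 0.0

    def test_death_counts_as_censoring(self):
        out = horizon_classify([0.5, 2.0], [2, 1], horizon=1.0)
        assert out.status[0] == "ambiguous"

    def test_hand_computed_km_weights(self):
        """6 subjects, censoring KM computed by hand.

        times  (0.4,C) (0.6,E) (0.8,C) (1.2,-) (1.5,-) (2.0,-), horizon 1.
        Censoring KM: drop 1/6 at 0.4 -> 5/6; at 0.8 (4 at risk after the
        0.6 event) -> 5/6 * 3/4 = 5/8. Case at 0.6: G(0.6-) = 5/6 -> w = 6/5.
        Controls: G(1) = 5/8 -> w = 8/5.
        """
        times = np.array([0.4, 0.6, 0.8, 1.2, 1.5, 2.0])
        events = np.array([0, 1, 0, 0, 0, 0])
        out = horizon_classify(times, events, 1.0)
        assert out.weight[1] == pytest.approx(6 / 5)
        controls = out.weight[out.is_control]
        assert np.allclose(controls, 8 / 5)
        assert out.weight[0] == 0.0 and out.weight[2] == 0.0

    def test_exhausted_censoring_support_raises(self):
        # externally supplied G that hits 0 before a case needs a weight
        dead = CensoringDistribution(times=np.array([1.0]), survival=np.array([0.0]))
        with pytest.raises(ValueError, match="horizon|follow-up"):
            horizon_classify([2.0, 3.0], [1, 0], horizon=2.5, censor_km=dead)


class TestAucT:
    def test_enumerated_pairs(self):
        # cases {0.9, 0.8}, controls {0.8, 0.1}: pairs 1 + 1 + 0.5 + 1 over 4
        risks = np.array([0.9, 0.8, 0.8, 0.1])
        out = _uncensored_outcomes(np.array([True, True, False, False]))
        assert auc_t(risks, out) == pytest.approx(0.875)

    def test_identical_risks_give_half(self):
        out = _uncensored_outcomes(np.array([True, False] * 10))
        assert auc_t(np.full(20, 0.3), out) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        is_case = np.array([True] * 5 + [False] * 5)
        risks = np.concatenate([np.linspace(0.6, 0.9, 5), np.linspace(0.1, 0.4, 5)])
        assert auc_t(risks, _uncensored_outcomes(is_case)) == pytest.approx(1.0)

    def test_needs_both_classes(self):
        out = _uncensored_outcomes(np.array([True, True]))
        with pytest.raises(ValueError):
            auc_t(np.array([0.1, 0.2]), out)

    def test_matches_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            risks, times, events = uncensored_instance(rng, 80)
            out = horizon_classify(times, events, 1.0)
            u = stats.mannwhitneyu(risks[out.is_case], risks[out.is_control]).statistic
            expected = u / (out.is_case.sum() * out.is_control.sum())
            assert auc_t(risks, out) == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_survival_under_censoring(self):
        from sksurv.metrics import cumulative_dynamic_auc

        rng = np.random.default_rng(8)
        n = 400
        lp = rng.normal(size=n)
        t_event = rng.exponential(scale=np.exp(-lp))
        t_cens = rng.uniform(0.2, 4.0, size=n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        risks = 1 - np.exp(-np.exp(lp))
        horizon = 0.8
        out = horizon_classify(times, events, horizon)
        y = np.array([(bool(e), t) for e, t in zip(events, times)],
                     dtype=[("event", "?"), ("time", "<f8")])
        ref_auc, _ = cumulative_dynamic_auc(y, y, risks, [horizon])
        assert auc_t(risks, out) == pytest.approx(ref_auc[0], abs=1e-9)


class TestPredictionError:
    def test_perfect_predictions_zero(self):
        is_case = np.array([True, True, False, False])
        out = _uncensored_outcomes(is_case)
        assert prediction_error(is_case.astype(float), out) == 0.0

    def test_constant_half_gives_quarter(self):
        out = _uncensored_outcomes(np.array([True, False] * 8))
        assert prediction_error(np.full(16, 0.5), out) == pytest.approx(0.25)

    def test_four_subject_hand_sum(self):
        # ((1-0.8)^2 + (0-0.6)^2 + (1-0.3)^2 + (0-0.1)^2) / 4 = 0.225
        risks = np.array([0.8, 0.6, 0.3, 0.1])
        out = _uncensored_outcomes(np.array([True, False, True, False]))
        assert prediction_error(risks, out) == pytest.approx(0.225)

    def test_matches_plain_brier_without_censoring(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            risks, times, events = uncensored_instance(rng, 60)
            out = horizon_classify(times, events, 1.0)
            brier = np.mean((out.is_case.astype(float) - risks) ** 2)
            assert prediction_error(risks, out) == pytest.approx(brier, abs=1e-12)

    def test_matches_scikit_survival_brier_under_censoring(self):
        from sksurv.metrics import brier_score

        rng = np.random.default_rng(9)
        n = 300
        t_event = rng.exponential(scale=1.5, size=n)
        t_cens = rng.uniform(0.2, 4.0, size=n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        risks = rng.uniform(size=n)
        horizon = 0.7
        out = horizon_classify(times, events, horizon)
        y = np.array([(bool(e), t) for e, t in zip(events, times)],
                     dtype=[("event", "?"), ("time", "<f8")])
        _, ref = brier_score(y, y, 1 - risks[None, :].T, [horizon])
        assert prediction_error(risks, out) == pytest.approx(ref[0], abs=1e-9)


class TestPcfPnf:
    def test_rank_instance(self):
        # ranks 1..10 as risks; cases at ranks 10, 9, 5; top 20% holds 2 of 3
        risks = np.arange(1, 11, dtype=float)
        is_case = np.isin(np.arange(1, 11), [10, 9, 5])
        out = _uncensored_outcomes(is_case)
        assert pcf(risks, out, 0.2) == pytest.approx(2 / 3)
        assert pnf(risks, out, 2 / 3) == pytest.approx(0.2, abs=1e-3)

    def test_all_cases_on_top(self):
        risks = np.arange(1, 11, dtype=float)
        is_case = np.isin(np.arange(1, 11), [10, 9])
        assert pcf(risks, _uncensored_outcomes(is_case), 0.2) == pytest.approx(1.0)

    def test_random_ranking_captures_q(self):
        rng = np.random.default_rng(5)
        risks, times, events = uncensored_instance(rng, 20_000, case_frac=0.3)
        out = horizon_classify(times, events, 1.0)
        n_cases = out.is_case.sum()
        for q in (0.1, 0.2, 0.5):
            se = np.sqrt(q * (1 - q) / n_cases)
            assert pcf(risks, out, q) == pytest.approx(q, abs=3 * se)

    def test_pcf_monotone_and_reaches_one(self):
        rng = np.random.default_rng(6)
        risks, times, events = uncensored_instance(rng, 500)
        out = horizon_classify(times, events, 1.0)
        qs = np.linspace(0.01, 1.0, 100)
        curve = pcf_curve(risks, out, qs)
        assert (np.diff(curve) >= -1e-12).all()
        assert curve[-1] == pytest.approx(1.0)

    def test_pnf_inverts_pcf_within_grid_step(self):
        rng = np.random.default_rng(7)
        risks, times, events = uncensored_instance(rng, 400)
        out = horizon_classify(times, events, 1.0)
        for q in (0.05, 0.1, 0.2, 0.4, 0.7):
            p = pcf(risks, out, q)
            if p >= 1.0:
                continue
            assert pnf(risks, out, p) <= q + 0.001 + 1e-12

    def test_perfect_ranking_pnf_is_p_times_case_fraction(self):
        n, n_cases = 1000, 200
        is_case = np.arange(n) < n_cases
        risks = np.where(is_case, 1.0 - np.arange(n) / n, 0.5 - np.arange(n) / (2 * n))
        out = _uncensored_outcomes(is_case)
        pi = n_cases / n
        for p in (0.5, 0.8, 0.9):
            assert pnf(risks, out, p) == pytest.approx(p * pi, abs=0.002)

    def test_model_based_estimator_uses_expected_events(self):
        risks = np.array([0.9, 0.5, 0.1, 0.1, 0.1])
        out = _uncensored_outcomes(np.array([True, False, False, False, False]))
        # top 20% = highest-risk subject: captures 0.9 of 1.7 expected events
        assert pcf(risks, out, 0.2, estimator="model") == pytest.approx(0.9 / 1.7)

    @pytest.mark.parametrize("bad_q", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_q_rejected(self, bad_q):
        out = _uncensored_outcomes(np.array([True, False]))
        with pytest.raises(ValueError):
            pcf(np.array([0.2, 0.1]), out, bad_q)


class TestBootstrapSe:
    def test_constant_metric_zero_se(self):
        rng = np.random.default_rng(10)
        risks, times, events = uncensored_instance(rng, 100)
        se = bootstrap_se(auc_t, np.full(100, 0.5), times, events, 1.0, B=50, seed=0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(11)
        risks, times, events = uncensored_instance(rng, 150)
        a = bootstrap_se(auc_t, risks, times, events, 1.0, B=60, seed=5)
        b = bootstrap_se(auc_t, risks, times, events, 1.0, B=60, seed=5)
        assert a == b

    def test_tracks_monte_carlo_truth(self):
        """Bootstrap SE of the AUC on one n=200 draw should land within 20%
        of the sampling SD across many fresh draws from the same law."""
        def draw(rng):
            lp = rng.normal(size=200)
            t_event = rng.exponential(scale=np.exp(-lp))
            t_cens = rng.uniform(0.5, 4.0, size=200)
            times, events = np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)
            return 1 - np.exp(-np.exp(lp)), times, events

        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(500):
            risks, times, events = draw(rng)
            aucs.append(auc_t(risks, horizon_classify(times, events, 1.0)))
        mc_sd = np.std(aucs, ddof=1)
        risks, times, events = draw(np.random.default_rng(99))
        se = bootstrap_se(auc_t, risks, times, events, 1.0, B=300, seed=1)
        assert se == pytest.approx(mc_sd, rel=0.20)

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se(auc_t, np.array([0.1]), np.array([1.0]), np.array([1]), 0.5, B=10)


class TestRiskDistributionSummary:
    def test_rank_thresholds(self):
        risks = np.concatenate([np.arange(0.1, 1.05, 0.1), [0.05] * 5])
        is_case = np.array([True] * 10 + [False] * 5)
        summ = risk_distribution_summary(risks, _uncensored_outcomes(is_case))
        assert summ.q80 == pytest.approx(0.2)
        assert summ.q90 == pytest.approx(0.1)
        assert summ.q90 <= summ.q80

    def test_degenerate_progressor_risks(self):
        risks = np.array([0.4] * 4 + [0.2, 0.3])
        is_case = np.array([True] * 4 + [False] * 2)
        summ = risk_distribution_summary(risks, _uncensored_outcomes(is_case))
        assert summ.q80 == summ.q90 == pytest.approx(0.4)

    def test_separated_groups_have_ordered_densities(self):
        rng = np.random.default_rng(14)
        case_risk = rng.uniform(0.6, 0.95, size=60)
        ctrl_risk = rng.uniform(0.05, 0.4, size=140)
        risks = np.concatenate([case_risk, ctrl_risk])
        is_case = np.array([True] * 60 + [False] * 140)
        summ = risk_distribution_summary(risks, _uncensored_outcomes(is_case))
        mean_prog = np.average(summ.grid, weights=summ.density_progressors)
        mean_non = np.average(summ.grid, weights=summ.density_nonprogressors)
        assert mean_prog > mean_non

    def test_no_progressors_rejected(self):
        out = _uncensored_outcomes(np.array([False, False]))
        with pytest.raises(ValueError):
            risk_distribution_summary(np.array([0.1, 0.2]), out)


class TestCensoringDistribution:
    def test_km_matches_hand_computation(self):
        cd = CensoringDistribution.fit([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        # censoring events at 1 (4 at risk) and 3 (2 at risk): 3/4, then 3/8
        assert cd.g(1.0) == pytest.approx(0.75)
        assert cd.g(3.5) == pytest.approx(0.375)
        assert cd.g_minus(1.0) == pytest.approx(1.0)
        assert cd.g_minus(3.0) == pytest.approx(0.75)
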