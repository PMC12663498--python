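"""Survival estimators against hand-computed values, closed forms and oracles."""

from fractions import Fraction

import numpy as np
import pytest

from cardioscore.cohort_model import RiskCategory
from cardioscore.survival_stats import (
    ConfusionMatrix,
    aalen_johansen_cif,
    classification_metrics,
    cox_ph_fit,
    dichotomize_and_tabulate,
    harrell_c,
    kaplan_meier,
    nelson_aalen,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 0])
        assert km.times.tolist() == [1, 2]
        assert km.survival.tolist() == pytest.approx(
            [float(Fraction(2, 3)), float(Fraction(2, 3) * Fraction(1, 2))])

    def test_all_censored_survival_is_one(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert km.at(5.0) == 1.0

    def test_greenwood_variance_exact_on_small_fixture(self):
        # times (1,2,3), events (1,1,0):
        # var(S(2)) = S(2)^2 * (1/(3*2) + 1/(2*1)) = (1/3)^2 * 2/3 = 2/27
        km = kaplan_meier([1, 2, 3], [1, 1, 0])
        assert km.variance[-1] == pytest.approx(float(Fraction(2, 27)))

    def test_ties_handled_like_grouped_events(self):
        km = kaplan_meier([1, 1, 2], [1, 1, 1])
        assert km.survival.tolist() == pytest.approx(
            [float(Fraction(1, 3)), 0.0])

    def test_step_lookup_before_first_event(self):
        km = kaplan_meier([2.0], [1])
        assert km.at(1.0) == 1.0 and km.at_minus(2.0) == 1.0 and km.at(2.0) == 0.0

    def test_converges_to_exponential_truth(self, rng):
        lam, n = 0.4, 4000
        t = rng.exponential(1 / lam, n)
        c = rng.uniform(0, 10, n)
        obs = np.minimum(t, c)
        km = kaplan_meier(obs, (t <= c).astype(int))
        grid = np.linspace(0.1, 4, 40)
        sup = max(abs(km.at(g) - np.exp(-lam * g)) for g in grid)
        assert sup < 0.03

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(2.0, 300)
        e = rng.integers(0, 2, 300)
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt in km.times[::17]:
            assert km.at(tt) == pytest.approx(
                kmf.survival_function_at_times(tt).iloc[0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestNelsonAalen:
    def test_hand_cumulative_hazard(self):
        na = nelson_aalen([1, 2], [1, 1])
        assert na.cumhaz.tolist() == pytest.approx([0.5, 1.5])

    def test_no_events_zero_hazard(self):
        na = nelson_aalen([1, 2], [0, 0])
        assert na.at(10.0) == 0.0

    def test_exp_minus_H_dominates_km(self, rng):
        """Classical inequality: exp(-H_NA) >= S_KM pointwise."""
        t = rng.exponential(1.0, 200)
        e = rng.integers(0, 2, 200)
        km = kaplan_meier(t, e)
        na = nelson_aalen(t, e)
        for tt in km.times:
            assert np.exp(-na.at(tt)) >= km.at(tt) - 1e-12


class TestAalenJohansen:
    def test_hand_cif(self):
        aj = aalen_johansen_cif([1, 2, 3], [1, 2, 0])
        assert aj.cif_at(1, 1.0) == pytest.approx(float(Fraction(1, 3)))
        assert aj.cif_at(2, 2.0) == pytest.approx(float(Fraction(1, 3)))

    def test_reduces_to_km_complement_without_competing_cause(self, rng):
        t = rng.exponential(1.0, 150)
        s = rng.integers(0, 2, 150)
        aj = aalen_johansen_cif(t, s)
        km = kaplan_meier(t, s)
        for tt in aj.times:
            assert aj.cif_at(1, tt) == pytest.approx(1 - km.at(tt))

    def test_partition_invariant(self, rng):
        t = rng.exponential(1.0, 200)
        s = rng.choice([0, 1, 2], 200)
        aj = aalen_johansen_cif(t, s)
        np.testing.assert_allclose(aj.cif1 + aj.cif2 + aj.overall_survival,
                                   1.0, atol=1e-12)
        assert (np.diff(aj.cif1) >= -1e-12).all()
        assert (np.diff(aj.cif2) >= -1e-12).all()

    def test_naive_km_complement_dominates_cif(self, rng):
        """1 - KM (competing deaths censored) >= CIF_1 pointwise."""
        t = rng.exponential(1.0, 300)
        s = rng.choice([0, 1, 2], 300, p=[0.3, 0.4, 0.3])
        aj = aalen_johansen_cif(t, s)
        km = kaplan_meier(t, (s == 1).astype(int))
        for tt in aj.times:
            assert 1 - km.at(tt) >= aj.cif_at(1, tt) - 1e-12

    def test_unknown_status_code_rejected(self):
        with pytest.raises(ValueError):
            aalen_johansen_cif([1, 2], [1, 3])


def brute_force_c(scores, times, events):
    """Independent O(n^2) oracle: plain pair enumeration."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if times[i] < times[j]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_ranking(self):
        r = harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1])
        assert r.c == 1.0

    def test_fully_tied_scores(self):
        r = harrell_c([1, 1], [1, 2], [1, 1])
        assert r.c == 0.5 and r.tied_score == 1

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [1, 2], [0, 0])

    def test_equals_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 60))
            scores = rng.integers(0, 4, n).astype(float)
            times = rng.exponential(1.0, n)
            events = rng.integers(0, 2, n)
            if events[times.argsort()][:-1].sum() == 0:
                continue
            r = harrell_c(scores, times, events)
            assert r.c == pytest.approx(
                brute_force_c(scores, times, events), abs=1e-12)

    def test_matches_lifelines_on_large_sample(self, rng):
        from lifelines.utils import concordance_index

        n = 500
        scores = rng.normal(0, 1, n)
        times = rng.exponential(1.0, n)
        events = rng.integers(0, 2, n)
        r = harrell_c(scores, times, events)
        assert r.c == pytest.approx(
            concordance_index(times, -scores, events), abs=1e-12)


class TestCoxPH:
    def test_single_binary_covariate_matches_grid_search_oracle(self):
        """Hand-maximised Breslow partial likelihood on a grid.

        Failure times interleave across groups so the maximiser is finite
        (fully separated groups have a monotone partial likelihood)."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def neg_pl(beta):
            risk = np.exp(beta * x)
            ll = 0.0
            order = np.argsort(times)
            for idx in order:
                if events[idx]:
                    in_risk = times >= times[idx]
                    ll += beta * x[idx] - np.log(risk[in_risk].sum())
            return -ll

        grid = np.linspace(-4, 4, 8001)
        beta_grid = grid[np.argmin([neg_pl(b) for b in grid])]
        fit = cox_ph_fit(x[:, None], times, events)
        assert fit.coef[0] == pytest.approx(beta_grid, abs=1e-3)

    def test_null_covariate_hr_near_one(self, rng):
        n = 2000
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0, n)  # independent of x
        e = (t < rng.uniform(0, 3, n)).astype(int)
        fit = cox_ph_fit(x[:, None], np.minimum(t, 3.0), e)
        lo, hi = fit.ci
        assert lo[0] < 1.0 < hi[0]
        assert abs(fit.coef[0]) < 0.1

    def test_matches_lifelines_on_continuous_times(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 200
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = rng.exponential(3.0 * np.exp(-0.4 * x1), n)  # no ties
        e = rng.integers(0, 2, n)
        fit = cox_ph_fit(np.column_stack([x1, x2]), t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2}), "t", "e")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_matches_statsmodels_breslow_with_ties(self, rng):
        import statsmodels.api as sm

        n = 200
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = np.ceil(rng.exponential(3.0 * np.exp(-0.4 * x1), n))  # tied times
        e = rng.integers(0, 2, n)
        fit = cox_ph_fit(np.column_stack([x1, x2]), t, e)
        ref = sm.PHReg(t, np.column_stack([x1, x2]), status=e,
                       ties="breslow").fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)

    def test_duplicate_column_rejected(self, rng):
        x = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="rank"):
            cox_ph_fit(np.column_stack([x, x]), rng.exponential(1, 50),
                       np.ones(50, dtype=int))

    def test_constant_column_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cox_ph_fit(np.ones((50, 1)), rng.exponential(1, 50),
                       np.ones(50, dtype=int))

    def test_separation_flagged(self):
        # perfectly separated: all events in x=1 happen first
        times = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        events = np.ones(8, dtype=int)
        fit = cox_ph_fit(x[:, None], times, events)
        assert fit.separation


class TestClassification:
    def test_worked_example_metrics(self):
        m = classification_metrics(ConfusionMatrix(tp=253, fp=600, fn=207, tn=1230))
        assert m.rounded() == {"sensitivity": 55, "specificity": 67,
                               "ppv": 30, "npv": 86, "accuracy": 65}

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionMatrix(1, 0, 0, 1))
        assert all(v == 100 for v in m.rounded().values())

    def test_zero_denominator_marked_undefined(self):
        m = classification_metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=5))
        assert m.sensitivity is None and m.specificity is not None

    def test_scale_invariance(self):
        a = classification_metrics(ConfusionMatrix(10, 20, 5, 65))
        b = classification_metrics(ConfusionMatrix(30, 60, 15, 195))
        assert a == b

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestDichotomize:
    def test_enumerated_four_subjects(self):
        cats = [RiskCategory.LOW, RiskCategory.MODERATE, RiskCategory.HIGH,
                RiskCategory.VERY_HIGH]
        status = [0, 1, 1, 0]
        cm = dichotomize_and_tabulate(cats, status)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_all_low_no_events(self):
        cm = dichotomize_and_tabulate([RiskCategory.LOW] * 5, [0] * 5)
        assert cm.tn == 5 and cm.n == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_and_tabulate([RiskCategory.LOW], [0, 1])

    def test_cell_counts_near_binomial_expectation(self, rng):
        """Configured per-category event probabilities reproduce expected cells."""
        n = 4000
        cats = rng.choice([0, 1, 2, 3], n, p=[0.28, 0.35, 0.34, 0.03])
        p_event = np.array([0.1, 0.2, 0.3, 0.4])[cats]
        status = (rng.random(n) < p_event).astype(int)
        cm = dichotomize_and_tabulate([RiskCategory(c) for c in cats], status)
        exp_tp = n * (0.34 * 0.3 + 0.03 * 0.4)
        se = np.sqrt(exp_tp)
        assert abs(cm.tp - exp_tp) < 4 * se
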