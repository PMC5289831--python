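"""Firth engine: closed forms, calibration against published minima, and a
generic-optimizer oracle for the penalized likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from rarephen.firth import (SingularDesignError, batch_screen, fit_firth,
                            lr_g, lr_i, lr_ko, lr_ko_from_counts,
                            penalized_lrt)
from rarephen.tables import SexStratifiedCounts, TwoByTwo

# LR_KO minimum attainable p for 7+7 knockouts, k abnormalities in one sex
PUBLISHED_MINIMA = {1: 0.44059, 2: 0.18407, 3: 0.06970, 4: 0.02299,
                    5: 0.00620, 6: 0.00121, 7: 0.00013}


def expand(cells):
    """(x, events, trials) cells -> weighted 0/1 design."""
    X, y, w = [], [], []
    for x, k, n in cells:
        X += [list(x), list(x)]
        y += [1.0, 0.0]
        w += [k, n - k]
    return np.array(X), np.array(y), np.array(w, float)


class TestFitFirth:
    def test_saturated_2x2_slope_equals_add_half_closed_form(self):
        # group1: 3/7 events, group0: 1/7; Firth on a saturated one-covariate
        # design equals adding 1/2 to every cell of the 2x2
        X, y, w = expand([((1, 0), 1, 7), ((1, 1), 3, 7)])
        fit = fit_firth(X, y, weights=w)
        expected = math.log(3.5 * 6.5 / (4.5 * 1.5))
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(expected, abs=1e-6)

    def test_intercept_only_all_zero_outcomes(self):
        # stationarity of the penalized score gives pi = (k + 1/2)/(n + 1)
        X = np.ones((7, 1))
        y = np.zeros(7)
        fit = fit_firth(X, y)
        pi = 1 / (1 + math.exp(-fit.coefficients[0]))
        assert pi == pytest.approx(0.5 / 8, abs=1e-8)

    def test_duplicated_free_column_raises(self):
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1]])
        y = np.array([0, 0, 1, 0, 1, 1.0])
        with pytest.raises(SingularDesignError):
            fit_firth(X, y)

    def test_weighted_fit_matches_expanded_rows(self):
        X, y, w = expand([((1, 0), 2, 9), ((1, 1), 5, 6)])
        fw = fit_firth(X, y, weights=w)
        Xe = np.repeat(X, w.astype(int), axis=0)
        ye = np.repeat(y, w.astype(int))
        fe = fit_firth(Xe, ye)
        assert np.allclose(fw.coefficients, fe.coefficients, atol=1e-7)
        assert fw.penalized_loglik == pytest.approx(fe.penalized_loglik, abs=1e-7)

    def test_complete_separation_yields_finite_coefficients(self):
        X, y, w = expand([((1, 0), 0, 7), ((1, 1), 7, 7)])
        fit = fit_firth(X, y, weights=w)
        assert fit.converged
        assert np.all(np.isfinite(fit.coefficients))
        evals = np.linalg.eigvalsh(fit.fisher_information)
        assert np.all(evals > -1e-10)


def pll_oracle(X, y, w, beta):
    """Penalized log-likelihood evaluated directly (no fitting code shared)."""
    eta = X @ beta
    pi = 1 / (1 + np.exp(-eta))
    ll = np.sum(w * (y * np.log(pi) + (1 - y) * np.log(1 - pi)))
    W = w * pi * (1 - pi)
    sign, logdet = np.linalg.slogdet(X.T @ (X * W[:, None]))
    return ll + 0.5 * logdet


class TestPenalizedLrt:
    @pytest.mark.parametrize("k,expected", sorted(PUBLISHED_MINIMA.items()))
    def test_knockout_sex_test_matches_published_minima(self, k, expected):
        # values are published rounded to 5 decimals; require 1% relative
        # agreement or agreement to the printed precision (half an ulp)
        p = lr_ko_from_counts(7, 7, k, 0).p_value
        assert abs(p - expected) <= 5e-6 or abs(p - expected) / expected <= 0.01

    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    def test_sex_relabel_invariance(self, k):
        assert lr_ko_from_counts(7, 7, k, 0).p_value == pytest.approx(
            lr_ko_from_counts(7, 7, 0, k).p_value, rel=1e-9)

    def test_lr_ko_monotone_in_abnormal_count(self):
        ps = [lr_ko_from_counts(7, 7, k, 0).p_value for k in range(1, 8)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_generic_optimizer_oracle(self, small_dataset):
        # direct Nelder-Mead maximization of the same penalized objective
        d = small_dataset
        X, y, w = expand([
            ((1, 0, 0, 0), d.female.events_b, d.female.total_b),
            ((1, 1, 0, 0), d.male.events_b, d.male.total_b),
            ((1, 0, 1, 0), d.female.events_a, d.female.total_a),
            ((1, 1, 1, 1), d.male.events_a, d.male.total_a),
        ])

        def fit_free(free_idx):
            def neg(theta):
                beta = np.zeros(4)
                beta[list(free_idx)] = theta
                return -pll_oracle(X, y, w, beta)
            best = min(
                (minimize(neg, np.zeros(len(free_idx)), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 20000})
                 for _ in range(1)),
                key=lambda r: r.fun)
            return -best.fun

        full = fit_free((0, 1, 2, 3))
        for test_fn, fixed in [(lr_g, (2, 3)), (lr_i, (3,))]:
            free = tuple(j for j in range(4) if j not in fixed)
            stat = max(0.0, 2 * (full - fit_free(free)))
            expected = chi2.sf(stat, len(fixed))
            assert test_fn(d).p_value == pytest.approx(expected, rel=1e-5)

    def test_no_events_far_from_significance(self):
        # with zero events everywhere there is no genotype information; under
        # the shared-penalty convention the statistic is small but not
        # exactly zero (the penalty shifts when columns are constrained)
        d = SexStratifiedCounts(male=TwoByTwo(0, 7, 0, 20),
                                female=TwoByTwo(0, 7, 0, 20))
        assert lr_g(d).p_value > 0.5
        assert lr_i(d).p_value == pytest.approx(1.0)

    def test_identical_strata_no_interaction(self, small_dataset):
        r = lr_i(small_dataset)
        assert r.statistic == pytest.approx(0.0, abs=1e-8)
        assert r.p_value == pytest.approx(1.0)

    def test_complete_separation_finite_statistic(self):
        d = SexStratifiedCounts(male=TwoByTwo(7, 7, 0, 20),
                                female=TwoByTwo(7, 7, 0, 20))
        r = lr_g(d)
        assert np.isfinite(r.statistic)
        assert 0 < r.p_value < 1

    def test_separate_null_mode_differs_but_close(self):
        p_full = lr_ko_from_counts(7, 7, 4, 0, mode="full-penalty").p_value
        p_sep = lr_ko_from_counts(7, 7, 4, 0, mode="separate-null").p_value
        assert p_full != p_sep
        assert p_sep == pytest.approx(p_full, rel=0.5)

    def test_lr_ko_requires_both_sexes(self):
        d = SexStratifiedCounts(male=TwoByTwo(0, 0, 0, 20),
                                female=TwoByTwo(2, 7, 0, 20))
        with pytest.raises(Exception):
            lr_ko(d)


class TestBatchScreen:
    @staticmethod
    def make_records(rate_by_batch, n_per_batch=100, seed=5):
        rng = np.random.default_rng(seed)
        rows = []
        for batch, rate in rate_by_batch.items():
            for i in range(n_per_batch):
                sex = "M" if i % 2 else "F"
                rows.append({"trait_id": "t1", "sex": sex, "batch": batch,
                             "outcome": int(rng.random() < rate)})
        return pd.DataFrame(rows)

    def test_strong_batch_effect_detected(self):
        rec = self.make_records({"b1": 0.01, "b2": 0.5})
        out = batch_screen(rec)
        assert out.loc[0, "q_value"] <= 0.05
        assert bool(out.loc[0, "batch_effect"])

    def test_zero_event_trait_flagged(self):
        rec = self.make_records({"b1": 0.0, "b2": 0.0})
        out = batch_screen(rec)
        assert out.loc[0, "p_value"] == 1.0
        assert bool(out.loc[0, "uninformative"])

    def test_single_batch_rejected(self):
        rec = self.make_records({"b1": 0.1})
        with pytest.raises(Exception):
            batch_screen(rec)
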