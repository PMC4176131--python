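"""Exact tests, odds ratios, Welch t, logistic IRLS, stepwise selection."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import uveprof as uv
from uveprof.stats import bivariate_table, build_design


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def fisher_2x2_oracle(table) -> float:
    """Exact-rational hypergeometric enumeration (independent of the package)."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c

    def pmf(x: int) -> Fraction:
        return (Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x),
                         math.comb(n, c1)))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


def fisher_rxc_oracle(table) -> float:
    """Full enumeration with exact rationals for small r x c tables."""
    t = np.asarray(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())

    def prob(tab) -> Fraction:
        num = Fraction(1)
        for r in rows:
            num *= math.factorial(int(r))
        for c in cols:
            num *= math.factorial(int(c))
        den = Fraction(math.factorial(n))
        for v in np.ravel(tab):
            den *= math.factorial(int(v))
        return num / den

    p_obs = prob(t)
    total = Fraction(0)
    ranges = [range(int(min(rows[i], cols[j])) + 1)
              for i in range(len(rows) - 1) for j in range(len(cols) - 1)]

    r_, c_ = len(rows), len(cols)
    for combo in itertools.product(*ranges):
        tab = np.zeros((r_, c_), dtype=int)
        tab[:-1, :-1] = np.reshape(combo, (r_ - 1, c_ - 1))
        tab[:-1, -1] = rows[:-1] - tab[:-1, :-1].sum(axis=1)
        tab[-1, :] = cols - tab[:-1, :].sum(axis=0)
        if (tab < 0).any():
            continue
        if prob(tab) <= p_obs:
            total += prob(tab)
    return float(total)


def logistic_grid_oracle(X, y, lo=-4.0, hi=4.0):
    """Brute-force likelihood maximisation by iterative grid refinement."""
    k = X.shape[1]

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    center = np.zeros(k)
    width = hi - lo
    for _ in range(24):
        axes = [np.linspace(c - width / 2, c + width / 2, 7) for c in center]
        best = min(itertools.product(*axes), key=lambda b: nll(np.array(b)))
        center = np.array(best)
        width /= 3.0
    return center


# --------------------------------------------------------------------------
# Fisher tests
# --------------------------------------------------------------------------

class TestFisher2x2:
    def test_balanced_table(self):
        assert uv.fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_small_table_vs_hand_enumeration(self):
        t = [[2, 1], [1, 2]]
        assert uv.fisher_exact_2x2(t) == pytest.approx(fisher_2x2_oracle(t), rel=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum() == 0:
                continue
            assert uv.fisher_exact_2x2(t) == pytest.approx(
                sps.fisher_exact(t).pvalue, rel=1e-9, abs=1e-12)

    def test_transpose_and_swap_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 20, size=(2, 2))
            if t.sum() == 0:
                continue
            p = uv.fisher_exact_2x2(t)
            assert uv.fisher_exact_2x2(t.T) == pytest.approx(p, rel=1e-12)
            assert uv.fisher_exact_2x2(t[::-1]) == pytest.approx(p, rel=1e-12)
            assert uv.fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(uv.StatsError):
            uv.fisher_exact_2x2([[1, -1], [2, 3]])

    def test_exact_test_is_conservative_under_null(self):
        """Type-I error of the exact test stays below nominal 5% (<= 6%
        rejections over 2,000 null tables at the study's group sizes)."""
        rng = np.random.default_rng(7)
        rejections = 0
        exposed_cases = rng.binomial(42, 0.3, size=2000)
        exposed_ctrls = rng.binomial(255, 0.3, size=2000)
        for a, c in zip(exposed_cases, exposed_ctrls):
            p = uv.fisher_exact_2x2([[a, 42 - a], [c, 255 - c]])
            rejections += (p < 0.05)
        assert rejections / 2000 <= 0.06


class TestFisherRxc:
    def test_single_row_degenerate(self):
        assert uv.fisher_exact_rxc([[3, 4, 5]]) == 1.0

    def test_toy_3x2_vs_exact_oracle(self):
        t = [[3, 1], [2, 4], [0, 3]]
        assert uv.fisher_exact_rxc(t) == pytest.approx(fisher_rxc_oracle(t), rel=1e-9)

    def test_agrees_with_2x2_implementation(self):
        """Two independent implementations, one answer on 2x2 input."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            assert uv.fisher_exact_rxc(t) == pytest.approx(
                uv.fisher_exact_2x2(t), rel=1e-9, abs=1e-12)

    def test_transpose_invariance(self):
        t = [[5, 2, 1], [1, 4, 3]]
        assert uv.fisher_exact_rxc(np.array(t).T) == pytest.approx(
            uv.fisher_exact_rxc(t), rel=1e-9)

    def test_monte_carlo_close_to_enumeration(self):
        t = [[8, 3], [2, 9], [5, 5]]
        exact = uv.fisher_exact_rxc(t)
        mc = uv.fisher_exact_rxc(t, max_tables=1, n_mc=20_000, seed=3)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_large_table_without_seed_raises(self):
        t = [[8, 3], [2, 9], [5, 5]]
        with pytest.raises(uv.StatsError, match="Monte Carlo"):
            uv.fisher_exact_rxc(t, max_tables=1)


# --------------------------------------------------------------------------
# Odds ratios & Welch
# --------------------------------------------------------------------------

class TestOddsRatio:
    def test_unit_table(self):
        r = uv.odds_ratio_wald([[1, 1], [1, 1]])
        assert r.odds_ratio == 1.0
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_reconstructed_study_table(self):
        # 25/42 exposed cases vs 85/255 exposed controls
        r = uv.odds_ratio_wald([[25, 17], [85, 170]])
        assert round(r.odds_ratio, 2) == 2.94

    def test_zero_cell_haldane_correction(self):
        r = uv.odds_ratio_wald([[0, 5], [5, 5]])
        assert np.isfinite(r.odds_ratio) and r.odds_ratio > 0
        assert np.isfinite(r.ci_low) and np.isfinite(r.ci_high)

    def test_all_zero_rejected(self):
        with pytest.raises(uv.StatsError):
            uv.odds_ratio_wald([[0, 0], [0, 0]])


class TestWelch:
    def test_identical_samples(self):
        assert uv.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_against_closed_form(self):
        x = np.array([4.1, 5.2, 6.3, 5.5, 4.9])
        y = np.array([7.0, 8.1, 6.9, 7.7])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
        expected = 2 * sps.t.sf(abs(t), df)
        assert uv.welch_t_test(x, y) == pytest.approx(expected, abs=1e-10)

    def test_fixture_age_difference(self, study):
        f = study["factors"]
        p = uv.welch_t_test(f.loc[f["case"] == 1, "age"], f.loc[f["case"] == 0, "age"])
        cases_mean = f.loc[f["case"] == 1, "age"].mean()
        ctrl_mean = f.loc[f["case"] == 0, "age"].mean()
        assert cases_mean < ctrl_mean
        assert p < 0.001

    def test_degenerate_variances_rejected(self):
        with pytest.raises(uv.StatsError):
            uv.welch_t_test([2.0, 2.0, 2.0], [3.0, 3.0])


# --------------------------------------------------------------------------
# Logistic regression
# --------------------------------------------------------------------------

class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = uv.fit_logistic(np.ones((10, 1)), y)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    def test_single_binary_covariate_equals_log_or(self):
        x = np.array([1] * 20 + [0] * 30)
        y = np.array([1] * 12 + [0] * 8 + [1] * 9 + [0] * 21)
        X = np.column_stack([np.ones(50), x])
        fit = uv.fit_logistic(X, y)
        sample_or = (12 * 21) / (8 * 9)
        assert fit.coefficients[1] == pytest.approx(math.log(sample_or), abs=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(120), rng.normal(size=120),
                             rng.integers(0, 2, 120)])
        eta = 0.3 - 0.8 * X[:, 1] + 0.5 * X[:, 2]
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = uv.fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
        assert np.allclose(fit.standard_errors, ref.bse, atol=1e-5)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(40), rng.integers(0, 2, 40).astype(float)])
        eta = -0.5 + 1.0 * X[:, 1]
        y = (rng.random(40) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = uv.fit_logistic(X, y)
        oracle = logistic_grid_oracle(X, y)
        assert np.allclose(fit.coefficients, oracle, atol=1e-4)

    def test_separation_flagged_not_raised(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        fit = uv.fit_logistic(np.column_stack([np.ones(8), x]), y)
        assert fit.converged is False

    def test_adjusted_or_is_exp_of_coefficient(self):
        y = np.array([1, 0, 1, 0, 1, 0, 0, 0])
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        fit = uv.fit_logistic(pd.DataFrame({"intercept": np.ones(8), "x": x}), y)
        or_, lo, hi = fit.adjusted_or("x")
        assert or_ == pytest.approx(math.exp(fit.coef("x")))
        assert lo <= or_ <= hi


class TestStepwise:
    def _frame(self, seed=0, n=250):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "age": rng.normal(9, 3, n),
            "gender": rng.choice(["Female", "Male"], n),
            "race": rng.choice(["White", "Asian", "Black", "Other"], n),
            "signal": rng.integers(0, 2, n),
            "noise": rng.integers(0, 2, n),
        })
        eta = -1.2 + 1.4 * df["signal"]
        df["case"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return df

    def test_zero_candidates_returns_forced_model(self):
        df = self._frame()
        fit = uv.stepwise_select([], ["age", "gender", "race"], df)
        assert set(fit.terms) == {"intercept", "age", "gender_Male",
                                  "race_Asian", "race_Black", "race_Other"}

    def test_informative_candidate_kept_noise_dropped(self):
        df = self._frame(seed=3)
        fit = uv.stepwise_select(["signal", "noise"], ["age", "gender", "race"], df)
        assert "signal" in fit.terms
        assert "noise" not in fit.terms

    def test_collinear_candidate_dropped_with_warning(self):
        df = self._frame()
        df["dup"] = (df["gender"] == "Male").astype(int)  # same as gender dummy
        with pytest.warns(UserWarning, match="collinear"):
            fit = uv.stepwise_select(["dup", "signal"], ["age", "gender", "race"], df)
        assert "dup" not in fit.terms

    def test_forced_terms_never_dropped(self):
        df = self._frame(seed=4)
        fit = uv.stepwise_select(["signal", "noise"], ["age", "gender", "race"], df)
        for forced in ("age", "gender_Male", "race_Asian"):
            assert forced in fit.terms


class TestBivariateTable:
    def test_counts_layout(self):
        df = pd.DataFrame({"case": [1, 1, 0, 0, 0], "f": [1, 0, 1, 0, 0]})
        t = bivariate_table(df, "f")
        assert t.tolist() == [[1, 1], [1, 2]]
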