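"""Association machinery: exact tests, odds ratios, logistic regression.

Implements the contracts the pipeline depends on precisely:

* two-tailed Fisher tests (2x2 and general r x c) under the probability-mass
  rule — sum the probabilities of all tables with the observed margins whose
  probability does not exceed the observed table's by more than a 1e-7
  relative tolerance (the convention of the statistical environments used in
  this field);
* Wald odds ratios with the Haldane–Anscombe +0.5 correction on zero cells;
* maximum-likelihood logistic regression by iteratively reweighted least
  squares with an explicit separation flag;
* deterministic bidirectional stepwise selection by AIC with forced-in
  adjustment covariates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

_REL_TOL = 1.0 + 1e-7


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fisher exact tests
# ---------------------------------------------------------------------------

def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise StatsError("contingency table must be 2-dimensional")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise StatsError("contingency table requires non-negative integers")
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table (probability-mass rule)."""
    t = _check_table(table)
    if t.shape != (2, 2):
        raise StatsError("fisher_exact_2x2 requires a 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    # log hypergeometric pmf over the support
    logp = (gammaln(r1 + 1) - gammaln(xs + 1) - gammaln(r1 - xs + 1)
            + gammaln(n - r1 + 1) - gammaln(c1 - xs + 1) - gammaln(n - r1 - (c1 - xs) + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))
    p = np.exp(logp)
    p_obs = p[a - lo]
    return float(min(1.0, p[p <= p_obs * _REL_TOL].sum()))


def _rxc_log_prob(table: np.ndarray, row_f: np.ndarray, col_f: np.ndarray,
                  log_n_fact: float) -> float:
    return float(row_f.sum() + col_f.sum() - log_n_fact - gammaln(table + 1.0).sum())


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def rec(i: int, remaining_cols: np.ndarray, acc: list):
        if i == r - 1:
            last = remaining_cols
            if np.all(last >= 0) and last.sum() == rows[-1]:
                yield np.array(acc + [last])
            return
        # enumerate row i cell by cell
        def cells(j: int, left: int, row_acc: list):
            if j == c - 1:
                if 0 <= left <= remaining_cols[-1]:
                    yield row_acc + [left]
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                yield from cells(j + 1, left - v, row_acc + [v])

        for row in cells(0, int(rows[i]), []):
            yield from rec(i + 1, remaining_cols - np.array(row), acc + [np.array(row)])

    yield from rec(0, cols.copy(), [])


def fisher_exact_rxc(table, max_tables: int = 2_000_000,
                     n_mc: int = 200_000, seed: int | None = None) -> float:
    """Exact (or seeded Monte Carlo) two-tailed Fisher p for an r x c table.

    Full enumeration over tables with the observed margins when the candidate
    space is tractable; otherwise a Monte Carlo estimate over random tables
    with fixed margins (requires ``seed``).
    """
    t = _check_table(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        # drop empty margins; a 1 x c or r x 1 table is degenerate
        t = t[rows > 0][:, cols > 0]
        rows, cols = t.sum(axis=1), t.sum(axis=0)
    if t.shape[0] <= 1 or t.shape[1] <= 1:
        return 1.0
    n = int(t.sum())
    row_f = gammaln(rows + 1.0)
    col_f = gammaln(cols + 1.0)
    log_n_fact = gammaln(n + 1.0)
    logp_obs = _rxc_log_prob(t.astype(float), row_f, col_f, log_n_fact)
    p_obs = math.exp(logp_obs)

    # rough bound on the enumeration size: product over free cells of margin+1
    bound = 1
    for i in range(t.shape[0] - 1):
        for j in range(t.shape[1] - 1):
            bound *= int(min(rows[i], cols[j])) + 1
            if bound > max_tables:
                break
        if bound > max_tables:
            break

    if bound <= max_tables:
        total = 0.0
        for cand in _enumerate_tables(rows, cols):
            p = math.exp(_rxc_log_prob(cand.astype(float), row_f, col_f, log_n_fact))
            if p <= p_obs * _REL_TOL:
                total += p
        return float(min(1.0, total))

    if seed is None:
        raise StatsError(
            "table too large for exact enumeration; pass a seed for Monte Carlo mode")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(t.shape[1]), cols)
    row_idx = np.repeat(np.arange(t.shape[0]), rows)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(labels)
        cand = np.zeros_like(t)
        np.add.at(cand, (row_idx, labels), 1)
        lp = _rxc_log_prob(cand.astype(float), row_f, col_f, log_n_fact)
        if math.exp(lp) <= p_obs * _REL_TOL:
            hits += 1
    return float((hits + 1) / (n_mc + 1))


# ---------------------------------------------------------------------------
# Odds ratios / group comparisons
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    factor: str
    table: np.ndarray  # 2x2: rows = exposed/unexposed, cols = case/control
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str


def odds_ratio_wald(table, factor: str = "") -> AssociationResult:
    """Sample odds ratio ad/bc with a 95% Wald interval.

    All cells get the Haldane–Anscombe +0.5 correction when any cell is zero;
    the p-value is the two-tailed Fisher exact p of the uncorrected table.
    """
    t = _check_table(table)
    if t.shape != (2, 2):
        raise StatsError("odds_ratio_wald requires a 2x2 table")
    if t.sum() == 0:
        raise StatsError("all-zero table")
    a, b, c, d = t.astype(float).ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    return AssociationResult(factor, t, float(or_), float(lo), float(hi),
                             fisher_exact_2x2(t), "fisher_2x2")


def welch_t_test(x, y) -> float:
    """Two-sided Welch t-test p-value (Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each sample needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 1.0
        raise StatsError("degenerate (zero-variance) samples with unequal means")
    return float(sps.ttest_ind(x, y, equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS) and stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    aic: float
    log_likelihood: float
    converged: bool
    n_iterations: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])

    def adjusted_or(self, term: str) -> tuple[float, float, float]:
        """(odds ratio, 95% CI low, high) for one model term."""
        b, s = self.coef(term), self.se(term)
        return math.exp(b), math.exp(b - 1.96 * s), math.exp(b + 1.96 * s)

    def wald_p(self, term: str) -> float:
        z = self.coef(term) / self.se(term)
        return float(2 * sps.norm.sf(abs(z)))


def fit_logistic(design: pd.DataFrame | np.ndarray, outcome,
                 max_iter: int = 50, tol: float = 1e-8,
                 separation_bound: float = 15.0) -> LogisticFit:
    """ML logistic fit by iteratively reweighted least squares.

    The design matrix must already contain an intercept column if one is
    wanted.  A coefficient diverging past ``separation_bound`` in absolute
    value flags (quasi-)separation: the fit is returned with
    ``converged=False`` rather than raising.
    """
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise StatsError("outcome must be binary 0/1")
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise StatsError(f"singular design matrix: {exc}") from exc
        delta = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > separation_bound:
            converged = False
            break
        if delta < tol:
            converged = True
            break
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.pinv((X.T * w) @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return LogisticFit(terms, beta, se, 2 * k - 2 * ll, ll, converged, it)


def build_design(df: pd.DataFrame, terms: list[str],
                 race_reference: str = "White",
                 gender_reference: str = "Female") -> pd.DataFrame:
    """Design matrix with intercept; race/gender dummy-coded against the
    stated reference levels; other terms passed through numerically."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for t in terms:
        if t == "race":
            levels = sorted(set(df["race"]) - {race_reference})
            for lv in levels:
                cols[f"race_{lv}"] = (df["race"] == lv).to_numpy(dtype=float)
        elif t == "gender":
            levels = sorted(set(df["gender"]) - {gender_reference})
            for lv in levels:
                cols[f"gender_{lv}"] = (df["gender"] == lv).to_numpy(dtype=float)
        else:
            cols[t] = df[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def stepwise_select(candidates: list[str], forced: list[str],
                    df: pd.DataFrame, outcome: str = "case") -> LogisticFit:
    """Bidirectional stepwise AIC selection starting from the forced model.

    Forced covariates (e.g. age, gender, race) are never dropped; at each
    round the single add-or-drop move yielding the lowest AIC is taken if it
    improves on the current model, ties broken by candidate list order.
    Candidates collinear with the current model are dropped with a warning.
    """
    y = df[outcome].to_numpy(dtype=float)

    usable = []
    for cand in candidates:
        X = build_design(df, forced + [cand]).to_numpy()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"candidate {cand!r} is collinear with the forced set; dropped")
        else:
            usable.append(cand)

    def fit(included: list[str]) -> LogisticFit:
        return fit_logistic(build_design(df, forced + included), y)

    included: list[str] = []
    current = fit(included)
    while True:
        moves: list[tuple[float, int, list[str]]] = []
        order = 0
        for cand in usable:
            if cand in included:
                trial = [t for t in included if t != cand]
            else:
                trial = included + [cand]
            X = build_design(df, forced + trial).to_numpy()
            if np.linalg.matrix_rank(X) < X.shape[1]:
                order += 1
                continue
            moves.append((fit(trial).aic, order, trial))
            order += 1
        if not moves:
            break
        best_aic, _, best_trial = min(moves, key=lambda m: (m[0], m[1]))
        if best_aic < current.aic - 1e-9:
            included = best_trial
            current = fit(included)
        else:
            break
    return current


def bivariate_table(df: pd.DataFrame, factor: str, outcome: str = "case") -> np.ndarray:
    """2x2 exposure-by-status table [[exposed cases, exposed controls],
    [unexposed cases, unexposed controls]]."""
    e = df[factor].to_numpy(dtype=int)
    y = df[outcome].to_numpy(dtype=int)
    return np.array([
        [int(((e == 1) & (y == 1)).sum()), int(((e == 1) & (y == 0)).sum())],
        [int(((e == 0) & (y == 1)).sum()), int(((e == 0) & (y == 0)).sum())],
    ])


def bivariate_associations(df: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Per-factor sample OR, Wald CI and Fisher p against case status."""
    rows = []
    for f in factors:
        t = bivariate_table(df, f)
        r = odds_ratio_wald(t, factor=f)
        rows.append({
            "factor": f,
            "a": int(t[0, 0]), "b": int(t[0, 1]),
            "c": int(t[1, 0]), "d": int(t[1, 1]),
            "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p": r.p_value,
        })
    return pd.DataFrame(rows)
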