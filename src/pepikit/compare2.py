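"""Comparison of two independent groups and of k groups or categories.

Effect measures for 2x2 tables (odds ratio, risk ratio, risk difference)
with the classical log-scale and score intervals; Pearson, likelihood-ratio
and Fisher exact tests; Mantel-Haenszel stratified pooling with
Robins-Breslow-Greenland / Greenland-Robins variances and a Woolf Q
heterogeneity test; ordered-category methods (Cochran-Armitage trend,
ridit analysis, the generalized odds ratio); full r x c contingency-table
analysis with adjusted residuals and association measures; Kruskal-Wallis;
and one-way ANOVA with the effect-magnitude indices epidemiologists meet
in practice (omega-squared, adjusted eta-squared, Cohen's f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .results import ConfInt, Estimate, Scale, Sidedness, TestResult
from .tables import (
    CorrectionRule,
    GroupedNumericSamples,
    OrderedTwoByK,
    RxCTable,
    StratifiedTwoByTwo,
    TwoByTwoTable,
    continuity_corrected,
)

DEFAULT_LEVELS = (0.95,)


def _z(level: float) -> float:
    return stats.norm.ppf(0.5 + level / 2.0)


def _log_scale_cis(point: float, se_log: float, levels) -> tuple[ConfInt, ...]:
    log_point = math.log(point)
    return tuple(
        ConfInt(level, math.exp(log_point - _z(level) * se_log), math.exp(log_point + _z(level) * se_log))
        for level in levels
    )


# ---------------------------------------------------------------------------
# 2x2 effect measures


def odds_ratio(
    table: TwoByTwoTable,
    levels=DEFAULT_LEVELS,
    method: str = "woolf",
    correction: CorrectionRule | str | None = CorrectionRule.only_if_zero_cell,
) -> Estimate:
    """Odds ratio ad/bc with Woolf (log-normal) or exact conditional CI.

    The point estimate is computed on the raw cells; a zero in b or c makes
    it infinite (flagged ``upper_unbounded``), a zero in a or d makes it 0
    (``lower_unbounded``).  The Woolf interval needs logs, so it is computed
    on a continuity-corrected copy under ``correction`` (default: add 0.5 to
    all cells only when some cell is zero).  ``method="exact"`` gives the
    conditional maximum-likelihood estimate's interval from the noncentral
    hypergeometric distribution.
    """
    flags: tuple[str, ...] = ()
    if method == "exact":
        if table.corrected:
            raise ValueError("exact odds-ratio interval requires integral counts")
        res = stats.contingency.odds_ratio(table.to_array().astype(int), kind="conditional")
        intervals = []
        for level in levels:
            ci = res.confidence_interval(confidence_level=level)
            intervals.append(ConfInt(level, ci.low, ci.high))
        point = float(res.statistic)
        if not math.isfinite(point):
            flags += ("upper_unbounded",)
        return Estimate(point, Scale.ratio, tuple(intervals), "conditional-exact", flags)
    if method != "woolf":
        raise ValueError(f"unknown odds-ratio method: {method!r}")

    if table.b * table.c == 0 and table.a * table.d == 0:
        raise ValueError("odds ratio undefined: both diagonals contain a zero")
    point: float
    if table.b * table.c == 0:
        point = math.inf
        flags += ("upper_unbounded",)
    elif table.a * table.d == 0:
        point = 0.0
        flags += ("lower_unbounded",)
    else:
        point = (table.a * table.d) / (table.b * table.c)

    if correction is None:
        work = table
    else:
        work = continuity_corrected(table, 0.5, correction)
        if work is not table:
            flags += ("zero_cell_correction",)
    if work.has_zero_cell:
        # no correction applied: only the informative one-sided bound exists
        intervals = tuple(
            ConfInt(level, 0.0 if point == 0.0 else 0.0, math.inf) for level in levels
        )
        return Estimate(point, Scale.ratio, intervals, "woolf", flags)
    se = math.sqrt(1 / work.a + 1 / work.b + 1 / work.c + 1 / work.d)
    work_point = (work.a * work.d) / (work.b * work.c)
    intervals = _log_scale_cis(work_point, se, levels)
    return Estimate(point, Scale.ratio, intervals, "woolf", flags)


def risk_ratio(
    table: TwoByTwoTable,
    levels=DEFAULT_LEVELS,
    correction: CorrectionRule | str | None = CorrectionRule.only_if_zero_cell,
) -> Estimate:
    """Risk ratio [a/(a+b)] / [c/(c+d)] with the Katz log-method interval."""
    n1, n2 = table.row_totals
    if n1 == 0 or n2 == 0:
        raise ValueError("both rows must contain observations")
    flags: tuple[str, ...] = ()
    p1, p2 = table.a / n1, table.c / n2
    if p2 == 0 and p1 == 0:
        raise ValueError("risk ratio undefined: no events in either group")
    if p2 == 0:
        point = math.inf
        flags += ("upper_unbounded",)
    elif p1 == 0:
        point = 0.0
        flags += ("lower_unbounded",)
    else:
        point = p1 / p2

    work = table
    if correction is not None and (table.a == 0 or table.c == 0):
        work = continuity_corrected(table, 0.5, correction)
        if work is not table:
            flags += ("zero_cell_correction",)
    if work.a == 0 or work.c == 0:
        intervals = tuple(ConfInt(level, 0.0, math.inf) for level in levels)
        return Estimate(point, Scale.ratio, intervals, "katz", flags)
    m1, m2 = work.row_totals
    se = math.sqrt(1 / work.a - 1 / m1 + 1 / work.c - 1 / m2)
    work_point = (work.a / m1) / (work.c / m2)
    intervals = _log_scale_cis(work_point, se, levels)
    return Estimate(point, Scale.ratio, intervals, "katz", flags)


def risk_difference(
    table: TwoByTwoTable,
    levels=DEFAULT_LEVELS,
    method: str = "newcombe",
) -> Estimate:
    """Risk difference p1 - p2 with Wald or Newcombe hybrid-score interval.

    The Newcombe (method 10) interval combines the Wilson score limits of
    the two proportions and behaves well near 0 and 1.
    """
    n1, n2 = table.row_totals
    if n1 == 0 or n2 == 0:
        raise ValueError("both rows must contain observations")
    p1, p2 = table.a / n1, table.c / n2
    point = p1 - p2
    intervals = []
    for level in levels:
        z = _z(level)
        if method == "wald":
            se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
            low, high = point - z * se, point + z * se
        elif method == "newcombe":
            l1, u1 = _wilson(table.a, n1, level)
            l2, u2 = _wilson(table.c, n2, level)
            low = point - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
            high = point + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
        else:
            raise ValueError(f"unknown risk-difference method: {method!r}")
        intervals.append(ConfInt(level, max(-1.0, low), min(1.0, high)))
    return Estimate(point, Scale.difference, tuple(intervals), method)


def _wilson(x: float, n: float, level: float) -> tuple[float, float]:
    z = _z(level)
    p = x / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return centre - half, centre + half


# ---------------------------------------------------------------------------
# 2x2 tests


def chi_square_2x2(table: TwoByTwoTable, yates: bool = False) -> list[TestResult]:
    """Pearson (optionally Yates-corrected) and likelihood-ratio chi-square.

    A zero margin makes the table degenerate: both tests return statistic 0
    and P = 1 with a ``degenerate_margin`` flag.
    """
    r1, r2 = table.row_totals
    c1, c2 = table.col_totals
    n = table.total
    if 0 in (r1, r2, c1, c2):
        flag = ("degenerate_margin",)
        return [
            TestResult(0.0, 0, 1.0, Sidedness.two, "pearson", flag),
            TestResult(0.0, 0, 1.0, Sidedness.two, "likelihood-ratio", flag),
        ]
    delta = abs(table.a * table.d - table.b * table.c)
    if yates:
        delta = max(0.0, delta - n / 2.0)
    pearson = n * delta * delta / (r1 * r2 * c1 * c2)
    method = "pearson-yates" if yates else "pearson"
    results = [
        TestResult(pearson, 1, float(stats.chi2.sf(pearson, 1)), Sidedness.two, method)
    ]
    observed = table.to_array()
    expected = np.outer([r1, r2], [c1, c2]) / n
    mask = observed > 0
    g2 = 2.0 * float(np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))
    g2 = max(0.0, g2)
    results.append(
        TestResult(g2, 1, float(stats.chi2.sf(g2, 1)), Sidedness.two, "likelihood-ratio")
    )
    return results


def fisher_exact(
    table: TwoByTwoTable,
    sidedness: Sidedness | str = Sidedness.two,
    mid_p: bool = False,
) -> TestResult:
    """Fisher's exact test by the probability method.

    Conditioning on both margins, cell ``a`` follows a hypergeometric
    distribution.  The two-sided P is the total probability of tables no
    more probable than the observed one; the one-sided P is the smaller
    hypergeometric tail.  ``mid_p`` counts the observed table with half
    weight.
    """
    if table.corrected:
        raise ValueError("exact test requires integral counts (uncorrected table)")
    sidedness = Sidedness(sidedness)
    a = int(table.a)
    r1, _ = (int(v) for v in table.row_totals)
    c1, _ = (int(v) for v in table.col_totals)
    n = int(table.total)
    support_lo = max(0, r1 + c1 - n)
    support_hi = min(r1, c1)
    support = np.arange(support_lo, support_hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(pmf[a - support_lo])
    if sidedness is Sidedness.two:
        # relative tolerance guards against float noise in "equal" tables
        include = pmf <= p_obs * (1 + 1e-9)
        p = float(pmf[include].sum())
        if mid_p:
            p -= 0.5 * p_obs
    else:
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = min(lower, upper)
        if mid_p:
            p -= 0.5 * p_obs
    p = min(1.0, max(0.0, p))
    method = "fisher-mid-p" if mid_p else "fisher-exact"
    return TestResult(float("nan"), None, p, sidedness, method)


# ---------------------------------------------------------------------------
# Stratified analysis


@dataclass(frozen=True)
class PooledEstimate:
    """A Mantel-Haenszel pooled effect with its heterogeneity assessment."""

    pooled: Estimate
    per_stratum: tuple[Estimate, ...]
    heterogeneity: TestResult
    labels: tuple[str, ...]


def mantel_haenszel(
    strata: StratifiedTwoByTwo,
    measure: str = "or",
    levels=DEFAULT_LEVELS,
) -> PooledEstimate:
    """Mantel-Haenszel pooled odds or risk ratio across strata.

    The pooled odds ratio is sum(a_i d_i / n_i) / sum(b_i c_i / n_i) with
    the Robins-Breslow-Greenland variance for its log; the pooled risk
    ratio is sum(a_i (c_i+d_i) / n_i) / sum(c_i (a_i+b_i) / n_i) with the
    Greenland-Robins variance.  Heterogeneity across strata is assessed by
    Woolf's Q on the per-stratum log estimates (0.5 added to all cells of a
    stratum containing zeros, within Q only), df = informative strata - 1.
    """
    if measure not in ("or", "rr"):
        raise ValueError(f"measure must be 'or' or 'rr', got {measure!r}")
    tables = strata.tables
    n = np.array([t.total for t in tables])
    a = np.array([t.a for t in tables])
    b = np.array([t.b for t in tables])
    c = np.array([t.c for t in tables])
    d = np.array([t.d for t in tables])

    if measure == "or":
        R_i = a * d / n
        S_i = b * c / n
    else:
        R_i = a * (c + d) / n
        S_i = c * (a + b) / n
    R, S = float(R_i.sum()), float(S_i.sum())
    if R == 0 and S == 0:
        raise ValueError("all strata are uninformative for the pooled estimate")
    flags: tuple[str, ...] = ()
    if S == 0:
        point, flags = math.inf, ("upper_unbounded",)
    elif R == 0:
        point, flags = 0.0, ("lower_unbounded",)
    else:
        point = R / S

    intervals: tuple[ConfInt, ...] = ()
    if R > 0 and S > 0:
        if measure == "or":
            P_i = (a + d) / n
            Q_i = (b + c) / n
            var_log = (
                float((P_i * R_i).sum()) / (2 * R * R)
                + float((P_i * S_i + Q_i * R_i).sum()) / (2 * R * S)
                + float((Q_i * S_i).sum()) / (2 * S * S)
            )
            method = "mantel-haenszel (RBG variance)"
        else:
            num = ((a + b) * (c + d) * (a + c) - a * c * n) / (n * n)
            var_log = float(num.sum()) / (R * S)
            method = "mantel-haenszel (Greenland-Robins variance)"
        se = math.sqrt(var_log)
        intervals = _log_scale_cis(point, se, levels)
    else:
        method = "mantel-haenszel"
        intervals = tuple(ConfInt(level, 0.0, math.inf) for level in levels)
    pooled = Estimate(point, Scale.ratio, intervals, method, flags)

    per_stratum = tuple(
        (odds_ratio if measure == "or" else risk_ratio)(t, levels) for t in tables
    )
    heterogeneity = _woolf_q(tables, measure)
    return PooledEstimate(pooled, per_stratum, heterogeneity, strata.labels)


def _woolf_q(tables, measure: str) -> TestResult:
    """Woolf heterogeneity Q on log per-stratum estimates.

    Strata containing a zero cell get 0.5 added to all cells (within Q
    only); strata with an empty row (or column for OR) stay uninformative.
    """
    logs, weights = [], []
    for t in tables:
        tc = continuity_corrected(t, 0.5, CorrectionRule.only_if_zero_cell)
        a, b, c, d = tc.cells
        if measure == "or":
            if min(a, b, c, d) <= 0:
                continue
            logs.append(math.log(a * d / (b * c)))
            weights.append(1.0 / (1 / a + 1 / b + 1 / c + 1 / d))
        else:
            n1, n2 = a + b, c + d
            if a <= 0 or c <= 0 or n1 <= 0 or n2 <= 0:
                continue
            logs.append(math.log((a / n1) / (c / n2)))
            weights.append(1.0 / (1 / a - 1 / n1 + 1 / c - 1 / n2))
    k = len(logs)
    if k <= 1:
        return TestResult(0.0, 0, 1.0, Sidedness.two, "woolf-q", ("too_few_informative_strata",))
    logs_arr = np.array(logs)
    w = np.array(weights)
    pooled_log = float((w * logs_arr).sum() / w.sum())
    q = float((w * (logs_arr - pooled_log) ** 2).sum())
    df = k - 1
    return TestResult(q, df, float(stats.chi2.sf(q, df)), Sidedness.two, "woolf-q")


# ---------------------------------------------------------------------------
# Ordered categories


def cochran_armitage_trend(table: OrderedTwoByK) -> TestResult:
    """Cochran-Armitage test for a linear trend in proportions over ordered
    categories, using the table's category scores (default 1..k)."""
    s = np.array(table.effective_scores)
    if np.allclose(s, s[0]):
        raise ValueError("all category scores are equal; trend is undefined")
    r1 = np.array(table.row1, dtype=float)
    r2 = np.array(table.row2, dtype=float)
    cols = r1 + r2
    if (cols > 0).sum() < 2:
        raise ValueError("need at least 2 nonempty categories")
    n = cols.sum()
    big_r = r1.sum()
    if big_r == 0 or r2.sum() == 0:
        raise ValueError("both rows must contain observations")
    p_bar = big_r / n
    num = float((s * r1).sum() - p_bar * (s * cols).sum())
    var = p_bar * (1 - p_bar) * (float((cols * s * s).sum()) - float((cols * s).sum()) ** 2 / n)
    if var <= 0:
        return TestResult(0.0, None, 1.0, Sidedness.two, "cochran-armitage", ("degenerate",))
    z = num / math.sqrt(var)
    p = 2 * float(stats.norm.sf(abs(z)))
    return TestResult(z, None, p, Sidedness.two, "cochran-armitage")


@dataclass(frozen=True)
class RiditResult:
    """Mean ridits of the two groups relative to the reference distribution.

    The comparison group's mean ridit estimates P(comparison > reference)
    + 0.5 P(tie); the reference group's own mean ridit is 0.5 by
    construction.
    """

    mean_ridit_reference: float
    mean_ridit_comparison: float
    ci: ConfInt
    method: str = "bross-fleiss"


def ridit_analysis(
    table: OrderedTwoByK,
    reference: str = "row1",
    level: float = 0.95,
) -> RiditResult:
    """Ridit analysis of a 2 x k ordered table.

    Ridits are computed from the reference row (proportion below each
    category plus half the proportion within it); the standard error of the
    comparison group's mean ridit is Fleiss's 1/sqrt(12 n), which treats
    the reference distribution as fixed.
    """
    if reference not in ("row1", "row2"):
        raise ValueError("reference must be 'row1' or 'row2'")
    ref = np.array(table.row1 if reference == "row1" else table.row2, dtype=float)
    comp = np.array(table.row2 if reference == "row1" else table.row1, dtype=float)
    if ref.sum() == 0:
        raise ValueError("reference row is empty")
    if comp.sum() == 0:
        raise ValueError("comparison row is empty")
    prop = ref / ref.sum()
    ridits = np.cumsum(prop) - prop / 2.0
    mean_ref = float((prop * ridits).sum())
    n_comp = comp.sum()
    mean_comp = float((comp * ridits).sum() / n_comp)
    se = 1.0 / math.sqrt(12.0 * n_comp)
    z = _z(level)
    ci = ConfInt(level, max(0.0, mean_comp - z * se), min(1.0, mean_comp + z * se))
    return RiditResult(mean_ref, mean_comp, ci)


def generalized_odds_ratio(table: OrderedTwoByK, level: float = 0.95) -> Estimate:
    """Agresti's generalized odds ratio for two groups on an ordered scale.

    Point estimate: P(a random row-1 observation exceeds a random row-2
    observation) divided by the reverse probability, i.e. concordant over
    discordant pairs.  The interval is a log-scale delta-method interval
    treating the two rows as independent multinomials.
    """
    r1 = np.array(table.row1, dtype=float)
    r2 = np.array(table.row2, dtype=float)
    n1, n2 = r1.sum(), r2.sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("both rows must contain observations")
    q1, q2 = r1 / n1, r2 / n2
    cum2_below = np.concatenate(([0.0], np.cumsum(q2)[:-1]))  # P(row2 < cat j)
    cum2_above = 1.0 - np.cumsum(q2)                          # P(row2 > cat j)
    c_prob = float((q1 * cum2_below).sum())  # P(row1 > row2)
    d_prob = float((q1 * cum2_above).sum())  # P(row1 < row2)

    flags: tuple[str, ...] = ()
    if d_prob == 0 and c_prob == 0:
        raise ValueError("no discordance in either direction (all mass in one category)")
    if d_prob == 0:
        return Estimate(math.inf, Scale.ratio, (ConfInt(level, 0.0, math.inf),),
                        "generalized-or", ("upper_unbounded",))
    if c_prob == 0:
        return Estimate(0.0, Scale.ratio, (ConfInt(level, 0.0, math.inf),),
                        "generalized-or", ("lower_unbounded",))
    point = c_prob / d_prob

    # delta method: d(log alpha)/dq contributions from each row
    cum1_above = np.concatenate((np.cumsum(q1[::-1])[::-1][1:], [0.0]))  # P(row1 > cat j)
    cum1_below = np.concatenate(([0.0], np.cumsum(q1)[:-1]))             # P(row1 < cat j)
    g1 = cum2_below / c_prob - cum2_above / d_prob
    g2 = cum1_above / c_prob - cum1_below / d_prob
    var = (
        float((q1 * g1 * g1).sum() - (q1 * g1).sum() ** 2) / n1
        + float((q2 * g2 * g2).sum() - (q2 * g2).sum() ** 2) / n2
    )
    se = math.sqrt(max(0.0, var))
    ci = ConfInt(level, point * math.exp(-_z(level) * se), point * math.exp(_z(level) * se))
    return Estimate(point, Scale.ratio, (ci,), "generalized-or", flags)


# ---------------------------------------------------------------------------
# r x c tables


@dataclass(frozen=True)
class RxCResult:
    pearson: TestResult
    likelihood_ratio: TestResult
    adjusted_residuals: np.ndarray
    cramers_v: float
    sakoda_c: float
    pairwise_columns: tuple[TestResult, ...]
    trend: TestResult | None = None
    kruskal_wallis_ranks: TestResult | None = None
    dropped_rows: tuple[int, ...] = ()
    dropped_cols: tuple[int, ...] = ()


def rxc_analysis(table: RxCTable) -> RxCResult:
    """Analysis of a large contingency table.

    Pearson and likelihood-ratio chi-square, Haberman adjusted residuals,
    Cramer's V and Sakoda's adjusted contingency coefficient, and
    Bonferroni-adjusted pairwise column comparisons.  When the columns are
    declared ordered: a Cochran-Armitage trend test (2 x k tables) and a
    Kruskal-Wallis test treating rows as groups and columns as ranks.
    Rows or columns with a zero margin are dropped (recorded in the result).
    """
    counts = np.asarray(table.counts, dtype=float)
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    dropped_rows = tuple(int(i) for i in np.flatnonzero(~row_keep))
    dropped_cols = tuple(int(j) for j in np.flatnonzero(~col_keep))
    counts = counts[np.ix_(row_keep, col_keep)]
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("fewer than 2 nonzero rows or columns remain")
    n = counts.sum()
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    expected = np.outer(row_m, col_m) / n
    df = (r - 1) * (c - 1)

    chi2 = float(((counts - expected) ** 2 / expected).sum())
    pearson = TestResult(chi2, df, float(stats.chi2.sf(chi2, df)), Sidedness.two, "pearson")
    mask = counts > 0
    g2 = max(0.0, 2.0 * float((counts[mask] * np.log(counts[mask] / expected[mask])).sum()))
    lr = TestResult(g2, df, float(stats.chi2.sf(g2, df)), Sidedness.two, "likelihood-ratio")

    adj = (counts - expected) / np.sqrt(
        expected * np.outer(1 - row_m / n, 1 - col_m / n)
    )
    q = min(r, c)
    cramers_v = math.sqrt(chi2 / (n * (q - 1)))
    c_coeff = math.sqrt(chi2 / (chi2 + n))
    sakoda = c_coeff / math.sqrt((q - 1) / q)

    pairs = list(combinations(range(c), 2))
    pairwise = []
    for j1, j2 in pairs:
        sub = counts[:, [j1, j2]]
        sub = sub[sub.sum(axis=1) > 0]
        if sub.shape[0] < 2 or (sub.sum(axis=0) == 0).any():
            continue
        sub_n = sub.sum()
        sub_e = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / sub_n
        sub_chi2 = float(((sub - sub_e) ** 2 / sub_e).sum())
        sub_df = sub.shape[0] - 1
        raw_p = float(stats.chi2.sf(sub_chi2, sub_df))
        adj_p = min(1.0, raw_p * len(pairs))
        pairwise.append(
            TestResult(sub_chi2, sub_df, adj_p, Sidedness.two,
                       f"pearson cols {j1 + 1} vs {j2 + 1} (bonferroni x{len(pairs)})")
        )

    trend = kw = None
    if table.col_ordered:
        if r == 2:
            trend = cochran_armitage_trend(
                OrderedTwoByK(tuple(int(v) for v in counts[0]),
                              tuple(int(v) for v in counts[1]))
            )
        expanded = [np.repeat(np.arange(c), counts[i].astype(int)) for i in range(r)]
        expanded = [g for g in expanded if len(g) > 0]
        if len(expanded) >= 2 and len(np.unique(np.concatenate(expanded))) > 1:
            h, p = stats.kruskal(*expanded)
            kw = TestResult(float(h), len(expanded) - 1, float(p), Sidedness.two,
                            "kruskal-wallis on column ranks")

    return RxCResult(pearson, lr, adj, cramers_v, sakoda, tuple(pairwise),
                     trend, kw, dropped_rows, dropped_cols)


# ---------------------------------------------------------------------------
# k numeric samples


def kruskal_wallis(samples: GroupedNumericSamples) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation."""
    if samples.n_total < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(samples.groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, samples.k - 1, 1.0, Sidedness.two,
                          "kruskal-wallis", ("all_identical",))
    h, p = stats.kruskal(*samples.groups)
    return TestResult(float(h), samples.k - 1, float(p), Sidedness.two, "kruskal-wallis")


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with effect-magnitude indices.

    ``omega_squared`` and ``eta_squared_adjusted`` can be slightly negative
    in near-null data; they are reported as computed, with a
    ``negative_effect_size`` flag.
    """

    f_test: TestResult
    omega_squared: float
    eta_squared: float
    eta_squared_adjusted: float
    cohens_f: float
    variance_homogeneity: TestResult
    linear_trend: TestResult
    trend_slope: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    flags: tuple[str, ...] = ()


def anova_with_effects(
    samples: GroupedNumericSamples,
    trend_scores=None,
) -> AnovaResult:
    """One-way ANOVA with omega-squared, adjusted eta-squared and Cohen's f,
    a Brown-Forsythe homogeneity-of-variances test, and a test for the
    linear trend of means over ``trend_scores`` (default: group indices
    1..k).

    omega^2 = (SSb - (k-1) MSw) / (SSt + MSw); adjusted eta^2 is the
    Wherry-type shrinkage 1 - MSw/MSt; Cohen's f = sqrt(eta^2 / (1-eta^2))
    from the unadjusted eta^2.
    """
    groups = samples.groups
    k = samples.k
    ns = np.array(samples.sizes, dtype=float)
    n_total = float(samples.n_total)
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    grand = float(np.concatenate(groups).mean())

    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    sst = ssb + ssw
    df_b, df_w = k - 1, n_total - k
    msw = ssw / df_w
    mst = sst / (n_total - 1)
    flags: tuple[str, ...] = ()
    if ssw == 0:
        f_stat = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        flags += ("zero_within_variance",)
    else:
        f_stat = (ssb / df_b) / msw
        p = float(stats.f.sf(f_stat, df_b, df_w))
    f_test = TestResult(f_stat, df_b, p, Sidedness.two, f"one-way F ({df_b:.0f}, {df_w:.0f})")

    if sst == 0:
        omega2 = eta2 = eta2_adj = 0.0
        flags += ("zero_total_variance",)
    else:
        omega2 = (ssb - df_b * msw) / (sst + msw)
        eta2 = ssb / sst
        eta2_adj = 1.0 - msw / mst
    if omega2 < 0 or eta2_adj < 0:
        flags += ("negative_effect_size",)
    cohens_f = math.sqrt(max(0.0, eta2) / (1 - eta2)) if eta2 < 1 else math.inf

    bf_stat, bf_p = stats.levene(*groups, center="median")
    homogeneity = TestResult(float(bf_stat), k - 1, float(bf_p), Sidedness.two,
                             "brown-forsythe")

    s = np.array(trend_scores, dtype=float) if trend_scores is not None else np.arange(1, k + 1, dtype=float)
    if len(s) != k:
        raise ValueError("trend_scores length must equal the number of groups")
    s_bar = float((ns * s).sum() / n_total)
    sxx = float((ns * (s - s_bar) ** 2).sum())
    if sxx == 0 or msw == 0:
        linear = TestResult(0.0, 1, 1.0, Sidedness.two, "linear trend", ("degenerate",))
        slope = 0.0
    else:
        slope = float((ns * (s - s_bar) * means).sum()) / sxx
        ss_trend = slope * slope * sxx
        f_trend = ss_trend / msw
        linear = TestResult(f_trend, 1, float(stats.f.sf(f_trend, 1, df_w)),
                            Sidedness.two, "linear trend of means")

    return AnovaResult(f_test, omega2, eta2, eta2_adj, cohens_f, homogeneity,
                       linear, slope, tuple(means), tuple(sds), flags)
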