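"""Matched-pair comparisons and reliability / agreement statistics.

McNemar's test (exact and chi-square forms), the conditional matched-pairs
odds ratio with its exact binomial interval, Cohen's kappa (unweighted and
weighted) with ceiling kappa and PABAK, indices of proportionate positive
and negative agreement, intraclass correlation coefficients, and
Bland-Altman 95% limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .results import ConfInt, Estimate, Scale, Sidedness, TestResult
from .tables import PairedDichotomousTable, PairedNumericSeries, RatingMatrix, RxCTable


def _z(level: float) -> float:
    return stats.norm.ppf(0.5 + level / 2.0)


# ---------------------------------------------------------------------------
# McNemar and the matched odds ratio


def mcnemar(
    table: PairedDichotomousTable,
    mode: str = "exact",
) -> TestResult:
    """McNemar's test on the discordant pair counts f and g.

    ``chi_square``: (f-g)^2 / (f+g); ``corrected``: (|f-g|-1)^2 / (f+g)
    (Edwards continuity correction); ``exact``: double the binomial(f+g,
    1/2) tail of min(f, g), capped at 1.
    """
    f, g = table.f, table.g
    nd = f + g
    if mode in ("chi_square", "corrected"):
        if nd == 0:
            return TestResult(0.0, 1, 1.0, Sidedness.two, f"mcnemar-{mode}",
                              ("no_discordant_pairs",))
        num = abs(f - g)
        if mode == "corrected":
            num = max(0.0, num - 1)
        statistic = num * num / nd
        return TestResult(statistic, 1, float(stats.chi2.sf(statistic, 1)),
                          Sidedness.two, f"mcnemar-{mode}")
    if mode == "exact":
        if nd == 0:
            raise ValueError("exact McNemar test requires at least one discordant pair")
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(f, g), nd, 0.5)))
        return TestResult(float("nan"), None, p, Sidedness.two, "mcnemar-exact")
    raise ValueError(f"unknown mode {mode!r}; use exact, chi_square or corrected")


def matched_or(table: PairedDichotomousTable, level: float = 0.95) -> Estimate:
    """Conditional maximum-likelihood odds ratio f/g for matched pairs.

    Conditioning on the discordant total, f ~ Binomial(f+g, OR/(1+OR)); the
    exact interval inverts the Clopper-Pearson bounds for that binomial
    proportion and maps them back to the odds-ratio scale.
    """
    f, g = table.f, table.g
    nd = f + g
    if nd == 0:
        raise ValueError("matched odds ratio requires at least one discordant pair")
    flags: tuple[str, ...] = ()
    if g == 0:
        point = math.inf
        flags += ("upper_unbounded",)
    else:
        point = f / g
    # Clopper-Pearson for theta = f/(f+g), then OR = theta / (1 - theta)
    alpha = 1 - level
    theta_lo = 0.0 if f == 0 else float(stats.beta.ppf(alpha / 2, f, nd - f + 1))
    theta_hi = 1.0 if f == nd else float(stats.beta.ppf(1 - alpha / 2, f + 1, nd - f))
    or_lo = theta_lo / (1 - theta_lo) if theta_lo < 1 else math.inf
    or_hi = theta_hi / (1 - theta_hi) if theta_hi < 1 else math.inf
    return Estimate(point, Scale.ratio, (ConfInt(level, or_lo, or_hi),),
                    "conditional-ml, exact binomial CI", flags)


# ---------------------------------------------------------------------------
# Kappa


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected agreement between two raters.

    ``maximum_kappa`` is the ceiling attainable given the observed
    marginals (kappa has a ceiling below 1 whenever the raters' marginal
    distributions differ); ``pabak`` is the prevalence-and-bias-adjusted
    kappa, defined for dichotomous ratings only.
    """

    kappa: float
    se: float
    ci: ConfInt
    observed_agreement: float
    expected_agreement: float
    maximum_kappa: float
    pabak: float | None
    weighted: bool
    method: str = "cohen"


def _weight_matrix(q: int, weights, custom) -> np.ndarray:
    if weights == "none":
        return np.eye(q)
    idx = np.arange(q)
    penalty = np.abs(idx[:, None] - idx[None, :]) / (q - 1)
    if weights == "linear":
        return 1.0 - penalty
    if weights == "quadratic":
        return 1.0 - penalty**2
    if weights == "custom":
        w = np.asarray(custom, dtype=float)
        if w.shape != (q, q) or not np.allclose(w, w.T) or not np.allclose(np.diag(w), 1.0):
            raise ValueError("custom weights must be a symmetric q x q matrix with unit diagonal")
        return w
    raise ValueError(f"unknown weight scheme {weights!r}")


def rating_matrix_to_square_table(matrix: RatingMatrix) -> RxCTable:
    """Cross-classify a two-rater RatingMatrix into a square agreement table."""
    if matrix.n_raters != 2:
        raise ValueError("kappa requires exactly 2 raters")
    levels = matrix.levels()
    q = len(levels)
    if q < 2:
        raise ValueError("ratings use a single level; agreement is degenerate")
    index = {v: i for i, v in enumerate(levels)}
    counts = np.zeros((q, q), dtype=int)
    for r1, r2 in matrix.ratings:
        counts[index[r1], index[r2]] += 1
    labels = tuple(str(int(v)) if float(v).is_integer() else str(v) for v in levels)
    return RxCTable(counts, row_labels=labels, col_labels=labels)


def cohens_kappa(
    data: RatingMatrix | RxCTable | np.ndarray,
    weights: str = "none",
    level: float = 0.95,
    custom_weights=None,
) -> KappaResult:
    """Cohen's kappa (optionally weighted) for two raters.

    Accepts a square cross-classification table (rows = rater 1, columns =
    rater 2) or a RatingMatrix with exactly two raters.  The standard error
    is the Fleiss-Cohen-Everitt large-sample SE of the estimate (not the
    null SE), so the interval is kappa +/- z * SE.
    """
    if isinstance(data, RatingMatrix):
        data = rating_matrix_to_square_table(data)
    if isinstance(data, RxCTable):
        counts = np.asarray(data.counts, dtype=float)
    else:
        counts = np.asarray(data, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("kappa requires a square cross-classification")
    q = counts.shape[0]
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    p = counts / n
    row_m = p.sum(axis=1)
    col_m = p.sum(axis=0)
    w = _weight_matrix(q, weights, custom_weights)

    po = float((w * p).sum())
    pe = float((w * np.outer(row_m, col_m)).sum())
    if pe >= 1.0 - 1e-12:
        raise ValueError("expected agreement is 1 (degenerate marginals); kappa undefined")
    kappa = (po - pe) / (1 - pe)

    # Fleiss-Cohen-Everitt large-sample variance of weighted kappa-hat
    w_row = (w * col_m[None, :]).sum(axis=1)  # E_j w_ij over rater-2 marginal
    w_col = (w * row_m[:, None]).sum(axis=0)  # E_i w_ij over rater-1 marginal
    term = (w - (w_row[:, None] + w_col[None, :]) * (1 - kappa)) ** 2
    var = (float((p * term).sum()) - (kappa - pe * (1 - kappa)) ** 2) / (n * (1 - pe) ** 2)
    se = math.sqrt(max(0.0, var))
    z = _z(level)
    ci = ConfInt(level, max(-1.0, kappa - z * se), min(1.0, kappa + z * se))

    # ceiling kappa: maximum po attainable with the observed marginals
    po_max = float(np.minimum(row_m, col_m).sum()) if weights == "none" else _max_po(w, row_m, col_m)
    kappa_max = (po_max - pe) / (1 - pe)

    pabak = 2 * float(np.diag(p).sum()) - 1 if q == 2 else None
    return KappaResult(kappa, se, ci, po, pe, kappa_max, pabak,
                       weighted=(weights != "none"),
                       method=f"cohen ({weights} weights)" if weights != "none" else "cohen")


def _max_po(w: np.ndarray, row_m: np.ndarray, col_m: np.ndarray) -> float:
    """Maximum weighted agreement over joint tables with the given marginals
    (linear program solved by scipy)."""
    from scipy.optimize import linprog

    q = len(row_m)
    a_eq = []
    for i in range(q):
        row = np.zeros((q, q))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(q):
        col = np.zeros((q, q))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(-w.ravel(), A_eq=np.array(a_eq),
                  b_eq=np.concatenate([row_m, col_m]), bounds=(0, 1), method="highs")
    return float(-res.fun)


# ---------------------------------------------------------------------------
# Positive / negative agreement


@dataclass(frozen=True)
class AgreementIndices:
    positive_agreement: float
    negative_agreement: float
    positive_ci: ConfInt
    negative_ci: ConfInt
    n_bootstrap: int
    seed: int


def positive_negative_agreement(
    table: PairedDichotomousTable,
    level: float = 0.95,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> AgreementIndices:
    """Proportionate positive and negative agreement between two raters.

    ppos = 2e / (2e + f + g), pneg = 2h / (2h + f + g).  Confidence
    intervals are seeded bootstrap percentile intervals over multinomial
    resamples of the four cells.
    """
    e, f, g, h = table.e, table.f, table.g, table.h
    if 2 * e + f + g == 0:
        raise ValueError("positive agreement undefined: no positive ratings (2e+f+g = 0)")
    if 2 * h + f + g == 0:
        raise ValueError("negative agreement undefined: no negative ratings (2h+f+g = 0)")
    ppos = 2 * e / (2 * e + f + g)
    pneg = 2 * h / (2 * h + f + g)

    rng = np.random.default_rng(seed)
    n = table.total
    probs = np.array([e, f, g, h], dtype=float) / n
    draws = rng.multinomial(n, probs, size=n_bootstrap).astype(float)
    eb, fb, gb, hb = draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]
    with np.errstate(invalid="ignore", divide="ignore"):
        ppos_b = 2 * eb / (2 * eb + fb + gb)
        pneg_b = 2 * hb / (2 * hb + fb + gb)
    alpha = 1 - level
    pos_lo, pos_hi = np.nanquantile(ppos_b, [alpha / 2, 1 - alpha / 2])
    neg_lo, neg_hi = np.nanquantile(pneg_b, [alpha / 2, 1 - alpha / 2])
    pos_ci = ConfInt(level, float(pos_lo), float(pos_hi))
    neg_ci = ConfInt(level, float(neg_lo), float(neg_hi))
    return AgreementIndices(ppos, pneg, pos_ci, neg_ci, n_bootstrap, seed)


# ---------------------------------------------------------------------------
# Intraclass correlation


@dataclass(frozen=True)
class ICCResult:
    """A single-measure intraclass correlation coefficient.

    ``oneway_random`` is ICC(1,1) from the one-way random-effects
    decomposition; ``twoway_absolute`` is the absolute-agreement
    single-measure ICC(A,1) from the two-way model with random raters.
    Variance components are truncated at zero (flagged) when a mean-square
    difference is negative.
    """

    icc: float
    model: str
    ci: ConfInt
    variance_components: dict
    flags: tuple[str, ...] = ()


def icc(
    ratings: RatingMatrix,
    model: str = "oneway_random",
    level: float = 0.95,
) -> ICCResult:
    """Intraclass correlation from a complete subjects x raters matrix."""
    x = np.asarray(ratings.ratings, dtype=float)
    n, m = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance; ICC undefined")
    alpha = 1 - level
    flags: tuple[str, ...] = ()

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = m * float(((row_means - grand) ** 2).sum())

    if model == "oneway_random":
        ss_within = ss_total - ss_rows
        msb = ss_rows / (n - 1)
        msw = ss_within / (n * (m - 1))
        icc_val = (msb - msw) / (msb + (m - 1) * msw)
        sigma_b = max(0.0, (msb - msw) / m)
        if (msb - msw) / m < 0:
            flags += ("variance_component_truncated",)
        components = {"between_subjects": sigma_b, "within_subjects": msw}
        if msw == 0:
            ci = ConfInt(level, icc_val, icc_val)
        else:
            f_obs = msb / msw
            df1, df2 = n - 1, n * (m - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = ConfInt(level, (fl - 1) / (fl + m - 1), (fu - 1) / (fu + m - 1))
        return ICCResult(icc_val, model, ci, components, flags)

    if model == "twoway_absolute":
        ss_cols = n * float(((col_means - grand) ** 2).sum())
        ss_err = ss_total - ss_rows - ss_cols
        msr = ss_rows / (n - 1)
        msc = ss_cols / (m - 1)
        mse = ss_err / ((n - 1) * (m - 1))
        icc_val = (msr - mse) / (msr + (m - 1) * mse + m * (msc - mse) / n)
        sigma_r = max(0.0, (msr - mse) / m)
        sigma_c = max(0.0, (msc - mse) / n)
        if (msr - mse) / m < 0 or (msc - mse) / n < 0:
            flags += ("variance_component_truncated",)
        components = {"between_subjects": sigma_r, "between_raters": sigma_c,
                      "residual": mse}
        if mse == 0:
            ci = ConfInt(level, icc_val, icc_val)
        else:
            # McGraw & Wong (1996) CI for ICC(A,1)
            a = m * icc_val / (n * (1 - icc_val))
            b = 1 + m * icc_val * (n - 1) / (n * (1 - icc_val))
            f_obs = msr / mse
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (m - 1) + (b * mse) ** 2 / ((n - 1) * (m - 1))
            )
            f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_star_l * mse) / (
                f_star_l * (m * msc + (m * n - m - n) * mse) + n * msr
            )
            hi = n * (f_star_u * msr - mse) / (
                m * msc + (m * n - m - n) * mse + n * f_star_u * msr
            )
            ci = ConfInt(level, min(lo, icc_val), max(hi, icc_val))
        return ICCResult(icc_val, model, ci, components, flags)

    raise ValueError(f"unknown ICC model {model!r}")


# ---------------------------------------------------------------------------
# Limits of agreement


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    lower_loa: float
    upper_loa: float
    mean_ci: ConfInt
    lower_loa_ci: ConfInt
    upper_loa_ci: ConfInt
    level: float


def limits_of_agreement(series: PairedNumericSeries, level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman limits of agreement between two measurement methods.

    The limits are mean(x-y) +/- z * SD(x-y); about ``level`` of
    between-method differences are expected to fall inside them.  t-based
    confidence intervals are given for the mean difference and for each
    limit (SE of a limit: SD * sqrt(1/n + z^2 / (2(n-1)))).
    """
    d = series.differences
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    z = _z(level)
    lower, upper = mean - z * sd, mean + z * sd
    t = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
    se_mean = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(1.0 / n + z * z / (2 * (n - 1)))
    return BlandAltmanResult(
        mean, sd, lower, upper,
        ConfInt(level, mean - t * se_mean, mean + t * se_mean),
        ConfInt(level, lower - t * se_loa, lower + t * se_loa),
        ConfInt(level, upper - t * se_loa, upper + t * se_loa),
        level,
    )
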