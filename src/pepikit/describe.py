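"""Descriptive epidemiology.

Direct and indirect standardization (with the embedded Segi world, 1976
European and African standard populations), two-source capture-recapture
estimation of the size of an incompletely listed population, appraisal of
screening and diagnostic tests (sensitivity, specificity, likelihood
ratios, predictive values across prevalences, optimal cutpoints,
stratum-specific likelihood ratios), correction of a prevalence or risk
ratio for nondifferential misclassification, and confidence intervals for
a single proportion.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .results import ConfInt, Estimate, Scale
from .tables import Orientation, StandardPopulation, StratumCounts, TwoByTwoTable


def _z(level: float) -> float:
    return stats.norm.ppf(0.5 + level / 2.0)


# ---------------------------------------------------------------------------
# Standard populations and standardization


def load_standard_population(name: str) -> StandardPopulation:
    """Load one of the embedded standards: 'world', 'european', 'african'.

    Each embedded set of weights sums to 100,000.
    """
    name = name.lower()
    labels: list[str] = []
    weights: list[float] = []
    path = resources.files("pepikit").joinpath("data/standard_populations.csv")
    with path.open("r", encoding="utf-8") as handle:
        rows = [r for r in csv.reader(handle) if r and not r[0].startswith("#")]
    header, body = rows[0], rows[1:]
    if header != ["standard", "label", "weight"]:
        raise ValueError("unexpected standard-population file format")
    available = sorted({row[0] for row in body})
    for std, label, weight in body:
        if std == name:
            labels.append(label)
            weights.append(float(weight))
    if not labels:
        raise ValueError(f"unknown standard population {name!r}; available: {available}")
    return StandardPopulation(name, tuple(labels), tuple(weights))


@dataclass(frozen=True)
class StandardizedRateResult:
    """A directly standardized rate per ``multiplier`` population."""

    rate: float
    ci: ConfInt
    multiplier: float
    standard_name: str


def interval_width_weights(labels: Sequence[str]) -> StandardPopulation:
    """Build standardization weights from the width of each age interval.

    Labels must look like "lo-hi" (width hi - lo + 1) or "lo+" (open-ended;
    given the width of the widest closed interval).  This dispenses with an
    external standard population when none is wanted.
    """
    widths: list[float] = []
    open_idx: list[int] = []
    for i, label in enumerate(labels):
        text = str(label).strip()
        if text.endswith("+"):
            open_idx.append(i)
            widths.append(math.nan)
        elif "-" in text:
            lo, hi = text.split("-", 1)
            widths.append(float(hi) - float(lo) + 1)
        else:
            raise ValueError(f"cannot parse age interval {label!r} (want 'lo-hi' or 'lo+')")
    fallback = max((w for w in widths if not math.isnan(w)), default=1.0)
    for i in open_idx:
        widths[i] = fallback
    return StandardPopulation("interval-widths", tuple(str(l) for l in labels), tuple(widths))


def direct_standardization(
    data: StratumCounts,
    std: StandardPopulation | str,
    multiplier: float = 100_000.0,
    level: float = 0.95,
) -> StandardizedRateResult:
    """Directly standardized rate: the weighted mean of stratum rates.

    Stratum event counts are treated as Poisson, giving variance
    sum(w_i^2 e_i / d_i^2) / (sum w_i)^2 for the standardized rate; the
    normal interval is truncated at zero.  ``std`` may be an embedded
    standard's name, a StandardPopulation, or the result of
    :func:`interval_width_weights`.
    """
    if isinstance(std, str):
        std = load_standard_population(std)
    weights = np.array(std.aligned_weights(data.labels), dtype=float)
    events = np.array(data.events, dtype=float)
    denoms = np.array(data.denominators, dtype=float)
    rates = events / denoms
    w_total = weights.sum()
    rate = float((weights * rates).sum() / w_total)
    var = float((weights**2 * events / denoms**2).sum() / w_total**2)
    z = _z(level)
    half = z * math.sqrt(var)
    ci = ConfInt(level, max(0.0, (rate - half)) * multiplier, (rate + half) * multiplier)
    return StandardizedRateResult(rate * multiplier, ci, multiplier, std.name)


@dataclass(frozen=True)
class SMRResult:
    """Standardized mortality/morbidity ratio with an exact Poisson CI."""

    observed: int
    expected: float
    smr: float
    ci: ConfInt


def poisson_exact_ci(observed: int, level: float = 0.95) -> tuple[float, float]:
    """Exact CI for a Poisson mean via the chi-square relation."""
    alpha = 1 - level
    lower = 0.0 if observed == 0 else float(stats.chi2.ppf(alpha / 2, 2 * observed) / 2)
    upper = float(stats.chi2.ppf(1 - alpha / 2, 2 * observed + 2) / 2)
    return lower, upper


def indirect_standardization(
    observed: int,
    reference_rates: StratumCounts,
    local_denominators: StratumCounts,
    level: float = 0.95,
) -> SMRResult:
    """SMR = observed / expected, with expected = sum of reference stratum
    rates applied to the local denominators.

    ``reference_rates`` carries the reference population's events and
    denominators per stratum (its ``rates`` are used); labels must align
    with ``local_denominators``.
    """
    if int(observed) != observed or observed < 0:
        raise ValueError("observed must be a nonnegative integer count")
    observed = int(observed)
    ref = dict(zip(reference_rates.labels, reference_rates.rates))
    missing = [l for l in local_denominators.labels if l not in ref]
    if missing:
        raise ValueError(f"reference rates lack strata: {', '.join(missing)}")
    expected = float(
        sum(ref[l] * d for l, d in zip(local_denominators.labels, local_denominators.denominators))
    )
    if expected <= 0:
        raise ValueError("expected count is zero; SMR undefined")
    lo, hi = poisson_exact_ci(observed, level)
    return SMRResult(observed, expected, observed / expected,
                     ConfInt(level, lo / expected, hi / expected))


# ---------------------------------------------------------------------------
# Capture-recapture


@dataclass(frozen=True)
class CaptureRecaptureResult:
    """Chapman two-source capture-recapture estimate of population size.

    ``exhaustiveness1``/``exhaustiveness2`` estimate the completeness of
    each source list (n_i divided by the estimated total).
    """

    n1: int
    n2: int
    m: int
    estimate: float
    ci: ConfInt
    exhaustiveness1: float
    exhaustiveness2: float
    flags: tuple[str, ...] = ()


def capture_recapture(n1: int, n2: int, m: int, level: float = 0.95) -> CaptureRecaptureResult:
    """Estimate the total number of cases from two overlapping lists.

    Chapman's nearly unbiased estimator N = (n1+1)(n2+1)/(m+1) - 1 with
    Seber's variance; the normal interval is clamped below at the observed
    union n1 + n2 - m.
    """
    for name, v in (("n1", n1), ("n2", n2), ("m", m)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    n1, n2, m = int(n1), int(n2), int(m)
    if n1 < 1 or n2 < 1:
        raise ValueError("both lists must contain at least one case")
    if m > min(n1, n2):
        raise ValueError(f"overlap m={m} exceeds the smaller list size {min(n1, n2)}")
    estimate = (n1 + 1) * (n2 + 1) / (m + 1) - 1
    var = ((n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m)) / ((m + 1) ** 2 * (m + 2))
    z = _z(level)
    union = n1 + n2 - m
    lo = max(float(union), estimate - z * math.sqrt(var))
    hi = estimate + z * math.sqrt(var)
    flags = ("sparse_overlap",) if m == 0 else ()
    return CaptureRecaptureResult(n1, n2, m, estimate, ConfInt(level, lo, hi),
                                  n1 / estimate if estimate > 0 else 1.0,
                                  n2 / estimate if estimate > 0 else 1.0, flags)


# ---------------------------------------------------------------------------
# Diagnostic tests


@dataclass(frozen=True)
class TestValidityResult:
    """Validity of a dichotomous screening or diagnostic test.

    ``ppv_curve`` and ``npv_curve`` map a hypothetical prevalence to the
    positive and negative predictive values via Bayes' theorem, showing how
    predictive value depends on prevalence for fixed sensitivity and
    specificity.
    """

    sensitivity: Estimate
    specificity: Estimate
    lr_positive: Estimate
    lr_negative: Estimate
    youden: float
    ppv_curve: Callable[[float], float]
    npv_curve: Callable[[float], float]


def _proportion_estimate(x: float, n: float, level: float, label: str) -> Estimate:
    lo, hi = _wilson_bounds(x, n, level)
    return Estimate(x / n, Scale.probability, (ConfInt(level, lo, hi),), f"{label} (wilson)")


def _wilson_bounds(x: float, n: float, level: float) -> tuple[float, float]:
    z = _z(level)
    p = x / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def diagnostic_test_appraisal(table: TwoByTwoTable, level: float = 0.95) -> TestValidityResult:
    """Appraise a test x disease 2x2 table (a=TP, b=FN, c=FP, d=TN)."""
    if table.orientation is not Orientation.test_disease:
        raise ValueError("table orientation must be test_disease (a=TP, b=FN, c=FP, d=TN)")
    a, b, c, d = table.cells
    diseased, healthy = a + b, c + d
    if diseased == 0 or healthy == 0:
        raise ValueError("need both diseased and non-diseased subjects")
    sens = a / diseased
    spec = d / healthy
    sens_est = _proportion_estimate(a, diseased, level, "sensitivity")
    spec_est = _proportion_estimate(d, healthy, level, "specificity")

    def lr_estimate(num_x, num_n, den_x, den_n, label) -> Estimate:
        flags: tuple[str, ...] = ()
        if den_x == 0:
            return Estimate(math.inf, Scale.ratio, (ConfInt(level, 0.0, math.inf),),
                            label, ("upper_unbounded",))
        if num_x == 0:
            return Estimate(0.0, Scale.ratio, (ConfInt(level, 0.0, math.inf),),
                            label, ("lower_unbounded",))
        point = (num_x / num_n) / (den_x / den_n)
        se = math.sqrt(1 / num_x - 1 / num_n + 1 / den_x - 1 / den_n)
        z = _z(level)
        ci = ConfInt(level, point * math.exp(-z * se), point * math.exp(z * se))
        return Estimate(point, Scale.ratio, (ci,), label, flags)

    lr_pos = lr_estimate(a, diseased, c, healthy, "LR+ (log method)")
    lr_neg = lr_estimate(b, diseased, d, healthy, "LR- (log method)")

    def ppv(prevalence: float) -> float:
        if not 0 <= prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        num = prevalence * sens
        den = num + (1 - prevalence) * (1 - spec)
        return num / den if den > 0 else 0.0

    def npv(prevalence: float) -> float:
        if not 0 <= prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        num = (1 - prevalence) * spec
        den = num + prevalence * (1 - sens)
        return num / den if den > 0 else 1.0

    return TestValidityResult(sens_est, spec_est, lr_pos, lr_neg,
                              sens + spec - 1, ppv, npv)


def stratum_specific_lr(
    test_levels: Sequence[tuple[float, float]],
    level: float = 0.95,
) -> list[Estimate]:
    """Likelihood ratio of each test-result level (stratum-specific LRs).

    ``test_levels`` lists (diseased_count, nondiseased_count) per level.
    LR_i = (diseased_i / diseased_total) / (nondiseased_i / nondiseased_total);
    a zero cell gets 0.5 added within that level (flagged); a level with
    both counts zero is dropped with a warning.
    """
    kept = [(d, nd) for d, nd in test_levels if d + nd > 0]
    if len(kept) < len(list(test_levels)):
        warnings.warn("dropped test levels with no observations", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("need at least 2 informative test levels")
    d_total = sum(d for d, _ in kept)
    nd_total = sum(nd for _, nd in kept)
    if d_total == 0 or nd_total == 0:
        raise ValueError("need diseased and non-diseased subjects overall")
    out = []
    z = _z(level)
    for d, nd in kept:
        flags: tuple[str, ...] = ()
        dc, ndc, dt, ndt = d, nd, d_total, nd_total
        if d == 0 or nd == 0:
            dc, ndc = d + 0.5, nd + 0.5
            dt, ndt = d_total + 0.5, nd_total + 0.5
            flags = ("zero_cell_correction",)
        point = (dc / dt) / (ndc / ndt)
        se = math.sqrt(1 / dc - 1 / dt + 1 / ndc - 1 / ndt)
        ci = ConfInt(level, point * math.exp(-z * se), point * math.exp(z * se))
        raw_point = (d / d_total) / (nd / nd_total) if nd > 0 else math.inf
        out.append(Estimate(raw_point, Scale.ratio, (ci,), "stratum LR (log method)", flags))
    return out


def optimal_cutpoint(
    scores_diseased: Sequence[float],
    scores_nondiseased: Sequence[float],
) -> tuple[float, float, float, float]:
    """Cutpoint maximizing Youden's J = sensitivity + specificity - 1.

    A subject is test-positive when its score is >= the cutpoint.
    Candidate cutpoints are the midpoints between adjacent distinct pooled
    values plus -inf/+inf sentinels; ties are broken toward the lowest
    cutpoint.  Returns (cutpoint, youden, sensitivity, specificity).
    """
    diseased = np.asarray(scores_diseased, dtype=float)
    healthy = np.asarray(scores_nondiseased, dtype=float)
    if len(diseased) == 0 or len(healthy) == 0:
        raise ValueError("both score lists must be nonempty")
    pooled = np.unique(np.concatenate([diseased, healthy]))
    if len(pooled) == 1:
        raise ValueError("all scores identical; no cutpoint discriminates")
    candidates = np.concatenate([[-math.inf], (pooled[:-1] + pooled[1:]) / 2.0, [math.inf]])
    best = None
    for cut in candidates:
        sens = float((diseased >= cut).mean())
        spec = float((healthy < cut).mean())
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-12:
            best = (float(cut), j, sens, spec)
    return best


# ---------------------------------------------------------------------------
# Misclassification


def rogan_gladen_correct(
    observed_p: float,
    sensitivity: float,
    specificity: float,
) -> float:
    """True prevalence from an observed prevalence and the measure's
    sensitivity and specificity (Rogan-Gladen back-calculation).

    true = (observed - (1 - specificity)) / (sensitivity + specificity - 1),
    clamped to [0, 1] with a warning when clamping occurs.  An imperfect
    measure can distort prevalence badly: with sensitivity and specificity
    both 0.90, an observed prevalence of 12% corresponds to a true
    prevalence of only 2.5%.
    """
    for name, v in (("observed_p", observed_p), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = sensitivity + specificity - 1
    if denom == 0:
        raise ValueError("sensitivity + specificity = 1: prevalence is not identifiable")
    corrected = (observed_p - (1 - specificity)) / denom
    if corrected < 0 or corrected > 1:
        warnings.warn(
            f"corrected prevalence {corrected:.4f} clamped to [0, 1]; the observed "
            "prevalence is inconsistent with the stated sensitivity/specificity",
            stacklevel=2,
        )
        corrected = min(1.0, max(0.0, corrected))
    return corrected


def misclassification_adjusted_rr(
    observed_p1: float,
    observed_p2: float,
    sensitivity: float,
    specificity: float,
) -> Estimate:
    """Risk ratio corrected for nondifferential outcome misclassification.

    Each observed risk is back-corrected by Rogan-Gladen and the ratio of
    corrected risks returned.  Flags record when a corrected risk had to be
    clamped to [0, 1] (the ratio is then boundary-driven).
    """
    flags: tuple[str, ...] = ()
    corrected = []
    for p in (observed_p1, observed_p2):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            value = rogan_gladen_correct(p, sensitivity, specificity)
        if caught:
            flags += ("clamped",)
        corrected.append(value)
    p1c, p2c = corrected
    if p2c == 0:
        return Estimate(math.inf, Scale.ratio, (), "rogan-gladen corrected RR",
                        flags + ("upper_unbounded",))
    return Estimate(p1c / p2c, Scale.ratio, (), "rogan-gladen corrected RR", flags)


# ---------------------------------------------------------------------------
# Proportion confidence intervals


_PROPORTION_METHODS = {
    "wald": "normal",
    "wilson": "wilson",
    "clopper_pearson": "beta",
    "agresti_coull": "agresti_coull",
}


def proportion_ci(
    x: int,
    n: int,
    method: str = "wilson",
    level: float = 0.95,
) -> Estimate:
    """Confidence interval for a binomial proportion x/n.

    Methods: wald, wilson (score), clopper_pearson (exact), agresti_coull.
    Bounds are clamped to [0, 1].
    """
    if int(x) != x or int(n) != n:
        raise ValueError("x and n must be integers")
    x, n = int(x), int(n)
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if method not in _PROPORTION_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_PROPORTION_METHODS)}")
    lo, hi = proportion_confint(x, n, alpha=1 - level, method=_PROPORTION_METHODS[method])
    lo = 0.0 if (math.isnan(lo) or lo < 0) else float(lo)
    hi = 1.0 if (math.isnan(hi) or hi > 1) else float(hi)
    return Estimate(x / n, Scale.probability, (ConfInt(level, lo, hi),), method)
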