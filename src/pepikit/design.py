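"""Sample-size and power calculation.

Classical normal-approximation formulas for comparing two independent
proportions (with Fleiss's continuity correction as an option), for the
McNemar matched-pairs test (Connor's formula on the discordant
proportions), for detecting a change in kappa between two raters of a
dichotomous trait (goodness-of-fit noncentrality under the
common-correlation agreement model), and for comparing two means.  Sample
sizes are rounded up and reported with the power achieved at the returned
integer n.
"""

from __future__ import annotations

import math

from scipy import stats

from .results import DesignResult, Sidedness


def _alpha_z(alpha: float, sidedness: Sidedness) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.norm.isf(alpha / 2 if sidedness is Sidedness.two else alpha))


def _beta_z(power: float) -> float:
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    return float(stats.norm.isf(1 - power))


def power_two_proportions(
    n_per_group: int,
    p1: float,
    p2: float,
    alpha: float = 0.05,
    sidedness: Sidedness | str = Sidedness.two,
) -> float:
    """Normal-approximation power of the two-proportion z test at n per group.

    Both rejection tails are counted for the two-sided test, so the power
    at p1 = p2 equals alpha.
    """
    sidedness = Sidedness(sidedness)
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    z_a = _alpha_z(alpha, sidedness)
    sd = math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
    if sd == 0:
        return 1.0 if p1 != p2 else alpha
    shift = (p1 - p2) * math.sqrt(n_per_group) / sd
    power = float(stats.norm.cdf(abs(shift) - z_a))
    if sidedness is Sidedness.two:
        power += float(stats.norm.cdf(-abs(shift) - z_a))
    return min(1.0, power)


def _minimal_n(n_start: int, power_fn, target: float, floor: int = 2) -> int:
    """Smallest integer n >= floor with power_fn(n) >= target."""
    n = max(floor, n_start)
    while power_fn(n) < target:
        n += 1
    while n > floor and power_fn(n - 1) >= target:
        n -= 1
    return n


def sample_size_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sidedness: Sidedness | str = Sidedness.two,
    continuity_correction: bool = False,
) -> DesignResult:
    """Per-group n for detecting p1 vs p2 with the two-proportion z test.

    n = (z_alpha + z_beta)^2 (p1 q1 + p2 q2) / (p1 - p2)^2, rounded up to
    the smallest integer whose normal-approximation power meets the target.
    ``continuity_correction`` applies Fleiss's adjustment
    n' = (n/4)(1 + sqrt(1 + 4 / (n |p1 - p2|)))^2.
    """
    sidedness = Sidedness(sidedness)
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be strictly between 0 and 1")
    if p1 == p2:
        raise ValueError("p1 = p2: no difference to detect (infinite n)")
    z_a = _alpha_z(alpha, sidedness)
    z_b = _beta_z(power)
    delta = abs(p1 - p2)
    n_raw = (z_a + z_b) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2)) / delta**2
    if continuity_correction:
        n_cc = (n_raw / 4.0) * (1 + math.sqrt(1 + 4 / (n_raw * delta))) ** 2
        n = math.ceil(n_cc - 1e-9)
        achieved = power_two_proportions(n, p1, p2, alpha, sidedness)
    else:
        n = _minimal_n(math.ceil(n_raw - 1e-9),
                       lambda m: power_two_proportions(m, p1, p2, alpha, sidedness),
                       power)
        achieved = power_two_proportions(n, p1, p2, alpha, sidedness)
    return DesignResult(
        n, achieved, alpha, sidedness, "two-proportion z approximation"
        + (" with Fleiss continuity correction" if continuity_correction else ""),
        {"p1": p1, "p2": p2, "alpha": alpha, "power": power,
         "sidedness": sidedness.value, "continuity_correction": continuity_correction},
    )


def power_mcnemar(
    n_pairs: int,
    p_discordant_10: float,
    p_discordant_01: float,
    alpha: float = 0.05,
    sidedness: Sidedness | str = Sidedness.two,
) -> float:
    """Normal-approximation power of McNemar's test at ``n_pairs`` pairs
    (Connor 1987)."""
    sidedness = Sidedness(sidedness)
    psi = p_discordant_10 + p_discordant_01
    delta = p_discordant_10 - p_discordant_01
    if psi <= 0:
        raise ValueError("discordant probabilities sum to zero")
    z_a = _alpha_z(alpha, sidedness)
    num = abs(delta) * math.sqrt(n_pairs) - z_a * math.sqrt(psi)
    den = math.sqrt(psi - delta**2)
    if den <= 0:
        return 1.0
    return float(stats.norm.cdf(num / den))


def sample_size_mcnemar(
    p_discordant_10: float,
    p_discordant_01: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sidedness: Sidedness | str = Sidedness.two,
) -> DesignResult:
    """Number of pairs for McNemar's test (Connor 1987).

    ``p_discordant_10`` and ``p_discordant_01`` are the two discordant-pair
    probabilities.  n = [z_alpha sqrt(psi) + z_beta sqrt(psi - delta^2)]^2
    / delta^2 with psi their sum and delta their difference, rounded up.
    """
    sidedness = Sidedness(sidedness)
    p10, p01 = p_discordant_10, p_discordant_01
    for name, p in (("p_discordant_10", p10), ("p_discordant_01", p01)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if p10 + p01 > 1:
        raise ValueError("discordant probabilities sum to more than 1")
    if p10 == p01:
        raise ValueError("equal discordant probabilities: no effect to detect")
    psi = p10 + p01
    delta = abs(p10 - p01)
    z_a = _alpha_z(alpha, sidedness)
    z_b = _beta_z(power)
    n_raw = (z_a * math.sqrt(psi) + z_b * math.sqrt(psi - delta**2)) ** 2 / delta**2
    n = _minimal_n(math.ceil(n_raw - 1e-9),
                   lambda m: power_mcnemar(m, p10, p01, alpha, sidedness), power)
    achieved = power_mcnemar(n, p10, p01, alpha, sidedness)
    return DesignResult(
        n, achieved, alpha, sidedness, "mcnemar (Connor approximation)",
        {"p_discordant_10": p10, "p_discordant_01": p01, "alpha": alpha,
         "power": power, "sidedness": sidedness.value},
    )


def kappa_cell_probabilities(kappa: float, prevalence: float) -> tuple[float, float, float]:
    """(both positive, discordant, both negative) probabilities for two
    raters of a dichotomous trait under the common-correlation model."""
    pi = prevalence
    p11 = pi**2 + pi * (1 - pi) * kappa
    pd = 2 * pi * (1 - pi) * (1 - kappa)
    p00 = (1 - pi) ** 2 + pi * (1 - pi) * kappa
    if min(p11, pd, p00) < 0:
        raise ValueError(f"kappa {kappa} infeasible at prevalence {prevalence}")
    return p11, pd, p00


def sample_size_kappa(
    kappa_null: float,
    kappa_alt: float,
    trait_prevalence: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> DesignResult:
    """Subjects needed to detect kappa_alt against H0: kappa = kappa_null
    for two raters of a dichotomous trait.

    Under the common-correlation agreement model the (both-positive,
    discordant, both-negative) probabilities are determined by kappa and
    the trait prevalence; the goodness-of-fit chi-square of those three
    cells against H0 has noncentrality n * sum (p1_i - p0_i)^2 / p0_i, and
    n is chosen so that noncentrality reaches (z_alpha/2 + z_beta)^2.
    """
    for name, k in (("kappa_null", kappa_null), ("kappa_alt", kappa_alt)):
        if not 0 <= k < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if not 0 < trait_prevalence < 1:
        raise ValueError("trait_prevalence must be strictly between 0 and 1")
    if kappa_null == kappa_alt:
        raise ValueError("kappa_null = kappa_alt: no difference to detect")
    p0 = kappa_cell_probabilities(kappa_null, trait_prevalence)
    p1 = kappa_cell_probabilities(kappa_alt, trait_prevalence)
    effect = sum((b - a) ** 2 / a for a, b in zip(p0, p1) if a > 0)
    z_a = _alpha_z(alpha, Sidedness.two)
    z_b = _beta_z(power)
    n = math.ceil((z_a + z_b) ** 2 / effect - 1e-9)
    n = max(2, n)
    lam = n * effect
    achieved = float(stats.ncx2.sf(stats.chi2.isf(alpha, 1), 1, lam))
    return DesignResult(
        n, achieved, alpha, Sidedness.two, "kappa (goodness-of-fit noncentrality)",
        {"kappa_null": kappa_null, "kappa_alt": kappa_alt,
         "trait_prevalence": trait_prevalence, "alpha": alpha, "power": power},
    )


def power_mean_difference(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    sidedness: Sidedness | str = Sidedness.two,
) -> float:
    """Normal-approximation power of the two-sample z test for means."""
    sidedness = Sidedness(sidedness)
    z_a = _alpha_z(alpha, sidedness)
    shift = abs(delta) / (sd * math.sqrt(2.0 / n_per_group))
    power = float(stats.norm.cdf(shift - z_a))
    if sidedness is Sidedness.two:
        power += float(stats.norm.cdf(-shift - z_a))
    return min(1.0, power)


def sample_size_mean_difference(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sidedness: Sidedness | str = Sidedness.two,
) -> DesignResult:
    """Per-group n for detecting a mean difference ``delta`` at common SD.

    n = 2 sd^2 (z_alpha + z_beta)^2 / delta^2, rounded up to the smallest
    integer meeting the power target.
    """
    sidedness = Sidedness(sidedness)
    if delta == 0:
        raise ValueError("delta = 0: no difference to detect")
    if sd <= 0:
        raise ValueError("sd must be positive")
    z_a = _alpha_z(alpha, sidedness)
    z_b = _beta_z(power)
    n_raw = 2.0 * sd**2 * (z_a + z_b) ** 2 / delta**2
    n = _minimal_n(math.ceil(n_raw - 1e-9),
                   lambda m: power_mean_difference(m, delta, sd, alpha, sidedness), power)
    achieved = power_mean_difference(n, delta, sd, alpha, sidedness)
    return DesignResult(
        n, achieved, alpha, sidedness, "two-sample z approximation for means",
        {"delta": delta, "sd": sd, "alpha": alpha, "power": power,
         "sidedness": sidedness.value},
    )
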