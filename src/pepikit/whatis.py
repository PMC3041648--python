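"""Ready-reckoner utilities.

Conversions between P values and the z, t, chi-square and F statistics
that produced them; Bayesian calibration of a P value into a minimum Bayes
factor and minimum posterior probability of the null; and five procedures
for adjusting P values from multiple significance tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .results import Sidedness

_TWO_TAIL_DISTS = ("z", "t")
_UPPER_TAIL_DISTS = ("chi2", "f")


def _frozen(dist: str, df1: float | None, df2: float | None):
    if dist == "z":
        return stats.norm()
    if dist == "t":
        if df1 is None or df1 <= 0:
            raise ValueError("t distribution needs df1 > 0")
        return stats.t(df1)
    if dist == "chi2":
        if df1 is None or df1 <= 0:
            raise ValueError("chi-square distribution needs df1 > 0")
        return stats.chi2(df1)
    if dist == "f":
        if df1 is None or df1 <= 0 or df2 is None or df2 <= 0:
            raise ValueError("F distribution needs df1 > 0 and df2 > 0")
        return stats.f(df1, df2)
    raise ValueError(f"unknown distribution {dist!r}; choose z, t, chi2 or f")


def p_from_statistic(
    stat: float,
    dist: str = "z",
    df1: float | None = None,
    df2: float | None = None,
    sidedness: Sidedness | str = Sidedness.two,
) -> float:
    """P value for an observed statistic.

    z and t are two-sided by default (one-sided gives the upper tail);
    chi-square and F are upper-tail only, whatever ``sidedness`` says.
    """
    frozen = _frozen(dist, df1, df2)
    if dist in _UPPER_TAIL_DISTS:
        if stat < 0:
            raise ValueError(f"{dist} statistic must be nonnegative")
        return float(frozen.sf(stat))
    sidedness = Sidedness(sidedness)
    if sidedness is Sidedness.two:
        return float(2.0 * frozen.sf(abs(stat)))
    return float(frozen.sf(stat))


def statistic_from_p(
    p: float,
    dist: str = "z",
    df1: float | None = None,
    df2: float | None = None,
    sidedness: Sidedness | str = Sidedness.two,
) -> float:
    """The statistic whose P value (per :func:`p_from_statistic`) is ``p``."""
    if not 0 < p < 1:
        raise ValueError(f"p must be strictly between 0 and 1, got {p}")
    frozen = _frozen(dist, df1, df2)
    if dist in _UPPER_TAIL_DISTS:
        return float(frozen.isf(p))
    sidedness = Sidedness(sidedness)
    if sidedness is Sidedness.two:
        return float(frozen.isf(p / 2.0))
    return float(frozen.isf(p))


@dataclass(frozen=True)
class CalibratedP:
    """A P value calibrated against the Bayesian null.

    ``min_bayes_factor`` is the Sellke-Bayarri-Berger lower bound
    -e p ln(p) on the Bayes factor in favour of the null (1 for
    p >= 1/e); ``min_posterior_prob`` is the resulting minimum posterior
    probability of the null at the stated prior.
    """

    p: float
    min_bayes_factor: float
    min_posterior_prob: float
    prior_prob_null: float


def bayes_calibrate_p(p: float, prior_prob_null: float = 0.5) -> CalibratedP:
    """Minimum Bayes factor and posterior null probability for a P value.

    B(p) = -e p ln(p) for p < 1/e, else 1; the minimum posterior
    probability of the null is [1 + ((1-pi)/pi) / B]^-1 at prior pi.
    Even p = 0.05 leaves the null a posterior probability of about 0.29
    under equal priors — a caution against equating "significant" with
    "the null is improbable".
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if not 0 < prior_prob_null < 1:
        raise ValueError("prior_prob_null must be strictly between 0 and 1")
    if p >= 1 / math.e:
        bf = 1.0
    else:
        bf = -math.e * p * math.log(p)
    prior_odds_alt = (1 - prior_prob_null) / prior_prob_null
    posterior = 1.0 / (1.0 + prior_odds_alt / bf)
    return CalibratedP(p, bf, posterior, prior_prob_null)


_ADJUST_METHODS = {
    "bonferroni": "bonferroni",
    "sidak": "sidak",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "benjamini_hochberg": "fdr_bh",
}


def adjust_p_values(ps: Sequence[float], method: str = "holm") -> list[float]:
    """Adjust P values from multiple significance tests.

    Methods: bonferroni, sidak, holm (step-down), hochberg (step-up), and
    benjamini_hochberg (false-discovery-rate control).  Adjusted values are
    returned in the input order, capped at 1.
    """
    ps = list(ps)
    if not ps:
        raise ValueError("need at least one P value")
    for p in ps:
        if not 0 <= p <= 1:
            raise ValueError(f"P value outside [0, 1]: {p}")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_ADJUST_METHODS)}")
    _, adjusted, _, _ = multipletests(ps, alpha=0.05, method=_ADJUST_METHODS[method],
                                      is_sorted=False)
    return [float(min(1.0, v)) for v in adjusted]
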