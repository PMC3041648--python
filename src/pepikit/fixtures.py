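"""Seeded synthetic-data generator for tests and demonstrations.

Each generator draws a dataset of one of the package's input kinds from a
fully specified probability model and returns it together with a ``truth``
record of the generating parameters, so estimator behaviour can be checked
against known values.  Identical spec + seed always reproduce the same
dataset (all randomness flows through one ``numpy`` generator).

The ``stratified_confounded`` kind couples exposure prevalence to a
stratum-specific baseline risk so that the crude odds ratio differs from
the common within-stratum odds ratio — the classic confounding structure a
Mantel-Haenszel analysis is meant to undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .design import kappa_cell_probabilities
from .tables import (
    GroupedNumericSamples,
    OrderedTwoByK,
    PairedDichotomousTable,
    PairedNumericSeries,
    RatingMatrix,
    StratifiedTwoByTwo,
    TwoByTwoTable,
)

KINDS = (
    "two_by_two",
    "stratified_confounded",
    "ordered_two_by_k",
    "ratings",
    "paired_dichotomous",
    "paired_numeric",
    "grouped_numeric",
    "diagnostic_scores",
)


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: a kind, its parameters, and a seed."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")


@dataclass(frozen=True)
class Fixture:
    """A generated dataset plus the parameters that generated it."""

    spec: FixtureSpec
    data: Any
    truth: dict


def _check_prob(value: float, name: str) -> float:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return float(value)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Draw the dataset described by ``spec`` (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    params = dict(spec.parameters)
    generator = _GENERATORS[spec.kind]
    data, truth = generator(rng, params)
    if params:
        raise ValueError(f"unused parameters for kind {spec.kind!r}: {sorted(params)}")
    return Fixture(spec, data, truth)


def _two_by_two(rng, params):
    p1 = _check_prob(params.pop("p1", 0.3), "p1")
    p2 = _check_prob(params.pop("p2", 0.3), "p2")
    n1 = int(params.pop("n1", 100))
    n2 = int(params.pop("n2", 100))
    a = int(rng.binomial(n1, p1))
    c = int(rng.binomial(n2, p2))
    table = TwoByTwoTable(a, n1 - a, c, n2 - c)
    odds1, odds2 = p1 / (1 - p1) if p1 < 1 else np.inf, p2 / (1 - p2) if p2 < 1 else np.inf
    return table, {"p1": p1, "p2": p2, "n1": n1, "n2": n2,
                   "true_or": odds1 / odds2 if odds2 > 0 else np.inf,
                   "true_rr": p1 / p2 if p2 > 0 else np.inf}


def _stratified_confounded(rng, params):
    """Two strata, common within-stratum OR, exposure prevalence coupled to
    a stratum-specific baseline odds so the crude OR is confounded."""
    stratum_or = float(params.pop("stratum_or", 4.0))
    n_per_stratum = int(params.pop("n_per_stratum", 1000))
    exposure_prev = tuple(params.pop("exposure_prevalence", (0.8, 0.2)))
    baseline_odds = tuple(params.pop("baseline_odds", (0.5, 0.05)))
    if len(exposure_prev) != len(baseline_odds):
        raise ValueError("exposure_prevalence and baseline_odds must align")
    strata = []
    for i, (prev, odds0) in enumerate(zip(exposure_prev, baseline_odds)):
        _check_prob(prev, "exposure_prevalence")
        n_exp = int(rng.binomial(n_per_stratum, prev))
        n_unexp = n_per_stratum - n_exp
        odds1 = odds0 * stratum_or
        p_exp = odds1 / (1 + odds1)
        p_unexp = odds0 / (1 + odds0)
        a = int(rng.binomial(n_exp, p_exp)) if n_exp else 0
        c = int(rng.binomial(n_unexp, p_unexp)) if n_unexp else 0
        strata.append((f"stratum{i + 1}", TwoByTwoTable(a, n_exp - a, c, n_unexp - c)))
    data = StratifiedTwoByTwo(tuple(strata))
    return data, {"stratum_or": stratum_or, "n_per_stratum": n_per_stratum,
                  "exposure_prevalence": exposure_prev, "baseline_odds": baseline_odds}


def _ordered_two_by_k(rng, params):
    probs1 = np.asarray(params.pop("probs1", (0.4, 0.3, 0.2, 0.1)), dtype=float)
    probs2 = np.asarray(params.pop("probs2", (0.1, 0.2, 0.3, 0.4)), dtype=float)
    n1 = int(params.pop("n1", 100))
    n2 = int(params.pop("n2", 100))
    for name, pr in (("probs1", probs1), ("probs2", probs2)):
        if np.any(pr < 0) or not np.isclose(pr.sum(), 1.0):
            raise ValueError(f"{name} must be nonnegative and sum to 1")
    if len(probs1) != len(probs2):
        raise ValueError("probs1 and probs2 must have equal length")
    row1 = rng.multinomial(n1, probs1)
    row2 = rng.multinomial(n2, probs2)
    data = OrderedTwoByK(tuple(int(v) for v in row1), tuple(int(v) for v in row2))
    return data, {"probs1": tuple(probs1), "probs2": tuple(probs2), "n1": n1, "n2": n2}


def _ratings(rng, params):
    """Two raters of a dichotomous trait under the common-correlation model
    with a target kappa."""
    kappa = float(params.pop("kappa", 0.6))
    prevalence = _check_prob(params.pop("prevalence", 0.5), "prevalence")
    n = int(params.pop("n", 100))
    p11, pd, p00 = kappa_cell_probabilities(kappa, prevalence)
    cells = rng.multinomial(n, [p11, pd / 2, pd / 2, p00])
    pairs = ([(2, 2)] * cells[0] + [(2, 1)] * cells[1]
             + [(1, 2)] * cells[2] + [(1, 1)] * cells[3])
    rng.shuffle(pairs)
    data = RatingMatrix(np.array(pairs, dtype=float))
    return data, {"kappa": kappa, "prevalence": prevalence, "n": n}


def _paired_dichotomous(rng, params):
    p_both = _check_prob(params.pop("p_both", 0.4), "p_both")
    p10 = _check_prob(params.pop("p10", 0.15), "p10")
    p01 = _check_prob(params.pop("p01", 0.05), "p01")
    n = int(params.pop("n", 100))
    p_neither = 1 - p_both - p10 - p01
    if p_neither < 0:
        raise ValueError("cell probabilities sum to more than 1")
    e, f, g, h = rng.multinomial(n, [p_both, p10, p01, p_neither])
    data = PairedDichotomousTable(int(e), int(f), int(g), int(h))
    return data, {"p_both": p_both, "p10": p10, "p01": p01, "n": n,
                  "true_matched_or": p10 / p01 if p01 > 0 else np.inf}


def _paired_numeric(rng, params):
    n = int(params.pop("n", 50))
    bias = float(params.pop("bias", 0.0))
    sd_subject = float(params.pop("sd_subject", 1.0))
    sd_error = float(params.pop("sd_error", 0.2))
    true = rng.normal(0.0, sd_subject, size=n)
    x = true + rng.normal(0.0, sd_error, size=n)
    y = true - bias + rng.normal(0.0, sd_error, size=n)
    data = PairedNumericSeries(x, y)
    return data, {"n": n, "bias": bias, "sd_subject": sd_subject, "sd_error": sd_error,
                  "true_loa_sd": float(np.sqrt(2) * sd_error)}


def _grouped_numeric(rng, params):
    means = tuple(params.pop("means", (0.0, 0.5, 1.0)))
    sds = tuple(params.pop("sds", (1.0,) * len(means)))
    ns = tuple(params.pop("ns", (30,) * len(means)))
    if not len(means) == len(sds) == len(ns):
        raise ValueError("means, sds and ns must align")
    groups = tuple(rng.normal(m, s, size=int(n)) for m, s, n in zip(means, sds, ns))
    data = GroupedNumericSamples(groups)
    return data, {"means": means, "sds": sds, "ns": ns}


def _diagnostic_scores(rng, params):
    """Binormal diagnostic-marker model: diseased scores shifted up by
    ``separation`` standard deviations."""
    separation = float(params.pop("separation", 2.0))
    n_diseased = int(params.pop("n_diseased", 100))
    n_nondiseased = int(params.pop("n_nondiseased", 100))
    diseased = rng.normal(separation, 1.0, size=n_diseased)
    healthy = rng.normal(0.0, 1.0, size=n_nondiseased)
    return (diseased, healthy), {
        "separation": separation, "n_diseased": n_diseased,
        "n_nondiseased": n_nondiseased,
        # J of the binormal model is maximized at the midpoint separation/2
        "optimal_cutpoint": separation / 2.0,
    }


_GENERATORS = {
    "two_by_two": _two_by_two,
    "stratified_confounded": _stratified_confounded,
    "ordered_two_by_k": _ordered_two_by_k,
    "ratings": _ratings,
    "paired_dichotomous": _paired_dichotomous,
    "paired_numeric": _paired_numeric,
    "grouped_numeric": _grouped_numeric,
    "diagnostic_scores": _diagnostic_scores,
}
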