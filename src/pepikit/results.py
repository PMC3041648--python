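"""Shared result containers.

Every analytical routine in the package returns either an :class:`Estimate`
(a point estimate with one or more confidence intervals), a
:class:`TestResult` (a test statistic with its reference distribution and
P value), or a small dataclass composed of the two.  Both carry a ``flags``
tuple of short machine-readable strings ("zero_cell_correction",
"upper_unbounded", ...) so callers can detect boundary handling without
parsing text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator


class Scale(str, Enum):
    """What kind of quantity an :class:`Estimate` carries."""

    ratio = "ratio"
    difference = "difference"
    rate = "rate"
    probability = "probability"


class Sidedness(str, Enum):
    one = "one"
    two = "two"


@dataclass(frozen=True)
class ConfInt:
    """A single confidence interval at ``level`` (e.g. 0.95)."""

    level: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"confidence level must be in (0, 1), got {self.level}")
        if self.low > self.high and not (math.isnan(self.low) or math.isnan(self.high)):
            raise ValueError(f"interval bounds out of order: ({self.low}, {self.high})")

    def __iter__(self) -> Iterator[float]:
        return iter((self.low, self.high))

    @property
    def width(self) -> float:
        return self.high - self.low

    def __contains__(self, value: object) -> bool:
        return isinstance(value, (int, float)) and self.low <= value <= self.high


@dataclass(frozen=True)
class Estimate:
    """A point estimate with confidence intervals.

    ``point`` may be ``math.inf`` for unbounded ratio measures (a zero
    denominator without continuity correction); the accompanying flag is
    "upper_unbounded" or "lower_unbounded" and only the informative bound
    of the interval is finite.
    """

    point: float
    scale: Scale
    intervals: tuple[ConfInt, ...] = ()
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        levels = [ci.level for ci in self.intervals]
        if len(set(levels)) != len(levels):
            raise ValueError("duplicate confidence levels in Estimate")

    def ci(self, level: float = 0.95) -> ConfInt:
        """Return the interval at ``level`` (exact match required)."""
        for interval in self.intervals:
            if math.isclose(interval.level, level):
                return interval
        raise KeyError(f"no {level:.0%} interval available (have {[c.level for c in self.intervals]})")

    def with_flags(self, *flags: str) -> "Estimate":
        return replace(self, flags=self.flags + flags)


@dataclass(frozen=True)
class TestResult:
    """A significance-test outcome."""

    statistic: float
    df: float | None
    p_value: float
    sidedness: Sidedness = Sidedness.two
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1e-12 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        object.__setattr__(self, "p_value", min(1.0, max(0.0, self.p_value)))


@dataclass(frozen=True)
class DesignResult:
    """A sample-size / power answer together with the inputs that produced it.

    ``n`` is per group for two-sample designs and the number of pairs (or
    subjects) for matched designs; it is the smallest integer meeting the
    power target under the stated approximation.  ``assumptions`` echoes
    every input verbatim, so a result is auditable on its own.
    """

    n: int
    achieved_power: float
    alpha: float
    sidedness: Sidedness
    method: str
    assumptions: dict = field(default_factory=dict)

    @property
    def n_per_group(self) -> int:
        return self.n

    @property
    def n_pairs(self) -> int:
        return self.n
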