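"""Validated input containers for summary data.

Epidemiological "ready reckoner" analyses start from small summary tables —
2x2 cross-classifications, stratified sets of them, paired-dichotomous
counts, rating matrices, stratum event/population counts — rather than from
individual records.  These classes validate such inputs once, at
construction, so every downstream routine can assume a well-formed table.

Counts are validated as integers at construction.  Continuity-corrected
copies (see :func:`continuity_corrected`) carry real-valued cells and are
marked ``corrected=True`` so that exact tests can refuse them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np


class Orientation(str, Enum):
    """What the rows and columns of a 2x2 table mean.

    ``exposure_outcome``: rows exposed / unexposed, columns cases / non-cases.
    ``test_disease``: rows test-positive / test-negative, columns diseased /
    non-diseased (so a = true positives, b = false negatives, c = false
    positives, d = true negatives).
    """

    exposure_outcome = "exposure_outcome"
    test_disease = "test_disease"


def _check_count(value: float, name: str, *, allow_real: bool = False) -> float:
    if isinstance(value, bool):
        raise ValueError(f"cell {name} must be a number, got bool")
    if not isinstance(value, (int, float, np.integer, np.floating)):
        raise ValueError(f"cell {name} must be a number, got {type(value).__name__}")
    value = float(value)
    if math.isnan(value) or value < 0:
        raise ValueError(f"cell {name} must be nonnegative, got {value}")
    if not allow_real and value != int(value):
        raise ValueError(f"cell {name} must be an integer count, got {value}")
    return value


@dataclass(frozen=True)
class TwoByTwoTable:
    """A 2x2 cross-classification with cells ::

        a  b     (row 1: exposed, or test-positive)
        c  d     (row 2: unexposed, or test-negative)

    ``corrected`` marks tables produced by :func:`continuity_corrected`;
    their cells may be non-integral and exact (conditional) procedures
    refuse them.
    """

    a: float
    b: float
    c: float
    d: float
    orientation: Orientation = Orientation.exposure_outcome
    corrected: bool = False

    def __post_init__(self) -> None:
        for name in "abcd":
            value = _check_count(getattr(self, name), name, allow_real=self.corrected)
            object.__setattr__(self, name, value)
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if self.total < 1:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[float, float]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[float, float]:
        return (self.a + self.c, self.b + self.d)

    @property
    def has_zero_cell(self) -> bool:
        return 0 in self.cells

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def build_2x2(
    a: int,
    b: int,
    c: int,
    d: int,
    orientation: Orientation | str = Orientation.exposure_outcome,
) -> TwoByTwoTable:
    """Validate four cell counts into a :class:`TwoByTwoTable`."""
    return TwoByTwoTable(a, b, c, d, orientation=Orientation(orientation))


class CorrectionRule(str, Enum):
    always = "always"
    only_if_zero_cell = "only_if_zero_cell"


def continuity_corrected(
    table: TwoByTwoTable,
    amount: float = 0.5,
    rule: CorrectionRule | str = CorrectionRule.only_if_zero_cell,
) -> TwoByTwoTable:
    """Return a copy of ``table`` with ``amount`` added to every cell.

    The default (Haldane–Anscombe) policy adds 0.5 to all four cells only
    when some cell is zero; it is applied by log-scale interval methods,
    never by exact tests.  The returned table is marked ``corrected`` unless
    nothing was added and the input was uncorrected.
    """
    rule = CorrectionRule(rule)
    if amount < 0:
        raise ValueError(f"correction amount must be nonnegative, got {amount}")
    apply = amount > 0 and (rule is CorrectionRule.always or table.has_zero_cell)
    if not apply:
        return table
    return TwoByTwoTable(
        table.a + amount,
        table.b + amount,
        table.c + amount,
        table.d + amount,
        orientation=table.orientation,
        corrected=True,
    )


@dataclass(frozen=True)
class RxCTable:
    """An r x c contingency table of counts.

    ``col_ordered`` declares the columns as ordinal (dose levels, grades),
    enabling trend and rank procedures.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()
    col_ordered: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"table must be at least 2x2, got shape {arr.shape}")
        if np.any(arr < 0) or np.any(arr != np.round(arr)) or np.any(np.isnan(arr)):
            raise ValueError("cells must be nonnegative integer counts")
        if not (arr.sum(axis=1) > 0).any() or not (arr.sum(axis=0) > 0).any():
            raise ValueError("table needs at least one nonzero row and column")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        r, c = arr.shape
        rl = tuple(self.row_labels) or tuple(f"row{i + 1}" for i in range(r))
        cl = tuple(self.col_labels) or tuple(f"col{j + 1}" for j in range(c))
        if len(rl) != r or len(cl) != c:
            raise ValueError("label lengths do not match table shape")
        object.__setattr__(self, "row_labels", rl)
        object.__setattr__(self, "col_labels", cl)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def is_square(self) -> bool:
        return self.shape[0] == self.shape[1]


@dataclass(frozen=True)
class OrderedTwoByK:
    """Two groups cross-classified over k ordered categories.

    ``scores`` assigns a numeric dose/severity value to each category for
    trend tests; the default is 1..k.
    """

    row1: tuple[int, ...]
    row2: tuple[int, ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        r1 = tuple(int(_check_count(v, f"row1[{i}]")) for i, v in enumerate(self.row1))
        r2 = tuple(int(_check_count(v, f"row2[{i}]")) for i, v in enumerate(self.row2))
        if len(r1) != len(r2):
            raise ValueError("rows must have equal length")
        if len(r1) < 2:
            raise ValueError("need at least 2 ordered categories")
        object.__setattr__(self, "row1", r1)
        object.__setattr__(self, "row2", r2)
        if self.scores is not None:
            sc = tuple(float(s) for s in self.scores)
            if len(sc) != len(r1):
                raise ValueError("scores length must match number of categories")
            object.__setattr__(self, "scores", sc)

    @property
    def k(self) -> int:
        return len(self.row1)

    @property
    def effective_scores(self) -> tuple[float, ...]:
        return self.scores if self.scores is not None else tuple(range(1, self.k + 1))

    def to_rxc(self, col_ordered: bool = True) -> RxCTable:
        return RxCTable(np.array([self.row1, self.row2]), col_ordered=col_ordered)


@dataclass(frozen=True)
class StratifiedTwoByTwo:
    """A set of 2x2 tables, one per stratum of a potential confounder."""

    strata: tuple[tuple[str, TwoByTwoTable], ...]

    def __post_init__(self) -> None:
        strata = tuple((str(label), table) for label, table in self.strata)
        if not strata:
            raise ValueError("need at least one stratum")
        labels = [label for label, _ in strata]
        if len(set(labels)) != len(labels):
            raise ValueError("stratum labels must be unique")
        for _, table in strata:
            if not isinstance(table, TwoByTwoTable):
                raise ValueError("each stratum must hold a TwoByTwoTable")
        object.__setattr__(self, "strata", strata)

    def __len__(self) -> int:
        return len(self.strata)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.strata)

    @property
    def tables(self) -> tuple[TwoByTwoTable, ...]:
        return tuple(table for _, table in self.strata)

    def collapsed(self) -> TwoByTwoTable:
        """The crude table obtained by summing over strata."""
        cells = np.sum([t.cells for t in self.tables], axis=0)
        return TwoByTwoTable(*cells)


@dataclass(frozen=True)
class PairedDichotomousTable:
    """Paired dichotomous outcomes::

                     second +   second -
        first +         e          f
        first -         g          h

    ``f`` and ``g`` are the discordant counts driving McNemar-type
    procedures; for a matched case-control study "first" is the case and
    "second" the matched control.
    """

    e: int
    f: int
    g: int
    h: int

    def __post_init__(self) -> None:
        for name in "efgh":
            object.__setattr__(self, name, int(_check_count(getattr(self, name), name)))
        if self.total < 1:
            raise ValueError("paired table must contain at least one pair")

    @property
    def total(self) -> int:
        return self.e + self.f + self.g + self.h

    @property
    def discordant(self) -> int:
        return self.f + self.g


@dataclass(frozen=True)
class RatingMatrix:
    """n subjects rated by m raters.

    For agreement statistics the entries are categorical levels 1..q; for
    intraclass correlation they are treated as numeric.  ``level_weights``
    is an optional q x q symmetric matrix of agreement weights in [0, 1]
    (1 on the diagonal) used by weighted kappa.
    """

    ratings: np.ndarray
    level_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratings, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if np.any(np.isnan(arr)):
            raise ValueError("missing ratings are not supported")
        arr.setflags(write=False)
        object.__setattr__(self, "ratings", arr)
        if self.level_weights is not None:
            w = np.asarray(self.level_weights, dtype=float)
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError("level_weights must be square")
            if not np.allclose(w, w.T):
                raise ValueError("level_weights must be symmetric")
            if not np.allclose(np.diag(w), 1.0):
                raise ValueError("level_weights diagonal must be 1")
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError("level_weights must lie in [0, 1]")
            w.setflags(write=False)
            object.__setattr__(self, "level_weights", w)

    @property
    def n_subjects(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    def levels(self) -> np.ndarray:
        return np.unique(self.ratings)


@dataclass(frozen=True)
class PairedNumericSeries:
    """Two measurements (methods or occasions) on the same subjects."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError("x and y must be 1-d and of equal length")
        if len(x) < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(np.isnan(x)) or np.any(np.isnan(y)):
            raise ValueError("missing values are not supported")
        x.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass(frozen=True)
class GroupedNumericSamples:
    """k independent samples of numeric observations."""

    groups: tuple[np.ndarray, ...]
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        groups = tuple(np.asarray(g, dtype=float) for g in self.groups)
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        for i, g in enumerate(groups):
            if g.ndim != 1 or len(g) < 2:
                raise ValueError(f"group {i + 1} needs at least 2 observations")
            if np.any(np.isnan(g)):
                raise ValueError(f"group {i + 1} contains missing values")
            g.setflags(write=False)
        object.__setattr__(self, "groups", groups)
        labels = tuple(self.group_labels) or tuple(f"group{i + 1}" for i in range(len(groups)))
        if len(labels) != len(groups):
            raise ValueError("group_labels length must match number of groups")
        object.__setattr__(self, "group_labels", labels)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)

    @property
    def n_total(self) -> int:
        return sum(self.sizes)


@dataclass(frozen=True)
class StratumCounts:
    """Events and denominators (population or person-time) per stratum."""

    labels: tuple[str, ...]
    events: tuple[float, ...]
    denominators: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(label) for label in self.labels)
        events = tuple(float(e) for e in self.events)
        denoms = tuple(float(d) for d in self.denominators)
        if not labels or len(labels) != len(events) or len(labels) != len(denoms):
            raise ValueError("labels, events and denominators must align and be nonempty")
        if len(set(labels)) != len(labels):
            raise ValueError("stratum labels must be unique")
        if any(e < 0 for e in events):
            raise ValueError("events must be nonnegative")
        if any(d <= 0 for d in denoms):
            raise ValueError("denominators must be positive")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "denominators", denoms)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(e / d for e, d in zip(self.events, self.denominators))


@dataclass(frozen=True)
class StandardPopulation:
    """A named set of positive stratum weights for direct standardization."""

    name: str
    labels: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(label) for label in self.labels)
        weights = tuple(float(w) for w in self.weights)
        if not labels or len(labels) != len(weights):
            raise ValueError("labels and weights must align and be nonempty")
        if len(set(labels)) != len(labels):
            raise ValueError("stratum labels must be unique")
        if any(w <= 0 for w in weights):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> float:
        return sum(self.weights)

    def aligned_weights(self, labels: Sequence[str]) -> tuple[float, ...]:
        """Weights reordered to ``labels``; raises naming any offenders."""
        mapping = dict(zip(self.labels, self.weights))
        missing = [label for label in labels if label not in mapping]
        if missing:
            raise ValueError(
                f"standard population '{self.name}' lacks strata: {', '.join(missing)}"
            )
        return tuple(mapping[label] for label in labels)
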