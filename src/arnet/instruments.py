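"""Scoring and categorisation of the two patient-reported instruments.

Two instruments are supported: the single-question symptom/severity item,
whose five canonical responses map one-to-one onto ARIA-style severity
categories, and the mini-RQLQ quality-of-life questionnaire, summarised by
the mean item score and binned into four impairment categories.
"""

from __future__ import annotations

import enum
import functools
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .density import percentage

__all__ = [
    "SeverityCategory",
    "QolCategory",
    "QolBins",
    "DEFAULT_QOL_BINS",
    "MiniRqlqResult",
    "CANONICAL_SEVERITY_RESPONSES",
    "classify_severity",
    "score_mini_rqlq",
    "bin_qol",
    "severity_distribution",
]

MAX_ITEM_SCORE = 6.0
DEFAULT_ITEM_COUNT = 14


def _normalise(text: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return re.sub(r"\s+", " ", text.strip()).casefold()


@functools.total_ordering
class SeverityCategory(enum.Enum):
    """Five-level severity categorisation of the single symptom question."""

    NONE = ("none", "None")
    MILD_INTERMITTENT = ("mild_intermittent", "Mild intermittent")
    MODERATE_SEVERE_INTERMITTENT = (
        "moderate_severe_intermittent",
        "Moderate to severe intermittent",
    )
    MILD_PERSISTENT = ("mild_persistent", "Mild persistent")
    MODERATE_SEVERE_PERSISTENT = (
        "moderate_severe_persistent",
        "Moderate to severe persistent",
    )

    def __init__(self, code: str, label: str) -> None:
        self.code = code
        self.label = label

    def __lt__(self, other: "SeverityCategory") -> bool:
        if not isinstance(other, SeverityCategory):
            return NotImplemented
        order = list(SeverityCategory)
        return order.index(self) < order.index(other)


#: Canonical response strings for the severity question, version 1.
CANONICAL_SEVERITY_RESPONSES: dict[str, SeverityCategory] = {
    "Never": SeverityCategory.NONE,
    "Occasionally and are of little bother": SeverityCategory.MILD_INTERMITTENT,
    "Occasionally and are quite a bother": SeverityCategory.MODERATE_SEVERE_INTERMITTENT,
    "Most days but are of little bother": SeverityCategory.MILD_PERSISTENT,
    "Most days and are a lot of bother": SeverityCategory.MODERATE_SEVERE_PERSISTENT,
}

_RESPONSE_LOOKUP = {_normalise(k): v for k, v in CANONICAL_SEVERITY_RESPONSES.items()}


@functools.total_ordering
class QolCategory(enum.Enum):
    """Quality-of-life impairment category, ordered ZERO < MILD < MOD < SEV."""

    QOL_ZERO = ("QOL_ZERO", 0)
    QOL_MILD = ("QOL_MILD", 1)
    QOL_MOD = ("QOL_MOD", 2)
    QOL_SEV = ("QOL_SEV", 3)

    def __init__(self, code: str, rank: int) -> None:
        self.code = code
        self.rank = rank

    def __lt__(self, other: "QolCategory") -> bool:
        if not isinstance(other, QolCategory):
            return NotImplemented
        return self.rank < other.rank


@dataclass(frozen=True)
class QolBins:
    """Half-open partition of the mean-score scale into the four categories.

    ``edges = (e1, e2, e3)`` means ZERO = {0}, MILD = (0, e1],
    MOD = (e1, e2], SEV = (e2, e3]; e3 must equal the scale maximum so that
    the partition is total on [0, 6].
    """

    edges: tuple[float, float, float] = (2.0, 4.0, MAX_ITEM_SCORE)

    def __post_init__(self) -> None:
        e1, e2, e3 = self.edges
        if not (0.0 < e1 < e2 < e3):
            raise ValueError(f"bin edges must be strictly increasing and positive: {self.edges}")
        if e3 != MAX_ITEM_SCORE:
            raise ValueError(f"last edge must equal the scale maximum {MAX_ITEM_SCORE}")


DEFAULT_QOL_BINS = QolBins()


@dataclass(frozen=True)
class MiniRqlqResult:
    """mini-RQLQ outcome: per-item scores (when available) and their mean."""

    mean_score: float
    item_scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_score <= MAX_ITEM_SCORE:
            raise ValueError(f"mean_score {self.mean_score} outside [0, {MAX_ITEM_SCORE}]")


def classify_severity(response: str) -> SeverityCategory:
    """Map a canonical severity-question response to its category.

    Matching is exact after whitespace normalisation and case-folding;
    unknown responses are rejected rather than fuzzily matched.
    """
    key = _normalise(response)
    try:
        return _RESPONSE_LOOKUP[key]
    except KeyError:
        known = ", ".join(repr(r) for r in CANONICAL_SEVERITY_RESPONSES)
        raise ValueError(
            f"unknown severity response {response!r}; expected one of: {known}"
        ) from None


def score_mini_rqlq(item_scores: Sequence[float]) -> MiniRqlqResult:
    """Score a completed mini-RQLQ: unrounded arithmetic mean of the items."""
    items = tuple(float(s) for s in item_scores)
    if not items:
        raise ValueError("item_scores must be non-empty")
    for i, s in enumerate(items):
        if not 0.0 <= s <= MAX_ITEM_SCORE:
            raise ValueError(f"item {i} score {s} outside [0, {MAX_ITEM_SCORE}]")
    return MiniRqlqResult(mean_score=sum(items) / len(items), item_scores=items)


def bin_qol(mean_score: float, bins: QolBins = DEFAULT_QOL_BINS) -> QolCategory:
    """Bin a mean mini-RQLQ score into its impairment category.

    Uses a continuous half-open partition (ZERO = {0}, then half-open
    intervals up to each edge) so every score in [0, 6] maps to exactly
    one category.
    """
    s = float(mean_score)
    if not 0.0 <= s <= MAX_ITEM_SCORE:
        raise ValueError(f"mean score {s} outside [0, {MAX_ITEM_SCORE}]")
    if s == 0.0:
        return QolCategory.QOL_ZERO
    e1, e2, _ = bins.edges
    if s <= e1:
        return QolCategory.QOL_MILD
    if s <= e2:
        return QolCategory.QOL_MOD
    return QolCategory.QOL_SEV


def severity_distribution(cohort: Iterable, decimals: int = 1) -> pd.DataFrame:
    """Tabulate severity counts and percentages over a cohort.

    ``cohort`` may hold Participant-like objects (with a ``severity``
    attribute) or bare :class:`SeverityCategory` values.  Rows follow the
    canonical category order; percentages use the shared rounding rule.
    """
    categories = [getattr(p, "severity", p) for p in cohort]
    if not categories:
        raise ValueError("cohort must contain at least one participant")
    for c in categories:
        if not isinstance(c, SeverityCategory):
            raise TypeError(f"not a severity category: {c!r}")
    total = len(categories)
    rows = []
    for cat in SeverityCategory:
        n = sum(1 for c in categories if c is cat)
        rows.append(
            {
                "category": cat.code,
                "label": cat.label,
                "count": n,
                "percentage": percentage(n, total, decimals),
            }
        )
    return pd.DataFrame(rows).set_index("category")
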