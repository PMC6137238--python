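"""Weighted alter-score / network-alter-density statistics and summaries.

The central statistic scores each alter by a circle-weighted count of the
participants placing it (innermost circle heaviest), then expresses each
score as a percentage of the sum of all scores in the (sub)network.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

__all__ = [
    "DEFAULT_CIRCLE_WEIGHTS",
    "percentage",
    "alter_score",
    "network_alter_density",
    "circle_composition",
    "network_size_summary",
    "NetworkSizeSummary",
]

#: Default circle weights: circle 1 (most influential) -> 4 ... circle 4 -> 1.
DEFAULT_CIRCLE_WEIGHTS: tuple[int, ...] = (4, 3, 2, 1)


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Shared percentage rule: 100*count/total, rounded half-away-from-zero.

    All printed percentages in reports go through this one function so the
    rounding convention is uniform.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError(f"count {count} outside [0, {total}]")
    exact = Decimal(str(count)) * 100 / Decimal(str(total))
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def alter_score(
    n1: int, n2: int, n3: int, n4: int, weights: Sequence[int] = DEFAULT_CIRCLE_WEIGHTS
) -> int:
    """Circle-weighted placement count for one alter.

    ``n1..n4`` count the participants who placed the alter on circles 1..4;
    the default weights are (4, 3, 2, 1).
    """
    counts = (n1, n2, n3, n4)
    if len(weights) != len(counts):
        raise ValueError("weights must have one entry per circle")
    for c in counts:
        if c < 0 or int(c) != c:
            raise ValueError(f"counts must be non-negative integers, got {counts}")
    return sum(w * int(c) for w, c in zip(weights, counts))


def _weighted_score(counts: Sequence[int], weights: Sequence[int]) -> int:
    return sum(w * int(c) for w, c in zip(weights, counts))


def network_alter_density(cohort, weights: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-alter score and density table for a cohort network.

    Density = 100 * score / sum of all scores (unrounded; round only when
    printing).  Rows are sorted by descending density, ties broken
    alphabetically by category code.
    """
    if weights is None:
        weights = tuple(range(cohort.n_circles, 0, -1))
    if len(weights) != cohort.n_circles:
        raise ValueError("weights must have one entry per circle")
    counts = cohort.placement_counts
    if not counts:
        raise ValueError("cohort has no placements")
    rows = []
    for code, ns in counts.items():
        score = _weighted_score(ns, weights)
        row = {"alter": code}
        row.update({f"n{i + 1}": int(n) for i, n in enumerate(ns)})
        row["alter_score"] = score
        rows.append(row)
    frame = pd.DataFrame(rows)
    total = frame["alter_score"].sum()
    if total <= 0:
        raise ValueError("sum of alter scores is zero")
    frame["density"] = 100.0 * frame["alter_score"] / total
    frame = frame.sort_values(
        ["density", "alter"], ascending=[False, True], kind="mergesort"
    )
    return frame.set_index("alter")


def circle_composition(cohort, circle: int, decimals: int = 0) -> pd.DataFrame:
    """Composition of one circle: per alter, the count of egos placing it
    there, the percentage of the cohort doing so, and the percentage of all
    placements on that circle.
    """
    if circle not in range(1, cohort.n_circles + 1):
        raise ValueError(f"circle must be in 1..{cohort.n_circles}, got {circle}")
    n_egos = len(cohort.egos)
    idx = circle - 1
    entries = {
        code: int(ns[idx]) for code, ns in cohort.placement_counts.items() if ns[idx] > 0
    }
    circle_total = sum(entries.values())
    rows = [
        {
            "alter": code,
            "count": n,
            "pct_of_cohort": percentage(n, n_egos, decimals),
            "pct_of_circle_placements": percentage(n, circle_total, decimals),
        }
        for code, n in entries.items()
    ]
    frame = pd.DataFrame(rows, columns=["alter", "count", "pct_of_cohort", "pct_of_circle_placements"])
    frame = frame.sort_values(["count", "alter"], ascending=[False, True], kind="mergesort")
    return frame.set_index("alter")


@dataclass(frozen=True)
class NetworkSizeSummary:
    counts: tuple[int, ...]
    minimum: int
    maximum: int
    mean: float
    median: float
    modes: tuple[int, ...]


def network_size_summary(cohort) -> NetworkSizeSummary:
    """Summarise per-ego alter counts: min, max, mean, median and mode(s).

    All modes are reported when the distribution is multimodal.
    """
    counts = tuple(len(ego.placements) for ego in cohort.egos)
    if not counts:
        raise ValueError("cohort must contain at least one ego")
    return NetworkSizeSummary(
        counts=counts,
        minimum=min(counts),
        maximum=max(counts),
        mean=sum(counts) / len(counts),
        median=float(statistics.median(counts)),
        modes=tuple(sorted(statistics.multimode(counts))),
    )
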