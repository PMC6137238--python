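"""Egocentric data model: egos, circle placements, cohort aggregation.

Each participant ("ego") nominates alters and places each on one of the
concentric circles (1 = most influential ... 4 = little influence).  A
cohort network aggregates, per alter category, how many egos placed it on
each circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .instruments import (
    DEFAULT_QOL_BINS,
    MiniRqlqResult,
    QolBins,
    QolCategory,
    SeverityCategory,
    bin_qol,
    classify_severity,
    score_mini_rqlq,
)
from .naming import AlterCategory, Taxonomy, default_taxonomy

__all__ = [
    "DEFAULT_N_CIRCLES",
    "Placement",
    "Participant",
    "CohortNetwork",
    "build_ego_network",
    "aggregate_cohort",
    "filter_by_qol",
]

DEFAULT_N_CIRCLES = 4


@dataclass(frozen=True)
class Placement:
    """One ego--alter tie: the alter category and its circle."""

    participant_id: str
    alter: AlterCategory
    circle: int


@dataclass(frozen=True)
class Participant:
    id: str
    severity: SeverityCategory
    qol: QolCategory
    rqlq: MiniRqlqResult
    placements: tuple[Placement, ...]
    age: float | None = None
    sex: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError(f"participant {self.id!r} has no placements")
        codes = [p.alter.code for p in self.placements]
        if len(set(codes)) != len(codes):
            raise ValueError(f"participant {self.id!r} has duplicate alter categories")


@dataclass(frozen=True)
class CohortNetwork:
    """A collection of egos plus per-alter circle placement counts.

    ``placement_counts[code]`` holds, for circles 1..n, the number of
    distinct egos who placed that alter there.
    """

    egos: tuple[Participant, ...]
    placement_counts: Mapping[str, tuple[int, ...]]
    n_circles: int = DEFAULT_N_CIRCLES

    @property
    def placements(self) -> tuple[Placement, ...]:
        return tuple(p for ego in self.egos for p in ego.placements)


def build_ego_network(
    record: Mapping,
    taxonomy: Taxonomy | None = None,
    qol_bins: QolBins = DEFAULT_QOL_BINS,
    n_circles: int = DEFAULT_N_CIRCLES,
) -> Participant:
    """Validate and score one participant record into a Participant.

    ``record`` needs ``participant_id``, ``severity_response``, either
    ``rqlq_items`` (sequence) or ``rqlq_mean`` (number), and ``placements``
    as an iterable of (alter label, circle) pairs.  Alter labels are
    canonicalised; if the same category appears on several circles it is
    collapsed to its innermost (most influential) placement.
    """
    taxonomy = taxonomy or default_taxonomy()
    pid = str(record["participant_id"])
    raw = list(record["placements"])
    if not raw:
        raise ValueError(f"participant {pid!r} has zero placements")

    innermost: dict[str, tuple[AlterCategory, int]] = {}
    for label, circle in raw:
        circle = int(circle)
        if circle not in range(1, n_circles + 1):
            raise ValueError(
                f"participant {pid!r}: circle must be in 1..{n_circles}, got {circle}"
            )
        cat = taxonomy.canonicalize(label)
        prior = innermost.get(cat.code)
        if prior is None or circle < prior[1]:
            innermost[cat.code] = (cat, circle)

    placements = tuple(
        Placement(participant_id=pid, alter=cat, circle=circle)
        for cat, circle in innermost.values()
    )

    if record.get("rqlq_items") is not None:
        rqlq = score_mini_rqlq(record["rqlq_items"])
    elif record.get("rqlq_mean") is not None:
        rqlq = MiniRqlqResult(mean_score=float(record["rqlq_mean"]))
    else:
        raise ValueError(f"participant {pid!r}: need rqlq_items or rqlq_mean")

    def _opt(key):
        v = record.get(key)
        return None if v is None or v == "" else v

    age = _opt("age")
    return Participant(
        id=pid,
        severity=classify_severity(record["severity_response"]),
        qol=bin_qol(rqlq.mean_score, qol_bins),
        rqlq=rqlq,
        placements=placements,
        age=float(age) if age is not None else None,
        sex=_opt("sex"),
        region=_opt("region"),
    )


def _tabulate(egos: Sequence[Participant], n_circles: int) -> dict[str, tuple[int, ...]]:
    counts: dict[str, list[int]] = {}
    for ego in egos:
        for p in ego.placements:
            counts.setdefault(p.alter.code, [0] * n_circles)[p.circle - 1] += 1
    return {code: tuple(ns) for code, ns in sorted(counts.items())}


def aggregate_cohort(
    egos: Iterable[Participant], n_circles: int = DEFAULT_N_CIRCLES
) -> CohortNetwork:
    """Aggregate ego networks into a cohort network.

    Each ego contributes at most one count per alter category (guaranteed
    by the Participant invariant); duplicate participant ids are rejected.
    """
    egos = tuple(egos)
    if not egos:
        raise ValueError("cohort must contain at least one ego")
    ids = [e.id for e in egos]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate participant ids: {dupes}")
    for ego in egos:
        for p in ego.placements:
            if p.circle not in range(1, n_circles + 1):
                raise ValueError(f"placement circle {p.circle} outside 1..{n_circles}")
    return CohortNetwork(
        egos=egos, placement_counts=_tabulate(egos, n_circles), n_circles=n_circles
    )


def filter_by_qol(cohort: CohortNetwork, category: QolCategory) -> CohortNetwork:
    """Sub-cohort of egos in one QOL category, counts re-tabulated from scratch.

    An empty subgroup is a valid (empty) result.
    """
    if not isinstance(category, QolCategory):
        raise TypeError(f"not a QOL category: {category!r}")
    subset = tuple(e for e in cohort.egos if e.qol is category)
    return CohortNetwork(
        egos=subset,
        placement_counts=_tabulate(subset, cohort.n_circles),
        n_circles=cohort.n_circles,
    )
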