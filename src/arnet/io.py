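"""Cohort-table reading/writing, the VNA network dialect, and run reports.

Cohort tables are delimited text in long format: one row per placement with
the participant-level fields repeated.  VNA documents follow a fixed
NetDraw-compatible dialect: a ``*node data`` section with header
``ID label group value`` and a ``*tie data`` section with header
``from to strength``; fields are space-delimited, labels quoted when they
contain spaces; tie strength encodes the circle (circle 1 -> 4 ... circle
4 -> 1).
"""

from __future__ import annotations

import shlex
from pathlib import Path
from typing import Sequence

import pandas as pd

from .density import (
    circle_composition,
    network_alter_density,
    network_size_summary,
    percentage,
)
from .instruments import (
    DEFAULT_QOL_BINS,
    QolBins,
    QolCategory,
    severity_distribution,
)
from .model import (
    CohortNetwork,
    Participant,
    aggregate_cohort,
    build_ego_network,
    filter_by_qol,
)
from .naming import Taxonomy, default_taxonomy, saturation_index

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_table",
    "write_cohort_table",
    "participants_from_frame",
    "cohort_frame",
    "write_vna",
    "read_vna",
    "build_report",
    "render_report_text",
]

COHORT_COLUMNS = (
    "participant_id",
    "age",
    "sex",
    "region",
    "severity_response",
    "rqlq_items",
    "rqlq_mean",
    "alter_label",
    "circle",
)

_REQUIRED = ("participant_id", "severity_response", "alter_label", "circle")
_ITEM_SEP = ";"


def _parse_items(cell: str) -> tuple[float, ...] | None:
    if cell is None or str(cell).strip() == "":
        return None
    return tuple(float(x) for x in str(cell).split(_ITEM_SEP))


def participants_from_frame(
    frame: pd.DataFrame,
    taxonomy: Taxonomy | None = None,
    qol_bins: QolBins = DEFAULT_QOL_BINS,
    n_circles: int = 4,
) -> list[Participant]:
    """Parse a long-format cohort frame into validated Participants.

    Rows are grouped by ``participant_id`` in order of first appearance;
    participant-level fields are taken from each group's first row and must
    be consistent across the group.  Errors carry 1-based data row numbers.
    """
    taxonomy = taxonomy or default_taxonomy()
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")

    records: dict[str, dict] = {}
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        pid = str(row["participant_id"]).strip()
        if not pid:
            raise ValueError(f"row {pos}: empty participant_id")
        try:
            circle = int(str(row["circle"]).strip())
        except (TypeError, ValueError):
            raise ValueError(f"row {pos}: malformed circle {row['circle']!r}") from None
        rec = records.get(pid)
        if rec is None:
            rec = {
                "participant_id": pid,
                "age": row.get("age"),
                "sex": row.get("sex"),
                "region": row.get("region"),
                "severity_response": str(row["severity_response"]),
                "rqlq_items": _parse_items(row.get("rqlq_items")),
                "rqlq_mean": row.get("rqlq_mean"),
                "placements": [],
                "_first_row": pos,
            }
            if rec["rqlq_mean"] is not None and str(rec["rqlq_mean"]).strip() == "":
                rec["rqlq_mean"] = None
            records[pid] = rec
        rec["placements"].append((str(row["alter_label"]), circle))
        rec["_last_row"] = pos

    participants = []
    for rec in records.values():
        pos = rec.pop("_first_row")
        rec.pop("_last_row", None)
        try:
            participants.append(
                build_ego_network(rec, taxonomy=taxonomy, qol_bins=qol_bins, n_circles=n_circles)
            )
        except ValueError as exc:
            raise ValueError(f"row {pos} (participant {rec['participant_id']!r}): {exc}") from None
    return participants


def read_cohort_table(
    path: str | Path,
    taxonomy: Taxonomy | None = None,
    qol_bins: QolBins = DEFAULT_QOL_BINS,
    n_circles: int = 4,
) -> list[Participant]:
    """Read and validate a delimited cohort table (CSV, long format)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return participants_from_frame(frame, taxonomy=taxonomy, qol_bins=qol_bins, n_circles=n_circles)


def _fmt_items(items: tuple[float, ...] | None) -> str:
    if items is None:
        return ""
    return _ITEM_SEP.join(f"{x:.4f}".rstrip("0").rstrip(".") for x in items)


def cohort_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    """Long-format frame for a validated participant collection."""
    rows = []
    for p in participants:
        items = p.rqlq.item_scores
        for pl in p.placements:
            rows.append(
                {
                    "participant_id": p.id,
                    "age": "" if p.age is None else (f"{p.age:g}"),
                    "sex": p.sex or "",
                    "region": p.region or "",
                    "severity_response": _severity_response(p),
                    "rqlq_items": _fmt_items(items),
                    "rqlq_mean": "" if items is not None else f"{p.rqlq.mean_score:.6g}",
                    "alter_label": pl.alter.code,
                    "circle": pl.circle,
                }
            )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def _severity_response(p: Participant) -> str:
    from .instruments import CANONICAL_SEVERITY_RESPONSES

    for response, cat in CANONICAL_SEVERITY_RESPONSES.items():
        if cat is p.severity:
            return response
    raise AssertionError("unreachable: severity category without response")


def write_cohort_table(participants: Sequence[Participant], path: str | Path) -> None:
    cohort_frame(participants).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# VNA


def _q(label: str) -> str:
    return f'"{label}"' if (" " in label or not label) else label


def _weight(circle: int, n_circles: int) -> int:
    return n_circles + 1 - circle


def _vna_lines(egos: Sequence[Participant], n_circles: int) -> list[str]:
    lines = ["*node data", "ID label group value"]
    for ego in egos:
        lines.append(f"{_q(ego.id)} {_q(ego.id)} ego 0")
    alters: dict[str, list[int]] = {}
    names: dict[str, str] = {}
    groups: dict[str, str] = {}
    for ego in egos:
        for pl in ego.placements:
            alters.setdefault(pl.alter.code, []).append(_weight(pl.circle, n_circles))
            names[pl.alter.code] = pl.alter.display_name
            groups[pl.alter.code] = pl.alter.group
    for code in sorted(alters):
        ws = alters[code]
        value = sum(ws) / len(ws)
        lines.append(f"{_q(code)} {_q(names[code])} {_q(groups[code])} {value:g}")
    lines.append("*tie data")
    lines.append("from to strength")
    for ego in egos:
        for pl in sorted(ego.placements, key=lambda p: p.alter.code):
            lines.append(f"{_q(ego.id)} {_q(pl.alter.code)} {_weight(pl.circle, n_circles)}")
    return lines


def write_vna(
    network: CohortNetwork | Participant,
    path: str | Path,
    mode: str = "aggregate",
) -> list[Path]:
    """Write a network as one or more VNA documents.

    ``aggregate`` writes a single document for the whole cohort (alter node
    value = placement-weighted mean circle weight).  ``per_ego`` treats
    ``path`` as a directory and writes ``<ego_id>.vna`` per ego, with alter
    node values equal to that ego's circle weights.  Returns the paths
    written.
    """
    if isinstance(network, Participant):
        egos: tuple[Participant, ...] = (network,)
        n_circles = 4
    else:
        egos = network.egos
        n_circles = network.n_circles
    if not egos:
        raise ValueError("cannot write a VNA document for an empty network")

    path = Path(path)
    if mode == "aggregate":
        path.write_text("\n".join(_vna_lines(egos, n_circles)) + "\n", encoding="utf-8")
        return [path]
    if mode == "per_ego":
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for ego in egos:
            p = path / f"{ego.id}.vna"
            p.write_text("\n".join(_vna_lines((ego,), n_circles)) + "\n", encoding="utf-8")
            written.append(p)
        return written
    raise ValueError(f"unknown mode {mode!r}; expected 'aggregate' or 'per_ego'")


def read_vna(path: str | Path, n_circles: int = 4) -> list[tuple[str, str, int]]:
    """Parse a VNA document back into (ego id, alter code, circle) placements.

    Strengths map back to circles (strength 4 -> circle 1, ...).  Unknown
    section headers, strengths outside the circle range, ties referencing
    undeclared nodes and documents without ties are rejected.
    """
    nodes: dict[str, str] = {}
    placements: list[tuple[str, str, int]] = []
    section = None
    expect_header = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("*"):
                name = line.lower()
                if name == "*node data":
                    section = "node"
                elif name == "*tie data":
                    section = "tie"
                else:
                    raise ValueError(f"line {lineno}: unknown section header {line!r}")
                expect_header = True
                continue
            if section is None:
                raise ValueError(f"line {lineno}: data before any section header")
            if expect_header:
                expect_header = False
                continue
            fields = shlex.split(line)
            if section == "node":
                if len(fields) != 4:
                    raise ValueError(f"line {lineno}: expected 4 node fields, got {len(fields)}")
                nodes[fields[0]] = fields[2]
            else:
                if len(fields) != 3:
                    raise ValueError(f"line {lineno}: expected 3 tie fields, got {len(fields)}")
                src, dst, strength_s = fields
                try:
                    strength = int(strength_s)
                except ValueError:
                    raise ValueError(f"line {lineno}: malformed strength {strength_s!r}") from None
                if strength not in range(1, n_circles + 1):
                    raise ValueError(
                        f"line {lineno}: strength {strength} outside 1..{n_circles}"
                    )
                for node in (src, dst):
                    if node not in nodes:
                        raise ValueError(f"line {lineno}: tie references undeclared node {node!r}")
                placements.append((src, dst, n_circles + 1 - strength))
    if not placements:
        raise ValueError(f"{path}: VNA document contains no ties")
    return placements


# ---------------------------------------------------------------------------
# Reports


def _density_rows(cohort: CohortNetwork) -> list[dict]:
    table = network_alter_density(cohort)
    total = int(table["alter_score"].sum())
    rows = []
    for code, row in table.iterrows():
        rows.append(
            {
                "alter": code,
                **{f"n{i}": int(row[f"n{i}"]) for i in range(1, cohort.n_circles + 1)},
                "alter_score": int(row["alter_score"]),
                "density": percentage(row["alter_score"], total, 1),
            }
        )
    return rows


def build_report(
    cohort: CohortNetwork,
    seed: int | None = None,
    qol_bins: QolBins = DEFAULT_QOL_BINS,
) -> dict:
    """Full structured report for a cohort: severity and QOL distributions,
    network-size summary, saturation, total and per-QOL density tables, and
    Circle-One composition (both denominators)."""
    egos = cohort.egos
    n = len(egos)
    sev = severity_distribution(egos).reset_index().to_dict("records")
    qol_rows = []
    for cat in QolCategory:
        count = sum(1 for e in egos if e.qol is cat)
        qol_rows.append(
            {"category": cat.code, "count": count, "percentage": percentage(count, n, 1)}
        )
    size = network_size_summary(cohort)
    sat_index, sat_log = saturation_index(egos)
    comp = circle_composition(cohort, 1, decimals=0).reset_index().to_dict("records")

    by_qol = {}
    for cat in QolCategory:
        sub = filter_by_qol(cohort, cat)
        by_qol[cat.code] = _density_rows(sub) if sub.egos else []

    report = {
        "meta": {
            "n_egos": n,
            "n_placements": len(cohort.placements),
            "n_circles": cohort.n_circles,
            "qol_bin_edges": list(qol_bins.edges),
            "seed": seed,
        },
        "severity_distribution": sev,
        "qol_distribution": qol_rows,
        "network_size": {
            "min": size.minimum,
            "max": size.maximum,
            "mean": size.mean,
            "median": size.median,
            "modes": list(size.modes),
        },
        "saturation": {
            "index": sat_index,
            "log": [{"participant_id": pid, "new_alters": list(new)} for pid, new in sat_log],
        },
        "density_total": _density_rows(cohort),
        "density_by_qol": by_qol,
        "circle_one_composition": comp,
    }
    return report


def _table(rows: list[dict], columns: list[str]) -> str:
    if not rows:
        return "  (empty)\n"
    widths = {c: max(len(c), *(len(str(r.get(c, ""))) for r in rows)) for c in columns}
    out = ["  " + "  ".join(c.ljust(widths[c]) for c in columns)]
    for r in rows:
        out.append("  " + "  ".join(str(r.get(c, "")).ljust(widths[c]) for c in columns))
    return "\n".join(out) + "\n"


def render_report_text(report: dict) -> str:
    """Plain-text rendering of a structured report."""
    m = report["meta"]
    parts = [
        f"Cohort: {m['n_egos']} egos, {m['n_placements']} placements"
        + (f" (seed {m['seed']})" if m.get("seed") is not None else ""),
        "",
        "Severity distribution:",
        _table(report["severity_distribution"], ["label", "count", "percentage"]),
        "QOL distribution:",
        _table(report["qol_distribution"], ["category", "count", "percentage"]),
        "Network size: "
        + f"min {report['network_size']['min']}, max {report['network_size']['max']}, "
        + f"mean {report['network_size']['mean']:.2f}, median {report['network_size']['median']:g}, "
        + f"mode(s) {report['network_size']['modes']}",
        f"Saturation index: {report['saturation']['index']}",
        "",
        "Network alter density (total):",
        _table(report["density_total"], ["alter", "n1", "n2", "n3", "n4", "alter_score", "density"]),
        "Circle One composition:",
        _table(
            report["circle_one_composition"],
            ["alter", "count", "pct_of_cohort", "pct_of_circle_placements"],
        ),
    ]
    for code, rows in report["density_by_qol"].items():
        parts.append(f"Network alter density ({code}):")
        parts.append(_table(rows, ["alter", "alter_score", "density"]))
    return "\n".join(parts)
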