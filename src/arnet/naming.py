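"""Alter taxonomy: canonicalisation of free-text labels and saturation.

The taxonomy is shipped as a versioned YAML table (``data/taxonomy.yaml``)
so a study with a different alter inventory can swap in its own file; it is
never extended at runtime.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "AlterCategory",
    "Taxonomy",
    "default_taxonomy",
    "canonicalize_alter",
    "saturation_index",
    "alter_inventory",
]

GROUPS = ("HCP", "non-HCP", "self", "media_internet")


def _normalise(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).casefold()


@dataclass(frozen=True)
class AlterCategory:
    """A canonical influence source (e.g. GP, pharmacist, own experience)."""

    code: str
    display_name: str
    group: str
    synonyms: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


class Taxonomy:
    """An ordered collection of alter categories with a synonym lookup."""

    def __init__(self, categories: Sequence[AlterCategory], version: int = 1) -> None:
        if not categories:
            raise ValueError("taxonomy must contain at least one category")
        codes = [c.code for c in categories]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate category codes in taxonomy")
        self.version = version
        self.categories: tuple[AlterCategory, ...] = tuple(categories)
        self._by_code = {c.code: c for c in self.categories}
        self._lookup: dict[str, AlterCategory] = {}
        for cat in self.categories:
            for label in (cat.code, cat.display_name, *cat.synonyms):
                key = _normalise(label)
                prior = self._lookup.get(key)
                if prior is not None and prior is not cat:
                    raise ValueError(
                        f"label {label!r} maps to both {prior.code!r} and {cat.code!r}"
                    )
                self._lookup[key] = cat

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def by_code(self, code: str) -> AlterCategory:
        return self._by_code[code]

    def canonicalize(self, raw_label: str) -> AlterCategory:
        """Resolve a raw alter label to its canonical category.

        Unmapped labels are rejected (listing the known categories) rather
        than silently bucketed.
        """
        if not raw_label or not raw_label.strip():
            raise ValueError("alter label must be non-empty")
        cat = self._lookup.get(_normalise(raw_label))
        if cat is None:
            known = ", ".join(c.code for c in self.categories)
            raise ValueError(f"unknown alter label {raw_label!r}; known categories: {known}")
        return cat

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Taxonomy":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "Taxonomy":
        cats = [
            AlterCategory(
                code=entry["code"],
                display_name=entry["display_name"],
                group=entry["group"],
                synonyms=tuple(entry.get("synonyms", ())),
            )
            for entry in doc["categories"]
        ]
        return cls(cats, version=int(doc.get("version", 1)))


_DEFAULT: Taxonomy | None = None


def default_taxonomy() -> Taxonomy:
    """The packaged taxonomy (14 canonical categories), loaded once."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("arnet").joinpath("data/taxonomy.yaml").read_text("utf-8")
        _DEFAULT = Taxonomy._from_doc(yaml.safe_load(text))
    return _DEFAULT


def canonicalize_alter(raw_label: str, taxonomy: Taxonomy | None = None) -> AlterCategory:
    """Module-level convenience wrapper around :meth:`Taxonomy.canonicalize`."""
    return (taxonomy or default_taxonomy()).canonicalize(raw_label)


def _new_alter_log(ordered_cohort: Sequence) -> list[tuple[str, tuple[str, ...]]]:
    seen: set[str] = set()
    log = []
    for ego in ordered_cohort:
        new = []
        for placement in ego.placements:
            code = placement.alter.code
            if code not in seen:
                seen.add(code)
                new.append(code)
        log.append((ego.id, tuple(new)))
    return log


def saturation_index(ordered_cohort: Sequence) -> tuple[int, list[tuple[str, tuple[str, ...]]]]:
    """Detect name-generation saturation in an interview-ordered cohort.

    Returns ``(m, log)`` where ``m`` is the 1-based index of the last
    participant to introduce a first-appearance alter category (so every
    later participant introduced none), and ``log`` records each
    participant's newly introduced category codes.  A cohort whose final
    participant still introduces a new category yields ``m == len(cohort)``.
    """
    if not ordered_cohort:
        raise ValueError("cohort must contain at least one participant")
    log = _new_alter_log(ordered_cohort)
    index = max(i + 1 for i, (_, new) in enumerate(log) if new)
    return index, log


def alter_inventory(ordered_cohort: Sequence) -> list[tuple[AlterCategory, int]]:
    """First-appearance listing: each category with the 1-based index of the
    first ego naming it, in order of first appearance."""
    if not ordered_cohort:
        raise ValueError("cohort must contain at least one participant")
    inventory: list[tuple[AlterCategory, int]] = []
    seen: set[str] = set()
    for i, ego in enumerate(ordered_cohort, start=1):
        for placement in ego.placements:
            if placement.alter.code not in seen:
                seen.add(placement.alter.code)
                inventory.append((placement.alter, i))
    return inventory
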