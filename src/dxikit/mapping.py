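"""Multi-membership diagnosis grouper.

A *mapping table* sends ICD-10-CM-shaped diagnosis codes to diagnostic items
of three kinds:

``main``
    binary main-effect items; a code may carry up to four, and broad and
    narrow items may deliberately overlap (e.g. a STEMI item alongside a
    broader acute-MI item on the same code);
``modifier``
    cross-cutting binary flags (severity, laterality, surveillance); V-Z
    codes may legally carry modifiers with no main item at all;
``scale``
    numeric severity variables (BMI bands, birth weight, coma scores) whose
    value is encoded by the diagnosis code itself.

Besides the multi-membership ``dxi`` system the same machinery hosts two
comparator styles: ``ccsr_like`` (flat, exactly one main item per code) and
``hcc_like`` (coarse categories plus dominance hierarchies that suppress
less-severe items when a more severe one is present).

Lookup falls back from an exact code match to the longest proper prefix of
at least three characters (the ICD category root), mirroring the inclusion
of nonbillable root stems in the published mapping.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .chapters import (
    CHAPTER_ABBREVS,
    CROSS_CUTTING,
    InvalidCodeError,
    canonicalize_code,
    chapter_of,
)

SYSTEM_NAMES = ("dxi", "ccsr_like", "hcc_like", "custom")
ITEM_KINDS = ("main", "modifier", "scale")
MAX_MAIN_ITEMS = 4
MIN_STEM_LEN = 3

#: Well-known scale items and their admissible value ranges; callers may
#: extend or override these via the ``scale_ranges`` argument of
#: :func:`load_mapping`.
DEFAULT_SCALE_RANGES: dict[str, tuple[float, float]] = {"BMI": (18.5, 70.0)}

MAPPING_COLUMNS = ["code", "item_id", "kind", "scale_value", "label", "chapter"]
HIERARCHY_COLUMNS = ["dominant_item", "suppressed_item"]


class MappingError(ValueError):
    """Malformed or rule-violating mapping content (carries line numbers)."""


@dataclass(frozen=True)
class DxiItem:
    item_id: str
    kind: str  # main | modifier | scale
    label: str = ""
    chapter: str = CROSS_CUTTING

    def __post_init__(self) -> None:
        if self.kind not in ITEM_KINDS:
            raise MappingError(f"unknown item kind {self.kind!r} for {self.item_id}")


@dataclass(frozen=True)
class Assignment:
    """Items assigned to one diagnosis code (or returned for a lookup)."""

    main_items: tuple[str, ...] = ()
    modifier_items: tuple[str, ...] = ()
    scale_values: tuple[tuple[str, float], ...] = ()
    source: str = "exact"  # exact | root_stem | unmapped

    @property
    def is_empty(self) -> bool:
        return not (self.main_items or self.modifier_items or self.scale_values)

    def all_item_ids(self) -> tuple[str, ...]:
        return (
            self.main_items
            + self.modifier_items
            + tuple(item for item, _ in self.scale_values)
        )


_UNMAPPED = Assignment(source="unmapped")


@dataclass
class MappingTable:
    """A validated diagnosis-to-item index with optional hierarchies."""

    system_name: str
    items: dict[str, DxiItem] = field(default_factory=dict)
    entries: dict[str, Assignment] = field(default_factory=dict)
    scale_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    hierarchy_rules: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.system_name not in SYSTEM_NAMES:
            raise MappingError(f"unknown system_name {self.system_name!r}")

    # -- lookup ---------------------------------------------------------

    def assign(self, code: str) -> Assignment:
        """Look up a code: exact, then longest root-stem prefix, else unmapped."""
        canonical = canonicalize_code(code)
        hit = self.entries.get(canonical)
        if hit is not None:
            return hit
        for cut in range(len(canonical) - 1, MIN_STEM_LEN - 1, -1):
            stem = self.entries.get(canonical[:cut])
            if stem is not None:
                return replace(stem, source="root_stem")
        return _UNMAPPED

    def apply_hierarchies(self, person_items: set[str]) -> set[str]:
        """Suppress dominated items for ``hcc_like`` systems.

        Suppression is decided against the input set in a single pass, so a
        chain a>b>c with all three present keeps only a. Non-hierarchical
        systems return the input unchanged. Idempotent.
        """
        if self.system_name != "hcc_like" or not self.hierarchy_rules:
            return set(person_items)
        suppressed = {b for a, b in self.hierarchy_rules if a in person_items}
        return set(person_items) - suppressed

    # -- summaries ------------------------------------------------------

    @property
    def main_item_ids(self) -> list[str]:
        return sorted(i for i, it in self.items.items() if it.kind == "main")

    @property
    def modifier_item_ids(self) -> list[str]:
        return sorted(i for i, it in self.items.items() if it.kind == "modifier")

    @property
    def scale_item_ids(self) -> list[str]:
        return sorted(i for i, it in self.items.items() if it.kind == "scale")

    def summarize_by_chapter(
        self, significant_items: Optional[set[str]] = None
    ) -> pd.DataFrame:
        """Per-chapter counts of codes, main items and (optionally) flagged items.

        Items are counted once, under their declared chapter; codes under the
        chapter derived from their leading range.
        """
        code_counts: Counter[str] = Counter(chapter_of(c) for c in self.entries)
        item_counts: Counter[str] = Counter()
        sig_counts: Counter[str] = Counter()
        for item_id, item in self.items.items():
            if item.kind != "main":
                continue
            item_counts[item.chapter] += 1
            if significant_items is not None and item_id in significant_items:
                sig_counts[item.chapter] += 1
        order = CHAPTER_ABBREVS + [CROSS_CUTTING]
        chapters = [
            ch for ch in order
            if code_counts.get(ch) or item_counts.get(ch) or sig_counts.get(ch)
        ]
        frame = pd.DataFrame(
            {
                "n_codes": [code_counts.get(ch, 0) for ch in chapters],
                "n_main_items": [item_counts.get(ch, 0) for ch in chapters],
            },
            index=pd.Index(chapters, name="chapter"),
        )
        if significant_items is not None:
            frame["n_significant"] = [sig_counts.get(ch, 0) for ch in chapters]
        return frame

    def validate(self) -> None:
        """Re-check table-level invariants (raises :class:`MappingError`)."""
        for code, entry in self.entries.items():
            if len(entry.main_items) > MAX_MAIN_ITEMS:
                raise MappingError(
                    f"code {code}: {len(entry.main_items)} main items exceeds "
                    f"the limit of {MAX_MAIN_ITEMS}"
                )
            if self.system_name == "ccsr_like" and len(entry.main_items) != 1:
                raise MappingError(
                    f"code {code}: ccsr_like systems require exactly one main "
                    f"item, found {len(entry.main_items)}"
                )
            for item_id in entry.all_item_ids():
                if item_id not in self.items:
                    raise MappingError(f"code {code}: unknown item {item_id!r}")
            for item_id, value in entry.scale_values:
                lo, hi = self.scale_ranges.get(item_id, (float("-inf"), float("inf")))
                if not lo <= value <= hi:
                    raise MappingError(
                        f"code {code}: scale value {value} for {item_id} "
                        f"outside declared range [{lo}, {hi}]"
                    )
        known = set(self.items)
        for dominant, suppressed in self.hierarchy_rules:
            if dominant not in known or suppressed not in known:
                raise MappingError(
                    f"hierarchy rule ({dominant}, {suppressed}) references an "
                    f"unknown item"
                )
        _check_acyclic(self.hierarchy_rules)


def _check_acyclic(rules: Sequence[tuple[str, str]]) -> None:
    adjacency: dict[str, list[str]] = {}
    for a, b in rules:
        adjacency.setdefault(a, []).append(b)
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node: str) -> None:
        color[node] = GRAY
        for nxt in adjacency.get(node, ()):  # iterative depth is tiny in practice
            state = color.get(nxt, WHITE)
            if state == GRAY:
                raise MappingError(f"hierarchy rules contain a cycle through {nxt!r}")
            if state == WHITE:
                visit(nxt)
        color[node] = BLACK

    for node in adjacency:
        if color.get(node, WHITE) == WHITE:
            visit(node)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_mapping(
    path: str | Path,
    system_name: str = "dxi",
    scale_ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    hierarchy_path: Optional[str | Path] = None,
) -> MappingTable:
    """Load and validate a mapping TSV.

    The file has a required header and one row per (code, item) with columns
    ``code, item_id, kind, scale_value, label, chapter``; ``scale_value`` is
    only meaningful for ``kind=scale`` rows and ``chapter`` may be blank for
    cross-cutting items. Duplicate (code, item) rows collapse to one. Errors
    name the offending line.
    """
    path = Path(path)
    ranges = dict(DEFAULT_SCALE_RANGES)
    if scale_ranges:
        ranges.update({k: (float(a), float(b)) for k, (a, b) in scale_ranges.items()})

    items: dict[str, DxiItem] = {}
    mains: dict[str, list[str]] = {}
    modifiers: dict[str, list[str]] = {}
    scales: dict[str, list[tuple[str, float]]] = {}

    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return MappingTable(system_name=system_name, scale_ranges=ranges)
        header = [h.strip() for h in header]
        if header[: len(MAPPING_COLUMNS)] != MAPPING_COLUMNS:
            raise MappingError(
                f"{path}: line 1: expected header {MAPPING_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(MAPPING_COLUMNS):
                row = row + [""] * (len(MAPPING_COLUMNS) - len(row))
            raw_code, item_id, kind, scale_value, label, chapter = (
                cell.strip() for cell in row[: len(MAPPING_COLUMNS)]
            )
            try:
                code = canonicalize_code(raw_code)
            except InvalidCodeError as err:
                raise MappingError(f"{path}: line {lineno}: {err}") from err
            if kind not in ITEM_KINDS:
                raise MappingError(
                    f"{path}: line {lineno}: unknown kind {kind!r} "
                    f"(expected one of {ITEM_KINDS})"
                )
            if not item_id:
                raise MappingError(f"{path}: line {lineno}: empty item_id")
            declared_chapter = chapter or (
                CROSS_CUTTING if kind != "main" else chapter_of(code)
            )
            item = DxiItem(item_id=item_id, kind=kind, label=label,
                           chapter=declared_chapter)
            seen = items.get(item_id)
            if seen is None:
                items[item_id] = item
            elif seen.kind != item.kind:
                raise MappingError(
                    f"{path}: line {lineno}: item {item_id!r} redeclared with "
                    f"kind {kind!r} (was {seen.kind!r})"
                )
            if kind == "main":
                bucket = mains.setdefault(code, [])
                if item_id not in bucket:
                    bucket.append(item_id)
                    if len(bucket) > MAX_MAIN_ITEMS:
                        raise MappingError(
                            f"{path}: line {lineno}: code {code} assigned more "
                            f"than {MAX_MAIN_ITEMS} main items"
                        )
            elif kind == "modifier":
                bucket = modifiers.setdefault(code, [])
                if item_id not in bucket:
                    bucket.append(item_id)
            else:
                try:
                    value = float(scale_value)
                except ValueError as err:
                    raise MappingError(
                        f"{path}: line {lineno}: scale row for {item_id!r} "
                        f"needs a numeric scale_value, got {scale_value!r}"
                    ) from err
                lo, hi = ranges.get(item_id, (float("-inf"), float("inf")))
                if not lo <= value <= hi:
                    raise MappingError(
                        f"{path}: line {lineno}: scale value {value} for "
                        f"{item_id!r} outside declared range [{lo}, {hi}]"
                    )
                bucket_s = scales.setdefault(code, [])
                if (item_id, value) not in bucket_s:
                    bucket_s.append((item_id, value))

    entries = {
        code: Assignment(
            main_items=tuple(mains.get(code, ())),
            modifier_items=tuple(modifiers.get(code, ())),
            scale_values=tuple(scales.get(code, ())),
            source="exact",
        )
        for code in sorted(set(mains) | set(modifiers) | set(scales))
    }
    table = MappingTable(
        system_name=system_name,
        items=items,
        entries=entries,
        scale_ranges=ranges,
    )
    if hierarchy_path is not None:
        table.hierarchy_rules = load_hierarchy(hierarchy_path)
    table.validate()
    return table


def load_hierarchy(path: str | Path) -> list[tuple[str, str]]:
    """Load dominance rules from a two-column TSV (header required)."""
    path = Path(path)
    rules: list[tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            return rules
        if header[:2] != HIERARCHY_COLUMNS:
            raise MappingError(
                f"{path}: line 1: expected header {HIERARCHY_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise MappingError(f"{path}: line {lineno}: expected two columns")
            rules.append((row[0].strip(), row[1].strip()))
    return rules


def write_mapping(table: MappingTable, path: str | Path) -> None:
    """Write a mapping TSV that :func:`load_mapping` round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MAPPING_COLUMNS)
        for code in sorted(table.entries):
            entry = table.entries[code]
            for item_id in entry.main_items:
                item = table.items[item_id]
                writer.writerow([code, item_id, "main", "", item.label, item.chapter])
            for item_id in entry.modifier_items:
                item = table.items[item_id]
                writer.writerow(
                    [code, item_id, "modifier", "", item.label, item.chapter]
                )
            for item_id, value in entry.scale_values:
                item = table.items[item_id]
                writer.writerow(
                    [code, item_id, "scale", repr(value), item.label, item.chapter]
                )


def write_hierarchy(rules: Iterable[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(HIERARCHY_COLUMNS)
        for dominant, suppressed in rules:
            writer.writerow([dominant, suppressed])


# thin functional wrappers over the table methods (stable module surface)

def assign(table: MappingTable, code: str) -> Assignment:
    return table.assign(code)


def apply_hierarchies(table: MappingTable, person_items: set[str]) -> set[str]:
    return table.apply_hierarchies(person_items)


def summarize_by_chapter(
    table: MappingTable, significant_items: Optional[set[str]] = None
) -> pd.DataFrame:
    return table.summarize_by_chapter(significant_items)
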