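"""Flattening of grouped metadata and reduction to guideline report tables.

A reporting guideline (MIAPE-MS, journal-specific requirements, or a
laboratory's own style) is expressed as a *term-matching table*: rows
mapping a display label to a path in the flattened parameter tree.  The
bundled registry (``data/term_registry.tsv``) ships a MIAPE-MS-derived
``miape`` origin and a generic ``jpr`` origin, both re-derived from the
published guideline texts, and can be extended or overridden by user TSV
files of the same layout (columns ``origin_key``, ``instrument``,
``term_label``, ``source_path``, ``display_order``, ``required``).

Paths join tree keys with ``/`` (literal separators backslash-escaped).  A
term row may give the full path or a suffix pattern: instrument classes lay
the same parameter out at different depths, and a suffix like
``Method/MS2/Top N`` covers them all.  An exact path match always wins over
suffix matching; a suffix matching several distinct values is an error, not
a guess.  Required terms with no match are reported with the explicit
absent marker ``(not recorded)`` — publication tables must show gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .model import (
    MetadataError,
    MetadataTree,
    SourceFloat,
    iter_leaves,
    join_path,
    split_path,
)

__all__ = [
    "ABSENT_MARKER",
    "AmbiguousTermError",
    "FlatTable",
    "GroupReport",
    "TermMatchingTable",
    "TermRow",
    "UnknownOriginError",
    "create_term_matching_table",
    "flatten_group",
    "match_terms",
    "unflatten",
    "value_text",
]

logger = logging.getLogger(__name__)

ABSENT_MARKER = "(not recorded)"
_REGISTRY_RESOURCE = "data/term_registry.tsv"
_REGISTRY_COLUMNS = ["origin_key", "instrument", "term_label", "source_path",
                     "display_order", "required"]


class UnknownOriginError(MetadataError):
    """The requested reporting-guideline key is not in the registry."""


class AmbiguousTermError(MetadataError):
    """A term pattern matched several paths carrying different values."""


@dataclass
class FlatTable:
    """One group's shared tree as ``(path, value)`` rows in canonical
    depth-first order; values keep their scalar types until export."""

    group_id: int
    rows: List[Tuple[str, object]] = field(default_factory=list)


@dataclass(frozen=True)
class TermRow:
    origin_key: str
    instrument: str
    term_label: str
    source_path: str
    display_order: int
    required: bool


@dataclass
class TermMatchingTable:
    """A display-ordered selection of term rows for one reporting origin."""

    origin_key: str
    rows: List[TermRow] = field(default_factory=list)


@dataclass
class GroupReport:
    """One group's publication table: ordered (label, value) rows."""

    group_id: int
    rows: List[Tuple[str, str]] = field(default_factory=list)
    file_names: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def flatten_group(shared: MetadataTree, group_id: int) -> FlatTable:
    """Flatten a shared tree into path/value rows.

    Lossless: :func:`unflatten` rebuilds the tree (keys containing the
    separator are backslash-escaped in paths).
    """
    return FlatTable(group_id=group_id,
                     rows=[(join_path(path), value)
                           for path, value in iter_leaves(shared)])


def unflatten(rows: Iterable[Tuple[str, object]]) -> MetadataTree:
    """Rebuild a tree from flattened rows (inverse of :func:`flatten_group`)."""
    tree: MetadataTree = {}
    for path, value in rows:
        keys = split_path(path)
        node = tree
        for key in keys[:-1]:
            child = node.setdefault(key, {})
            if not isinstance(child, dict):
                raise MetadataError(
                    f"path {path!r} descends through the leaf {key!r}")
            node = child
        if keys[-1] in node:
            raise MetadataError(f"duplicate flattened path {path!r}")
        node[keys[-1]] = value
    return tree


def value_text(value) -> str:
    """Human-readable rendering of a leaf for report tables."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, SourceFloat):
        return value.text
    if isinstance(value, float):
        return repr(value)
    return str(value)


# ---------------------------------------------------------------------------
# Term-matching tables
# ---------------------------------------------------------------------------

def _read_registry_frame(source) -> pd.DataFrame:
    frame = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    missing = [c for c in _REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise MetadataError(f"term table missing columns: {missing}")
    frame = frame[_REGISTRY_COLUMNS].fillna("")
    frame["display_order"] = frame["display_order"].astype(int)
    frame["required"] = frame["required"].str.lower().isin(
        ("true", "1", "yes"))
    return frame


def _bundled_registry() -> pd.DataFrame:
    with resources.files("mzmeta").joinpath(_REGISTRY_RESOURCE).open(
            "r", encoding="utf-8") as handle:
        return _read_registry_frame(handle)


def create_term_matching_table(
        instrument_list: Sequence[str],
        origin_key: str,
        user_tables: Iterable[Union[str, Path]] = (),
) -> TermMatchingTable:
    """Build the guideline filter for the requested origin and instruments.

    User TSV files extend the bundled registry; a user row with the same
    (origin, instrument, label) replaces the bundled one.  An unknown
    origin raises, listing the available keys; an instrument with no rows
    for the origin yields a warning and contributes nothing.
    """
    if not instrument_list:
        raise MetadataError("instrument_list must be non-empty")
    frames = [_bundled_registry()]
    for table in user_tables:
        frames.append(_read_registry_frame(table))
    registry = pd.concat(frames, ignore_index=True).drop_duplicates(
        subset=["origin_key", "instrument", "term_label"], keep="last")

    available = sorted(registry["origin_key"].unique())
    if origin_key not in available:
        raise UnknownOriginError(
            f"unknown origin_key {origin_key!r}; available: {available}")

    selected = registry[(registry["origin_key"] == origin_key)
                        & registry["instrument"].isin(list(instrument_list))]
    for instrument in instrument_list:
        if not (selected["instrument"] == instrument).any():
            logger.warning("no %r terms registered for instrument %r",
                           origin_key, instrument)
    selected = selected.sort_values(["display_order", "term_label"],
                                    kind="stable")
    rows = [TermRow(origin_key=r.origin_key, instrument=r.instrument,
                    term_label=r.term_label, source_path=r.source_path,
                    display_order=int(r.display_order),
                    required=bool(r.required))
            for r in selected.itertuples(index=False)]
    return TermMatchingTable(origin_key=origin_key, rows=rows)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _resolve(row: TermRow, paths: Dict[str, object]):
    if row.source_path in paths:  # exact match always wins
        return True, paths[row.source_path]
    suffix = "/" + row.source_path
    candidates = {p: v for p, v in paths.items() if p.endswith(suffix)}
    if not candidates:
        return False, None
    texts = {value_text(v) for v in candidates.values()}
    if len(texts) > 1:
        raise AmbiguousTermError(
            f"term {row.term_label!r} pattern {row.source_path!r} matches "
            f"paths with different values: {sorted(candidates)}")
    return True, next(iter(candidates.values()))


def match_terms(flat_tables: Sequence[FlatTable],
                table: TermMatchingTable,
                file_names: Optional[Mapping[int, Sequence[str]]] = None,
                ) -> List[GroupReport]:
    """Reduce each group's flat table to the guideline's report rows.

    Rows follow the table's display order.  Required terms with no match
    carry :data:`ABSENT_MARKER`; optional unmatched terms are omitted.
    """
    reports = []
    for flat in flat_tables:
        paths = dict(flat.rows)
        rows: List[Tuple[str, str]] = []
        for term in table.rows:
            found, value = _resolve(term, paths)
            if found:
                rows.append((term.term_label, value_text(value)))
            elif term.required:
                logger.warning("group %d: required term %r not recorded",
                               flat.group_id, term.term_label)
                rows.append((term.term_label, ABSENT_MARKER))
        members = list(file_names.get(flat.group_id, ())) if file_names else []
        reports.append(GroupReport(group_id=flat.group_id, rows=rows,
                                   file_names=members))
    return reports
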