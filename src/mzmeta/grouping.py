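"""Reduction of a file collection to its minimal set of parameter groups.

Hundreds of acquisition files from one experiment typically derive from a
handful of instrument methods.  After removing the fields that legitimately
vary per file, each file's merged parameter tree is content-hashed and the
collection partitioned by hash: every group links one shared parameter tree
to the names of the files that carry it.  Because the hash is computed over
a canonical serialization, the partition is deterministic — independent of
input order, concurrency and platform — and minimal: two groups always
differ in at least one parameter path, which :func:`diff_groups` reports,
making unintended parameter drift across a long acquisition series directly
visible.

The grouped JSON interchange format (schema shipped as
``data/grouped_collection.schema.json``)::

    {"Version": "1.0",
     "Groups": [{"GroupId": 1, "FileNames": [...], "SharedParameters": {...}}],
     "Failed": [{"FileName": "...", "Error": "..."}]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from . import ingest
from .lc_method import attach_gradient
from .model import (
    ABSENT,
    FileMetadata,
    MetadataError,
    MetadataTree,
    content_hash,
    iter_leaves,
    join_path,
    render_scalar,
    strip_file_specific,
    validate_tree,
)

__all__ = [
    "FORMAT_VERSION",
    "GroupedCollection",
    "ParameterGroup",
    "diff_groups",
    "group_files",
    "prepare_tree",
    "read_grouped_json",
    "write_grouped_json",
]

FORMAT_VERSION = "1.0"


@dataclass
class ParameterGroup:
    """A maximal set of files sharing one parameter tree."""

    group_id: int
    shared: MetadataTree
    file_names: List[str]
    first_seen: int  # index of earliest member in manifest (sorted) order

    def __post_init__(self) -> None:
        if not self.file_names:
            raise MetadataError("a parameter group cannot be empty")
        self.file_names = sorted(self.file_names)


@dataclass
class GroupedCollection:
    """The reduced representation of a collection."""

    groups: List[ParameterGroup]
    failed: List[Tuple[str, str]] = field(default_factory=list)
    source_manifest: Optional[ingest.CollectionManifest] = field(
        default=None, compare=False)

    def group_of(self, file_name: str) -> ParameterGroup:
        for group in self.groups:
            if file_name in group.file_names:
                return group
        raise KeyError(file_name)


def prepare_tree(meta: FileMetadata,
                 exclude_paths: Iterable[str] = ()) -> MetadataTree:
    """The tree a file is grouped by: LC methods parsed and attached, then
    file-specific fields stripped."""
    prepared = FileMetadata(
        file_name=meta.file_name,
        acquired_date=meta.acquired_date,
        sample_info=meta.sample_info,
        instruments=[attach_gradient(inst) for inst in meta.instruments],
    )
    return strip_file_specific(prepared, exclude_paths)


def group_files(metadata: Sequence[FileMetadata],
                exclude_paths: Iterable[str] = (),
                failed: Iterable[Tuple[str, str]] = (),
                source_manifest: Optional[ingest.CollectionManifest] = None,
                ) -> GroupedCollection:
    """Partition files into the minimal set of parameter groups.

    Files are keyed by the content hash of their prepared tree; groups are
    numbered 1… by first occurrence in lexicographic file-name order, so the
    result is identical for any input ordering or degree of concurrency.
    Raises on an empty input or duplicate file names.
    """
    if not metadata:
        raise MetadataError("cannot group an empty collection")
    names = [m.file_name for m in metadata]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise MetadataError(f"duplicate file names: {dupes}")
    exclude_paths = tuple(exclude_paths)

    ordered = sorted(metadata, key=lambda m: m.file_name)
    by_hash: dict = {}
    order: List[str] = []
    for index, meta in enumerate(ordered):
        tree = prepare_tree(meta, exclude_paths)
        digest = content_hash(tree)
        if digest not in by_hash:
            by_hash[digest] = (tree, [], index)
            order.append(digest)
        by_hash[digest][1].append(meta.file_name)

    groups = [
        ParameterGroup(group_id=i + 1, shared=shared, file_names=members,
                       first_seen=first)
        for i, (shared, members, first)
        in enumerate(by_hash[d] for d in order)
    ]
    return GroupedCollection(groups=groups, failed=list(failed),
                             source_manifest=source_manifest)


# ---------------------------------------------------------------------------
# Grouped JSON round trip
# ---------------------------------------------------------------------------

def write_grouped_json(collection: GroupedCollection,
                       path: Union[str, Path]) -> None:
    """Write the grouped JSON interchange document."""
    doc = {
        "Version": FORMAT_VERSION,
        "Groups": [
            {
                "GroupId": group.group_id,
                "FileNames": list(group.file_names),
                "SharedParameters": group.shared,
            }
            for group in collection.groups
        ],
        "Failed": [
            {"FileName": name, "Error": error}
            for name, error in collection.failed
        ],
    }
    Path(path).write_text(ingest.dump_json(doc), encoding="utf-8",
                          newline="\n")


def read_grouped_json(path: Union[str, Path]) -> GroupedCollection:
    """Read and validate a grouped JSON document.

    Rejects overlapping group memberships, non-sequential group ids,
    duplicate shared trees (a non-minimal partition) and malformed
    parameter trees.  ``read(write(gc)) == gc``.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text, parse_float=ingest.SourceFloat,
                         object_pairs_hook=ingest._reject_duplicates)
    except json.JSONDecodeError as exc:
        raise ingest.FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("Groups"), list):
        raise ingest.ValidationError([("/Groups", "required array")])

    all_names: set = set()
    hashes: set = set()
    groups: List[ParameterGroup] = []
    raw_groups = doc["Groups"]
    for i, raw in enumerate(raw_groups):
        ptr = f"/Groups/{i}"
        if not isinstance(raw, dict):
            raise ingest.ValidationError([(ptr, "must be an object")])
        group_id = raw.get("GroupId")
        file_names = raw.get("FileNames")
        shared = raw.get("SharedParameters")
        if group_id != i + 1:
            raise ingest.ValidationError(
                [(f"{ptr}/GroupId", f"must be {i + 1} (sequential ids)")])
        if (not isinstance(file_names, list) or not file_names
                or not all(isinstance(n, str) for n in file_names)):
            raise ingest.ValidationError(
                [(f"{ptr}/FileNames", "required non-empty string array")])
        overlap = all_names.intersection(file_names)
        if overlap or len(set(file_names)) != len(file_names):
            raise ingest.ValidationError(
                [(f"{ptr}/FileNames",
                  f"file names appear in more than one group: "
                  f"{sorted(overlap) or sorted(file_names)}")])
        all_names.update(file_names)
        if not isinstance(shared, dict):
            raise ingest.ValidationError(
                [(f"{ptr}/SharedParameters", "required object")])
        validate_tree(shared)
        digest = content_hash(shared)
        if digest in hashes:
            raise ingest.ValidationError(
                [(f"{ptr}/SharedParameters",
                  "duplicate shared tree: partition is not minimal")])
        hashes.add(digest)
        groups.append(ParameterGroup(group_id=group_id, shared=shared,
                                     file_names=list(file_names),
                                     first_seen=0))

    # first_seen is derived, not stored: position of each group's earliest
    # member in the lexicographic order of all member names
    ordered_names = sorted(all_names)
    position = {name: i for i, name in enumerate(ordered_names)}
    for group in groups:
        group.first_seen = min(position[n] for n in group.file_names)
    if [g.first_seen for g in groups] != sorted(g.first_seen for g in groups):
        raise ingest.ValidationError(
            [("/Groups", "groups are not ordered by first occurrence")])

    failed = []
    for i, raw in enumerate(doc.get("Failed", [])):
        if (not isinstance(raw, dict) or "FileName" not in raw
                or "Error" not in raw):
            raise ingest.ValidationError(
                [(f"/Failed/{i}", "must be an object with FileName and Error")])
        failed.append((raw["FileName"], raw["Error"]))
    return GroupedCollection(groups=groups, failed=failed)


# ---------------------------------------------------------------------------
# Group comparison (parameter-drift inspection)
# ---------------------------------------------------------------------------

def diff_groups(a: ParameterGroup, b: ParameterGroup) -> List[Tuple[str, object, object]]:
    """Exactly the tree paths on which two groups' shared trees differ.

    One-sided presence is signaled with the :data:`~mzmeta.model.ABSENT`
    marker.  An empty list is returned exactly when the trees are
    content-equal (hash-equal).  Sorted by path.
    """
    leaves_a = {join_path(p): v for p, v in iter_leaves(a.shared)}
    leaves_b = {join_path(p): v for p, v in iter_leaves(b.shared)}
    diffs = []
    for path in sorted(set(leaves_a) | set(leaves_b)):
        in_a, in_b = path in leaves_a, path in leaves_b
        if in_a and in_b:
            if render_scalar(leaves_a[path]) != render_scalar(leaves_b[path]):
                diffs.append((path, leaves_a[path], leaves_b[path]))
        elif in_a:
            diffs.append((path, leaves_a[path], ABSENT))
        else:
            diffs.append((path, ABSENT, leaves_b[path]))
    return diffs
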