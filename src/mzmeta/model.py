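"""Metadata data model: parameter trees, canonicalization and content hashing.

Acquisition metadata from a mass-spectrometry run is carried as an ordered
tree of string keys mapping to scalar leaves (string, integer, decimal,
boolean, null) or sub-trees.  The tree abstracts over instrument-class
specific layouts: every reader in :mod:`mzmeta.ingest` produces the same
structure regardless of the source format.

Grouping files that share all relevant acquisition parameters relies on two
primitives defined here:

``strip_file_specific``
    merges a file's per-instrument parameter trees into one tree and removes
    everything that legitimately varies per file (file name, acquisition
    date, sample information, plus a user-extensible list of tree paths).

``content_hash``
    a SHA-256 digest over a canonical byte serialization of a tree; two
    trees receive the same hash exactly when they carry the same content,
    independent of sibling insertion order.

Decimals are kept as :class:`SourceFloat`, a ``float`` subclass remembering
the exact source text, so canonical serialization (and hence hashing) is
reproducible across platforms and re-serialization round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Iterator, Mapping, Sequence, Union

__all__ = [
    "ABSENT",
    "DuplicateKeyError",
    "FileMetadata",
    "InstrumentMetadata",
    "MetadataError",
    "MetadataTree",
    "ModuleType",
    "Scalar",
    "SourceFloat",
    "TreeStructureError",
    "UnsupportedLeafError",
    "apply_exclusions",
    "canonical_serialize",
    "content_hash",
    "copy_tree",
    "join_path",
    "split_path",
    "strip_file_specific",
    "tree_equal",
    "validate_tree",
]

PATH_SEPARATOR = "/"
HASH_ALGORITHM = "sha256"

#: Reserved leaf keys injected into each instrument's subtree by
#: :func:`strip_file_specific` so instrument identity and the verbatim
#: method text participate in grouping and can be cited in reports.
RESERVED_INSTRUMENT_KEYS = ("Model", "ModuleType", "MethodText")


class MetadataError(Exception):
    """Base class for all metadata handling errors."""


class TreeStructureError(MetadataError):
    """A parameter tree violates a structural invariant.

    Carries the path of the offending node as a tuple of keys.
    """

    def __init__(self, message: str, path: Sequence[str] = ()):
        self.path = tuple(path)
        where = join_path(self.path) if self.path else "<root>"
        super().__init__(f"{message} (at {where!r})")


class UnsupportedLeafError(TreeStructureError):
    """A leaf holds a value of a type the model does not carry."""


class DuplicateKeyError(MetadataError):
    """Two sibling keys are identical; silently dropping one would lose
    parameters, so this is always rejected."""


class SourceFloat(float):
    """A decimal leaf that remembers its exact source text.

    ``SourceFloat("2.10")`` compares numerically like ``float`` but renders
    (and canonically serializes) as ``"2.10"``, so a tree survives a
    parse → serialize round trip byte-identically.
    """

    __slots__ = ("text",)

    def __new__(cls, text: Union[str, float]) -> "SourceFloat":
        obj = super().__new__(cls, text)
        obj.text = text if isinstance(text, str) else repr(float(text))
        return obj

    def __repr__(self) -> str:  # honored by json.dump when indent is used
        return self.text


Scalar = Union[str, int, float, bool, None]
#: Parameter trees are plain (insertion-ordered) dicts of str -> Scalar|tree.
MetadataTree = dict


class ModuleType(str, Enum):
    """Coarse class of an instrument module attached to an acquisition."""

    MS = "MS"
    LC = "LC"
    OTHER = "OTHER"


@dataclass
class InstrumentMetadata:
    """One instrument module of an acquisition file.

    Parameters
    ----------
    model:
        Instrument model designation, e.g. ``"Q Exactive - Orbitrap_MS"``.
    module_type:
        ``MS``, ``LC`` or ``OTHER``.
    method_text:
        The verbatim acquisition-method string, if the module carries one.
    parameters:
        Nested parameter tree for the module.
    """

    model: str
    module_type: ModuleType
    method_text: Union[str, None] = None
    parameters: MetadataTree = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.model:
            raise MetadataError("instrument model must be non-empty")
        self.module_type = ModuleType(self.module_type)


@dataclass
class FileMetadata:
    """Full metadata of one acquisition file: fixed header plus modules."""

    file_name: str
    acquired_date: Union[str, None] = None
    sample_info: dict = field(default_factory=dict)
    instruments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.file_name:
            raise MetadataError("file_name must be non-empty")
        if self.instruments is None:  # degenerate files are allowed, null is not
            raise MetadataError("instruments may be empty but never null")


# ---------------------------------------------------------------------------
# Path handling ("/" separated, backslash-escaped)
# ---------------------------------------------------------------------------

def escape_key(key: str) -> str:
    """Escape a tree key for inclusion in a slash-separated path."""
    return key.replace("\\", "\\\\").replace(PATH_SEPARATOR, "\\" + PATH_SEPARATOR)


def join_path(keys: Iterable[str]) -> str:
    """Join tree keys into a path, escaping literal separators."""
    return PATH_SEPARATOR.join(escape_key(k) for k in keys)


def split_path(path: str) -> tuple:
    """Inverse of :func:`join_path`: split a path into unescaped keys."""
    keys = []
    current = []
    it = iter(path)
    for ch in it:
        if ch == "\\":
            nxt = next(it, None)
            if nxt is None:
                current.append(ch)
            else:
                current.append(nxt)
        elif ch == PATH_SEPARATOR:
            keys.append("".join(current))
            current = []
        else:
            current.append(ch)
    keys.append("".join(current))
    return tuple(keys)


# ---------------------------------------------------------------------------
# Tree validation and copying
# ---------------------------------------------------------------------------

def _is_scalar(value: Any) -> bool:
    return value is None or isinstance(value, (str, bool, int, float))


def validate_tree(tree: Any, path: Sequence[str] = ()) -> None:
    """Check the structural invariants of a parameter tree.

    Raises :class:`TreeStructureError` naming the offending path on the
    first violation found.
    """
    if not isinstance(tree, Mapping):
        raise TreeStructureError(
            f"expected a mapping, found {type(tree).__name__}", path)
    for key, value in tree.items():
        if not isinstance(key, str) or not key:
            raise TreeStructureError(
                f"tree keys must be non-empty strings, found {key!r}", path)
        child_path = (*path, key)
        if isinstance(value, Mapping):
            validate_tree(value, child_path)
        elif not _is_scalar(value):
            raise UnsupportedLeafError(
                f"unsupported leaf type {type(value).__name__}", child_path)


def copy_tree(tree: MetadataTree) -> MetadataTree:
    """Deep copy a tree; scalars (including SourceFloat) are shared."""
    return {
        key: copy_tree(value) if isinstance(value, Mapping) else value
        for key, value in tree.items()
    }


def iter_leaves(tree: MetadataTree, _prefix: Sequence[str] = ()) -> Iterator:
    """Yield ``(key_tuple, value)`` for every leaf, in canonical (sorted,
    depth-first) order."""
    for key in sorted(tree, key=_sort_key):
        value = tree[key]
        path = (*_prefix, key)
        if isinstance(value, Mapping):
            yield from iter_leaves(value, path)
        else:
            yield path, value


# ---------------------------------------------------------------------------
# Canonical serialization and hashing
# ---------------------------------------------------------------------------

def _norm(text: str) -> str:
    # byte-wise comparison after Unicode NFC; no case folding — "Full MS" and
    # "full ms" may denote different vendor labels
    return unicodedata.normalize("NFC", text)


def _sort_key(key: str) -> str:
    return _norm(key)


def render_scalar(value: Scalar, path: Sequence[str] = ()) -> str:
    """Fixed, type-tagged text rendering of a leaf used for hashing.

    Integers render as decimal text, decimals by their preserved source text
    (shortest round-trip representation otherwise), booleans as
    ``true``/``false`` and null as ``null``; a type tag keeps the string
    ``"1"`` distinct from the integer ``1``.
    """
    if value is None:
        return "null"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, SourceFloat):
        return "f:" + _norm(value.text)
    if isinstance(value, int):
        return "i:" + str(value)
    if isinstance(value, float):
        return "f:" + repr(value)
    if isinstance(value, str):
        # JSON-quoted so delimiter characters in values cannot make two
        # distinct trees serialize identically
        return "s:" + json.dumps(_norm(value), ensure_ascii=False)
    raise UnsupportedLeafError(
        f"unsupported leaf type {type(value).__name__}", path)


def _serialize_into(tree: MetadataTree, out: list, path: Sequence[str]) -> None:
    out.append("{")
    seen = set()
    first = True
    for key in sorted(tree, key=_sort_key):
        norm_key = _norm(key)
        if norm_key in seen:
            raise DuplicateKeyError(
                f"sibling keys collide after NFC normalization: {key!r} "
                f"at {join_path(path) or '<root>'!r}")
        seen.add(norm_key)
        if not first:
            out.append(",")
        first = False
        out.append(json.dumps(norm_key, ensure_ascii=False))
        out.append("=")
        value = tree[key]
        child_path = (*path, key)
        if isinstance(value, Mapping):
            _serialize_into(value, out, child_path)
        else:
            out.append(render_scalar(value, child_path))
    out.append("}")


def canonical_serialize(tree: MetadataTree) -> bytes:
    """Deterministic UTF-8 byte serialization of a parameter tree.

    Keys are sorted lexicographically by Unicode code point (after NFC
    normalization) at every level, so two trees with the same content yield
    the same bytes regardless of insertion order.
    """
    validate_tree(tree)
    parts: list = []
    _serialize_into(tree, parts, ())
    return "".join(parts).encode("utf-8")


def content_hash(tree: MetadataTree) -> str:
    """SHA-256 hex digest of :func:`canonical_serialize`.

    Stable across runs and platforms; used as the grouping key.
    """
    return hashlib.new(HASH_ALGORITHM, canonical_serialize(tree)).hexdigest()


def tree_equal(a: MetadataTree, b: MetadataTree) -> bool:
    """Content equality under the same rules the hash uses (decimals by
    source text, strings NFC-normalized, sibling order ignored)."""
    return canonical_serialize(a) == canonical_serialize(b)


# ---------------------------------------------------------------------------
# File-specific field stripping
# ---------------------------------------------------------------------------

def apply_exclusions(tree: MetadataTree,
                     exclude_paths: Iterable[str]) -> MetadataTree:
    """Return a copy of *tree* with every listed path removed.

    Paths are ``"/"``-separated (backslash-escaped) key sequences rooted at
    *tree*; a path that does not exist is silently ignored, so one exclusion
    list can serve heterogeneous collections.  Idempotent.
    """
    validate_tree(tree)
    result = copy_tree(tree)
    for raw in exclude_paths:
        keys = split_path(raw)
        node = result
        parents = []
        for key in keys[:-1]:
            child = node.get(key)
            if not isinstance(child, Mapping):
                node = None
                break
            parents.append((node, key))
            node = child
        if node is not None and keys[-1] in node:
            del node[keys[-1]]
            # prune now-empty subtrees so exclusion cannot leave husks that
            # would still split groups
            for parent, key in reversed(parents):
                if not parent[key]:
                    del parent[key]
                else:
                    break
    return result


def strip_file_specific(meta: FileMetadata,
                        exclude_paths: Iterable[str] = ()) -> MetadataTree:
    """Merge a file's instrument parameters into one tree, dropping
    everything that varies per file.

    The header fields (file name, acquisition date, sample information)
    never enter the result; each instrument's parameters appear under a key
    equal to its model, suffixed ``#2``, ``#3`` … for duplicate models, and
    gain ``Model``/``ModuleType``/``MethodText`` leaves so instrument
    identity and method differences participate in grouping.  Any path in
    *exclude_paths* (rooted at the merged tree) is removed afterwards.
    The input is not modified.
    """
    merged: MetadataTree = {}
    model_counts: dict = {}
    for instrument in meta.instruments:
        validate_tree(instrument.parameters, (instrument.model,))
        count = model_counts.get(instrument.model, 0) + 1
        model_counts[instrument.model] = count
        key = instrument.model if count == 1 else f"{instrument.model}#{count}"
        subtree = copy_tree(instrument.parameters)
        for reserved, value in (
            ("Model", instrument.model),
            ("ModuleType", instrument.module_type.value),
            ("MethodText", instrument.method_text),
        ):
            if reserved in subtree:
                raise TreeStructureError(
                    f"parameter key {reserved!r} collides with a reserved "
                    "instrument field", (key, reserved))
            subtree[reserved] = value
        merged[key] = subtree
    return apply_exclusions(merged, exclude_paths)


#: Sentinel used by diffs and reports for a value absent on one side.
class _Absent:
    _instance = None

    def __new__(cls) -> "_Absent":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "(absent)"


ABSENT = _Absent()
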