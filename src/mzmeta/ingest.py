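"""Readers: the native per-file metadata JSON dialect, mzML headers, and
collection scanning.

The native JSON dialect is the open interchange format for one acquisition
file's metadata (schema shipped as ``data/native_metadata.schema.json``)::

    {
      "FileName": "run_0001.raw",
      "AcquiredDate": "2024-03-01T10:15:00",
      "SampleInfo": {"Sample ID": "S1"},
      "Instruments": [
        {"Model": "Q Exactive - Orbitrap_MS", "ModuleType": "MS",
         "MethodText": null, "Parameters": {...}}
      ]
    }

mzML ingestion reads only the header sections of a (possibly indexed)
mzML 1.1 document — instrument configurations, sample, run attributes —
and never touches spectra.  CV parameters become tree leaves keyed by term
name, with the accession retained as a ``"<name>@accession"`` sibling leaf.
"""

from __future__ import annotations

import fnmatch
import json
import logging
import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import IO, Iterable, List, Mapping, Optional, Tuple, Union

from lxml import etree

from .model import (
    DuplicateKeyError,
    FileMetadata,
    InstrumentMetadata,
    MetadataError,
    ModuleType,
    SourceFloat,
    validate_tree,
)

__all__ = [
    "CollectionManifest",
    "FormatError",
    "ManifestEntry",
    "NoInputFilesError",
    "ValidationError",
    "dump_json",
    "read_collection",
    "read_entry",
    "read_mzml_metadata",
    "read_native_json",
    "scan_collection",
    "write_native_json",
]

logger = logging.getLogger(__name__)

DEFAULT_PATTERNS = ("*.json", "*.mzml")  # extension match is case-insensitive


class ValidationError(MetadataError):
    """A document violates the native dialect; lists JSON-pointer paths."""

    def __init__(self, pointers_and_messages: List[Tuple[str, str]]):
        self.errors = list(pointers_and_messages)
        lines = "; ".join(f"{ptr}: {msg}" for ptr, msg in self.errors)
        super().__init__(f"invalid metadata document: {lines}")


class FormatError(MetadataError):
    """The input is not in the expected file format."""


class NoInputFilesError(MetadataError):
    """A scan matched no input files — never an empty success."""


# ---------------------------------------------------------------------------
# JSON emission preserving decimal source text
# ---------------------------------------------------------------------------

def _emit_json(obj, out: List[str], indent: int) -> None:
    # the stdlib encoder renders floats via float.__repr__, which would lose
    # the preserved decimal source text, so values are rendered here
    pad = " " * indent
    if isinstance(obj, Mapping):
        if not obj:
            out.append("{}")
            return
        out.append("{")
        for i, (key, value) in enumerate(obj.items()):
            out.append(("," if i else "") + "\n" + pad + "  "
                       + json.dumps(str(key), ensure_ascii=False) + ": ")
            _emit_json(value, out, indent + 2)
        out.append("\n" + pad + "}")
    elif isinstance(obj, (list, tuple)):
        if not obj:
            out.append("[]")
            return
        out.append("[")
        for i, value in enumerate(obj):
            out.append(("," if i else "") + "\n" + pad + "  ")
            _emit_json(value, out, indent + 2)
        out.append("\n" + pad + "]")
    elif obj is None:
        out.append("null")
    elif obj is True:
        out.append("true")
    elif obj is False:
        out.append("false")
    elif isinstance(obj, SourceFloat):
        out.append(obj.text)
    elif isinstance(obj, float):
        out.append(repr(obj))
    elif isinstance(obj, int):
        out.append(str(obj))
    elif isinstance(obj, str):
        out.append(json.dumps(obj, ensure_ascii=False))
    else:
        raise MetadataError(f"cannot serialize {type(obj).__name__} to JSON")


def dump_json(obj, fp: Union[IO[str], None] = None) -> str:
    """Serialize to pretty-printed JSON, keeping decimal source text."""
    parts: List[str] = []
    _emit_json(obj, parts, 0)
    text = "".join(parts) + "\n"
    if fp is not None:
        fp.write(text)
    return text


# ---------------------------------------------------------------------------
# Native JSON dialect
# ---------------------------------------------------------------------------

def _reject_duplicates(pairs):
    seen = set()
    for key, _ in pairs:
        if key in seen:
            raise DuplicateKeyError(
                f"duplicate object key {key!r}; refusing to drop parameters")
        seen.add(key)
    return dict(pairs)


def _load_json(text: str):
    return json.loads(text, parse_float=SourceFloat,
                      object_pairs_hook=_reject_duplicates)


_MODULE_TYPES = {m.value for m in ModuleType}


def _check_tree(node, pointer: str, errors: List[Tuple[str, str]]) -> None:
    if isinstance(node, Mapping):
        for key, value in node.items():
            if not key:
                errors.append((pointer, "empty parameter key"))
            _check_tree(value, f"{pointer}/{_escape_pointer(key)}", errors)
    elif isinstance(node, list):
        errors.append((pointer, "arrays are not allowed in parameter trees"))
    # scalars (str/int/float/bool/None) are all legal leaves


def _escape_pointer(key: str) -> str:
    return key.replace("~", "~0").replace("/", "~1")


def _parse_document(doc) -> FileMetadata:
    errors: List[Tuple[str, str]] = []
    if not isinstance(doc, Mapping):
        raise ValidationError([("", "top level must be a JSON object")])

    file_name = doc.get("FileName")
    if not isinstance(file_name, str) or not file_name:
        errors.append(("/FileName", "required non-empty string"))

    acquired = doc.get("AcquiredDate")
    if acquired is not None:
        if not isinstance(acquired, str):
            errors.append(("/AcquiredDate", "must be an ISO-8601 string or null"))
        else:
            try:
                datetime.fromisoformat(acquired.replace("Z", "+00:00"))
            except ValueError:
                errors.append(("/AcquiredDate",
                               f"not an ISO-8601 timestamp: {acquired!r}"))

    sample_info = doc.get("SampleInfo", {})
    if not isinstance(sample_info, Mapping) or not all(
            isinstance(k, str) and isinstance(v, str)
            for k, v in sample_info.items()):
        errors.append(("/SampleInfo", "must be a flat string-to-string map"))
        sample_info = {}

    raw_instruments = doc.get("Instruments")
    instruments: List[InstrumentMetadata] = []
    if not isinstance(raw_instruments, list):
        errors.append(("/Instruments", "required array"))
    else:
        for i, inst in enumerate(raw_instruments):
            ptr = f"/Instruments/{i}"
            if not isinstance(inst, Mapping):
                errors.append((ptr, "must be an object"))
                continue
            model = inst.get("Model")
            if not isinstance(model, str) or not model:
                errors.append((f"{ptr}/Model", "required non-empty string"))
                continue
            module_type = inst.get("ModuleType")
            if module_type not in _MODULE_TYPES:
                errors.append((f"{ptr}/ModuleType",
                               f"must be one of {sorted(_MODULE_TYPES)}"))
                continue
            method_text = inst.get("MethodText")
            if method_text is not None and not isinstance(method_text, str):
                errors.append((f"{ptr}/MethodText", "must be a string or null"))
                continue
            parameters = inst.get("Parameters", {})
            if not isinstance(parameters, Mapping):
                errors.append((f"{ptr}/Parameters", "must be an object"))
                continue
            _check_tree(parameters, f"{ptr}/Parameters", errors)
            instruments.append(InstrumentMetadata(
                model=model, module_type=ModuleType(module_type),
                method_text=method_text, parameters=dict(parameters)))

    if errors:
        raise ValidationError(errors)
    return FileMetadata(
        file_name=file_name,
        acquired_date=acquired,
        sample_info=dict(sample_info),
        instruments=instruments,
    )


def read_native_json(path: Union[str, Path]) -> FileMetadata:
    """Read one acquisition file's metadata from the native JSON dialect.

    Duplicate object keys and schema violations raise (the latter with
    JSON-pointer paths); decimal source text is preserved.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = _load_json(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    return _parse_document(doc)


def write_native_json(meta: FileMetadata, path: Union[str, Path]) -> None:
    """Write metadata in the native dialect; read → write → read is the
    identity and re-writing a read document is byte-identical."""
    for inst in meta.instruments:
        validate_tree(inst.parameters, (inst.model,))
    doc = {
        "FileName": meta.file_name,
        "AcquiredDate": meta.acquired_date,
        "SampleInfo": dict(meta.sample_info),
        "Instruments": [
            {
                "Model": inst.model,
                "ModuleType": inst.module_type.value,
                "MethodText": inst.method_text,
                "Parameters": inst.parameters,
            }
            for inst in meta.instruments
        ],
    }
    Path(path).write_text(dump_json(doc), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# mzML header ingestion
# ---------------------------------------------------------------------------

_ACCESSION = re.compile(r"^[A-Za-z]+:\d+$")


def _localname(elem) -> str:
    return etree.QName(elem.tag).localname if isinstance(elem.tag, str) else ""


def _params_into(elem, tree: dict, ref_groups: dict, context: str) -> None:
    for child in elem:
        name = _localname(child)
        if name == "cvParam":
            term = child.get("name") or child.get("accession") or "cvParam"
            accession = child.get("accession")
            if accession and not _ACCESSION.match(accession):
                logger.warning("unknown CV accession %r for %r in %s",
                               accession, term, context)
            if term in tree:
                raise DuplicateKeyError(
                    f"duplicate CV term {term!r} in {context}")
            tree[term] = child.get("value")
            if accession:
                tree[f"{term}@accession"] = accession
        elif name == "userParam":
            term = child.get("name") or "userParam"
            if term in tree:
                raise DuplicateKeyError(
                    f"duplicate userParam {term!r} in {context}")
            tree[term] = child.get("value")
        elif name == "referenceableParamGroupRef":
            ref = child.get("ref")
            if ref in ref_groups:
                _params_into(ref_groups[ref], tree, ref_groups, context)
            else:
                logger.warning("unresolved referenceableParamGroupRef %r", ref)


_COMPONENT_LABELS = {"source": "Source", "analyzer": "Analyzer",
                     "detector": "Detector"}


def _instrument_from_configuration(elem, ref_groups: dict) -> InstrumentMetadata:
    config_id = elem.get("id", "?")
    tree: dict = {}
    _params_into(elem, tree, ref_groups, f"instrumentConfiguration {config_id!r}")
    counts: dict = {}
    for child in elem:
        if _localname(child) != "componentList":
            continue
        for comp in child:
            label = _COMPONENT_LABELS.get(_localname(comp))
            if label is None:
                continue
            counts[label] = counts.get(label, 0) + 1
            key = label if counts[label] == 1 else f"{label}#{counts[label]}"
            sub: dict = {}
            _params_into(comp, sub, ref_groups,
                         f"{key} of instrumentConfiguration {config_id!r}")
            if sub:
                tree[key] = sub
    model = tree.get("instrument model")
    if not isinstance(model, str) or not model:
        model = next(
            (k for k, v in tree.items()
             if not k.endswith("@accession") and isinstance(v, (str, type(None)))),
            None) or config_id
    return InstrumentMetadata(model=model, module_type=ModuleType.MS,
                              method_text=None, parameters=tree)


def read_mzml_metadata(path: Union[str, Path]) -> FileMetadata:
    """Read run/instrument metadata from an mzML 1.1 document.

    Maps ``run@startTimeStamp`` to the acquisition date, every
    ``instrumentConfiguration`` to one MS instrument module (CV params as
    leaves, accessions as ``@accession`` siblings, components as
    ``Source``/``Analyzer``/``Detector`` subtrees), and the ``sample``
    element to the sample-info map.  Parsing stops at the spectrum list;
    indexed mzML wrappers are accepted transparently.
    """
    path = Path(path)
    ref_groups: dict = {}
    instruments: List[InstrumentMetadata] = []
    sample_info: dict = {}
    acquired: Optional[str] = None
    saw_mzml = False
    saw_config_list = False
    try:
        for event, elem in etree.iterparse(
                str(path), events=("start", "end"), recover=False):
            name = _localname(elem)
            if event == "start":
                if not saw_mzml:
                    if name == "indexedmzML":  # transparent wrapper
                        continue
                    if name != "mzML":
                        raise FormatError(f"{path}: root element {name!r} is "
                                          "not an mzML document")
                    saw_mzml = True
                if name == "instrumentConfigurationList":
                    saw_config_list = True
                elif name == "run":
                    acquired = elem.get("startTimeStamp")
                elif name in ("spectrumList", "chromatogramList"):
                    break  # header sections end here; spectra are never read
            else:
                if name == "referenceableParamGroup":
                    ref_groups[elem.get("id")] = elem
                elif name == "instrumentConfiguration":
                    instruments.append(
                        _instrument_from_configuration(elem, ref_groups))
                elif name == "sample" and not sample_info:
                    for attr in ("id", "name"):
                        if elem.get(attr):
                            sample_info[attr] = elem.get(attr)
                    for child in elem:
                        if _localname(child) in ("cvParam", "userParam"):
                            term = child.get("name")
                            if term:
                                sample_info[term] = child.get("value") or ""
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    if not saw_config_list:
        raise FormatError(f"{path}: missing instrumentConfigurationList")
    return FileMetadata(
        file_name=path.name,
        acquired_date=acquired,
        sample_info=sample_info,
        instruments=instruments,
    )


# ---------------------------------------------------------------------------
# Collection scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    """One input file of a collection."""

    file_name: str
    source_format: str  # "json" | "mzML"
    path: Path


@dataclass
class CollectionManifest:
    """Sorted, duplicate-free list of a collection's input files."""

    root_path: str
    entries: List[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.file_name for e in self.entries]
        if len(set(names)) != len(names):
            raise MetadataError("duplicate file names in collection")
        self.entries = sorted(self.entries, key=lambda e: e.file_name)


def _format_of(path: Path) -> Optional[str]:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".mzml":
        return "mzML"
    return None


def scan_collection(path: Union[str, Path],
                    patterns: Iterable[str] = DEFAULT_PATTERNS
                    ) -> CollectionManifest:
    """Enumerate input files under *path* (a file or a directory).

    Entries are sorted lexicographically by file name so all downstream
    ordering is independent of OS directory iteration order.  An empty
    match raises :class:`NoInputFilesError`.
    """
    path = Path(path)
    if not path.exists():
        raise NoInputFilesError(f"input path does not exist: {path}")
    if path.is_file():
        fmt = _format_of(path)
        if fmt is None:
            raise FormatError(f"unrecognized input format: {path.name}")
        return CollectionManifest(str(path.parent),
                                  [ManifestEntry(path.name, fmt, path)])
    entries = []
    lowered = [p.lower() for p in patterns]
    for child in path.iterdir():
        if not child.is_file():
            continue
        if not any(fnmatch.fnmatch(child.name.lower(), p) for p in lowered):
            continue
        fmt = _format_of(child)
        if fmt is not None:
            entries.append(ManifestEntry(child.name, fmt, child))
    if not entries:
        raise NoInputFilesError(
            f"no input files matching {sorted(patterns)} under {path}")
    return CollectionManifest(str(path), entries)


def read_entry(entry: ManifestEntry) -> FileMetadata:
    """Dispatch one manifest entry to the reader for its format."""
    if entry.source_format == "json":
        return read_native_json(entry.path)
    if entry.source_format == "mzML":
        return read_mzml_metadata(entry.path)
    raise FormatError(f"unknown source format {entry.source_format!r}")


def read_collection(manifest: CollectionManifest, jobs: int = 1
                    ) -> Tuple[List[FileMetadata], List[Tuple[str, str]]]:
    """Read every manifest entry; per-entry reads are independent.

    Returns ``(metadata, failed)`` where *failed* lists ``(file_name,
    error)`` for entries that could not be read — one corrupt file must not
    abort the collection.  Output order equals manifest order regardless of
    *jobs*.
    """
    def _one(entry: ManifestEntry):
        try:
            meta = read_entry(entry)
            logger.info("ingested %s (%s)", entry.file_name, entry.source_format)
            return meta, None
        except MetadataError as exc:
            logger.warning("failed to read %s: %s", entry.file_name, exc)
            return None, str(exc)

    if jobs > 1:
        with ThreadPoolExecutor(max_workers=jobs) as pool:
            results = list(pool.map(_one, manifest.entries))
    else:
        results = [_one(entry) for entry in manifest.entries]
    metadata = [meta for meta, _ in results if meta is not None]
    failed = [(entry.file_name, err)
              for entry, (_, err) in zip(manifest.entries, results)
              if err is not None]
    return metadata, failed
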