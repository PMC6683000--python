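"""Seeded generator of synthetic acquisition-metadata collections.

Real proteomics experiments routinely comprise hundreds of acquisition
files that derive from a handful of instrument-method templates: the
instrument settings are constant across a batch while the file name,
acquisition timestamp and sample information vary per file, and occasional
*parameter drift* — an instrument setting changing mid-series, usually
unnoticed — splits a batch into several parameter groups.  This module
emulates exactly that structure, with a known ground-truth partition, so
the grouping engine and the reporting pipeline can be exercised end to end
without any vendor data.

Two template families are bundled (names and parameter vocabulary modeled
on a Q Exactive orbitrap instrument and an EASY-nLC nano-flow LC; all
values are invented):

``qexactive_nlc_<k>`` (k = 0…5)
    a full LC/MS setup: nested MS parameter tree plus an LC module whose
    gradient is carried as method text in the documented dialect.  Emitted
    as native JSON only.

``qexactive_ms_<k>`` (k = 0…5)
    an MS-only configuration with the flat parameter layout mzML can
    express; emitted as native JSON and/or mzML, with identical stripped
    parameter trees across the two formats.

Drift events ``(file_index, tree_path, new_value)`` take effect from their
file index onward (a step change — the scenario that makes drift dangerous
over a long series); a point glitch is modeled by a second event restoring
the original value.  Ground truth is computed from the template identity
and the effective value of every drifted path, never via the hashing or
grouping code it serves to check.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from lxml import etree

from .ingest import CollectionManifest, ManifestEntry, write_native_json
from .model import (
    FileMetadata,
    InstrumentMetadata,
    MetadataError,
    ModuleType,
    SourceFloat,
    copy_tree,
    render_scalar,
    split_path,
)

__all__ = [
    "DriftEvent",
    "GeneratorSpec",
    "TEMPLATE_IDS",
    "build_template",
    "default_templates",
    "generate_collection",
    "generate_metadata",
]

MS_MODEL = "Q Exactive - Orbitrap_MS"
LC_MODEL = "Thermo EASY-nLC"

# per-variant parameter values; variants are pairwise distinct
_SPRAY_KV = ["2.10", "2.20", "2.00", "2.30", "1.90", "2.40"]
_NCE = ["27.0", "25.0", "28.0", "30.0", "27.5", "26.0"]
_TOP_N = [10, 12, 15, 10, 20, 12]
_MS1_RESOLUTION = [70000, 70000, 120000, 70000, 140000, 60000]
_GRADIENT_MID_B = ["38.0", "35.0", "40.0", "38.0", "30.0", "45.0"]
_GRADIENT_MID_DURATION = ["55.0", "85.0", "115.0", "45.0", "145.0", "40.0"]

N_VARIANTS = len(_SPRAY_KV)
TEMPLATE_IDS = tuple(
    [f"qexactive_nlc_{k}" for k in range(N_VARIANTS)]
    + [f"qexactive_ms_{k}" for k in range(N_VARIANTS)]
)


def _method_text(k: int) -> str:
    mid_duration = _GRADIENT_MID_DURATION[k]
    final_start = SourceFloat(mid_duration) + 5.0
    return "\n".join([
        "Sample pickup: 2.0 µl",
        "Equilibration: 4.0 µl",
        "Column oven: off",  # exercised as an unparsed (verbatim) line
        "Gradient:",
        "0.0 / 5.0 / 300.0 / 5.0",
        f"5.0 / {mid_duration} / 300.0 / {_GRADIENT_MID_B[k]}",
        f"{final_start:.1f} / 5.0 / 300.0 / 95.0",
    ])


def _ms_parameters(k: int) -> dict:
    return {
        "Ion source": {
            "Spray voltage [kV]": SourceFloat(_SPRAY_KV[k]),
            "Capillary temperature [°C]": 275,
            "S-lens RF level": SourceFloat("50.0"),
        },
        "Tune": {
            "Polarity": "positive",
            "Tune file": "default.mstune",
        },
        "Method": {
            "MS1": {
                "Resolution": _MS1_RESOLUTION[k],
                "AGC target": 3000000,
                "Maximum IT [ms]": 20,
                "Scan range [m/z]": "300-1750",
            },
            "MS2": {
                "Resolution": 17500,
                "AGC target": 100000,
                "Maximum IT [ms]": 60,
                "Normalized collision energy": SourceFloat(_NCE[k]),
                "Isolation window [m/z]": SourceFloat("1.6"),
                "Top N": _TOP_N[k],
                "Dynamic exclusion [s]": SourceFloat("30.0"),
            },
        },
    }


def _ms_flat_parameters(k: int) -> dict:
    # the layout an mzML instrumentConfiguration can carry: flat params plus
    # Source/Analyzer/Detector component subtrees, accessions as siblings
    return {
        "instrument model": MS_MODEL,
        "spray voltage": _SPRAY_KV[k],
        "resolution": str(_MS1_RESOLUTION[k]),
        "Source": {
            "electrospray ionization": None,
            "electrospray ionization@accession": "MS:1000073",
        },
        "Analyzer": {
            "orbitrap": None,
            "orbitrap@accession": "MS:1000484",
        },
        "Detector": {
            "inductive detector": None,
            "inductive detector@accession": "MS:1000624",
        },
    }


def build_template(template_id: str) -> List[InstrumentMetadata]:
    """Instantiate the instrument modules of a bundled template."""
    try:
        family, k_text = template_id.rsplit("_", 1)
        k = int(k_text)
        if k not in range(N_VARIANTS):
            raise ValueError
    except ValueError:
        raise MetadataError(f"unknown template id {template_id!r}; "
                            f"available: {list(TEMPLATE_IDS)}") from None
    if family == "qexactive_nlc":
        return [
            InstrumentMetadata(model=MS_MODEL, module_type=ModuleType.MS,
                               method_text=None, parameters=_ms_parameters(k)),
            InstrumentMetadata(model=LC_MODEL, module_type=ModuleType.LC,
                               method_text=_method_text(k),
                               parameters={
                                   "Column length [cm]": 50,
                                   "Column inner diameter [µm]": 75,
                               }),
        ]
    if family == "qexactive_ms":
        return [
            InstrumentMetadata(model=MS_MODEL, module_type=ModuleType.MS,
                               method_text=None,
                               parameters=_ms_flat_parameters(k)),
        ]
    raise MetadataError(f"unknown template id {template_id!r}; "
                        f"available: {list(TEMPLATE_IDS)}")


def template_is_mzml_compatible(template_id: str) -> bool:
    return template_id.startswith("qexactive_ms_")


def default_templates(n: int, mzml: bool = False) -> List[Tuple[str, float]]:
    """Equal-weight selection of the first *n* bundled template variants."""
    if not 1 <= n <= N_VARIANTS:
        raise MetadataError(f"n must be in 1..{N_VARIANTS}")
    family = "qexactive_ms" if mzml else "qexactive_nlc"
    return [(f"{family}_{k}", 1.0) for k in range(n)]


@dataclass(frozen=True)
class DriftEvent:
    """A step change of one parameter, effective from *file_index* onward.

    *tree_path* addresses a leaf of the merged stripped tree
    (``"<model>/<keys…>"``); files whose template lacks the path are
    unaffected.
    """

    file_index: int
    tree_path: str
    new_value: object


@dataclass
class GeneratorSpec:
    """Conditions of one synthetic collection."""

    n_files: int
    templates: List[Tuple[str, float]]
    drift_events: List[DriftEvent] = field(default_factory=list)
    seed: int = 0
    emit_formats: Tuple[str, ...] = ("json",)

    def __post_init__(self) -> None:
        if self.n_files <= 0:
            raise MetadataError("n_files must be positive")
        if not self.templates:
            raise MetadataError("at least one template is required")
        for template_id, weight in self.templates:
            build_template(template_id)  # validates the id
            if weight <= 0:
                raise MetadataError("template weights must be positive")
        unknown = set(self.emit_formats) - {"json", "mzML"}
        if unknown or not self.emit_formats:
            raise MetadataError(
                f"emit_formats must be a non-empty subset of json/mzML, "
                f"got {self.emit_formats!r}")
        seen = set()
        for event in self.drift_events:
            if not 0 <= event.file_index < self.n_files:
                raise MetadataError(
                    f"drift index {event.file_index} out of range")
            key = (event.file_index, event.tree_path)
            if key in seen:
                raise MetadataError(
                    f"conflicting drift events on {event.tree_path!r} "
                    f"at index {event.file_index}")
            seen.add(key)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_COMMENTS = ("", "replicate 1", "replicate 2", "pooled QC", "blank before run")
_BASE_MINUTES = 37  # one injection every ~37 min


def _acquired_date(index: int, rng: random.Random) -> str:
    total = index * _BASE_MINUTES * 60 + rng.randrange(0, 300)
    day, rem = divmod(total, 86400)
    hour, rem = divmod(rem, 3600)
    minute, second = divmod(rem, 60)
    return (f"2024-03-{1 + day:02d}T{hour:02d}:{minute:02d}:{second:02d}Z"
            if day < 28 else
            f"2024-04-{day - 27:02d}T{hour:02d}:{minute:02d}:{second:02d}Z")


def _apply_drift(instruments: List[InstrumentMetadata], index: int,
                 events: Sequence[DriftEvent]) -> List[InstrumentMetadata]:
    result = [InstrumentMetadata(model=i.model, module_type=i.module_type,
                                 method_text=i.method_text,
                                 parameters=copy_tree(i.parameters))
              for i in instruments]
    for event in sorted(events, key=lambda e: e.file_index):
        if event.file_index > index:
            continue
        keys = split_path(event.tree_path)
        target = next((i for i in result if i.model == keys[0]), None)
        if target is None:
            continue
        node = target.parameters
        ok = True
        for key in keys[1:-1]:
            child = node.get(key)
            if not isinstance(child, dict):
                ok = False
                break
            node = child
        if ok and keys[-1] in node and not isinstance(node[keys[-1]], dict):
            node[keys[-1]] = event.new_value
    return result


def _effective_drift_key(template_id: str, index: int,
                         events: Sequence[DriftEvent]) -> tuple:
    """Ground-truth group key: template plus the rendered effective value of
    every drifted path, dropping paths drifted back to their original."""
    instruments = build_template(template_id)
    original: Dict[str, object] = {}
    effective: Dict[str, object] = {}
    for event in sorted(events, key=lambda e: e.file_index):
        keys = split_path(event.tree_path)
        template_instrument = next(
            (i for i in instruments if i.model == keys[0]), None)
        if template_instrument is None:
            continue
        node = template_instrument.parameters
        found = True
        for key in keys[1:-1]:
            child = node.get(key)
            if not isinstance(child, dict):
                found = False
                break
            node = child
        if not found or keys[-1] not in node or isinstance(node[keys[-1]], dict):
            continue
        original[event.tree_path] = node[keys[-1]]
        if event.file_index <= index:
            effective[event.tree_path] = event.new_value
    deltas = tuple(sorted(
        (path, render_scalar(value))
        for path, value in effective.items()
        if render_scalar(value) != render_scalar(original[path])))
    return (template_id, deltas)


def _make_file(template_id: str, index: int, spec: GeneratorSpec,
               rng: random.Random, file_name: str) -> FileMetadata:
    instruments = _apply_drift(build_template(template_id), index,
                               spec.drift_events)
    sample_info = {
        "Sample ID": f"S{index + 1:03d}",
        "Vial": f"{rng.choice('ABCDEF')}{rng.randrange(1, 13)}",
        "Comment": rng.choice(_COMMENTS),
    }
    return FileMetadata(file_name=file_name,
                        acquired_date=_acquired_date(index, rng),
                        sample_info=sample_info,
                        instruments=instruments)


def _plan(spec: GeneratorSpec) -> List[str]:
    rng = random.Random(spec.seed)
    ids = [t for t, _ in spec.templates]
    weights = [w for _, w in spec.templates]
    return [rng.choices(ids, weights=weights)[0] for _ in range(spec.n_files)]


def generate_metadata(spec: GeneratorSpec
                      ) -> Tuple[List[FileMetadata], List[List[str]]]:
    """Generate the collection in memory (native-dialect metadata records).

    Returns ``(records, ground_truth)`` where *ground_truth* is the exact
    expected partition: lists of file names, ordered by first occurrence,
    members sorted — the same convention the grouping engine uses.  Fully
    reproducible from the seed.
    """
    chosen = _plan(spec)
    rng = random.Random(spec.seed + 1)
    records = []
    truth_order: List[tuple] = []
    truth_members: Dict[tuple, List[str]] = {}
    suffixes = sorted({"json": ".json", "mzML": ".mzML"}[fmt]
                      for fmt in spec.emit_formats)
    for index, template_id in enumerate(chosen):
        stem = f"run_{index:04d}"
        records.append(_make_file(template_id, index, spec, rng,
                                  stem + suffixes[0]))
        key = _effective_drift_key(template_id, index, spec.drift_events)
        if key not in truth_members:
            truth_members[key] = []
            truth_order.append(key)
        truth_members[key].extend(stem + s for s in suffixes)
    ground_truth = [sorted(truth_members[key]) for key in truth_order]
    return records, ground_truth


def generate_collection(spec: GeneratorSpec, out_dir: Union[str, Path]
                        ) -> Tuple[CollectionManifest, List[List[str]]]:
    """Write the collection to disk in the requested formats.

    With both formats requested, every file is emitted twice (same stem,
    ``.json`` and ``.mzML``) and both land in the same ground-truth group.
    mzML emission requires MS-only (flat-layout) templates: mzML has no
    slot for an LC module or a nested tune tree.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "mzML" in spec.emit_formats:
        incompatible = [t for t, _ in spec.templates
                        if not template_is_mzml_compatible(t)]
        if incompatible:
            raise MetadataError(
                f"templates {incompatible} cannot be emitted as mzML "
                "(LC modules / nested parameter trees)")
    records, ground_truth = generate_metadata(spec)
    entries = []
    for record in records:
        stem = record.file_name.rsplit(".", 1)[0]
        if "json" in spec.emit_formats:
            name = stem + ".json"
            path = out_dir / name
            write_native_json(
                FileMetadata(file_name=name,
                             acquired_date=record.acquired_date,
                             sample_info=record.sample_info,
                             instruments=record.instruments),
                path)
            entries.append(ManifestEntry(name, "json", path))
        if "mzML" in spec.emit_formats:
            name = stem + ".mzML"
            path = out_dir / name
            _write_mzml(record, name, path)
            entries.append(ManifestEntry(name, "mzML", path))
    return CollectionManifest(str(out_dir), entries), ground_truth


# ---------------------------------------------------------------------------
# Minimal mzML emission
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _write_mzml(record: FileMetadata, name: str, path: Path) -> None:
    E = etree.SubElement
    root = etree.Element(f"{{{_MZML_NS}}}mzML",
                         nsmap={None: _MZML_NS}, version="1.1.0")
    cv_list = E(root, f"{{{_MZML_NS}}}cvList", count="1")
    E(cv_list, f"{{{_MZML_NS}}}cv", id="MS",
      fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
      URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    file_description = E(root, f"{{{_MZML_NS}}}fileDescription")
    content = E(file_description, f"{{{_MZML_NS}}}fileContent")
    E(content, f"{{{_MZML_NS}}}cvParam", cvRef="MS", accession="MS:1000579",
      name="MS1 spectrum", value="")

    sample_list = E(root, f"{{{_MZML_NS}}}sampleList", count="1")
    sample = E(sample_list, f"{{{_MZML_NS}}}sample", id="sample1",
               name=record.sample_info.get("Sample ID", "sample"))
    for key in ("Vial", "Comment"):
        if record.sample_info.get(key):
            E(sample, f"{{{_MZML_NS}}}userParam", name=key,
              value=record.sample_info[key])

    software_list = E(root, f"{{{_MZML_NS}}}softwareList", count="1")
    software = E(software_list, f"{{{_MZML_NS}}}software", id="acq",
                 version="1.0")
    E(software, f"{{{_MZML_NS}}}cvParam", cvRef="MS", accession="MS:1000531",
      name="software", value="")

    config_list = E(root, f"{{{_MZML_NS}}}instrumentConfigurationList",
                    count=str(len(record.instruments)))
    for number, instrument in enumerate(record.instruments, start=1):
        config = E(config_list, f"{{{_MZML_NS}}}instrumentConfiguration",
                   id=f"IC{number}")
        components: Dict[str, dict] = {}
        for key, value in instrument.parameters.items():
            if isinstance(value, dict):
                components[key] = value
                continue
            if key.endswith("@accession"):
                continue
            accession = instrument.parameters.get(f"{key}@accession")
            if accession:
                E(config, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                  accession=str(accession), name=key,
                  **({"value": str(value)} if value is not None else {}))
            else:
                E(config, f"{{{_MZML_NS}}}userParam", name=key,
                  **({"value": str(value)} if value is not None else {}))
        if components:
            component_list = E(config, f"{{{_MZML_NS}}}componentList",
                               count=str(len(components)))
            tags = {"Source": "source", "Analyzer": "analyzer",
                    "Detector": "detector"}
            for order, (label, subtree) in enumerate(components.items(),
                                                     start=1):
                tag = tags.get(label.split("#")[0])
                if tag is None:
                    raise MetadataError(
                        f"subtree {label!r} has no mzML component slot")
                component = E(component_list, f"{{{_MZML_NS}}}{tag}",
                              order=str(order))
                for key, value in subtree.items():
                    if key.endswith("@accession"):
                        continue
                    accession = subtree.get(f"{key}@accession")
                    attrs = {"value": str(value)} if value is not None else {}
                    if accession:
                        E(component, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                          accession=str(accession), name=key, **attrs)
                    else:
                        E(component, f"{{{_MZML_NS}}}userParam", name=key,
                          **attrs)

    processing_list = E(root, f"{{{_MZML_NS}}}dataProcessingList", count="1")
    processing = E(processing_list, f"{{{_MZML_NS}}}dataProcessing", id="dp")
    method = E(processing, f"{{{_MZML_NS}}}processingMethod", order="1",
               softwareRef="acq")
    E(method, f"{{{_MZML_NS}}}cvParam", cvRef="MS", accession="MS:1000544",
      name="Conversion to mzML", value="")

    run_attrs = {"id": name.rsplit(".", 1)[0],
                 "defaultInstrumentConfigurationRef": "IC1",
                 "sampleRef": "sample1"}
    if record.acquired_date:
        run_attrs["startTimeStamp"] = record.acquired_date
    run = E(root, f"{{{_MZML_NS}}}run", **run_attrs)
    E(run, f"{{{_MZML_NS}}}spectrumList", count="0", defaultDataProcessingRef="dp")

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)
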