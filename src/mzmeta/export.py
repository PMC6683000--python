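"""Serialization of group reports to tab-delimited text and XLSX workbooks.

Per group one ``group_<id>.txt`` (UTF-8, LF line endings, two unquoted
columns ``term_label<TAB>value``) and/or one workbook ``groups.xlsx`` with a
sheet per group plus a ``files`` sheet mapping file names to group ids.
Tabs inside values would corrupt the two-column layout and are replaced by
single spaces with a warning.  TSV bytes are deterministic for identical
input; styling is limited to a bold header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

from openpyxl import Workbook
from openpyxl.styles import Font

from . import grouping
from .model import MetadataError
from .term_matching import GroupReport

__all__ = ["ExportBundle", "load_group_table", "save_all_groups"]

logger = logging.getLogger(__name__)

FORMATS = ("tsv", "xlsx", "json")
WORKBOOK_NAME = "groups.xlsx"
GROUPED_JSON_NAME = "groups.json"


@dataclass
class ExportBundle:
    """What to write where: reports, output directory, formats."""

    reports: List[GroupReport]
    out_dir: Union[str, Path]
    formats: Set[str] = field(default_factory=lambda: {"tsv"})
    grouped: Optional[grouping.GroupedCollection] = None
    force: bool = False

    def __post_init__(self) -> None:
        self.formats = set(self.formats)
        unknown = self.formats.difference(FORMATS)
        if unknown:
            raise MetadataError(f"unknown export formats: {sorted(unknown)}")
        if not self.formats:
            raise MetadataError("at least one export format must be selected")


def _sanitize(value: str, where: str) -> str:
    if "\t" in value:
        logger.warning("tab character in %s replaced by a space", where)
        return value.replace("\t", " ")
    return value


def _render_tsv(report: GroupReport) -> str:
    lines = []
    for label, value in report.rows:
        label = _sanitize(label, f"group {report.group_id} term label")
        value = _sanitize(value, f"group {report.group_id} term {label!r}")
        lines.append(f"{label}\t{value}")
    return "\n".join(lines) + ("\n" if lines else "")


def save_all_groups(bundle: ExportBundle) -> List[Path]:
    """Write every group report in the selected formats.

    Returns the written paths.  Existing target files raise unless
    ``force`` is set; an empty reports list is an error.
    """
    if not bundle.reports:
        raise MetadataError("no group reports to export")
    out_dir = Path(bundle.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    targets: List[Path] = []
    if "tsv" in bundle.formats:
        targets += [out_dir / f"group_{r.group_id}.txt" for r in bundle.reports]
    if "xlsx" in bundle.formats:
        targets.append(out_dir / WORKBOOK_NAME)
    if "json" in bundle.formats:
        if bundle.grouped is None:
            raise MetadataError(
                "json passthrough requested but no grouped collection given")
        targets.append(out_dir / GROUPED_JSON_NAME)
    existing = [t for t in targets if t.exists()]
    if existing and not bundle.force:
        raise MetadataError(
            f"refusing to overwrite {[str(p) for p in existing]} "
            "(use force to allow)")

    written: List[Path] = []
    if "tsv" in bundle.formats:
        for report in bundle.reports:
            path = out_dir / f"group_{report.group_id}.txt"
            path.write_text(_render_tsv(report), encoding="utf-8",
                            newline="\n")
            written.append(path)
    if "xlsx" in bundle.formats:
        written.append(_write_workbook(bundle.reports, out_dir))
    if "json" in bundle.formats:
        path = out_dir / GROUPED_JSON_NAME
        grouping.write_grouped_json(bundle.grouped, path)
        written.append(path)
    return written


def _write_workbook(reports: Sequence[GroupReport], out_dir: Path) -> Path:
    workbook = Workbook()
    bold = Font(bold=True)
    first = True
    for report in reports:
        if first:
            sheet = workbook.active
            sheet.title = f"group_{report.group_id}"
            first = False
        else:
            sheet = workbook.create_sheet(f"group_{report.group_id}")
        sheet.append(["Term", "Value"])
        for cell in sheet[1]:
            cell.font = bold
        for label, value in report.rows:
            sheet.append([label, value])
    files_sheet = workbook.create_sheet("files")
    files_sheet.append(["FileName", "GroupId"])
    for cell in files_sheet[1]:
        cell.font = bold
    for report in reports:
        for name in report.file_names:
            files_sheet.append([name, report.group_id])
    path = out_dir / WORKBOOK_NAME
    workbook.save(path)
    return path


def load_group_table(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """Re-import a ``group_<id>.txt`` file into (label, value) rows."""
    rows = []
    for number, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line:
            continue
        if "\t" not in line:
            raise MetadataError(f"{path}:{number}: expected two tab-delimited "
                                f"columns, got {line!r}")
        label, _, value = line.partition("\t")
        rows.append((label, value))
    return rows
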