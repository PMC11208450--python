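"""Readers and writers for lane counts and calibration tables.

Three plain-text formats are supported:

* **RCC** — the bracket-delimited per-lane file an nCounter instrument
  emits (``<Header>``, ``<Sample_Attributes>``, ``<Lane_Attributes>``,
  ``<Code_Summary>`` sections; the code summary holds
  ``CodeClass,Name,Accession,Count`` rows).
* **Wide count table** — probes down the rows, one sample per column,
  the layout of the spreadsheet analysis templates.  CSV or TSV,
  autodetected.  Known non-sample trailing columns (printed cutoffs,
  interpretation notes) are ignored.
* **Calibration table** — one row per probe with background moments,
  cutoffs and housekeeping thresholds.

Counts are non-negative integers.  A count that cannot be parsed (the
templates occasionally contain stray flags such as ``F``) becomes the
MISSING marker (``None``) with a logged warning; MISSING is never
silently coerced to zero downstream.  Parsers tolerate surrounding
whitespace and thousands separators, since the source files are usually
spreadsheet exports.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calibration import CalibrationError, CalibrationTable, FusionCutoffs
from .panel import PanelManifest, ProbeKind, Tube

logger = logging.getLogger(__name__)

#: marker for a count value that is present in the file but unusable.
MISSING = None

#: header-row cells of a wide count table that are not sample columns.
NON_SAMPLE_COLUMNS = frozenset(
    {
        "",
        "AVE + 3 SD",
        "AVE + 5 SD",
        "POSITIVITY CUTOFFS",
        "POSITIVITYCUTOFFS",
        "HK threshold",
        "Interpretation",
    }
)


class RccParseError(ValueError):
    """An RCC file is structurally invalid."""


class CountTableError(ValueError):
    """A wide count table is structurally invalid."""


@dataclass
class SampleCounts:
    """Raw per-probe counts for one lane (one RNA sample, one tube)."""

    sample_id: str
    counts: dict[str, int | None]
    rna_input_ng: float | None = None
    instrument_id: str | None = None
    tube: Tube | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        for probe_id, value in self.counts.items():
            if value is None:
                continue
            if (
                not isinstance(value, (int, np.integer))
                or isinstance(value, bool)
                or value < 0
            ):
                raise ValueError(
                    f"sample {self.sample_id!r}, probe {probe_id!r}: count must "
                    f"be a non-negative integer or MISSING, got {value!r}"
                )


def _parse_count(cell: str, *, context: str) -> int | None:
    text = cell.strip().replace(",", "").replace(" ", "")
    if not text:
        return MISSING
    try:
        value = int(text)
    except ValueError:
        try:
            f = float(text)
        except ValueError:
            logger.warning("%s: unparseable count %r set to MISSING", context, cell)
            return MISSING
        if not f.is_integer() or f < 0:
            logger.warning("%s: non-count value %r set to MISSING", context, cell)
            return MISSING
        value = int(f)
    if value < 0:
        logger.warning("%s: negative count %r set to MISSING", context, cell)
        return MISSING
    return value


# ----------------------------------------------------------------------
# RCC
# ----------------------------------------------------------------------

_KIND_TO_CODECLASS = {
    ProbeKind.FUSION: "Endogenous",
    ProbeKind.HOUSEKEEPING: "Housekeeping",
    ProbeKind.POS_CONTROL: "Positive",
    ProbeKind.NEG_CONTROL: "Negative",
}


def write_rcc(sample: SampleCounts, path: str | Path, manifest: PanelManifest) -> None:
    """Write one lane as an RCC file, probe classes taken from the manifest."""
    lines = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,4.0.0",
        "</Header>",
        "<Sample_Attributes>",
        f"ID,{sample.sample_id}",
    ]
    if sample.tube is not None:
        lines.append(f"GeneRLF,{sample.tube.value}")
    if sample.rna_input_ng is not None:
        lines.append(f"RNAInput,{sample.rna_input_ng:g}")
    lines += ["</Sample_Attributes>", "<Lane_Attributes>", "ID,1"]
    if sample.instrument_id is not None:
        lines.append(f"ScannerID,{sample.instrument_id}")
    lines += ["</Lane_Attributes>", "<Code_Summary>", "CodeClass,Name,Accession,Count"]
    for probe_id, count in sample.counts.items():
        if probe_id in manifest:
            code_class = _KIND_TO_CODECLASS[manifest.probe(probe_id).kind]
        else:
            code_class = "Endogenous"
        cell = "" if count is None else str(count)
        lines.append(f"{code_class},{probe_id},NA,{cell}")
    lines.append("</Code_Summary>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_SECTION_RE = re.compile(r"^<(/?)([A-Za-z_]+)>\s*$")


def _split_sections(text: str, path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        m = _SECTION_RE.match(line.strip())
        if m:
            closing, name = m.group(1), m.group(2)
            if closing:
                if name != current:
                    raise RccParseError(f"{path}: mismatched </{name}>")
                current = None
            else:
                current = name
                sections.setdefault(name, [])
            continue
        if current is not None and line.strip():
            sections[current].append(line)
    if current is not None:
        raise RccParseError(f"{path}: section <{current}> is never closed")
    return sections


def read_rcc(path: str | Path) -> SampleCounts:
    """Parse one RCC lane file into :class:`SampleCounts`."""
    path = Path(path)
    sections = _split_sections(path.read_text(encoding="utf-8"), path)
    if "Code_Summary" not in sections:
        raise RccParseError(f"{path}: missing <Code_Summary> section")

    def attrs(name: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for line in sections.get(name, []):
            key, _, value = line.partition(",")
            out[key.strip()] = value.strip()
        return out

    sample_attrs = attrs("Sample_Attributes")
    lane_attrs = attrs("Lane_Attributes")
    sample_id = sample_attrs.get("ID") or path.stem
    tube_cell = sample_attrs.get("GeneRLF", "")
    tube = Tube(tube_cell) if tube_cell in Tube._value2member_map_ else None
    rna_input = None
    if sample_attrs.get("RNAInput"):
        try:
            rna_input = float(sample_attrs["RNAInput"])
        except ValueError:
            logger.warning("%s: unparseable RNAInput %r", path, sample_attrs["RNAInput"])

    counts: dict[str, int | None] = {}
    rows = sections["Code_Summary"]
    for line in rows:
        cells = next(csv.reader([line]))
        if not cells or cells[0].strip() == "CodeClass":
            continue
        if len(cells) < 4:
            raise RccParseError(f"{path}: malformed Code_Summary row {line!r}")
        name = cells[1].strip()
        counts[name] = _parse_count(cells[3], context=f"{path}:{name}")
    return SampleCounts(
        sample_id=sample_id,
        counts=counts,
        rna_input_ng=rna_input,
        instrument_id=lane_attrs.get("ScannerID") or None,
        tube=tube,
    )


# ----------------------------------------------------------------------
# Wide count table
# ----------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_count_table(
    path: str | Path,
    manifest: PanelManifest,
    *,
    ignore_columns: frozenset[str] = NON_SAMPLE_COLUMNS,
) -> list[SampleCounts]:
    """Read a probes x samples count table into one lane per column.

    The first column holds probe labels; every other column is a sample
    unless its header is in ``ignore_columns``.  Probe labels absent
    from the manifest are retained under their literal id with a logged
    warning.  When all of the manifest's fusion probes live in a single
    tube, that tube is recorded on every returned lane.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        return []
    delimiter = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delimiter))
    header = [c.strip() for c in rows[0]]
    sample_cols = [
        (i, name)
        for i, name in enumerate(header[1:], start=1)
        if name not in ignore_columns
    ]
    names = [name for _, name in sample_cols]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise CountTableError(f"{path}: duplicate sample columns {sorted(dupes)}")

    tube = manifest.uniform_tube()
    counts_per_sample: dict[str, dict[str, int | None]] = {n: {} for n in names}
    for row in rows[1:]:
        if not row or not any(cell.strip() for cell in row):
            continue
        probe_id = row[0].strip()
        if not probe_id:
            continue
        if probe_id not in manifest:
            logger.warning(
                "%s: probe label %r not in manifest %r; retained as-is",
                path,
                probe_id,
                manifest.name,
            )
        for col, name in sample_cols:
            cell = row[col] if col < len(row) else ""
            counts_per_sample[name][probe_id] = _parse_count(
                cell, context=f"{path}:{probe_id}/{name}"
            )
    return [
        SampleCounts(sample_id=name, counts=counts_per_sample[name], tube=tube)
        for name in names
    ]


def write_count_table(
    samples: Sequence[SampleCounts],
    path: str | Path,
    *,
    probe_order: Sequence[str] | None = None,
    delimiter: str = "\t",
) -> None:
    """Write lanes as a probes x samples table (MISSING as empty cells)."""
    if probe_order is None:
        seen: dict[str, None] = {}
        for s in samples:
            for probe_id in s.counts:
                seen.setdefault(probe_id, None)
        probe_order = list(seen)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["Probe set"] + [s.sample_id for s in samples])
        for probe_id in probe_order:
            row = [probe_id]
            for s in samples:
                v = s.counts.get(probe_id)
                row.append("" if v is None else str(v))
            writer.writerow(row)


# ----------------------------------------------------------------------
# Calibration table
# ----------------------------------------------------------------------

_CALIB_COLUMNS = (
    "probe_id",
    "role",
    "bg_mean",
    "bg_sd",
    "cut3",
    "cut5",
    "hk_threshold",
    "n",
    "inherited",
)


def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    return repr(float(value))  # shortest string that round-trips exactly


def write_calibration(table: CalibrationTable, path: str | Path) -> None:
    lines = []
    if table.instrument_id is not None:
        lines.append(f"# instrument_id: {table.instrument_id}")
    if table.n_negatives is not None:
        lines.append(f"# n_negatives: {table.n_negatives}")
    lines.append("\t".join(_CALIB_COLUMNS))
    for probe_id, c in table.fusion.items():
        lines.append(
            "\t".join(
                [
                    probe_id,
                    "fusion",
                    _fmt(c.bg_mean),
                    _fmt(c.bg_sd),
                    _fmt(c.cut3),
                    _fmt(c.cut5),
                    "",
                    _fmt(c.n),
                    "1" if c.inherited else "0",
                ]
            )
        )
    for probe_id in sorted(table.uncalibrated):
        lines.append("\t".join([probe_id, "fusion", "", "", "", "", "", "", "0"]))
    for probe_id, threshold in table.hk_thresholds.items():
        lines.append(
            "\t".join(
                [probe_id, "housekeeping", "", "", "", "", _fmt(threshold), "", ""]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_calibration(path: str | Path) -> CalibrationTable:
    """Read a calibration table, validating cutoff invariants.

    Rows carrying background moments must satisfy
    ``cut3 = mean + 3*SD`` and ``cut5 = mean + 5*SD`` within a rounding
    tolerance; rows carrying only cutoffs (printed tables whose
    underlying moments were never published) skip that check but must
    still have ``cut5 >= cut3``.
    """
    path = Path(path)
    table = CalibrationTable()
    header: list[str] | None = None
    for raw in csv.reader(path.read_text(encoding="utf-8").splitlines(), delimiter="\t"):
        if not raw or not any(c.strip() for c in raw):
            continue
        if raw[0].startswith("#"):
            text = raw[0].lstrip("#").strip()
            key, _, value = text.partition(":")
            key, value = key.strip(), value.strip()
            if key == "instrument_id" and value:
                table.instrument_id = value
            elif key == "n_negatives" and value:
                table.n_negatives = int(value)
            continue
        if header is None:
            header = [c.strip() for c in raw]
            if tuple(header) != _CALIB_COLUMNS:
                raise CalibrationError(
                    f"{path}: calibration header must be {list(_CALIB_COLUMNS)}"
                )
            continue
        row = dict(zip(_CALIB_COLUMNS, (c.strip() for c in raw)))
        probe_id = row["probe_id"]
        role = row["role"]

        def num(key: str) -> float | None:
            cell = row.get(key, "")
            return float(cell) if cell else None

        if role == "fusion":
            cut3, cut5 = num("cut3"), num("cut5")
            if cut3 is None and cut5 is None:
                table.uncalibrated.add(probe_id)
                continue
            if cut3 is None or cut5 is None:
                raise CalibrationError(
                    f"{path}: probe {probe_id!r} has only one of cut3/cut5"
                )
            n_cell = row.get("n", "")
            table.fusion[probe_id] = FusionCutoffs(
                cut3=cut3,
                cut5=cut5,
                bg_mean=num("bg_mean"),
                bg_sd=num("bg_sd"),
                n=int(float(n_cell)) if n_cell else None,
                inherited=row.get("inherited", "") == "1",
            )
        elif role == "housekeeping":
            threshold = num("hk_threshold")
            if threshold is None:
                raise CalibrationError(
                    f"{path}: housekeeping probe {probe_id!r} lacks a threshold"
                )
            table.hk_thresholds[probe_id] = threshold
        else:
            raise CalibrationError(f"{path}: unknown role {role!r} for {probe_id!r}")
    if header is None:
        raise CalibrationError(f"{path}: empty calibration file")
    return table
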