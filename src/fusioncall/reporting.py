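"""Run-level report rendering and cohort summaries.

The run report reproduces the spreadsheet analysis template: a
probes x samples grid of raw counts with per-cell display classes —
``positive`` (yellow; count above the 5 SD cutoff), ``review`` (brown;
between the 3 and 5 SD cutoffs), ``hk_pass``/``hk_fail`` (green/red
housekeeping adequacy) and ``plain`` — plus a per-sample interpretation
row.  Lanes whose assay controls failed render every fusion cell
``plain``: their counts are not interpretable, however high.

Cell classes are a pure function of the probe-call and RNA-QC statuses;
the color palette is a separate small mapping so the spreadsheet
dialect can change without touching logic.
"""

from __future__ import annotations

import html as _html
import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calibration import CalibrationTable
from .calling import (
    ProbeStatus,
    SampleInterpretation,
    SampleStatus,
)
from .io import SampleCounts
from .panel import PanelManifest, ProbeKind

#: display class -> background color; presentation only.
PALETTE: dict[str, str] = {
    "positive": "#ffe97f",  # yellow: strong indicator of positivity
    "review": "#c8a165",  # brown: flag for additional review
    "hk_pass": "#b7e0b7",  # green: adequate RNA
    "hk_fail": "#f2a7a7",  # red: inadequate RNA
    "plain": "",
}

SUPPORTED_FORMATS = ("html", "csv")


@dataclass
class RunReport:
    """A rendered run: counts grid, per-cell classes, interpretations."""

    run_id: str
    counts: pd.DataFrame  # probes x samples, object dtype (None = missing)
    classes: pd.DataFrame  # same shape, display-class strings
    interpretations: dict[str, SampleInterpretation]

    @property
    def interpretation_row(self) -> dict[str, str]:
        return {
            sid: summary_line(interp) for sid, interp in self.interpretations.items()
        }


def summary_line(interp: SampleInterpretation) -> str:
    """One-line human-readable verdict for the interpretation row."""
    if interp.status is SampleStatus.POSITIVE:
        fusions = ", ".join(f.fusion_id for f in interp.positive_fusions)
        return f"POSITIVE: {fusions}"
    if interp.status is SampleStatus.REVIEW:
        fusions = ", ".join(f.fusion_id for f in interp.review_fusions)
        return f"REVIEW: repeat with more RNA to check {fusions}"
    if interp.status is SampleStatus.NEGATIVE:
        return "negative"
    if interp.status is SampleStatus.FAILED_RNA:
        return "failed RNA; repeat with more RNA"
    if interp.status is SampleStatus.FAILED_ASSAY:
        return "failed assay controls; fusion calls voided"
    if interp.status is SampleStatus.HIGH_BACKGROUND:
        return "high background; repeat with less RNA"
    return "not interpretable"


def _cell_class(
    probe_kind: ProbeKind,
    probe_id: str,
    interp: SampleInterpretation,
    call_index: Mapping[str, ProbeStatus],
) -> str:
    if probe_kind is ProbeKind.HOUSEKEEPING:
        check = interp.rna_qc.per_probe.get(probe_id)
        if check is None:
            return "plain"
        return "hk_pass" if check.passed else "hk_fail"
    if probe_kind is ProbeKind.FUSION:
        if interp.status is SampleStatus.FAILED_ASSAY:
            return "plain"
        status = call_index.get(probe_id)
        if status is ProbeStatus.POSITIVE:
            return "positive"
        if status is ProbeStatus.REVIEW:
            return "review"
    return "plain"


def build_run_report(
    interps: Sequence[SampleInterpretation],
    samples: Sequence[SampleCounts],
    calib: CalibrationTable,
    manifest: PanelManifest,
    run_id: str = "run",
) -> RunReport:
    """Assemble the grid and classes for one run (no side effects)."""
    by_id = {s.sample_id: s for s in samples}
    if set(i.sample_id for i in interps) - set(by_id):
        missing = sorted(set(i.sample_id for i in interps) - set(by_id))
        raise ValueError(f"interpretations without counts: {missing}")
    sample_ids = [i.sample_id for i in interps]
    probe_ids = manifest.probe_ids

    counts: dict[str, list[int | None]] = {}
    classes: dict[str, list[str]] = {}
    for interp in interps:
        sample = by_id[interp.sample_id]
        call_index = {c.probe_id: c.status for c in interp.probe_calls}
        col_counts: list[int | None] = []
        col_classes: list[str] = []
        for probe_id in probe_ids:
            col_counts.append(sample.counts.get(probe_id))
            col_classes.append(
                _cell_class(manifest.probe(probe_id).kind, probe_id, interp, call_index)
            )
        counts[interp.sample_id] = col_counts
        classes[interp.sample_id] = col_classes

    counts_df = pd.DataFrame(counts, index=probe_ids, columns=sample_ids, dtype=object)
    classes_df = pd.DataFrame(classes, index=probe_ids, columns=sample_ids)
    return RunReport(
        run_id=run_id,
        counts=counts_df,
        classes=classes_df,
        interpretations={i.sample_id: i for i in interps},
    )


def _report_to_html(report: RunReport) -> str:
    head = (
        "<html><head><style>"
        "table{border-collapse:collapse;font-family:sans-serif;font-size:12px}"
        "td,th{border:1px solid #999;padding:2px 6px;text-align:right}"
        "th{background:#eee}"
        + "".join(
            f".{cls}{{background:{color}}}"
            for cls, color in PALETTE.items()
            if color
        )
        + "</style></head><body>"
    )
    rows = [f"<h2>Run {_html.escape(report.run_id)}</h2>", "<table>"]
    rows.append(
        "<tr><th>Probe set</th>"
        + "".join(f"<th>{_html.escape(str(c))}</th>" for c in report.counts.columns)
        + "</tr>"
    )
    for probe_id in report.counts.index:
        cells = []
        for sid in report.counts.columns:
            value = report.counts.at[probe_id, sid]
            cls = report.classes.at[probe_id, sid]
            shown = "" if value is None else str(value)
            cls_attr = f' class="{cls}"' if cls != "plain" else ""
            cells.append(f"<td{cls_attr}>{shown}</td>")
        rows.append(f"<tr><th>{_html.escape(str(probe_id))}</th>{''.join(cells)}</tr>")
    row = report.interpretation_row
    rows.append(
        "<tr><th>Interpretation</th>"
        + "".join(f"<td>{_html.escape(row[str(sid)])}</td>" for sid in report.counts.columns)
        + "</tr>"
    )
    rows.append("</table></body></html>")
    return head + "".join(rows)


def render_run(
    interps: Sequence[SampleInterpretation],
    samples: Sequence[SampleCounts],
    calib: CalibrationTable,
    manifest: PanelManifest,
    fmt: str = "html",
    run_id: str = "run",
) -> str | dict[str, str]:
    """Render one run in the requested format.

    ``"html"`` returns a standalone HTML page.  ``"csv"`` returns a
    mapping with a ``grid.csv`` counts grid and a ``classes.json``
    sidecar of per-cell display classes plus the interpretation row
    (spreadsheet-compatible: the CSV carries the numbers, the sidecar
    the conditional-formatting classes).
    """
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unknown report format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    report = build_run_report(interps, samples, calib, manifest, run_id=run_id)
    if fmt == "html":
        return _report_to_html(report)
    grid = report.counts.copy()
    grid.index.name = "Probe set"
    sidecar = {
        "run_id": report.run_id,
        "classes": {
            sid: dict(zip(report.classes.index, report.classes[sid]))
            for sid in report.classes.columns
        },
        "interpretation": report.interpretation_row,
        "palette": PALETTE,
    }
    return {"grid.csv": grid.to_csv(), "classes.json": json.dumps(sidecar, indent=2)}


@dataclass
class CohortSummary:
    """Tallies of interpretation statuses and positive fusion identities."""

    status_counts: dict[SampleStatus, int]
    fusion_counts: dict[str, int]
    n_samples: int

    @property
    def n_interpretable(self) -> int:
        uninterpretable = {
            SampleStatus.FAILED_RNA,
            SampleStatus.FAILED_ASSAY,
            SampleStatus.NOT_INTERPRETABLE,
        }
        return sum(
            n for status, n in self.status_counts.items() if status not in uninterpretable
        )

    @property
    def positive_fraction(self) -> float | None:
        """Fraction of interpretable samples that are fusion-positive."""
        n = self.n_interpretable
        if n == 0:
            return None
        return self.status_counts.get(SampleStatus.POSITIVE, 0) / n

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "status_counts": {s.value: n for s, n in self.status_counts.items()},
            "fusion_counts": dict(self.fusion_counts),
            "positive_fraction": self.positive_fraction,
        }


def summarize_cohort(
    interps: Iterable[SampleInterpretation],
    exclude: frozenset[str] | set[str] = frozenset(),
) -> CohortSummary:
    """Tally statuses and positive fusions over a cohort.

    ``exclude`` lists sample ids (e.g. spiked control lanes) to leave
    out of the tallies.
    """
    status_counts: Counter[SampleStatus] = Counter()
    fusion_counts: Counter[str] = Counter()
    n = 0
    for interp in interps:
        if interp.sample_id in exclude:
            continue
        n += 1
        status_counts[interp.status] += 1
        if interp.status is SampleStatus.POSITIVE:
            for fusion in interp.positive_fusions:
                fusion_counts[fusion.fusion_id] += 1
    return CohortSummary(
        status_counts=dict(status_counts),
        fusion_counts=dict(fusion_counts),
        n_samples=n,
    )
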