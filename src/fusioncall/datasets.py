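"""Bundled example data: one worked Heme 1 run.

The package ships a byte-stable transcription of a single 9-lane run of
the two-tube hematologic fusion panel — raw counts for 6 positive
controls, 6 negative controls, 13 fusion breakpoint probes and 5
housekeeping probes, together with the laboratory's printed positivity
cutoffs and housekeeping thresholds.  The run exercises every
interpretation outcome: clean positives, a review-zone flag, a clean
negative, a degraded-RNA lane, a lane with collapsed assay controls,
and a spiked positive-control lane (``IVS-020``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .calibration import CalibrationTable
from .io import SampleCounts, read_calibration, read_count_table
from .panel import PanelManifest, load_manifest

_DATA_DIR = Path(__file__).parent / "data"

MANIFEST_FILE = _DATA_DIR / "heme1_example.manifest.tsv"
COUNTS_FILE = _DATA_DIR / "heme1_example_counts.tsv"
CALIBRATION_FILE = _DATA_DIR / "heme1_example_calibration.tsv"
PANEL_CONTENT_FILE = _DATA_DIR / "heme_panel_content.tsv"


@dataclass
class ExampleRun:
    """The bundled worked-example run, fully loaded."""

    manifest: PanelManifest
    samples: list[SampleCounts]
    calibration: CalibrationTable
    #: lanes that are spiked controls, not patient samples; excluded
    #: from cohort tallies.
    control_ids: frozenset[str]

    def sample(self, sample_id: str) -> SampleCounts:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def example_heme1_run() -> ExampleRun:
    """Load the bundled worked-example Heme 1 run."""
    manifest = load_manifest(MANIFEST_FILE)
    samples = read_count_table(COUNTS_FILE, manifest)
    calibration = read_calibration(CALIBRATION_FILE)
    return ExampleRun(
        manifest=manifest,
        samples=samples,
        calibration=calibration,
        control_ids=frozenset({"IVS-020"}),
    )


def panel_content():
    """Reference metadata for the full two-tube hematologic panel.

    One row per fusion (or fusion family): the number of breakpoint
    probe sets it carries, its published pediatric/adolescent cancer
    association (verbatim), the closed-set lineage labels that
    association maps onto, and how many positives of that fusion were in
    the validation sample set.  Per-family probe-set counts are stored
    as printed; no claim is made that they sum to the panel's total
    breakpoint count.  Individual breakpoint sequences are not modeled.

    Returns a :class:`pandas.DataFrame` indexed by ``fusion_id``.
    """
    import pandas as pd

    frame = pd.read_csv(PANEL_CONTENT_FILE, sep="\t", dtype={"fusion_id": str})
    return frame.set_index("fusion_id")
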