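"""Shared fixtures: the bundled worked-example run and a small toy panel."""

from __future__ import annotations

import pytest

from fusioncall import (
    Lineage,
    PanelManifest,
    ProbeKind,
    ProbeSet,
    SampleCounts,
    Tube,
    example_heme1_run,
)

# healthy assay-control counts used when composing synthetic lanes by hand
GOOD_CONTROLS = {
    "POS_A": 36000,
    "POS_B": 11000,
    "POS_C": 3200,
    "POS_D": 780,
    "POS_E": 230,
    "POS_F": 80,
    "NEG_A": 5,
    "NEG_B": 4,
    "NEG_C": 6,
    "NEG_D": 3,
    "NEG_E": 7,
    "NEG_F": 9,
}


@pytest.fixture(scope="session")
def run():
    return example_heme1_run()


@pytest.fixture(scope="session")
def manifest(run):
    return run.manifest


@pytest.fixture(scope="session")
def calib(run):
    return run.calibration


@pytest.fixture(scope="session")
def lanes(run):
    return {s.sample_id: s for s in run.samples}


def make_toy_manifest() -> PanelManifest:
    """Tiny panel: 4 fusion probes over 3 fusions, full control/hk set."""
    probes = [ProbeSet(f"POS_{c}", ProbeKind.POS_CONTROL) for c in "ABCDEF"]
    probes += [ProbeSet(f"NEG_{c}", ProbeKind.NEG_CONTROL) for c in "ABCDEF"]
    probes += [
        ProbeSet(
            "AA(ex1):BB(ex2)",
            ProbeKind.FUSION,
            fusion_id="AA::BB",
            tube=Tube.HEME1,
            lineages=frozenset({Lineage.AML}),
        ),
        ProbeSet(
            "AA(ex3):BB(ex2)",
            ProbeKind.FUSION,
            fusion_id="AA::BB",
            tube=Tube.HEME1,
            lineages=frozenset({Lineage.AML}),
        ),
        ProbeSet(
            "CC(ex1):DD(ex1)",
            ProbeKind.FUSION,
            fusion_id="CC::DD",
            tube=Tube.HEME1,
            lineages=frozenset({Lineage.B_ALL, Lineage.CML}),
        ),
        ProbeSet(
            "EE(ex1):FF(ex1)",
            ProbeKind.FUSION,
            fusion_id="EE::FF",
            tube=Tube.HEME1,
        ),
    ]
    probes += [
        ProbeSet(name, ProbeKind.HOUSEKEEPING)
        for name in ("B2M", "EEF2", "GUSB", "PGK1", "TBP")
    ]
    return PanelManifest(name="toy", probes=probes)


@pytest.fixture
def toy_manifest():
    return make_toy_manifest()


def make_lane(
    sample_id: str = "L1",
    fusion_counts: dict[str, int | None] | None = None,
    hk_counts: dict[str, int | None] | None = None,
    control_counts: dict[str, int] | None = None,
    tube: Tube | None = Tube.HEME1,
) -> SampleCounts:
    """A hand-built toy-panel lane with healthy controls and adequate RNA."""
    counts: dict[str, int | None] = dict(GOOD_CONTROLS)
    counts.update(control_counts or {})
    hk_defaults = {"B2M": 20000, "EEF2": 8000, "GUSB": 500, "PGK1": 2500, "TBP": 150}
    hk_defaults.update(hk_counts or {})
    counts.update(hk_defaults)
    fusion_defaults: dict[str, int | None] = {
        "AA(ex1):BB(ex2)": 5,
        "AA(ex3):BB(ex2)": 6,
        "CC(ex1):DD(ex1)": 4,
        "EE(ex1):FF(ex1)": 7,
    }
    fusion_defaults.update(fusion_counts or {})
    counts.update(fusion_defaults)
    return SampleCounts(sample_id=sample_id, counts=counts, tube=tube)
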