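"""Probe- and sample-level fusion calling with repeat/reflex logic.

Each fusion probe is classified against its calibrated background
cutoffs with strict inequalities: a count more than 5 SD above the
negative-sample mean (``count > cut5``) is POSITIVE; more than 3 SD
above (``count > cut3``) but not past ``cut5`` is REVIEW (flagged for
repeat testing); otherwise NEGATIVE.  A count exactly at ``cut5``
is therefore REVIEW, and exactly at ``cut3`` is NEGATIVE.

Sample interpretation applies, in order of precedence:

1. failed assay controls void the whole lane (no fusion calls are
   emitted, however high individual counts are) — the hybridization
   itself is untrustworthy;
2. flags spread across many distinct fusions indicate nonspecific high
   background, prompting a repeat with less RNA;
3. any POSITIVE probe makes the sample positive — inadequate RNA is
   noted but does not veto a positive call, since the adequacy
   requirement guards only negative calls;
4. any REVIEW probe prompts a repeat with more RNA naming the flagged
   fusion(s);
5. an otherwise-clean lane with adequate RNA is NEGATIVE (and, for a
   first-tube lane under reflex testing, triggers a second-tube
   recommendation);
6. a clean lane with inadequate RNA failed RNA quality and is repeated
   with more RNA.

Reflex testing runs the second tube only when the first tube is cleanly
negative; failed or review lanes are repeated, not reflexed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .calibration import CalibrationTable
from .io import SampleCounts
from .panel import Lineage, PanelManifest, Tube, lineages_for
from .qc import (
    AssayControlThresholds,
    AssayQC,
    RnaQC,
    assess_assay_controls,
    assess_rna_quality,
)


class ProbeStatus(enum.Enum):
    NEGATIVE = "NEGATIVE"
    REVIEW = "REVIEW"
    POSITIVE = "POSITIVE"
    UNCALIBRATED = "UNCALIBRATED"
    MISSING = "MISSING"


#: statuses that flag a probe for attention, ranked.
_FLAGGED = {ProbeStatus.REVIEW, ProbeStatus.POSITIVE}


class SampleStatus(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    REVIEW = "REVIEW"
    FAILED_RNA = "FAILED_RNA"
    FAILED_ASSAY = "FAILED_ASSAY"
    HIGH_BACKGROUND = "HIGH_BACKGROUND"
    NOT_INTERPRETABLE = "NOT_INTERPRETABLE"


class Recommendation(enum.Enum):
    NONE = "NONE"
    REPEAT_MORE_RNA = "REPEAT_MORE_RNA"
    REPEAT_LESS_RNA = "REPEAT_LESS_RNA"
    REFLEX_HEME2 = "REFLEX_HEME2"


class Concordance(enum.Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"
    NOT_ASSESSABLE = "NOT_ASSESSABLE"


@dataclass(frozen=True)
class ProbeCall:
    """Classification of one fusion probe in one lane."""

    probe_id: str
    fusion_id: str
    count: int | None
    cut3: float | None
    cut5: float | None
    status: ProbeStatus


@dataclass
class FusionCall:
    """All probe calls for one fusion in one lane, plus its overall status."""

    fusion_id: str
    calls: list[ProbeCall]

    @property
    def status(self) -> ProbeStatus:
        if any(c.status is ProbeStatus.POSITIVE for c in self.calls):
            return ProbeStatus.POSITIVE
        if any(c.status is ProbeStatus.REVIEW for c in self.calls):
            return ProbeStatus.REVIEW
        return ProbeStatus.NEGATIVE

    @property
    def signal_ratio(self) -> float:
        """Largest count/cut5 ratio across this fusion's probes (display order)."""
        best = 0.0
        for c in self.calls:
            if c.count is not None and c.cut5 is not None and c.cut5 > 0:
                best = max(best, c.count / c.cut5)
        return best


@dataclass(frozen=True)
class InterpretationConfig:
    """Tunable knobs of sample interpretation."""

    #: more than this many distinct flagged fusions means nonspecific
    #: high background rather than a real multi-fusion sample.
    high_background_k: int = 5
    #: recommend running the second tube after a clean first-tube negative.
    reflex: bool = True
    #: fraction of MISSING fusion probes past which a lane is not interpretable.
    missing_fraction: float = 0.5
    assay_thresholds: AssayControlThresholds = field(
        default_factory=AssayControlThresholds
    )


@dataclass
class SampleInterpretation:
    """The per-lane verdict: status, fusion calls, QC, recommendation."""

    sample_id: str
    status: SampleStatus
    assay_qc: AssayQC
    rna_qc: RnaQC
    positive_fusions: list[FusionCall] = field(default_factory=list)
    review_fusions: list[FusionCall] = field(default_factory=list)
    probe_calls: list[ProbeCall] = field(default_factory=list)
    recommendation: Recommendation = Recommendation.NONE
    notes: list[str] = field(default_factory=list)
    tube: Tube | None = None


def score_probes(
    sample: SampleCounts,
    calib: CalibrationTable,
    manifest: PanelManifest,
) -> list[ProbeCall]:
    """Classify every fusion probe of the sample's tube against its cutoffs."""
    calls: list[ProbeCall] = []
    for probe in manifest.fusion_probes:
        if (
            sample.tube is not None
            and probe.tube is not None
            and probe.tube is not sample.tube
        ):
            continue
        count = sample.counts.get(probe.probe_id)
        entry = calib.fusion.get(probe.probe_id)
        if entry is None:
            status, cut3, cut5 = ProbeStatus.UNCALIBRATED, None, None
        else:
            cut3, cut5 = entry.cut3, entry.cut5
            if count is None:
                status = ProbeStatus.MISSING
            elif count > cut5:
                status = ProbeStatus.POSITIVE
            elif count > cut3:
                status = ProbeStatus.REVIEW
            else:
                status = ProbeStatus.NEGATIVE
        assert probe.fusion_id is not None
        calls.append(
            ProbeCall(
                probe_id=probe.probe_id,
                fusion_id=probe.fusion_id,
                count=count,
                cut3=cut3,
                cut5=cut5,
                status=status,
            )
        )
    return calls


def _group_by_fusion(calls: list[ProbeCall]) -> list[FusionCall]:
    grouped: dict[str, list[ProbeCall]] = {}
    for call in calls:
        grouped.setdefault(call.fusion_id, []).append(call)
    return [FusionCall(fusion_id=fid, calls=cs) for fid, cs in grouped.items()]


def interpret_sample(
    sample: SampleCounts,
    calib: CalibrationTable,
    manifest: PanelManifest,
    config: InterpretationConfig | None = None,
) -> SampleInterpretation:
    """Produce the per-lane verdict (see module docstring for precedence)."""
    cfg = config or InterpretationConfig()
    assay_qc = assess_assay_controls(sample, manifest, cfg.assay_thresholds)
    rna_qc = assess_rna_quality(sample, calib, manifest)

    def interp(**kwargs) -> SampleInterpretation:
        return SampleInterpretation(
            sample_id=sample.sample_id,
            assay_qc=assay_qc,
            rna_qc=rna_qc,
            tube=sample.tube,
            **kwargs,
        )

    if not assay_qc.passed:
        return interp(
            status=SampleStatus.FAILED_ASSAY,
            recommendation=Recommendation.REPEAT_MORE_RNA,
            notes=["assay controls failed; fusion probe counts are not interpretable"]
            + assay_qc.reasons,
        )

    calls = score_probes(sample, calib, manifest)
    if calls:
        n_missing = sum(1 for c in calls if c.status is ProbeStatus.MISSING)
        if n_missing / len(calls) >= cfg.missing_fraction:
            return interp(
                status=SampleStatus.NOT_INTERPRETABLE,
                probe_calls=calls,
                notes=[
                    f"{n_missing}/{len(calls)} fusion probe counts missing; "
                    "lane not interpretable"
                ],
            )

    fusions = _group_by_fusion(calls)
    flagged = [f for f in fusions if f.status in _FLAGGED]
    positives = sorted(
        (f for f in flagged if f.status is ProbeStatus.POSITIVE),
        key=lambda f: -f.signal_ratio,
    )
    reviews = sorted(
        (f for f in flagged if f.status is ProbeStatus.REVIEW),
        key=lambda f: -f.signal_ratio,
    )

    if len(flagged) > cfg.high_background_k:
        return interp(
            status=SampleStatus.HIGH_BACKGROUND,
            probe_calls=calls,
            recommendation=Recommendation.REPEAT_LESS_RNA,
            notes=[
                f"{len(flagged)} distinct fusions flagged (> {cfg.high_background_k}); "
                "nonspecific high background, repeat with less RNA"
            ],
        )

    if positives:
        notes = []
        if not rna_qc.adequate:
            notes.append(
                f"RNA quality inadequate ({rna_qc.n_pass}/{rna_qc.n_evaluable} "
                "housekeeping probes passed); positive calls retained"
            )
        return interp(
            status=SampleStatus.POSITIVE,
            positive_fusions=positives,
            review_fusions=reviews,
            probe_calls=calls,
            notes=notes,
        )

    if reviews:
        named = ", ".join(f.fusion_id for f in reviews)
        return interp(
            status=SampleStatus.REVIEW,
            review_fusions=reviews,
            probe_calls=calls,
            recommendation=Recommendation.REPEAT_MORE_RNA,
            notes=[f"repeat with more RNA to check {named}"],
        )

    if rna_qc.adequate:
        recommendation = Recommendation.NONE
        if cfg.reflex and sample.tube is Tube.HEME1:
            recommendation = Recommendation.REFLEX_HEME2
        return interp(
            status=SampleStatus.NEGATIVE,
            probe_calls=calls,
            recommendation=recommendation,
        )

    return interp(
        status=SampleStatus.FAILED_RNA,
        probe_calls=calls,
        recommendation=Recommendation.REPEAT_MORE_RNA,
        notes=[
            f"RNA quality inadequate ({rna_qc.n_pass}/{rna_qc.n_evaluable} "
            "housekeeping probes passed); repeat with more RNA"
        ],
    )


def reflex_decision(heme1: SampleInterpretation) -> bool:
    """Should the second tube be run, given the first tube's verdict?

    True exactly when the first tube is cleanly NEGATIVE.  Failed or
    review lanes are repeated rather than reflexed.
    """
    if heme1.tube is not Tube.HEME1:
        raise ValueError(
            f"reflex decision applies to {Tube.HEME1.value} interpretations; "
            f"got tube {heme1.tube.value if heme1.tube else None!r} "
            f"for sample {heme1.sample_id!r}"
        )
    return heme1.status is SampleStatus.NEGATIVE


def check_concordance(
    interp: SampleInterpretation,
    flow_lineage: Lineage | None,
    manifest: PanelManifest,
) -> Concordance:
    """Compare fusion calls with the flow-cytometry immunophenotype.

    ``flow_lineage=None`` means flow cytometry detected no leukemia.
    A positive sample is concordant when every lineage-annotated
    positive fusion's lineage set contains the flow lineage, and
    discordant when some annotated fusion excludes it (or when flow saw
    no leukemia at all).  A clean negative concords with a
    flow-negative; a negative panel does not contradict a flow-detected
    leukemia (many leukemias carry no panel fusion), so that pairing —
    like any failed or review lane or a fusion without lineage
    annotation — is not assessable.
    """
    if interp.status in (
        SampleStatus.FAILED_RNA,
        SampleStatus.FAILED_ASSAY,
        SampleStatus.REVIEW,
        SampleStatus.HIGH_BACKGROUND,
        SampleStatus.NOT_INTERPRETABLE,
    ):
        return Concordance.NOT_ASSESSABLE
    if interp.status is SampleStatus.POSITIVE:
        lineage_sets = [
            lineages_for(manifest, f.fusion_id) for f in interp.positive_fusions
        ]
        annotated = [s for s in lineage_sets if s]
        if not annotated:
            return Concordance.NOT_ASSESSABLE
        if flow_lineage is None:
            return Concordance.DISCORDANT
        if any(flow_lineage not in s for s in annotated):
            return Concordance.DISCORDANT
        return Concordance.CONCORDANT
    # NEGATIVE
    if flow_lineage is None:
        return Concordance.CONCORDANT
    return Concordance.NOT_ASSESSABLE
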