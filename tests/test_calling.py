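"""Probe and sample classification, reflex and concordance rules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fusioncall import (
    Concordance,
    InterpretationConfig,
    Lineage,
    ProbeStatus,
    Recommendation,
    SampleCounts,
    SampleStatus,
    Tube,
    check_concordance,
    interpret_sample,
    lineages_for,
    reflex_decision,
    score_probes,
)

from conftest import make_lane, make_toy_manifest


def brute_force_status(count, entry):
    """Independent re-derivation of a probe status from first principles."""
    if entry is None:
        return ProbeStatus.UNCALIBRATED
    if count is None:
        return ProbeStatus.MISSING
    if count > entry.cut5:
        return ProbeStatus.POSITIVE
    if count > entry.cut3:
        return ProbeStatus.REVIEW
    return ProbeStatus.NEGATIVE


class TestScoreProbes:
    @pytest.mark.parametrize(
        ("sample_id", "probe_id", "count", "status"),
        [
            ("5", "RUNX1(ex6):RUNX1T1(ex2)", 373, ProbeStatus.POSITIVE),
            ("6", "CBFB(ex5):MYH11 (type A)(ex33)", 23, ProbeStatus.REVIEW),
            ("8", "ETV6(ex3):RUNX1(ex3)", 13, ProbeStatus.NEGATIVE),
            ("IVS-020", "PML(ex6):RARA(ex3)", 44, ProbeStatus.POSITIVE),
        ],
    )
    def test_worked_example_probe_calls(self, run, sample_id, probe_id, count, status):
        calls = {
            c.probe_id: c
            for c in score_probes(run.sample(sample_id), run.calibration, run.manifest)
        }
        assert calls[probe_id].count == count
        assert calls[probe_id].status is status

    @pytest.mark.parametrize(
        ("count", "status"),
        [
            (28, ProbeStatus.REVIEW),  # exactly at cut5: not positive
            (29, ProbeStatus.POSITIVE),
            (21, ProbeStatus.NEGATIVE),  # exactly at cut3: not review
            (22, ProbeStatus.REVIEW),
        ],
    )
    def test_strict_threshold_boundaries(self, run, count, status):
        # BCR(ex1):ABL1(ex3) has cut3=21, cut5=28
        lane = dataclasses.replace(
            run.sample("8"),
            counts={**run.sample("8").counts, "BCR(ex1):ABL1(ex3)": count},
        )
        calls = {c.probe_id: c for c in score_probes(lane, run.calibration, run.manifest)}
        assert calls["BCR(ex1):ABL1(ex3)"].status is status

    def test_uncalibrated_probe_status(self, run):
        calib = dataclasses.replace(run.calibration)
        calib.fusion = {
            k: v for k, v in run.calibration.fusion.items() if "PML" not in k
        }
        calls = {c.probe_id: c for c in score_probes(run.sample("5"), calib, run.manifest)}
        assert calls["PML(ex6):RARA(ex3)"].status is ProbeStatus.UNCALIBRATED

    def test_brute_force_equivalence_on_random_lanes(self, run):
        """Naive per-(probe, cutoff) re-scan reproduces every call on 1000
        random lanes."""
        rng = np.random.default_rng(2024)
        probe_ids = [p.probe_id for p in run.manifest.fusion_probes]
        for i in range(1000):
            counts: dict[str, int | None] = {}
            for pid in probe_ids:
                if rng.random() < 0.02:
                    counts[pid] = None
                else:
                    counts[pid] = int(rng.integers(0, 400))
            lane = SampleCounts(sample_id=f"R{i}", counts=counts, tube=Tube.HEME1)
            for call in score_probes(lane, run.calibration, run.manifest):
                expected = brute_force_status(
                    counts[call.probe_id], run.calibration.fusion.get(call.probe_id)
                )
                assert call.status is expected


GOLDEN = {
    "5": (SampleStatus.POSITIVE, ["RUNX1::RUNX1T1"], Recommendation.NONE),
    "6": (SampleStatus.REVIEW, [], Recommendation.REPEAT_MORE_RNA),
    "8": (SampleStatus.NEGATIVE, [], Recommendation.REFLEX_HEME2),
    "15": (SampleStatus.POSITIVE, ["RBM15::MKL1"], Recommendation.NONE),
    "16": (SampleStatus.FAILED_RNA, [], Recommendation.REPEAT_MORE_RNA),
    "22": (SampleStatus.POSITIVE, ["EBF1::PDGFRB"], Recommendation.NONE),
    "24": (SampleStatus.POSITIVE, ["TCF3::PBX1"], Recommendation.NONE),
    "24C": (SampleStatus.FAILED_ASSAY, [], Recommendation.REPEAT_MORE_RNA),
    "IVS-020": (SampleStatus.POSITIVE, ["PML::RARA"], Recommendation.NONE),
}


class TestInterpretSample:
    @pytest.mark.parametrize("sample_id", list(GOLDEN))
    def test_worked_example_interpretations(self, run, sample_id):
        status, fusions, recommendation = GOLDEN[sample_id]
        interp = interpret_sample(run.sample(sample_id), run.calibration, run.manifest)
        assert interp.status is status
        assert [f.fusion_id for f in interp.positive_fusions] == fusions
        assert interp.recommendation is recommendation

    def test_review_lane_names_the_flagged_fusion(self, run):
        interp = interpret_sample(run.sample("6"), run.calibration, run.manifest)
        assert [f.fusion_id for f in interp.review_fusions] == ["CBFB::MYH11"]
        assert any("CBFB::MYH11" in note for note in interp.notes)

    def test_all_zero_counts_with_good_controls_is_negative(self, toy_manifest, run):
        from fusioncall import estimate_background

        negatives = [
            make_lane(f"N{i}", fusion_counts=None) for i in range(6)
        ]
        calib = estimate_background(negatives, toy_manifest)
        calib.hk_thresholds = {"B2M": 5316.0, "EEF2": 920.0, "GUSB": 97.0,
                               "PGK1": 683.0, "TBP": 27.0}
        lane = make_lane(
            "Z",
            fusion_counts={p.probe_id: 0 for p in toy_manifest.fusion_probes},
        )
        interp = interpret_sample(lane, calib, toy_manifest)
        assert interp.status is SampleStatus.NEGATIVE

    def test_qc_precedence_voids_calls_despite_high_counts(self, run):
        """Grafting the collapsed control ladder onto any lane forces
        FAILED_ASSAY with no fusion calls, whatever the fusion counts."""
        collapsed = run.sample("24C")
        for sample in run.samples:
            counts = dict(sample.counts)
            for pid in run.manifest.pos_control_ids + run.manifest.neg_control_ids:
                counts[pid] = collapsed.counts[pid]
            grafted = dataclasses.replace(sample, counts=counts)
            interp = interpret_sample(grafted, run.calibration, run.manifest)
            assert interp.status is SampleStatus.FAILED_ASSAY
            assert interp.positive_fusions == [] and interp.probe_calls == []

    def test_collapsed_lane_pml_count_is_above_cutoff_yet_voided(self, run):
        # the collapsed-control lane would read fusion-positive if trusted
        lane = run.sample("24C")
        assert lane.counts["PML(ex6):RARA(ex3)"] == 82
        assert run.calibration.fusion["PML(ex6):RARA(ex3)"].cut5 == 30
        interp = interpret_sample(lane, run.calibration, run.manifest)
        assert interp.status is SampleStatus.FAILED_ASSAY
        assert interp.positive_fusions == []

    def test_many_flagged_fusions_is_high_background(self, run):
        lane = run.sample("8")
        counts = dict(lane.counts)
        fusion_probes = run.manifest.fusion_probes
        for probe in fusion_probes:
            entry = run.calibration.fusion[probe.probe_id]
            counts[probe.probe_id] = int(entry.cut3) + 5
        noisy = dataclasses.replace(lane, counts=counts)
        interp = interpret_sample(noisy, run.calibration, run.manifest)
        assert interp.status is SampleStatus.HIGH_BACKGROUND
        assert interp.recommendation is Recommendation.REPEAT_LESS_RNA

    def test_positive_survives_inadequate_rna_with_note(self, run):
        lane = run.sample("16")  # failed RNA
        counts = dict(lane.counts)
        counts["PML(ex6):RARA(ex3)"] = 500
        spiked = dataclasses.replace(lane, counts=counts)
        interp = interpret_sample(spiked, run.calibration, run.manifest)
        assert interp.status is SampleStatus.POSITIVE
        assert any("RNA quality inadequate" in n for n in interp.notes)

    def test_mostly_missing_lane_not_interpretable(self, run):
        lane = run.sample("8")
        counts = dict(lane.counts)
        for probe in run.manifest.fusion_probes[:8]:
            counts[probe.probe_id] = None
        holey = dataclasses.replace(lane, counts=counts)
        interp = interpret_sample(holey, run.calibration, run.manifest)
        assert interp.status is SampleStatus.NOT_INTERPRETABLE

    def test_raising_a_positive_count_never_demotes(self, run):
        lane = run.sample("5")
        for boost in (1, 10, 1000, 100_000):
            counts = dict(lane.counts)
            counts["RUNX1(ex6):RUNX1T1(ex2)"] = 373 + boost
            interp = interpret_sample(
                dataclasses.replace(lane, counts=counts), run.calibration, run.manifest
            )
            assert interp.status is SampleStatus.POSITIVE
            assert "RUNX1::RUNX1T1" in [f.fusion_id for f in interp.positive_fusions]

    def test_reflex_off_gives_no_recommendation(self, run):
        interp = interpret_sample(
            run.sample("8"),
            run.calibration,
            run.manifest,
            InterpretationConfig(reflex=False),
        )
        assert interp.status is SampleStatus.NEGATIVE
        assert interp.recommendation is Recommendation.NONE

    def test_determinism(self, run):
        a = interpret_sample(run.sample("6"), run.calibration, run.manifest)
        b = interpret_sample(run.sample("6"), run.calibration, run.manifest)
        assert a == b


class TestReflexDecision:
    @pytest.mark.parametrize("sample_id", list(GOLDEN))
    def test_reflex_only_on_clean_negative(self, run, sample_id):
        interp = interpret_sample(run.sample(sample_id), run.calibration, run.manifest)
        assert reflex_decision(interp) is (interp.status is SampleStatus.NEGATIVE)

    def test_wrong_tube_rejected(self, run):
        interp = interpret_sample(run.sample("8"), run.calibration, run.manifest)
        interp = dataclasses.replace(interp, tube=Tube.HEME2)
        with pytest.raises(ValueError, match="HEME1"):
            reflex_decision(interp)


class TestConcordance:
    def _positive_interp(self, run, probe_id):
        lane = run.sample("8")
        counts = dict(lane.counts)
        counts[probe_id] = int(run.calibration.fusion[probe_id].cut5) + 500
        return interpret_sample(
            dataclasses.replace(lane, counts=counts), run.calibration, run.manifest
        )

    def test_brute_force_over_the_lineage_map(self, run):
        """For every fusion probe and every lineage, concordance equals
        naive membership in the manifest's lineage map."""
        for probe in run.manifest.fusion_probes:
            interp = self._positive_interp(run, probe.probe_id)
            assert interp.status is SampleStatus.POSITIVE
            lineage_set = lineages_for(run.manifest, probe.fusion_id)
            for lineage in Lineage:
                verdict = check_concordance(interp, lineage, run.manifest)
                if not lineage_set:
                    assert verdict is Concordance.NOT_ASSESSABLE
                elif lineage in lineage_set:
                    assert verdict is Concordance.CONCORDANT
                else:
                    assert verdict is Concordance.DISCORDANT

    @pytest.mark.parametrize(
        ("probe_id", "lineage", "expected"),
        [
            ("PML(ex6):RARA(ex3)", Lineage.AML, Concordance.CONCORDANT),
            ("BCR(ex1):ABL1(ex3)", Lineage.B_ALL, Concordance.CONCORDANT),
            ("BCR(ex1):ABL1(ex3)", Lineage.CML, Concordance.CONCORDANT),
            ("PML(ex6):RARA(ex3)", Lineage.T_ALL, Concordance.DISCORDANT),
            ("PML(ex6):RARA(ex3)", None, Concordance.DISCORDANT),
        ],
    )
    def test_canonical_pairings(self, run, probe_id, lineage, expected):
        interp = self._positive_interp(run, probe_id)
        assert check_concordance(interp, lineage, run.manifest) is expected

    def test_negative_lane_concords_with_flow_negative(self, run):
        interp = interpret_sample(run.sample("8"), run.calibration, run.manifest)
        assert check_concordance(interp, None, run.manifest) is Concordance.CONCORDANT
        assert (
            check_concordance(interp, Lineage.B_ALL, run.manifest)
            is Concordance.NOT_ASSESSABLE
        )

    @pytest.mark.parametrize("sample_id", ["6", "16", "24C"])
    def test_failed_or_review_lanes_not_assessable(self, run, sample_id):
        interp = interpret_sample(run.sample(sample_id), run.calibration, run.manifest)
        assert (
            check_concordance(interp, Lineage.AML, run.manifest)
            is Concordance.NOT_ASSESSABLE
        )
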