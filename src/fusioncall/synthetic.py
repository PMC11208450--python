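"""Simulated fusion-assay runs with ground-truth labels.

The generator emulates the data regimes a real run exhibits: clean
background lanes, fusion-positive lanes with spiked breakpoint probes,
degraded-RNA lanes, lanes whose positive-control ladder collapsed, and
nonspecific high-background lanes.  It exists so calibration, QC,
calling and reporting are testable end-to-end with known truth.

Counts are negative-binomial draws (variance = mean + mean^2/size):
real hybridization background is overdispersed relative to Poisson, and
the ``size`` parameter makes Poisson recoverable as a limit.  Fusion
background defaults (mean 8, size 8) give cutoffs around 20 (review)
and 28 (positive), the magnitude a validated heme panel shows.  Spiked
fusion signal is near-Poisson (large ``size``): a spiked transcript's
abundance is fixed by the spike plan, leaving mostly molecule-counting
noise.  The positive-control ladder decays by ~0.3 per step from a
~35000-count top, resembling real Elements control ladders; a
failed-assay lane collapses the whole ladder to the negative-control
noise level.  A lane's RNA quality factor ``q`` scales housekeeping and
spiked-signal means (degraded RNA loses real transcripts) but not the
nonspecific fusion background.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import CalibrationTable, FusionCutoffs, POSITIVE_SD, REVIEW_SD
from .calling import InterpretationConfig, SampleStatus
from .io import SampleCounts
from .panel import PanelManifest, ProbeKind, Tube

#: default adequate-RNA means for the standard five housekeeping probes.
DEFAULT_HK_MEANS = {
    "B2M": 30000.0,
    "EEF2": 10000.0,
    "GUSB": 800.0,
    "PGK1": 3000.0,
    "TBP": 200.0,
}
_FALLBACK_HK_MEAN = 5000.0


class LaneRole(enum.Enum):
    BACKGROUND = "background"
    POSITIVE = "positive"
    DEGRADED = "degraded"
    FAILED_ASSAY = "failed_assay"
    HIGH_BACKGROUND = "high_background"


@dataclass(frozen=True)
class Spike:
    """Plant a fusion signal: mean = fold_over_cut5 x the probe's cut5."""

    sample_id: str
    fusion_id: str
    fold_over_cut5: float

    def __post_init__(self) -> None:
        if self.fold_over_cut5 <= 0:
            raise ValueError(f"fold_over_cut5 must be > 0, got {self.fold_over_cut5}")


@dataclass(frozen=True)
class LanePlan:
    sample_id: str
    role: LaneRole = LaneRole.BACKGROUND
    rna_quality: float = 1.0  # q in (0, 1]; scales housekeeping and signal means

    def __post_init__(self) -> None:
        if not 0.0 < self.rna_quality <= 1.0:
            raise ValueError(f"rna_quality must be in (0, 1], got {self.rna_quality}")


@dataclass
class SyntheticSpec:
    """Generative parameters for one simulated run."""

    manifest: PanelManifest
    lanes: list[LanePlan]
    spikes: list[Spike] = field(default_factory=list)
    seed: int = 0

    # fusion background count distribution
    bg_mean: float = 8.0
    bg_size: float = 8.0  # NB dispersion; variance = mean + mean^2/size
    bg_overrides: dict[str, float] = field(default_factory=dict)  # per-probe means

    # spiked fusion signal
    signal_size: float = 1000.0  # near-Poisson

    # housekeeping probes
    hk_means: dict[str, float] = field(default_factory=dict)
    hk_size: float = 10.0
    hk_threshold_factor: float = 0.3  # reference threshold = factor x adequate mean

    # assay controls
    pos_base: float = 35000.0
    pos_decay: float = 0.3  # per-step ladder decay factor
    pos_size: float = 100.0
    neg_mean: float = 8.0

    # auto-spiking for HIGH_BACKGROUND lanes without an explicit plan
    high_background_fusions: int = 8
    high_background_fold: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pos_decay < 1.0:
            raise ValueError(f"pos_decay must be in (0, 1), got {self.pos_decay}")
        ids = {lane.sample_id for lane in self.lanes}
        if len(ids) != len(self.lanes):
            raise ValueError("lane sample_ids must be unique")
        fusion_ids = set(self.manifest.fusion_ids)
        for spike in self.spikes:
            if spike.fusion_id not in fusion_ids:
                raise ValueError(
                    f"spike names fusion {spike.fusion_id!r} absent from "
                    f"manifest {self.manifest.name!r}"
                )
            if spike.sample_id not in ids:
                raise ValueError(
                    f"spike names unknown sample {spike.sample_id!r}"
                )

    def background_mean(self, probe_id: str) -> float:
        return self.bg_overrides.get(probe_id, self.bg_mean)

    def hk_mean(self, probe_id: str) -> float:
        if probe_id in self.hk_means:
            return self.hk_means[probe_id]
        return DEFAULT_HK_MEANS.get(probe_id, _FALLBACK_HK_MEAN)


@dataclass(frozen=True)
class LaneTruth:
    """Ground truth for one simulated lane."""

    sample_id: str
    role: LaneRole
    expected_status: SampleStatus
    spiked_fusions: tuple[str, ...]
    rna_quality: float


def reference_calibration(spec: SyntheticSpec) -> CalibrationTable:
    """The exact calibration implied by the generative parameters.

    Background moments are the true negative-binomial mean and SD, so
    cutoffs are mean + 3/5 x sqrt(mean + mean^2/size); housekeeping
    thresholds are ``hk_threshold_factor`` x the adequate-RNA mean.
    """
    fusion: dict[str, FusionCutoffs] = {}
    for probe in spec.manifest.fusion_probes:
        mean = spec.background_mean(probe.probe_id)
        sd = float(np.sqrt(mean + mean**2 / spec.bg_size))
        fusion[probe.probe_id] = FusionCutoffs(
            cut3=mean + REVIEW_SD * sd,
            cut5=mean + POSITIVE_SD * sd,
            bg_mean=mean,
            bg_sd=sd,
        )
    hk = {
        probe_id: spec.hk_threshold_factor * spec.hk_mean(probe_id)
        for probe_id in spec.manifest.housekeeping_ids
    }
    return CalibrationTable(fusion=fusion, hk_thresholds=hk, instrument_id="synthetic")


def _draw(rng: np.random.Generator, mean: float, size: float) -> int:
    if mean <= 0:
        return 0
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _lane_spikes(spec: SyntheticSpec, lane: LanePlan) -> dict[str, float]:
    explicit = {
        s.fusion_id: s.fold_over_cut5
        for s in spec.spikes
        if s.sample_id == lane.sample_id
    }
    if explicit or lane.role is not LaneRole.HIGH_BACKGROUND:
        return explicit
    # auto-plan: lift enough distinct fusions to exceed any sane flag cap
    chosen = spec.manifest.fusion_ids[: spec.high_background_fusions]
    return {fid: spec.high_background_fold for fid in chosen}


def _expected_status(lane: LanePlan, spiked: dict[str, float]) -> SampleStatus:
    if lane.role is LaneRole.FAILED_ASSAY:
        return SampleStatus.FAILED_ASSAY
    if lane.role is LaneRole.HIGH_BACKGROUND:
        # on a small panel the spikes may not span enough distinct
        # fusions to exceed the default flag cap; the honest label is
        # then POSITIVE, not HIGH_BACKGROUND
        if len(spiked) > InterpretationConfig().high_background_k:
            return SampleStatus.HIGH_BACKGROUND
        return SampleStatus.POSITIVE
    if spiked:
        return SampleStatus.POSITIVE
    if lane.role is LaneRole.DEGRADED:
        return SampleStatus.FAILED_RNA
    return SampleStatus.NEGATIVE


def simulate_run(
    spec: SyntheticSpec,
) -> tuple[list[SampleCounts], list[LaneTruth]]:
    """Draw one run: one lane per plan entry, plus per-lane truth labels.

    Fully reproducible given ``spec.seed``: draws are consumed in lane
    order, probes in manifest order within each lane.  Within a spiked
    fusion, the signal lands on its first (manifest-order) breakpoint
    probe, as a real fusion transcript matches one breakpoint.
    """
    rng = np.random.default_rng(spec.seed)
    ref = reference_calibration(spec)
    tube = spec.manifest.uniform_tube()
    samples: list[SampleCounts] = []
    truths: list[LaneTruth] = []

    first_probe_of_fusion: dict[str, str] = {}
    for probe in spec.manifest.fusion_probes:
        assert probe.fusion_id is not None
        first_probe_of_fusion.setdefault(probe.fusion_id, probe.probe_id)

    for lane in spec.lanes:
        spiked = _lane_spikes(spec, lane)
        spiked_probe_fold = {
            first_probe_of_fusion[fid]: fold for fid, fold in spiked.items()
        }
        q = lane.rna_quality
        counts: dict[str, int | None] = {}
        pos_rank = 0
        for probe in spec.manifest.probes:
            pid = probe.probe_id
            if probe.kind is ProbeKind.POS_CONTROL:
                if lane.role is LaneRole.FAILED_ASSAY:
                    mean = spec.neg_mean
                else:
                    mean = spec.pos_base * spec.pos_decay**pos_rank
                pos_rank += 1
                counts[pid] = _draw(rng, mean, spec.pos_size)
            elif probe.kind is ProbeKind.NEG_CONTROL:
                counts[pid] = _draw(rng, spec.neg_mean, spec.pos_size)
            elif probe.kind is ProbeKind.HOUSEKEEPING:
                counts[pid] = _draw(rng, spec.hk_mean(pid) * q, spec.hk_size)
            else:  # FUSION
                if pid in spiked_probe_fold:
                    mean = spiked_probe_fold[pid] * ref.fusion[pid].cut5 * q
                    counts[pid] = _draw(rng, mean, spec.signal_size)
                else:
                    counts[pid] = _draw(
                        rng, spec.background_mean(pid), spec.bg_size
                    )
        samples.append(
            SampleCounts(
                sample_id=lane.sample_id,
                counts=counts,
                instrument_id=ref.instrument_id,
                tube=tube,
            )
        )
        truths.append(
            LaneTruth(
                sample_id=lane.sample_id,
                role=lane.role,
                expected_status=_expected_status(lane, spiked),
                spiked_fusions=tuple(sorted(spiked)),
                rna_quality=q,
            )
        )
    return samples, truths


def default_run_spec(
    manifest: PanelManifest,
    *,
    seed: int,
    n_background: int = 10,
    n_positive: int = 2,
    n_degraded: int = 1,
    n_failed_assay: int = 1,
    n_high_background: int = 0,
    spike_fold: float = 10.0,
    spike_fusions: Sequence[str] | None = None,
    degraded_q: float = 0.1,
    **kwargs,
) -> SyntheticSpec:
    """Convenience factory: a run with the requested mix of lane roles.

    Positive lanes cycle through ``spike_fusions`` (default: the
    manifest's fusions in order) at ``spike_fold`` over the positive
    cutoff.  Extra keyword arguments pass through to
    :class:`SyntheticSpec`.
    """
    fusions = list(spike_fusions) if spike_fusions else manifest.fusion_ids
    if n_positive > 0 and not fusions:
        raise ValueError("manifest has no fusions to spike")
    lanes: list[LanePlan] = []
    spikes: list[Spike] = []
    idx = 1

    def lane_id() -> str:
        nonlocal idx
        sid = f"S{idx:03d}"
        idx += 1
        return sid

    for _ in range(n_background):
        lanes.append(LanePlan(lane_id(), LaneRole.BACKGROUND))
    for i in range(n_positive):
        sid = lane_id()
        lanes.append(LanePlan(sid, LaneRole.POSITIVE))
        spikes.append(Spike(sid, fusions[i % len(fusions)], spike_fold))
    for _ in range(n_degraded):
        lanes.append(LanePlan(lane_id(), LaneRole.DEGRADED, rna_quality=degraded_q))
    for _ in range(n_failed_assay):
        lanes.append(LanePlan(lane_id(), LaneRole.FAILED_ASSAY))
    for _ in range(n_high_background):
        lanes.append(LanePlan(lane_id(), LaneRole.HIGH_BACKGROUND))
    return SyntheticSpec(
        manifest=manifest, lanes=lanes, spikes=spikes, seed=seed, **kwargs
    )
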