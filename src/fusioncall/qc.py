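"""Lane-level quality gates: assay controls and housekeeping RNA quality.

Two independent gates are assessed per lane:

* **Assay controls** — the hybridization reagents carry six synthetic
  positive controls spiked at a descending concentration ladder
  (POS_A highest ... POS_F lowest) and six negative controls.  A healthy
  lane shows a high top-of-ladder count that decays down the ladder and
  near-zero negative controls; a collapsed ladder means the hybridization
  chemistry itself failed and nothing in the lane is interpretable.
* **RNA quality** — five housekeeping transcripts gauge whether enough
  intact RNA entered the reaction.  A lane may only be called
  fusion-negative when at least 3 of the 5 housekeeping probes exceed
  their thresholds; degraded RNA cannot distinguish "no fusion" from
  "no signal".

A housekeeping probe passes on a strict ``count > threshold``
comparison ("above the cutoff" read literally); a count exactly at its
threshold fails.  Missing housekeeping counts are evaluable-and-failed,
the conservative reading.

The numeric assay-control criteria (``pos_floor``, ladder step
tolerance, ``neg_ceiling``) are this package's defaults, chosen to
separate healthy ladders from collapsed ones by a wide margin; all are
configurable, and the negative-control check can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import CalibrationError, CalibrationTable
from .io import SampleCounts
from .panel import PanelManifest

#: a lane is RNA-adequate when at least this many housekeeping probes pass.
REQUIRED_HOUSEKEEPING_PASSES = 3


@dataclass(frozen=True)
class AssayControlThresholds:
    """Configurable numeric criteria for the assay-control gate."""

    pos_floor: float = 1000.0  # counts; minimum top-of-ladder signal
    ladder_tolerance: float = 1.5  # each step may exceed its predecessor by this factor
    neg_ceiling: float = 50.0  # counts; maximum mean negative-control level
    check_negatives: bool = True


@dataclass
class AssayQC:
    """Verdict of the assay-control gate for one lane."""

    pos_ladder_ok: bool
    neg_background_ok: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.pos_ladder_ok and self.neg_background_ok


@dataclass(frozen=True)
class HousekeepingCheck:
    count: int | None
    threshold: float
    passed: bool


@dataclass
class RnaQC:
    """Verdict of the housekeeping RNA-quality gate for one lane."""

    per_probe: dict[str, HousekeepingCheck]

    @property
    def n_evaluable(self) -> int:
        return len(self.per_probe)

    @property
    def n_pass(self) -> int:
        return sum(1 for c in self.per_probe.values() if c.passed)

    @property
    def adequate(self) -> bool:
        return self.n_pass >= REQUIRED_HOUSEKEEPING_PASSES


def assess_assay_controls(
    sample: SampleCounts,
    manifest: PanelManifest,
    thresholds: AssayControlThresholds | None = None,
) -> AssayQC:
    """Gate one lane on its internal positive/negative assay controls.

    The positive ladder passes when the top control reaches
    ``pos_floor`` and counts do not increase down the ladder beyond the
    step tolerance.  The negative check passes when the mean
    negative-control count stays at or below ``neg_ceiling``.
    """
    cfg = thresholds or AssayControlThresholds()
    pos_ids = manifest.pos_control_ids
    neg_ids = manifest.neg_control_ids
    if len(pos_ids) < 4:
        raise ValueError(
            f"manifest {manifest.name!r} declares {len(pos_ids)} positive "
            "controls; at least 4 (in ladder order) are required"
        )
    if not neg_ids:
        raise ValueError(f"manifest {manifest.name!r} declares no negative controls")

    reasons: list[str] = []
    top = sample.counts.get(pos_ids[0])
    if top is None:
        reasons.append(f"uninterpretable control: {pos_ids[0]} count missing")
    elif top < cfg.pos_floor:
        reasons.append(
            f"collapsed positive ladder: top control {pos_ids[0]}={top} "
            f"below floor {cfg.pos_floor:g}"
        )
    previous = top
    for probe_id in pos_ids[1:]:
        value = sample.counts.get(probe_id)
        if value is None:
            continue
        if previous is not None and value > cfg.ladder_tolerance * previous:
            reasons.append(
                f"positive ladder not descending: {probe_id}={value} exceeds "
                f"{cfg.ladder_tolerance:g}x its predecessor ({previous})"
            )
        previous = value
    pos_ok = not reasons

    neg_ok = True
    if cfg.check_negatives:
        values = [v for pid in neg_ids if (v := sample.counts.get(pid)) is not None]
        if not values:
            neg_ok = False
            reasons.append("uninterpretable control: all negative-control counts missing")
        else:
            mean = sum(values) / len(values)
            if mean > cfg.neg_ceiling:
                neg_ok = False
                reasons.append(
                    f"high negative-control background: mean {mean:.1f} exceeds "
                    f"ceiling {cfg.neg_ceiling:g}"
                )
    return AssayQC(pos_ladder_ok=pos_ok, neg_background_ok=neg_ok, reasons=reasons)


def assess_rna_quality(
    sample: SampleCounts,
    calib: CalibrationTable,
    manifest: PanelManifest,
) -> RnaQC:
    """Gate one lane on housekeeping counts against calibrated thresholds."""
    per_probe: dict[str, HousekeepingCheck] = {}
    for probe_id in manifest.housekeeping_ids:
        threshold = calib.hk_thresholds.get(probe_id)
        if threshold is None:
            continue
        count = sample.counts.get(probe_id)
        passed = count is not None and count > threshold
        per_probe[probe_id] = HousekeepingCheck(
            count=count, threshold=threshold, passed=passed
        )
    if not per_probe:
        raise CalibrationError(
            "calibration table carries no housekeeping thresholds for "
            f"manifest {manifest.name!r}; RNA quality cannot be assessed"
        )
    return RnaQC(per_probe=per_probe)
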