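"""Background calibration: per-probe positivity cutoffs from negative lanes.

Fusion probes accumulate a small nonspecific background count even in
samples that do not carry the fusion.  Positivity cutoffs are derived
from a cohort of fusion-negative lanes: for each probe the background
counts are averaged, and a sample is called positive when its count
exceeds the mean by more than 5 standard deviations; counts more than
3 SD above the mean fall into a review zone flagged for repeat testing.

The sample standard deviation (n-1 denominator) is used: calibration
cohorts are small, and the wider cutoffs it yields are the conservative
choice for a diagnostic assay.

Housekeeping thresholds (RNA-adequacy gates) are primarily a configured
input — laboratories set them on validated runs — but
:func:`derive_housekeeping_thresholds` offers a quantile-based helper.

Per-instrument recalibration is supported because background levels
differ between instruments; :func:`recalibrate` recomputes cutoffs from
locally run negative lanes, inheriting cutoffs from the base table for
any probe that cannot be calibrated locally.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .panel import PanelManifest

if TYPE_CHECKING:  # pragma: no cover
    from .io import SampleCounts

logger = logging.getLogger(__name__)

#: absolute tolerance when checking that stored cutoffs equal
#: mean + k*SD — generous enough for tables whose entries were rounded
#: to whole counts before being written out.
CONSISTENCY_ATOL = 0.75

REVIEW_SD = 3.0
POSITIVE_SD = 5.0


class CalibrationError(ValueError):
    """A calibration table or file violates its invariants."""


@dataclass
class FusionCutoffs:
    """Positivity cutoffs for one fusion probe.

    ``cut3``/``cut5`` are the review and positive thresholds
    (mean + 3·SD and mean + 5·SD of the negative background).  The
    moments themselves may be absent when a table carries only printed
    cutoffs; in that case the consistency check is skipped.
    ``inherited`` marks cutoffs carried over from a base table during
    per-instrument recalibration.
    """

    cut3: float
    cut5: float
    bg_mean: float | None = None
    bg_sd: float | None = None
    n: int | None = None
    inherited: bool = False

    def __post_init__(self) -> None:
        if self.cut5 < self.cut3 - 1e-9:
            raise CalibrationError(
                f"cut5 ({self.cut5}) must be >= cut3 ({self.cut3})"
            )
        if self.bg_sd is not None and self.bg_sd < 0:
            raise CalibrationError(f"bg_sd must be >= 0, got {self.bg_sd}")
        if self.bg_mean is not None and self.cut3 < self.bg_mean - 1e-9:
            raise CalibrationError(
                f"cut3 ({self.cut3}) must be >= bg_mean ({self.bg_mean})"
            )
        if self.bg_mean is not None and self.bg_sd is not None:
            for k, cut in ((REVIEW_SD, self.cut3), (POSITIVE_SD, self.cut5)):
                expected = self.bg_mean + k * self.bg_sd
                if abs(cut - expected) > CONSISTENCY_ATOL + 1e-6 * abs(expected):
                    raise CalibrationError(
                        f"cutoff {cut} inconsistent with mean+{k:g}*SD "
                        f"= {expected:.3f}"
                    )


@dataclass
class CalibrationTable:
    """Per-probe background cutoffs plus housekeeping thresholds."""

    fusion: dict[str, FusionCutoffs] = field(default_factory=dict)
    hk_thresholds: dict[str, float] = field(default_factory=dict)
    n_negatives: int | None = None
    instrument_id: str | None = None
    #: fusion probes seen during calibration but with too few usable
    #: values to derive cutoffs; never given fabricated cutoffs.
    uncalibrated: set[str] = field(default_factory=set)

    def copy(self) -> "CalibrationTable":
        return CalibrationTable(
            fusion={k: dataclasses.replace(v) for k, v in self.fusion.items()},
            hk_thresholds=dict(self.hk_thresholds),
            n_negatives=self.n_negatives,
            instrument_id=self.instrument_id,
            uncalibrated=set(self.uncalibrated),
        )


def _usable_values(
    samples: Sequence["SampleCounts"],
    probe_id: str,
    exclude: Mapping[str, Iterable[str]] | None,
) -> list[int]:
    excluded = set(exclude.get(probe_id, ())) if exclude else set()
    values = []
    for s in samples:
        if s.sample_id in excluded:
            continue
        v = s.counts.get(probe_id)
        if v is not None:
            values.append(v)
    return values


def estimate_background(
    negatives: Sequence["SampleCounts"],
    manifest: PanelManifest,
    *,
    exclude: Mapping[str, Iterable[str]] | None = None,
    review_sd: float = REVIEW_SD,
    positive_sd: float = POSITIVE_SD,
    instrument_id: str | None = None,
) -> CalibrationTable:
    """Estimate per-probe background moments and cutoffs from negatives.

    Parameters
    ----------
    negatives
        Lanes known (or assumed) negative for the panel fusions.  At
        least two are required.
    exclude
        Optional per-probe masking, ``probe_id -> sample_ids to drop``,
        for leave-positive-out calibration when individual samples are
        positive for specific fusions.
    review_sd, positive_sd
        SD multipliers for the review and positive cutoffs.

    Probes with fewer than two usable (non-missing, non-excluded)
    values are recorded in ``uncalibrated`` and receive no cutoffs.
    """
    if len(negatives) < 2:
        raise CalibrationError(
            f"background estimation needs >= 2 negative lanes, got {len(negatives)}"
        )
    if positive_sd < review_sd:
        raise CalibrationError("positive_sd must be >= review_sd")
    if instrument_id is None:
        ids = {s.instrument_id for s in negatives if s.instrument_id}
        if len(ids) == 1:
            instrument_id = ids.pop()

    fusion: dict[str, FusionCutoffs] = {}
    uncalibrated: set[str] = set()
    for probe in manifest.fusion_probes:
        values = _usable_values(negatives, probe.probe_id, exclude)
        if len(values) < 2:
            uncalibrated.add(probe.probe_id)
            continue
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        fusion[probe.probe_id] = FusionCutoffs(
            cut3=mean + review_sd * sd,
            cut5=mean + positive_sd * sd,
            bg_mean=mean,
            bg_sd=sd,
            n=len(values),
        )
    return CalibrationTable(
        fusion=fusion,
        n_negatives=len(negatives),
        instrument_id=instrument_id,
        uncalibrated=uncalibrated,
    )


def derive_housekeeping_thresholds(
    adequate_samples: Sequence["SampleCounts"],
    manifest: PanelManifest,
    quantile: float = 0.05,
) -> dict[str, float]:
    """Quantile-based housekeeping thresholds from RNA-adequate lanes.

    The threshold for each housekeeping probe is the ``quantile`` lower
    quantile of its counts among lanes judged RNA-adequate by an
    external criterion.  This is an optional helper: thresholds are
    normally configured from validated runs.
    """
    if not 0.0 < quantile <= 0.5:
        raise ValueError(f"quantile must be in (0, 0.5], got {quantile}")
    if len(adequate_samples) < 5:
        raise CalibrationError(
            "housekeeping threshold derivation needs >= 5 adequate lanes, "
            f"got {len(adequate_samples)}"
        )
    thresholds: dict[str, float] = {}
    for probe_id in manifest.housekeeping_ids:
        values = [
            s.counts[probe_id]
            for s in adequate_samples
            if s.counts.get(probe_id) is not None
        ]
        if not values:
            logger.warning("no usable counts for housekeeping probe %s", probe_id)
            continue
        thresholds[probe_id] = float(np.quantile(np.asarray(values, float), quantile))
    return thresholds


def recalibrate(
    base: CalibrationTable,
    local_negatives: Sequence["SampleCounts"],
    manifest: PanelManifest,
    *,
    exclude: Mapping[str, Iterable[str]] | None = None,
) -> CalibrationTable:
    """Recompute cutoffs from one instrument's own negative lanes.

    Background levels differ between instruments, so cutoffs derived on
    a validation instrument can be systematically off on another.  This
    recomputes every probe's cutoffs from ``local_negatives`` via
    :func:`estimate_background`; probes that cannot be calibrated
    locally fall back to the base cutoffs and are flagged ``inherited``.
    Housekeeping thresholds are carried over from the base table.

    An empty local set returns the base table unchanged (with a logged
    notice) rather than failing: a site with no local negatives yet
    simply keeps the validation cutoffs.
    """
    if not local_negatives:
        logger.info("recalibrate: no local negatives supplied; keeping base table")
        return base.copy()
    instruments = {s.instrument_id for s in local_negatives if s.instrument_id}
    if len(instruments) > 1:
        raise CalibrationError(
            f"local negatives span multiple instruments: {sorted(instruments)}"
        )
    local = estimate_background(local_negatives, manifest, exclude=exclude)
    for probe_id, entry in base.fusion.items():
        if probe_id not in local.fusion:
            local.fusion[probe_id] = dataclasses.replace(entry, inherited=True)
            local.uncalibrated.discard(probe_id)
    local.hk_thresholds = dict(base.hk_thresholds)
    return local
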