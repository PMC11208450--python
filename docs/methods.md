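# Methods

## Background calibration

Fusion probe sets accumulate nonspecific background counts even in
fusion-negative samples. For each probe, the background is summarized
over a cohort of negative lanes by the arithmetic mean μ and the sample
standard deviation σ with the n−1 denominator; cutoffs are
`cut3 = μ + 3σ` (review) and `cut5 = μ + 5σ` (positive). The n−1 choice
matters because calibration cohorts are small (tens of lanes): it
widens the cutoffs slightly, which is the conservative direction for a
diagnostic assay where a false positive changes therapy. Cutoffs are
kept at full precision internally and rounded only for display.

Missing counts are excluded per probe; a probe with fewer than two
usable values is recorded as *uncalibrated* and never given a
fabricated cutoff. The estimator supports per-probe leave-positive-out
masking, so a cohort in which individual samples are positive for
specific fusions can still calibrate every probe from the samples
negative for it. Robust alternatives (median/MAD) were considered and
deliberately not made the default: the mean/SD rule is the assay's
established definition, and changing the estimator silently would
change every historical cutoff.

A calibration table may carry cutoffs without moments — laboratories
publish integer cutoffs whose underlying moments are often not
retained. Such entries skip the internal consistency check
(`cut_k ≈ μ + kσ`, absolute tolerance 0.75 counts, sized for tables
rounded to whole counts); entries with moments must satisfy it, and
`cut5 ≥ cut3 ≥ μ` always holds, with equality exactly when σ = 0.

Per-instrument recalibration recomputes all cutoffs from locally run
negative lanes (instruments differ in background level, and a cutoff
validated on one instrument can be systematically off on another).
Full recomputation was chosen over rescaling the existing cutoffs:
background shifts between instruments need not be proportional across
probes. Probes that cannot be calibrated locally inherit the base
cutoffs and are flagged as inherited; housekeeping thresholds carry
over from the base table.

## Quality gates

**Assay controls.** The positive-control ladder must start high and
decay: the gate requires the top control at ≥ `pos_floor` (default
1000 counts) and no ladder step exceeding 1.5× its predecessor; the
mean negative-control count must stay ≤ `neg_ceiling` (default 50).
These three numbers are this package's own operating points — the
underlying criterion ("the positive controls failed") is qualitative —
chosen so that healthy ladders (top controls in the tens of thousands)
and collapsed ones (top controls at background level) are separated by
more than an order of magnitude on either side. All three are exposed
in configuration and on the CLI, and the negative-control check can be
disabled for laboratories that gate on positive controls only.

**RNA adequacy.** A housekeeping probe passes on strict
`count > threshold`; a count exactly at its threshold fails ("above the
cutoff" read literally — the boundary case is tested). A lane is
adequate when ≥ 3 of 5 housekeeping probes pass. Missing housekeeping
counts are evaluable-and-failed, the conservative reading: an
unmeasured housekeeping gene is no evidence of intact RNA. Thresholds
are primarily configuration (laboratories fix them on validated runs);
a derivation helper computes the 5% lower quantile of counts among
lanes judged RNA-adequate by an external criterion, a deliberately
permissive rule that flags only clearly degraded lanes.

## Interpretation precedence

Per lane, in order: (1) failed assay controls → `FAILED_ASSAY`, all
fusion calls voided regardless of counts — the chemistry failed, so no
count in the lane is evidence of anything; (2) ≥ 50% missing fusion
probes → `NOT_INTERPRETABLE` (this trigger is a package choice; the
category exists for structurally damaged lanes); (3) more than
`high_background_k` (default 5) distinct fusions flagged →
`HIGH_BACKGROUND`, repeat with less RNA — a real sample does not carry
six independent fusions, but an overloaded hybridization lights probes
nonspecifically; (4) any probe above its positive cutoff → `POSITIVE`;
inadequate RNA is appended as a note but does not veto the call, since
the adequacy requirement exists to protect *negative* calls from
degraded RNA, and a collapsed-assay lane — not a low-housekeeping
lane — is what voids positives; (5) any review-zone probe → `REVIEW`,
repeat with more RNA naming the flagged fusion(s); (6) adequate RNA →
`NEGATIVE` (with a second-tube reflex recommendation for first-tube
lanes when reflex mode is on); (7) otherwise `FAILED_RNA`, repeat with
more RNA.

Reflex testing recommends the second tube exactly on a clean first-tube
`NEGATIVE`. A review-only lane is repeated, not reflexed: that rule is
a package decision where practice is ambiguous, on the grounds that an
unresolved flag on tube one must be resolved before spending a second
tube. Multi-fusion positives are all reported without ranking; display
order is by descending count/cut5 ratio only.

**Concordance.** A positive sample is concordant with the
flow-cytometry immunophenotype when every lineage-annotated positive
fusion's lineage set contains the flow lineage (e.g. *BCR::ABL1* →
{B-ALL, CML} concords with either), discordant when an annotated
fusion excludes it or when flow detected no leukemia at all. A clean
negative concords with a flow-negative; a negative panel does not
contradict a flow-detected leukemia — many leukemias carry no panel
fusion — so that pairing is not assessable, as are failed/review lanes
and fusions without lineage annotation. Non-leukemia associations
(lymphoma, ALCL, histiocytosis) collapse onto an `other` label in the
closed lineage set.

## Synthetic runs

The generator draws integer counts from negative-binomial
distributions (variance = mean + mean²/size), since real hybridization
background is overdispersed relative to Poisson; Poisson is the
large-`size` limit. Defaults, fixed once on the magnitudes a validated
heme panel exhibits:

| parameter | default | rationale |
|---|---|---|
| fusion background mean / size | 8 / 8 counts | yields cutoffs ≈ 20 (review) / 28 (positive), matching observed printed cutoffs of ~15–36 / ~21–35 for most probes |
| spiked-signal size | 1000 (near-Poisson) | a spiked transcript's abundance is set by the spike plan; residual noise is molecule-counting noise |
| housekeeping means | B2M 30000, EEF2 10000, GUSB 800, PGK1 3000, TBP 200 (size 10) | magnitudes of RNA-adequate lanes |
| positive ladder | top 35000, decay 0.3/step (size 100) | resembles real control ladders (≈35000 → ≈85) |
| negative controls / failed-assay ladder | mean 8 | collapsed ladders sit at negative-control level |
| degraded-lane RNA quality q | 0.1 | scales housekeeping and spiked-signal means; background is nonspecific and is *not* scaled |

Spiked lanes place the signal (mean = fold × cut5 of the analytically
derived reference calibration) on the fusion's first breakpoint probe,
as a real fusion transcript matches one breakpoint. High-background
lanes lift enough distinct fusions past their cutoffs to exceed the
flag cap; on a panel with too few distinct fusions to exceed it, the
truth label honestly downgrades to `POSITIVE`. Runs are reproducible
from the seed alone: draws are consumed in lane order, probes in
manifest order.

What the generator does **not** emulate: probe cross-hybridization
structure, sequence-level effects, lane-metric artifacts (binding
density, field-of-view counts), or correlated background between
probes. Passing tests therefore demonstrate the correctness of the
calibration/QC/calling logic under the stated count model, not the
wet-lab performance of any panel on patient material.

A consequence of the model worth stating: cutoffs at μ + 3σ of a
distribution flag that distribution's own upper tail. On a 13-probe
panel the per-lane probability of at least one review-zone flag in
pure background is ≈ 8% (computable exactly from the negative-binomial
tail), so a run of background lanes is expected to contain occasional
review flags — that is what the repeat-testing workflow is for.
Positive miscalls past μ + 5σ are two orders of magnitude rarer
(≈ 0.2% of lanes). Tests assert both against the numerically computed
tail-mass oracle rather than pretending review flags away.

## Problem sizes and numerical choices

Simulation-backed tests use 48-lane calibration cohorts (20 seeds for
recovery checks), 500-lane cohorts for sensitivity/specificity and
prevalence checks, 1000 lanes for distribution-convergence and
brute-force-equivalence checks, and 200 independently seeded runs for
the spike-detection check; the whole suite runs in a few seconds.
Sensitivity/specificity are measured against the generator's exact
reference calibration so they isolate the calling engine; the
estimated-calibration path is exercised separately by the end-to-end
truth-recovery test. All randomness flows through
`numpy.random.default_rng` seeded explicitly; there is no randomness
anywhere in calibration, QC, calling or reporting. Tie-breaks are
strict inequalities at every threshold (documented above). Degenerate
inputs — zero-variance background (cut3 = cut5 = μ), missing counts,
uncalibrated probes, empty manifests, empty sample lists — flow through
as explicit statuses rather than errors wherever the lane itself is
well-formed.

## Known limitations

- Raw counts are compared directly against background cutoffs; no lane
  normalization (content or geometric-mean) is applied. This matches
  the assay's interpretation procedure, but cutoffs are therefore only
  valid for the instrument and input amount they were calibrated on —
  hence the recalibration operation.
- The assay is for diagnostic samples only; it has nowhere near the
  sensitivity needed for minimal-residual-disease monitoring, and no
  MRD functionality is provided.
- Fusions are detected only at panel breakpoints; novel partners or
  breakpoints outside the probe design are invisible.
- The `NOT_INTERPRETABLE` trigger (≥ 50% missing fusion probes) and the
  high-background cap (5 distinct fusions) are package-chosen operating
  points, exposed in configuration.
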