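# fusioncall

Interpretation pipeline for hybridization-based gene fusion panels on
nCounter-style digital counting platforms, built for molecular
diagnostics of pediatric leukemia in settings without sequencing
infrastructure.

A custom fusion panel counts molecules hybridizing to probe sets that
each span one fusion breakpoint (e.g. `BCR(ex1):ABL1(ex3)` for
*BCR::ABL1*). The platform reports raw counts per probe per lane — no
amplification, no alignment — so interpretation reduces to a
well-calibrated thresholding problem plus rigorous quality gating.
`fusioncall` implements that interpretation end to end, for laboratory
scientists and pipeline engineers who need reproducible, auditable
calls from raw lane counts.

## The model

For each fusion probe set, background counts are estimated from a
cohort of lanes negative for that fusion. With background mean μ and
sample standard deviation σ (n−1 denominator), two cutoffs are derived:

- **positive**: count > μ + 5σ — a strong indicator the fusion
  transcript is present;
- **review**: μ + 3σ < count ≤ μ + 5σ — flagged for repeat testing
  with more or less RNA.

Both comparisons are strict; a count exactly at a cutoff does not cross
it. Per-lane quality gates precede any call:

- **assay controls** — six spiked positive controls form a descending
  titration ladder (POS_A…POS_F) and six negative controls gauge the
  hybridization chemistry. A collapsed ladder voids the whole lane,
  no matter how high individual fusion counts are.
- **RNA adequacy** — a lane may be called fusion-negative only when at
  least 3 of 5 housekeeping probes (B2M, EEF2, GUSB, PGK1, TBP) exceed
  their thresholds; degraded RNA is repeated with more RNA, nonspecific
  high background (flags across many distinct fusions) with less.

Two-tube panels support reflex testing: the second tube is run only
after a cleanly negative first tube. Positive calls are checked for
concordance against the flow-cytometry immunophenotype via the panel's
fusion-to-lineage map (e.g. *PML::RARA* → AML). Per-instrument
recalibration recomputes cutoffs from locally run negative lanes, since
background levels differ between instruments.

## Worked example

The package bundles a complete 9-lane run of the Heme 1 tube (raw
counts, the laboratory's positivity cutoffs, housekeeping thresholds):

```python
from fusioncall import example_heme1_run, interpret_sample
from fusioncall.reporting import summary_line

run = example_heme1_run()
for sample in run.samples:
    interp = interpret_sample(sample, run.calibration, run.manifest)
    print(f"{sample.sample_id:>8}  {interp.status.value:<13} "
          f"{interp.recommendation.value:<16} {summary_line(interp)}")
```

prints

```
       5  POSITIVE      NONE             POSITIVE: RUNX1::RUNX1T1
       6  REVIEW        REPEAT_MORE_RNA  REVIEW: repeat with more RNA to check CBFB::MYH11
       8  NEGATIVE      REFLEX_HEME2     negative
      15  POSITIVE      NONE             POSITIVE: RBM15::MKL1
      16  FAILED_RNA    REPEAT_MORE_RNA  failed RNA; repeat with more RNA
      22  POSITIVE      NONE             POSITIVE: EBF1::PDGFRB
      24  POSITIVE      NONE             POSITIVE: TCF3::PBX1
     24C  FAILED_ASSAY  REPEAT_MORE_RNA  failed assay controls; fusion calls voided
 IVS-020  POSITIVE      NONE             POSITIVE: PML::RARA
```

Reading the output: lane 5's `RUNX1(ex6):RUNX1T1(ex2)` probe counts 373
against a positive cutoff of 142 — an unambiguous *RUNX1::RUNX1T1*
call. Lane 6's `CBFB(ex5):MYH11 (type A)` count of 23 sits between the
review (21) and positive (28) cutoffs, so the lane is flagged for
repeat rather than called. Lane 8 is clean with 5/5 housekeeping
passes, triggering the reflex recommendation to run the second tube.
Lane 16's housekeeping counts all fall below threshold (degraded RNA).
Lane 24C's positive-control ladder collapsed (top control at 35
counts), so its above-cutoff *PML::RARA* count of 82 is voided — the
chemistry, not the sample, failed. `IVS-020` is a spiked positive
control lane carrying *PML::RARA*.

The same pipeline is scriptable from the shell:

```sh
fusioncall call --manifest src/fusioncall/data/heme1_example.manifest.tsv \
    --calibration src/fusioncall/data/heme1_example_calibration.tsv \
    --counts src/fusioncall/data/heme1_example_counts.tsv --out interps.tsv
```

plus `fusioncall calibrate` (derive cutoffs from negative lanes),
`fusioncall report` (color-coded HTML/CSV run grid and cohort summary),
`fusioncall simulate` (synthetic runs with ground-truth labels) and
`fusioncall concordance`. Lanes failing QC are data, not errors: exit
codes are non-zero only for usage or parse problems.

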