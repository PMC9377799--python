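# moltclock

Analytics for the molting clock of *Caenorhabditis elegans*: the negative
feedback loop in which the nuclear receptor NHR-23 (the worm ROR homolog)
transcriptionally activates the *let-7* family of microRNAs, and the
*let-7*s in turn post-transcriptionally repress *nhr-23* through a
*let-7* consensus site (LCS) in its 3′ UTR. This loop paces the 8–10 h
molting cycle and — via stage-over-stage dampening of *nhr-23* expression —
appears to count down the worm's four molts.

The package is written for researchers analyzing molting-clock data: it
implements the computational procedures around that biology as a tested,
reusable pipeline, exercisable end to end on synthetic data with known
ground truth.

## What it computes

- **RORE scanning** (`sequence_scan`): occurrences of the ROR response
  element 5′-(A/G)GGTCA-3′ on both strands, genome-wide counts, and
  enrichment against chance. Under uniform base composition the
  both-strand expectation is 4 × (1/4)⁶ per nt ≈ 0.98 per kb; for
  *C. elegans* regions an empirical density of 41,203 occurrences per
  100.2 Mb is used instead. A region is enriched when observed > expected.
- **let-7 seed sites** (`mirna_sites`): LCSs in 3′ UTRs as Watson–Crick
  complements of the *let-7* seed (mature nt 2–8) with at most one seed
  mismatch, scanned on the sense strand only; chance expectation
  (L − k + 1)·n_words/4ᵏ; the criterion is non-strict (observed ≥ expected).
- **Target classification** (`target_classify`): a clock-controlled gene
  (CCG) is an NHR-23 target when ≥2 of {ChIP peak at Z ≥ 2, RORE
  enrichment, ≥1.2-fold knockdown reduction} hold, and a *let-7* target
  when both {ALG-1 iCLIP binding, LCS enrichment} hold; cohorts are
  tabulated into the four-way Venn (both / NHR-23 only / let-7 only /
  neither).
- **Waveform metrics** (`waveform`): per-stage trough and peak, rising
  slope (peak − trough)/Δt, fixed-period cosinor fit
  y = m + A·cos(2π(t − φ)/T) with T ∈ {8, 10} h, dampening as successive
  peak ratios, extra post-molt pulse detection, and time-aligned genotype
  comparison.
- **Actogram analytics** (`actogram`): the activity grading scale (high /
  medium / low at mean − 1 SD and mean − 2 SD of the wild-type pumping
  rate), lethargus bouts, wake-to-wake intervals, cohort statistics,
  quiescence prevalence, and the supernumerary-molt fate rubric.
- **Quantification** (`quantify`): ΔCt relative expression 2^−(Ct_t −
  Ct_ref), input-normalized ChIP fold enrichment, and ratiometric
  (tdTomato/GFP) reporter readout over the linear exposure range.
- **Synthetic data** (`simulate`): seeded generators for all of the above
  with ground-truth sidecars.

## Worked example

```python
from moltclock.sequence_scan import BackgroundModel, SequenceRecord, scan_region
from moltclock.simulate import gen_expression
from moltclock.waveform import dampening, segment_stages, stage_metrics

promoter = SequenceRecord("promoter", "AGGTCA" * 3 + "T" * 982)
scan = scan_region(promoter, BackgroundModel("uniform"))
print(scan.observed, round(scan.expected, 3), scan.enriched)

series, windows, truth = gen_expression(dampening_fold=1.5, baseline=0.0, seed=7)
metrics = [stage_metrics(s, period_h=8.0) for s in segment_stages(series, windows)]
print([round(r, 2) for r in dampening(metrics).ratios])
```

prints

```
3 0.977 True
[1.5, 1.5]
```

— three ROREs in a 1-kb promoter versus the ≈0.98 expected by chance (the
region is called enriched), and exact recovery of the planted 1.5-fold
stage-over-stage dampening from a noiseless synthetic *nhr-23* time
course.

The numbered scripts under `analysis/` walk the full pipeline: `python
analysis/01_simulate_inputs.py` generates the synthetic study inputs, and
scripts 02–06 scan elements, classify the 67-gene CCG cohort, compute
waveform metrics, analyze the behavioral cohorts, and run the
quantification arithmetic, writing tables under `results/`.

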