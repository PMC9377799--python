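# Methods

## The system being modeled

During *C. elegans* larval development, NHR-23 (the sole worm homolog of
mammalian RORs) and the *let-7* family of microRNAs form a
transcriptional–post-transcriptional negative feedback loop. NHR-23 binds
ROR response elements (ROREs) upstream of the *let-7* genes and activates
their transcription once per larval stage; mature *let-7* accumulates and
represses *nhr-23* through a seed-complementary site (LCS) in the *nhr-23*
3′ UTR. The loop sets the pace of the 8–10 h molting cycle, and the
~1.5-fold stage-over-stage dampening of *nhr-23* expression peaks is a
candidate counter for the worm's exactly four molts. The package
implements the measurement and classification procedures around this
biology; it does not simulate the oscillator itself (no ODE model is
implied by the data being analyzed).

## Element scanning and chance models

ROREs are exact matches to (A|G)GGTCA. Scanning enumerates every 6-nt
window on the forward strand and reports minus-strand occurrences at
their forward coordinates with the word as read 5′→3′ on the minus strand
(a minus hit is a window reading TGACCT or TGACCC). Overlapping
occurrences all count; windows containing N never match; coordinates are
1-based inclusive internally and converted to 0-based half-open only in
BED export.

Two background models give the expected count for a region of length L:

- *uniform*: 4 × (1/4)⁶ per nt (two words × two strands at equal base
  frequencies), i.e. ≈0.977 per kb — used for non-nematode sequences;
- *empirical*: 41,203/100.2×10⁶ per nt, the measured both-strand density
  on the *C. elegans* reference assembly.

RORE enrichment is strict (observed > expected). The genome-wide count is
read as an occurrence count over both strands; an external whole-genome
check against the reference assembly requires the genome FASTA and is not
part of the test suite, which validates the scanner against naive
enumeration instead.

LCSs are windows of the sense (mRNA) strand within Hamming distance 0–1
of the reverse complement of the *let-7* seed. The seed is taken as
mature nt 2–8 (a 7-mer); the 2–8 convention matches the "perfect seed
complementarity" phrasing used for the strongest sites, and the site
start is counted from the first base after the stop codon. Pairing is
Watson–Crick only — the detection rule is sequence complementarity, not
hybridization energy — so G:U wobble and free-energy filtering are
deliberately out of scope. For each site a coarse 3′-supplementary
descriptor counts exact complementary positions between the miRNA's
non-seed 3′ region and the UTR flank immediately 5′ of the seed match.
The chance expectation is (L − 7 + 1) × n_words/4⁷ with n_words = 1
(perfect) or 22 (≤1 mismatch), and the enrichment criterion is non-strict
(observed ≥ expected), intentionally asymmetric to the RORE rule, per the
two rules' definitions.

## Target classification

Evidence flags per gene: ChIP peak (Z ≥ 2, inclusive), RORE enrichment,
knockdown reduction (fold ≥ 1.2, inclusive), ALG-1 iCLIP binding of the
3′ UTR, LCS enrichment. NHR-23 targets satisfy ≥2 of the first three;
*let-7* targets satisfy both of the last two; the cross of the two calls
gives the four-way Venn. Unknown (missing) flags resolve to `False` with
a logged warning — a conservative choice, since every criterion is
positive evidence — and a strict mode raises instead. Percentages are
rounded to integers for display. Published per-gene annotation tables are
not redistributable here, so cohort-level checks run on synthetic
evidence tables whose class composition is planted exactly
(`gen_ccg_cohort_exact`); this validates the rules and tabulation, not
any external annotation.

## Waveform metrics

A stage runs from the end of one lethargus to the end of the next; the
stage's sub-series additionally reaches back to the start of the
preceding lethargus so the trough "before or during the preceding molt"
is visible. Peak = maximum raw sample within the stage proper; trough =
minimum sample up to the peak; ties break to the earliest time; no
smoothing is applied (typical series have ~14 samples at 2-h spacing, so
any smoother would dominate the data). Rising slope is
(peak − trough)/(t_peak − t_trough) in normalized units per hour.

Amplitude and phase come from a fixed-period cosinor: least squares on
y = m + a·cos(ωt) + b·sin(ωt) with ω = 2π/T and T fixed at 8 h (L3) or
10 h (L4); A = √(a² + b²) ≥ 0, φ = atan2(b, a)/ω reduced to [0, T) and
reported in hours after stage start. This deliberately replaces
rhythmicity packages (MetaCycle-style meta-analysis): with the period
fixed, the harmonic fit is a plain linear regression — fully determined,
dependency-free, and exact on noiseless cosines. Because those packages'
amplitude conventions differ across sub-methods, equality with any
externally printed amplitude is not claimed; amplitude here is the fitted
cosine amplitude (half the peak-to-trough swing of a pure cosine).

Dampening is the ordered sequence of successive peak ratios
peak_s/peak_{s+1} (≈1.5 per stage for wild-type *nhr-23*, ≈1.0 when
dampening is lost). Extra post-molt pulses are interior local maxima
after the final molt exceeding a configurable fraction (default 0.5) of
the **last** larval peak — the last pre-molt local maximum, not the
global larval maximum, because dampening makes the final peak the
smallest and the global maximum would inflate the threshold several-fold.
Genotype comparison shifts one series in time to align developmental
stages, reports per-timepoint fold differences, and delegates the
genotype-effect test to a standard two-way (genotype + time) ANOVA.

## Actogram analytics

Activity grades use the one-way standard scale anchored on the wild-type
pumping rate: high ≥ mean − 1 SD, medium ≥ mean − 2 SD, low below; with
the measured 3.9 ± 1.1 Hz this yields the 2.8 and 1.7 Hz cutoffs. An
animal with clear sinusoidal locomotion but no captured pumps grades low.
Lethargus bouts are maximal runs of lethargic samples; intervals are
computed at the sampling resolution (±Δt, no sub-sample interpolation,
matching the 1–2 h observation design); the wake-to-wake interval is the
time between the first two lethargus-to-activity transitions and equals
active + lethargus for a single complete cycle. Unobserved samples
terminate bouts conservatively with a warning, and a bout ending in an
unobserved sample contributes no wake transition. Grades are descriptive
only and do not enter interval computations. Cohort statistics (ANOVA +
Bonferroni or Mann–Whitney, chi-square for quiescence prevalence) are
delegated to scipy/statsmodels and reported, not re-derived.

Adult fate, for animals singled at the start of a quiescent bout:
ecdysis behaviors, aberrant-molt signs, or a shed cuticle after the bout
⇒ supernumerary molt; death without those signs ⇒ death without molt;
otherwise (reactivated, normal at endpoint) ⇒ transient quiescence.

## Quantification

ΔCt relative expression is 2^−(mean Ct_target − mean Ct_ref) with
amplification efficiency fixed at 2.0 (100%); efficiencies are rarely
reported for the assays this models, and the estimator is
shift-equivariant so a common efficiency error cancels in normalized
comparisons. Technical replicates deviating >5% from their mean trigger
a warning rather than rejection. ChIP recovery is input-normalized per
sample (2^(Ct_input − Ct_IP)); fold enrichment is tagged-strain mean over
untagged-strain mean, so a strain against itself is exactly 1.
Ratiometric reporter readout fits each channel's background-corrected
intensity against exposure time through the origin and searches, from the
longest prefix of the exposure ladder down to 3 points, for the first
prefix with uncentered R² ≥ 0.99 in both channels; the ratio is the red
slope over the green slope, and a worm's value is the mean over its ROIs
(ratio first, then average — chosen so ROIs with different linear ranges
still contribute comparable quantities). Background correction and ROI
segmentation are assumed done upstream.

## Synthetic data: what it emulates, and what it does not

One root seed fans out to named child streams (SeedSequence + a CRC of
the stream name), so each generator reproduces byte-identically and
independently.

- *Sequences*: i.i.d. bases at a target GC fraction; motif-free mode
  resamples windows spelling forbidden words (ROREs on either strand and
  the perfect seed complement by default); planting writes words at
  1-based positions and rejects overlaps. No dinucleotide structure,
  repeats, or isochores — chance expectations on these sequences are
  exactly the analytic ones, which is the point; real promoters are less
  uniform.
- *Evidence cohorts*: independent Bernoulli flags, or exact planted class
  compositions for fixed Venn counts.
- *Expression*: per stage a raised-cosine pulse (smooth, compact support
  — a modeling convenience, not a mechanistic claim) peaking 40% of the
  way through the stage (within the observed one-third to one-half),
  height A₀/d^(s−1) so peaks decline by the dampening factor d (default
  1.5) each stage, over a baseline (default 0.2) with additive Gaussian
  noise clipped at zero; 8-h stages with 2-h lethargi sampled every 2 h
  give the canonical 14-sample, three-molt design. An optional post-molt
  pulse (default 80% of the final peak) emulates derepressed genotypes.
- *Behavior*: active and lethargus durations drawn from normal
  distributions and discretized to the grid (round half up). Defaults:
  8.0 h active + 2.3 h lethargus (wake-to-wake 10.3 h, SD ≈ 0.4 via
  σ_active = 0.3, σ_leth = 0.25). Genotype modifiers encode the observed
  effects: knockdown-like = lethargus ×2 plus 0.4 h later onset
  (wake-to-wake ≈ 13 h); *let-7*-like = all intervals ×0.77 (≈ 7.9 h).
  Fate simulation emits quiescent bouts followed by ecdysis, reactivation
  or death per configured probabilities (default 97% supernumerary).
- *qPCR/ChIP*: Cts back-computed from planted levels with replicate
  noise.

Passing tests on these generators shows the estimators recover planted
parameters under the stated noise; it does not validate staging of real
animals, normalization of real qPCR series, or the external annotation
sources behind the evidence flags.

## Problem sizes and numerical choices

Oracle-equivalence suites run 1,000 random sequences (≤500 nt) for the
RORE scanner and 500 random UTRs (≤2 kb) for the LCS scanner against
naive enumeration; Monte-Carlo verification of the uniform RORE rate uses
2,000 random 1-kb sequences (4σ band); harmonic and dampening recovery
use 200 seeded replicates at 10% noise; the behavioral power check uses
100 replicates of two 15-animal cohorts with a planted 2-h wake-to-wake
difference. These sizes keep the full suite under a minute on one CPU
while leaving Monte-Carlo error well inside the asserted tolerances.

Degenerate inputs are defined rather than left to chance: empty UTRs
yield empty site lists; a constant expression series has trough = peak
and zero slope; a flat series fits amplitude ≈ 0; tabulating an empty
cohort yields zero counts with undefined percentages flagged; tracks with
fewer than two lethargus exits have an undefined wake-to-wake interval
(None, never 0).

## Known limitations

- Exact-match consensus scanning only; no position-weight matrices or
  motif discovery, and ChIP peaks/iCLIP calls are consumed as flags, not
  recomputed from reads.
- The seed span (2–8) and the stop-codon origin for UTR coordinates are
  conventions; external position checks against annotated UTRs depend on
  them.
- The cosinor assumes a single fixed period per stage; it estimates no
  period and tests no rhythmicity significance.
- Interval estimates inherit the ±Δt quantization of the observation
  design; sub-hour effects are invisible at 1-h sampling.
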