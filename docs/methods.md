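# Methods

## Polysome pool quantification

Sucrose-gradient fractions are assumed pre-pooled into free (F),
40S-associated (S), light-polysome (L, 1–3 ribosomes) and heavy-polysome
(H, >3 ribosomes) RNA pools per condition. Because only a fraction of
each pool's volume is used for cDNA synthesis, observed intensities are
divided by the per-(pool, condition) sampling fraction before anything
else; this correction is exactly invertible. Proportions are computed on
the linear intensity scale (`log2_input` in the pipeline config
exponentiates RMA-style signals first), since proportions of RNA amounts
are linear quantities: the corrected signal in a pool divided by the sum
over the four pools. Quadruples with all-zero corrected signal are
flagged undefined and excluded downstream rather than erroring. The
ribosome load is `H/L = pH/pL`, finite only when `pL > 0`; replicates are
averaged at the distribution level when a mean distribution is needed.

Percent polysomal from a UV trace: a straight baseline between the first
and last trace points is subtracted (configurable: `none`), areas are
trapezoidal, and the statistic is `100 · area(polysomes) / (area(80S) +
area(polysomes))`. The 40S/60S subunit region is excluded from the
denominator because the quantity is a percentage of *ribosomes*; whether
the 80S peak should also enter the numerator is ambiguous in the source
material, and here it is denominator-only.

## Shift detection

The trend of stimulated on control `log2(H/L)` is the first principal
axis of the centered cloud, computed in closed form from the second
moments (slope `(Syy−Sxx+√((Syy−Sxx)²+4Sxy²))/(2Sxy)`), through the
centroid. The cutoff scale `sd_d` is the empirical SD (ddof = 1) of the
fit's own signed orthogonal distances; a MAD-based robust alternative is
available (`robust=True`) but off by default. Distances are signed so
that positive means translationally up.

A gene is called up when its replicate-mean distance exceeds
`k_sd · sd_d` of the mean fit *and* at least `min_replicates` replicate
distances exceed the cutoffs of their own per-replicate fits on the same
side (defaults 2 SD, 2 of 3). Whether replicates should be measured
against per-replicate fits or projected onto the mean fit is genuinely
open; per-replicate fits respect replicate-specific trends and are the
default (`per_replicate_fits=False` switches). Genes with a non-finite
load in any replicate are excluded from fitting and calling and reported
in the QC table. A tiny absolute floor (1e-9) on the cutoff only matters
for degenerate zero-residual fits, where the empirical SD is rounding
noise.

## Time-course pattern classification

Size factors are the median-of-ratios estimators: the median over genes
(with positive geometric mean) of counts over geometric means; no
rescaling afterwards.

Because the course has one library per timepoint, the NB dispersion is
estimated blind: all samples are treated like biological replicates. Per
gene, with normalized mean `μ`, sample variance `v` and
`z̄ = mean(1/s_j)`, the raw method-of-moments dispersion is
`max(0, (v − μ·z̄)/μ²)`. The trend `α(μ) = a0 + a1/μ` is fitted by a
gamma-family GLM (identity link) over genes with positive raw
dispersion, iterating from the fixed starting coefficients (0.1, 1) and
excluding genes whose raw/fitted ratio falls outside [1e-4, 15] at each
pass. The fixed start matters: genes with genuine expression changes
have apparent dispersions far above the noise trend, and the exclusion
rule only removes them if the running fit has not already absorbed them.
Only fitted values are used downstream (fit-only), floored at 1e-8.
For genes that do change, this blind estimate *over*-states the
dispersion, making the tests conservative — an accepted property of the
design, with the consequence that changes are only detectable when their
amplitude is large relative to the square root of the fitted dispersion.

The pairwise test is the conditional NB exact test: under the null both
samples share the concentration `q = (kA+kB)/(sA+sB)`, the counts are
independent NB with means `s·q` and the fitted dispersion at `q`, and
the p-value is the probability of all splits of the observed total that
are no more likely than the observed one. Totals ≤ 10,000 are enumerated
fully; larger totals use a window around the conditional mean that is
doubled until the edge terms are ≥ 60 log-units below the peak
(capturing all but < 1e-12 of the mass). Ties in the split probability
are included with a 1e-10 relative tolerance. At dispersion 0 the test
reduces exactly to the two-sided conditional binomial test. The reported
`log2FC` compares normalized counts and adds a 0.5 pseudocount only when
one of them is zero; p-values never use pseudocounts.

Extrema are found by a state machine over timepoints with a running
reference (the control at first, afterwards the last finalized
extremum). A candidate maximum opens at a significant increase versus
the reference (`log2FC > 0.5`, `p < 0.05`), advances to any later
timepoint with a strictly larger significant increase versus the same
reference, and is finalized by a significant decrease versus the
candidate (which opens a candidate minimum) or by the end of the series;
minima are symmetric, with "significant decrease" read as
`log2FC < −0.5`. Groups: empty track g0; first extremum a max at ≥ 60
min g1, a min at ≥ 60 min g2; first max before 60 min with first min at
≥ 60 min g3; the mirror image g4; anything else (e.g. a single early
extremum) is reported as `unassigned` and treated as non-g1/non-g2 for
regulation classes. The 60-min boundary is inclusive. Tests run against
the running reference (matching the definition's wording); no
multiple-testing correction is applied inside the machine — the
classification uses raw `p < 0.05`.

## Regulation classes, enrichment, controls

`up + g2 → passive_up`, `down + g1 → passive_down`, any other shifted
combination is active, unshifted genes are `not_shifted`. Gene-set
enrichment is the upper-tail hypergeometric probability with the
universe defaulting to all genes in the report (configurable).
Group-score comparisons are two-sided Wilcoxon rank-sum tests
(`scipy.stats.mannwhitneyu`). ORF-matched control groups take all other
genes within ± 25 nt of the focal gene's ORF length (longest isoform),
returning the members' mean pool distribution per condition.

## ARE scoring

The score is additive over AUUUA pentamers (overlapping occurrences both
count, as in the canonical AUUUAUUUA core): a base score per pentamer,
a pair bonus for consecutive pentamers keyed on the gap between them
(negative gaps = overlap), and an AU-context bonus for pentamers whose
flanks within a fixed window are sufficiently AU-rich. The AU fraction
uses a fixed denominator of twice the window, with absent flanks and N
counting as non-AU; this keeps scores exactly additive across long
non-AU spacers. T and U are equivalent, matching is case-insensitive,
and N never matches. All weights live in a YAML file
(`data/arescore_defaults.yaml`); the shipped defaults (base 1.0, pair
bonuses 1.5 for gap ≤ 2 and 0.75 for gap 3–10, AU-context bonus 0.5 at
fraction ≥ 0.75 in 20-nt flanks) are this package's defaults for the
published structure of pentamer/proximity/context scoring, and analyses
that require a specific published weighting should supply it via
`AREScoreParams.from_yaml`.

## rpkm with unique k-mers

A gene's effective length is the number of distinct k-mers (default
k = 58, the read length) that occur in at least one of its transcript
isoforms and in no transcript of any other gene; duplicates within a
gene collapse (a positions-counting mode is available by flag, since
strings-vs-positions is an interpretation choice). No reverse-complement
matching by default — the reference protocol is stranded — with a
canonical-k-mer switch for unstranded data. `rpkm = count /
(unique_kmers/1000) / (library/1e6)`, undefined (NaN) when a gene has no
unique k-mer; the library size is the per-sample sum of gene-level
counts. Fold changes versus the control use size-factor-normalized
counts with a 0.5 pseudocount on zeros.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the reference experiment
with known ground truth, deterministically from the config seed (one RNG
stream per generator call).

* **Polysome signals.** Latent pool distributions are Dirichlet around
  baseline proportions (0.03, 0.03, 0.25, 0.69) — the observed medians
  of real macrophage mRNA distributions — with concentration scale 30,
  giving a realistic spread of per-gene `log2(H/L)`. The stimulated
  condition applies the global trend (slope 1, intercept 0.3 on
  `log2(H/L)`, the documented global polysome shift) as mass transfer
  between L and H on the log-odds scale, which automatically preserves
  distribution validity; with these values the simulated pool medians
  move from ≈ 69 %/25 % (H/L pools) to ≈ 73 %/21 %. Designated active
  genes get an orthogonal offset of `effect_size_sd` residual SDs (the
  residual SD unit is `replicate_noise_sd`, default 0.2 log2 units; a
  fixed 0.1 unit when noise is switched off so that noiseless effects
  remain nonzero). Replicate noise is Gaussian on `log2(H/L)` in both
  conditions; observed signals multiply proportions by a lognormal
  gene-abundance factor and the sampling fractions. Only the F-control
  (14.2 %) and H-control (0.4 %) sampling fractions are anchored to the
  reference protocol; S/L and the stimulated values interpolate
  plausibly between them.
* **Count courses.** Default grid 0–120 min with 8 samples
  (0, 15, 30, 45, 60, 75, 90, 120), one library each. Archetype
  trajectories on the log2 scale: g1 a late monotonic rise whose first
  maximum lands on the last timepoint, g2 its mirror, g3 a transient
  peak at 30 min crossing baseline around 70 min and drifting slightly
  below so the return minimum lands at or after the 60-min boundary, g4
  its mirror; amplitude `lfc_amplitude` (default 2). Counts are NB with
  dispersion 0.005 (Poisson at 0) around `base_mean · 2^lfc(t) ·
  depth_j`, base means log-uniform 100–10,000 and lognormal per-sample
  depth distortions (sd 0.15 log2 units). The dispersion default is
  deliberately *technical*-scale: the course samples a single culture
  over time, so sample-to-sample variation is library-level and
  near-Poisson, unlike biological replicates; the base-mean range
  corresponds to a few tens of millions of reads over ~10⁴ well-detected
  genes. The default archetype mix (g0 0.80, g1 0.08, g2 0.08, g3 0.03,
  g4 0.01) mirrors the observed relative group sizes.
* **3'UTRs.** Uniform-ACGT backgrounds, lengths uniform in 100–300 nt;
  designated up-genes receive `are_enrichment` (default 3) extra
  non-overlapping ATTTA pentamers at random positions. Background
  pentamers can arise on top of planted ones.

What the generator does **not** emulate: probe-level microarray effects,
fraction-level pooling chemistry, read-level sequencing artifacts,
correlated gene programs, mRNA-level/translation coupling (truth labels
for shifts and patterns are drawn independently), or oscillatory
expression. Passing recovery tests therefore demonstrate the
correctness and calibration of the estimators under the stated
generative model, not performance on real arrays or libraries.

## Numerical and degenerate-input choices

* TLS: all-identical points raise; a vertical major axis is returned
  with an infinite-slope flag. `sxy == 0` resolves to slope 0 (wider x)
  or vertical (wider y).
* Exact test: totals of 0 give `p = 1, log2FC = 0`; probability ties are
  included with 1e-10 relative tolerance; window edges must be ≥ 60
  log-units below the peak.
* Pool distributions: all-zero quadruples flagged, never raised;
  `pL = 0` gives a non-finite load, flagged.
* Extremum candidates advance only on *strictly* larger fold changes, so
  exact ties resolve to the earlier timepoint.
* The dispersion floor (1e-8) keeps fitted values positive without
  affecting any realistic fit.

## Problem sizes

The shipped verification runs use 5,000 genes for the shift-recovery and
null-calibration simulations (50 designated 4-SD up-shifts; flat
archetype), 1,000 genes for noise-minimal archetype recovery (dispersion
0, no depth distortion, base means 200–2,000, amplitude 6 — large enough
that the changing genes' apparent blind dispersion crosses the trend
fit's exclusion bound, which is what "noise-minimal" requires under a
self-estimated dispersion), 1,000 random clouds for the TLS oracle, all
totals ≤ 200 for the exact-test enumeration, and 100 random toy
transcriptomes for the unique-k-mer oracle.

## Known limitations

* The conditional exact test treats the fitted dispersion as known; no
  uncertainty in `α(μ)` propagates into p-values (as in the reference
  procedure).
* With one library per timepoint, dispersion and change are
  confounded; strongly changing genes inflate the blind estimate and
  only the ratio-exclusion in the trend fit limits the damage. Moderate
  changes (amplitude ≲ 2 log2 units) are detected conservatively.
* Pattern groups describe only the first one or two extrema; multi-phase
  (oscillatory) courses beyond that are truncated to their leading
  extrema.
* ARE scoring weights are configuration data; the shipped defaults
  follow the standard pentamer/proximity/context structure but are not a
  transcription of any specific published parameter set.
* The synthetic universe draws shift and pattern labels independently,
  so it cannot exhibit the negative correlation between mRNA change and
  apparent load change that motivates the passive-shift correction; the
  classifier logic is exercised, the biological coupling is not.
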