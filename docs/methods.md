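# Methods

This note documents the models, defaults and design choices behind each
stage of `l1quant`, what the synthetic-data generators do and do not
emulate, and the numerical conventions shared across the package.

## IP-MS interactor calling

Spectral counts (peptide-spectrum matches, PSM) are treated as
semi-quantitative protein abundance. The filter chain applies, in order:

1. **Background subtraction**, per replicate, against the matched negative
   control (beads-only BO preferred; isotype IgG otherwise; the
   per-replicate maximum when both exist, which is the conservative
   choice). A protein is excluded when `PSM_neg >= PSM_IP`, or when
   `PSM_neg >= 10` and `PSM_IP - PSM_neg < 3`. Both comparisons are read
   literally: a margin of exactly 3 is kept. Note the first rule excludes
   proteins absent from both IP and control (0 ≥ 0) — absence is not
   evidence of interaction.
2. **Stringency filter** on counts summed across a condition's replicates:
   exclude when the high-salt (300 mM KCl) count is zero while the
   standard-wash count is positive, or when `low/high > 3` strictly.
   Whether the comparison should be pooled or per-replicate is genuinely
   open; pooled is the default because summed counts are less noisy at the
   low means typical of spectral counting, and `stringency_pooled=False`
   selects the per-replicate variant.
3. **Intersection**: survivors must appear in every replicate of every
   experiment.

Surviving proteins are annotated with a bait-normalised abundance
`(PSM/MW)/(PSM_bait/MW_bait)` (MW in kDa; the bait is exactly 1 by
construction) and, where nuclease-treated IPs exist, an RNase class:
`lost` (abundance zero after digestion), `reduced` (drop > 3-fold), else
`resistant`. **The 3-fold reduction threshold is this package's default,
not a published constant** — figure legends distinguish only
resistant vs non-resistant interactors — so it is exposed as
`rnase_reduction_fold`. Ratios of 0/0 class as resistant (no evidence of
loss). Output is ordered by descending mean abundance, ties broken by
protein id, so reruns are byte-identical.

## RNA co-IP enrichment

Library depth is normalised by median-of-ratios size factors: for every
feature with nonzero counts in all samples, each sample's count is divided
by the feature's geometric mean, and the sample's factor is the median of
these ratios. Features present in no common sample raise an error rather
than silently switching reference.

Enrichment per feature is a negative-binomial Wald test on the log2 ratio
of group means of normalised counts, with a 0.5 pseudo-count on each mean
to keep zeros finite. The NB dispersion (`variance = mu + alpha*mu^2`) is
estimated per feature by method of moments, `alpha = (s^2 - mu)/mu^2`,
averaged over the two groups. With three replicates per group that
estimate is far too noisy to referee a normal-reference Wald statistic
(measured false-positive rate ~0.115 at nominal 0.05), so each per-feature
estimate is floored at the median estimate across all features — the same
information-sharing idea as DESeq2's dispersion shrinkage, in its simplest
monotone form. The moderation is conservative exactly for features whose
dispersion estimate falls below the ensemble median; measured type-I error
is ~0.05 on matched simulations. Features with zero counts everywhere are
flagged untested (`p = 1`, `log2FC = 0`). The implementation is
deliberately transparent rather than a GLM wrapper; results are
statistically comparable to, but not feature-for-feature identical with,
DESeq2/EBSeq.

P-values are Benjamini–Hochberg adjusted within each contrast separately
(whether the original analysis adjusted jointly is not stated; per-contrast
is the DESeq2 default). An mRNA is **bound** when enriched
(`log2FC > 1`, `padj < 0.05`) over both BO and INPUT; bound mRNAs are
`bound_enriched` if also enriched over TOTAL, `bound_depleted` under the
mirrored thresholds (`log2FC < -1`, `padj < 0.05` against TOTAL; the
original depleted group's statistical definition is not printed, so the
mirror is an assumption), else `bound_not_enriched`.

Repeat-element locus counts are collapsed to subfamilies by plain
summation (column totals conserved; unmapped loci are errors).
Association regressions are ordinary least squares with R² as squared
Pearson correlation and the slope's t-test p-value (identical to the
F-test for a single predictor); the length regression uses each gene's
maximum annotated transcript length.

## Coverage integrity

Bin *i* of 10 spans bases `[floor((i-1)L/10), floor(iL/10))` — a
deterministic partition for any transcript length L ≥ 10 — and holds the
sum of per-base depth over that span. Depth (not read 5' ends) is the
default because it matches "coverage across each region"; a read-start
mode is available via `coverage_mode = starts` in the run configuration.
The terminal integrity statistic `TIS = ((c1+c10)/2)/mean(c2..c9)` is this
package's operationalisation of the visual terminal-loss check and is
labelled as such in output: 1 for uniform coverage, 0.5 when one terminal
decile is missing. No significance test is attached — the underlying claim
is visual, and inventing a null here would overstate it.

## Gradient and expression calculators

Fraction percentages assume doubling per cycle:
`q_f = 2^(Ct_input - Ct_f)`, `percent_f = 100 q_f / sum(q)`. Non-detected
fractions are `NaN` in and 0% out — never Ct 0, which would silently
contribute `2^Ct_input`-fold signal. The transformation is invariant to a
constant shift of all Cts including the reference. ΔΔCt uses fixed
amplification efficiency 2.0 (efficiency calibration is out of scope);
replicate Cts are averaged before transformation. Densitometry fold change
is `(target/loading)/(target_ctrl/loading_ctrl)` on positive intensities.

## Colony assay

Segmentation: global Otsu threshold (bright colonies over dark
background), hole filling, 8-connected labelling; border-touching regions
are kept. A constant image yields zero regions with a warning. The
optional watershed split of merged blobs (`watershed_split`) is off by
default — it stands in for the manual proofreading step of the original
procedure and is not exercised by the default tests.

Features per region: equivalent diameter `2*sqrt(A/pi) * pixel_size`;
circularity `4*pi*A/P^2` with the Crofton 4-direction perimeter estimator.
The estimator choice matters: boundary-segment counting carries a ~9%
systematic bias on digitised disks, whereas Crofton converges
(measured disk circularity 0.968/0.992/0.995 at radii 20/50/100 px), at
the price of smoothing corners (a digitised square measures ~0.88 against
the ideal-perimeter π/4 ≈ 0.785). The estimator is named in output
metadata. The "gray level texture difference moment" of the original
MetaMorph analysis has no published formula; it is implemented as GLCM
contrast `sum((i-j)^2 p(i,j))` at distance 1 averaged over the 4 standard
directions, on 8 gray levels min-max rescaled within the region, counting
only pixel pairs that both lie inside the region (a masked co-occurrence
matrix, hand-rolled because library GLCMs cannot mask). All GLCM
parameters are config-exposed.

Gates are inclusive at all three printed bounds: diameter ≥ 194.5 µm,
circularity ≥ 0.45, texture ≤ 2.75. The correction chain is
`adjusted = mean(3 replicate counts)/transfection_efficiency`,
`corrected = adjusted_L1/adjusted_reporter`, and percent relative to the
baseline condition (exactly 100). Transfection efficiencies are supplied
counts (`EGFP+ / total`); automated fluorescence counting is out of scope.
A two-tailed unpaired t-test utility matches the statistics quoted in
figure legends.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their parameters and a numpy
`default_rng` seed; truth tables are emitted alongside the data and are
consistent with it by construction.

- **PSM tables** (defaults: 1000 proteins, 100 true interactors, 10
  salt-labile, 10 RNase-sensitive, 8-fold IP enrichment, mean-2 Poisson
  background, 3 replicates, 2 experiments): per-protein abundance is
  Gamma(4, rate/4) so background varies across proteins; counts are
  Poisson because spectral counts are low-mean (over-dispersion is a noted
  extension); the bait is fixed high in every IP. Salt-labile proteins
  drop 8-fold at high salt, RNase-sensitive ones 8-fold after digestion.
  For recovery metrics the positive class is true interactors plus
  RNase-sensitive proteins (RNase sensitivity classifies, never filters);
  salt-labile proteins are designed casualties of the stringency filter.
  Not emulated: peptide-level identification, shared peptides, MW-biased
  detectability.
- **Count matrices** (defaults: 2000 features, 200 bound at fold 4, NB
  dispersion 0.1, triplicate TOTAL/INPUT/BO/IP, unit library sizes):
  log-normal baselines (log-mean ln 100, log-sd 1.5) make expression span
  orders of magnitude, which is what lets the expression-association
  regression be tested; the bound multiplier applies to IP only, so BO
  carries expression-proportional background. Not emulated: multimapping
  reads, length-biased counting, sample-specific GC effects.
- **Coverage** (defaults: 2000-nt transcripts, 1e5 reads each): reads are
  point samples (read starts uniform, depth = start counts), making decile
  shares exactly multinomial; extended clipped reads are available via
  `read_length` but introduce terminal ramps that are an artefact of read
  geometry, not degradation. Truncation removes the 3' fraction of the
  start domain entirely — real degradation is gradual.
- **Gradient Ct tables**: `Ct_f = Ct_input - log2(percent_f/100 * total) +
  N(0, noise_sd)` over 12 fractions, default distribution peaked in early
  polysomal fractions 6–8 and 0.2-cycle noise; zero-percent fractions are
  emitted as the non-detected sentinel. Primer efficiency and saturation
  are not modelled.
- **Plates** (defaults: 50 colonies of 250–550 µm, 200 clutter objects, 5
  µm/px): colonies are radial-harmonic blobs (boundary noise < 15% of
  radius) with smoothed-noise interiors; clutter violates exactly one gate
  each — sub-threshold specks (30–120 µm), elongated smears (aspect 6–9,
  circularity ≈ 0.3–0.42), and colony-sized patches with i.i.d. speckle
  (GLCM contrast ≈ 10). Objects are placed without overlap,
  largest first, on a constant background (so a blank plate segments to
  zero regions). Not emulated: optics blur, illumination gradients,
  touching colonies, staining variability — so the measured
  precision/recall ≈ 1 bounds what segmentation can do on clean input and
  says nothing about crowded real plates.

## Problem sizes and runtime

The test suite and the acceptance script run each stochastic claim at the
scale its guarantee is stated for: 500 random tables for the interactome
oracle, 1000 vectors for BH, 20 simulation seeds (2000 features each) for
the bound-call FDR/sensitivity and 10 for the null type-I error, 1e5 reads
per transcript for coverage, and 10 rendered plates (~250 objects each)
for colony metrics. The whole suite completes in well under a minute on a
single CPU.

## Known limitations

- The enrichment test is a two-group Wald contrast, not a GLM; covariates
  (batch, library chemistry) are out of scope.
- The published raw IP-MS spectral-count tables live in a journal-hosted
  spreadsheet that is not redistributed here, so the two checks that
  reproduce the published interactor-set and detection counts require the
  user to export those tables locally (see `tests/test_acceptance.py`).
- TIS compares conditions by ratio only; no uncertainty is propagated.
- The colony pipeline assumes one stained channel and a spatially uniform
  background; uneven illumination would need flat-field correction
  upstream.
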