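# Methods

This note records the models, defaults, and numerical choices behind
`corona_quant`, and what the synthetic-data generators do and do not
emulate.

## Density-gradient fraction analysis

The fraction profile is treated as a vector of non-negative fluorescence
values over contiguous fractions 1..N (top to bottom, 0.5 mL each;
lissamine-rhodamine ex/em 560/580 nm).  Window recovery is a simple mass
ratio; blank (per-fraction background) subtraction is supported but **off by
default**, because plasma autofluorescence is negligible in this assay.
Negative blank-corrected values are clipped to zero before summation.
Window selection scans all contiguous windows of width k and takes the
maximum-recovery window, breaking ties toward the earlier start — the
low-density side where intact LNPs band.

Gradient-linearity QC fits measure ~ fraction index by ordinary least
squares over the full profile by default, with an optional sub-range for
tubes whose ends deviate from linearity; the default acceptance threshold is
R² ≥ 0.98.  A constant measure is reported as R² = 0 (no gradient) rather
than undefined.

## Hi3 quantification and enrichment

* **Hi3 / top-3**: per run (condition × replicate × batch), abundance =
  spike × mean(top-3 peptide intensities) / mean(top-3 of the standard).
  The spike defaults to 50 fmol of E. coli ClpB (P63284) per 5 µL of
  digest; abundances are reported in that per-run convention without volume
  rescaling.  Top-3 ties are broken by peptide-id lexicographic order so
  results are deterministic.  The ratio is computed before multiplying by
  the spike, which makes the standard's self-quantification *exactly* the
  spike amount in floating point.
* **Missingness**: a peptide missing in more than one replicate of a
  condition/batch is excluded from quantification of those runs (logged);
  proteins with fewer than three quantifiable peptides use what is
  available and are flagged.
* **CV summary**: per (peptide, condition, batch), CV% = 100·s/m̄ across
  technical replicates; peptides with fewer than two finite intensities are
  excluded, zero-mean peptides are excluded with a warning; the summary
  statistic is the per-condition median.
* **Enrichment**: only proteins quantified with ≥ 2 replicates in both
  conditions are tested.  The per-protein test is Welch's two-sample t on
  log2 abundances with Benjamini–Hochberg adjustment across the tested set.
  The vendor software behind the original q values is unspecified, so this
  transparent test stands in; it is robust to unequal variances and
  standard for label-free data, but exact agreement with vendor counts on
  real exports is not guaranteed.  Zero abundances are imputed at half the
  run's smallest nonzero abundance (logged).  Proteins seen in only one
  condition are reported in separate lists rather than given infinite fold
  changes.
* **EASE over-representation**: one-sided Fisher exact p of the 2×2 table
  with the observed overlap decremented by one (floored at zero) — a
  deliberately conservative variant; a term passes at count ≥ 5 and
  p ≤ 0.05.  Annotation maps are user-supplied; no remote service is
  queried.

## Imaging

Masks are global thresholds (Otsu by default, a fixed threshold as
override), applied with identical parameters across all conditions of an
experiment.  Nuclei are counted by Otsu + 8-connected labeling with a
minimum-area filter (default 50 px; when simulated geometry is known, an
area derived from the nucleus radius is appropriate).  The cell-membrane
mask from a cytoplasmic membrane stain is interpreted as whole-cell area;
the erosion analysis (inner = n-fold erosion, outer = XOR) presumes this
interpretation.  The structuring element is the full 3×3 square
(8-connectivity), so n erosions remove pixels within Chebyshev distance n of
the background — a property the tests exploit via an independent
distance-transform oracle.  The erosion depth defaults to n = 10.

FOVs with zero detected nuclei or zero in-mask Cy5 signal are excluded with
a warning.  Aggregation means FOVs into technical replicates and technical
replicates into biological replicates, retaining both levels for the nested
statistics.  Channel identity comes from an explicit sidecar JSON written
next to each TIFF, never from image statistics.

## Statistics

* **Nested one-way ANOVA**: condition fixed, biological replicate the error
  stratum.  Technical sub-values are averaged into replicate means first;
  for balanced sub-counts this reproduces the classical nested
  F = MS(condition)/MS(replicate-within-condition) exactly, and it is also
  the deliberate treatment of unbalanced designs (replicate means as error
  units; Satterthwaite df are not attempted).
* **Repeated-measures one-way ANOVA**: complete blocks required.  The
  Geisser–Greenhouse epsilon is computed from the double-centered sample
  covariance of the within-replicate condition measurements and multiplies
  both F degrees of freedom.  Post-hoc Dunnett comparisons use the
  uncorrected within-replicate error MS with (n−1)(k−1) df.
* **Dunnett adjustment**: adjusted p values and critical values are read
  from a Monte-Carlo reference distribution of max|T| over the many-to-one
  contrasts in the group-means model (group means ~ N(0, 1/nᵢ) with a
  shared chi-square scale), 200 000 draws with a fixed internal seed,
  cached per design.  The Monte-Carlo granularity is ~0.002 in p at
  p ≈ 0.05; exact quadrature is unnecessary at the working alpha.  The
  implementation is cross-checked in the tests against `scipy.stats.dunnett`
  and, for the critical value, against the multivariate-t quantile.
* **Flow gating**: the positive gate is a quantile of the non-treated
  control (default 0.995, configurable; the original gate placement is not
  stated).  MFI is reported over all sample events, with the gated-events
  mean alongside.

## Synthetic data

The generators produce every input the pipeline consumes, with ground truth
recorded beside each dataset, and all randomness flowing from one seed
through labeled sub-streams (`_random.substream`).

* **Fraction profiles**: two discretized Gaussian peaks (normalized on the
  fraction grid so each carries its configured mass) + baseline + Gaussian
  noise, clipped at zero.  Defaults: 24 fractions; sharp early peak at
  fraction 4 (sd 0.75) carrying 68 mass units and a broad late peak at
  fraction 14 (sd 4) carrying 32 — the early/late fluorescence split of the
  study gradient, with the late peak representing dissociated fluorophore.
  Its shape is not asserted beyond "broad and minor"; both peaks are free
  parameters.  Baseline defaults to 0.1 a.u. (negligible plasma
  autofluorescence) and noise to 0.5 a.u.  Refractive index ramps linearly
  1.344→1.384 (5→30% iodixanol) and absorbance 0.05→0.35, both with small
  noise, for the linearity QC.
* **Peptide tables**: intensity = abundance(fmol) × peptide response factor
  × unit-mean log-normal noise, with σ² = ln(1+CV²).  Response factors are
  drawn once per peptide from log-uniform [0.2, 5] so top-3 selection is
  nontrivial.  Plasma abundance = LNP abundance / 2^log2FC.  The default
  effect structure is 56 proteins: 39 enriched, 14 depleted (|log2FC| in
  1.5–5), 3 null; base abundances log-uniform 5–500 fmol; 3 technical
  replicates; the standard spiked at 50 fmol in every run.  The default
  noise CVs derive from the observed n=3 median CV% values of 11.8 (LNP)
  and 19.0 (plasma): the median of an n-replicate sample CV underestimates
  the population CV by √(median(χ²ₙ₋₁)/(n−1)) ≈ 0.833 at n=3, so the
  generating CVs are 0.142 and 0.228, chosen analytically so the *observed*
  medians of simulated data match the stated conditions.  The config takes
  a single LNP-side CV plus an optional plasma-side override, since the two
  sample types differ.
* **Fields of view**: non-overlapping disk cells (radius 26 px) with
  nuclear disks (radius 7 px), small lysosome vesicles in the inner region,
  and Cy5 puncta placed per compartment — inner (survives rim-width-fold
  3×3 erosion of the cell mask), outer rim, or lysosomal — then blurred by
  a Gaussian PSF and given Poisson-approximating Gaussian noise
  (sd = scale·√intensity).  The PSF default is σ = 0.8 px, of the order of
  the diffraction limit at the acquisition magnification and pixel size;
  puncta keep a 2 px margin from compartment boundaries (and inner puncta
  avoid the lysosome footprint) so the placement compartment remains
  unambiguous under blur and the recorded truth is directly comparable to
  the measured quantity.  Background is low (0.2 a.u.) relative to punctum
  amplitude (2000 a.u. integrated), as in background-subtracted confocal
  data.  Coordinates are row-major 0-based; masks include boundary pixels.
  Not emulated: spectral bleed-through, z-stacks, cell-shape variability,
  uneven illumination — so passing recovery tests demonstrate estimator
  correctness on idealized geometry, not robustness to those artifacts.
* **Flow samples**: Gaussian control and mean-shifted treated populations;
  the truth records the analytic percent positive above the population
  control quantile.

## Calibration studies and problem sizes

`corona_quant.validation` runs the full analysis paths on generated data:
FDR under a null proteome (200 runs of 30 proteins × 4 peptides), log2FC
recovery at a true effect of 2 (200 runs, CV 0.12, n=3), imaging
fold-change recovery (12 FOVs per condition at rates 5 vs 25 per cell),
outer-fraction recovery (12 FOVs at a 9:1 inner:outer split), and
family-wise type-I error of both ANOVA+Dunnett procedures (2000 simulated
experiments each; 5 conditions × 3 biological × 4 technical for the nested
design, 4 × 4 complete blocks for the repeated-measures design).  These
sizes keep the complete suite and the reproduction script in the
one-minute range on a single core while leaving Monte-Carlo error well
inside the stated tolerances.

## Known limitations

* The enrichment test is a stand-in for unspecified vendor statistics;
  concordance, not identity, is the expectation on real exports.
* The nested-ANOVA error structure (replicate means model) is one defensible
  choice; mixed-model REML machinery is deliberately out of scope.
* Whether reported fmol abundances are per-run or replicate-averaged is
  ambiguous in the source convention; the quantification table keeps
  per-run values so either summary can be formed.
* Image quantification is per-FOV normalized by nuclei count; no
  instance-level (cell-by-cell) distributions, tracking, deconvolution, or
  3D handling.
* The 68% window-recovery figure is reproduced on raw (not
  blank-corrected) profiles; both modes are exposed because the original
  convention is not stated.
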