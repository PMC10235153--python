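# Methods

## The measurement model

The pipeline quantifies chromogenic in situ hybridization (ISH) signal in
coronal sections of the embryonic chicken nucleus magnocellularis (NM), an
auditory hindbrain nucleus whose neurons are ordered tonotopically from the
rostro-medial (high characteristic frequency) to the caudo-lateral (low
characteristic frequency) pole. On each section a fixed set of equal-area
square regions of interest (ROIs) is measured: RM and RL on rostral
sections, MM, MC and ML on middle sections, CM and CL on caudal sections,
plus one same-sized background reference region (REF) per section placed on
unstained tissue.

Measurement follows the ImageJ-style densitometry workflow:

1. the grayscale image is inverted, `v -> (2^bit_depth - 1) - v`, so that
   stronger staining (more transcript) gives larger values;
2. the arithmetic mean gray value of each ROI is taken exactly (half-open
   pixel rectangles, no resampling);
3. the ROI mean is divided by the same-section REF mean, giving a
   dimensionless *relative intensity*. Normalizing by ratio rather than
   subtraction makes the quantity invariant to slide-to-slide scale
   (exposure, development time); a subtraction mode is available through
   `AnalysisParams(normalization="subtract")` for sensitivity checks.
4. Each ROI is measured 2–4 times ("replicates"). A replicate is modelled
   as a re-placement of the rectangle by a uniform integer offset of at most
   `jitter_px` pixels (default 2), for both the ROI and the REF region.
   Replicates of one ROI are averaged before any testing, keeping the
   statistical sampling unit at the section (slice) level and avoiding
   pseudoreplication of within-section re-reads.

## Statistical comparisons and the decision tree

Three unpaired two-sided t-tests drive the pattern call, all at strict
p < alpha (default alpha = 0.05, Student pooled-variance; Welch available):

* **rostral vs caudal** — one value per rostral section, the mean of its RM
  and RL relative intensities, against one value per caudal section (mean of
  CM and CL);
* **MM vs MC** and **MC vs ML** — one value per middle section per ROI.

The decision tree:

1. If rostral vs caudal is not significant the pattern is **homogeneous**
   (the middle-plane tests are not run). Otherwise it is **differential**,
   with the direction given by the sign of the mean difference.
2. On the differential branch: both middle tests significant with the same
   sign → **gradient** (monotone medial–lateral change, direction reported);
   MM vs MC significant and MC vs ML not → **selective** (medially
   restricted expression); anything else stays plain **differential**. In
   particular, two significant middle tests of *opposite* sign (a V-shape)
   are not a monotone gradient and fall back to differential.

Two identical constant samples are given t = 0, p = 1 by convention (no
evidence of a difference) rather than an error; two *different* constant
samples are rejected, since the t statistic is undefined at zero pooled
variance. No multiple-testing correction is applied across the three tests
by default, matching the uncorrected three-test design this analysis
reproduces; a Holm option (`AnalysisParams(holm=True)`) exists for
sensitivity analysis.

The middle-plane comparisons are run as *unpaired* tests even though MM, MC
and ML come from the same sections. One consequence (see the noise model
below) is that comparisons between truly equal middle ROIs are conservative,
while the rostral-vs-caudal test across independent sections is exactly
nominal.

## The synthetic section generator

No section images are distributed with the study design this package
implements, so every stage is exercised against a seeded generator that
emulates the design's statistical structure, not NM histology:

```
pixel = background_level - stain_gain * level * section_jitter + pixel_noise
```

rendered in stain space (dark NBT/BCIP-like precipitate on light tissue,
so the pipeline's inversion step is genuinely exercised), clipped to the
bit-depth range and rounded. The noise model has exactly two tiers:

* `section_jitter ~ Normal(1, sigma_section)`, one multiplicative factor
  per section shared by all its ROIs — biological variability between
  slices and animals. This is the tier inference runs on. Default
  `sigma_section = 0.05` (5% between-section level variation).
* additive per-pixel Gaussian noise, `sigma_pixel = 4` intensity units on
  an 8-bit scale — camera noise and stain granularity. Averaged over a
  40×40 px ROI its standard error is 0.1 intensity units, negligible
  relative to the jitter tier.

Defaults: 8-bit 240×80 px images, 40 px square ROIs laid out left-to-right
with an 8 px gap, stain painted with a 4 px margin beyond each ROI so that
replicate jitter (≤ 2 px) stays on uniformly stained tissue, background 200,
stain gain 60, three sections per plane, three replicates per ROI. ROI pixel
sizes are arbitrary (the imaging magnification of the original measurements
is not part of the design); what matters for inference is the ROI-mean noise
scale, which the defaults keep realistic.

Because the section jitter is shared within a section, two middle ROIs with
equal true levels (e.g. the selective preset's MC and ML) produce nearly
identical samples — their between-section variance is common — so the
unpaired MC vs ML test almost never fires falsely, whereas rostral vs caudal
compares *independent* sections and has exactly its nominal alpha-level
false-positive rate. This makes the ≥95% recovery of the selective and
plain-differential calls and the nominal 5% type-I rate of the step-1 test
simultaneously achievable at three sections per plane.

### Presets

`make_preset(name)` returns the frozen level tables (dimensionless expected
expression per ROI):

| preset             | RM/RL | MM   | MC   | ML   | CM/CL | generating pattern        |
|--------------------|-------|------|------|------|-------|---------------------------|
| `atoh7_e13`        | 0.15  | 0.60 | 0.60 | 0.60 | 1.20  | differential, caudal-high |
| `hes1_e13`         | 1.20  | 0.70 | 0.70 | 0.70 | 0.30  | differential, rostral-high|
| `pax6_e13`         | 1.30  | 1.00 | 0.70 | 0.40 | 0.50  | gradient, medial-high     |
| `eya2_e13`         | 1.25  | 1.00 | 0.70 | 0.40 | 0.55  | gradient, medial-high     |
| `ebf3_e13`         | 1.25  | 0.90 | 0.35 | 0.35 | 0.25  | selective                 |
| `homogeneous_null` | 0.80  | 0.80 | 0.80 | 0.80 | 0.80  | homogeneous               |

The ordinal relations encode each gene's reported E13 NM pattern; the
numeric values were fixed once by a power calculation so that the default
design (3 sections/plane, default noise) recovers every generating pattern
in well over 95% of runs (the smallest standardized group difference,
pax6/eya2 MM−MC, is ≈ 6 pooled standard deviations at these settings), and
are frozen. Every ground-truth label is recomputed from the level table by
the classifier's noiseless rules (`pattern_from_levels`, equality within
1e-9 standing in for non-significance), so labels cannot drift from the
classifier's semantics.

### Determinism

One dataset seed fans out through `numpy.random.SeedSequence((seed, plane,
section))` to per-section streams, and through a separate substream to
replicate placement, so identical configurations reproduce bit-identical
images and byte-identical measurement/comparison CSVs (the run manifest,
which carries a timestamp, is the one file excluded from that guarantee).

### What the generator does and does not emulate

It reproduces the study design's statistical skeleton — plane-specific ROI
sets, per-section biological jitter, pixel noise, a background reference,
replicate re-measurement — but not anatomy: no nucleus shapes, cell bodies,
staining texture, uneven background, or ROI placement error beyond the
replicate jitter. Passing recovery tests therefore shows that the
measurement and decision machinery is correct and well calibrated under the
stated noise model, not that the original imaging conditions would yield the
same power.

## Monte-Carlo calibration

`estimate_type1_error` repeatedly pipes homogeneous datasets through the
full pipeline and reports the fraction leaving the homogeneous branch, with
a Wilson 95% interval (2000 repetitions in the acceptance run; binomial SE
≈ 0.005 at alpha = 0.05). `pattern_recovery_matrix` tabulates called against
generating patterns per preset. Per-repetition seeds are spawned from one
master seed, so both are exactly reproducible.

## In-silico PCR

`find_amplicon` performs exact string matching of the forward primer and
the reverse complement of the reverse primer, in both orientations of the
template; the product length includes both primers, coordinates are 0-based
half-open on the plus strand. Zero products raise a "no amplicon" error and
multiple products an "ambiguous priming" error listing every hit — ambiguity
is a specificity failure, never resolved silently. No thermodynamics (melting
temperature, dimers) and no mismatch tolerance: the probe primers were
designed against the cited assemblies. The shipped table carries the ten
probe primer pairs (five genes × chicken/mouse) with their expected product
sizes (240–570 bp). Offline validation plants each pair on a synthetic
template (random flanks and insert sized to the expected product, pairs
sharing a chromosome accession co-planted on one template); fetching the
real accessions is possible with `scripts/fetch_templates.py` but nothing
depends on it. In the flowed-text rendering of the primer table the
forward/reverse boundary of some rows is ambiguous; the shipped splits
follow primer-like lengths (20–25 nt) and are exercised end-to-end by the
planted-template checks, which are split-invariant.

## Numerical choices and edge cases

* All means and ratios are computed in float64; images are quantized only
  at file boundaries (8/16-bit TIFF or PNG).
* ROI rectangles are 0-based, half-open; equal-area squares satisfy the
  equal-size constraint of the design.
* Replicate jitter offsets are clamped so the rectangle stays inside the
  image; an ROI that does not fit at all is an error.
* The section jitter factor is clamped at 0.01 (a >19-sigma event at the
  default sigma) to keep levels positive.
* A configuration whose expected stain pixel would be negative before
  clipping is rejected with advice to lower the stain gain.
* Significance is strict (p < alpha), and `significant` is always derived
  from the reported p-value, also after Holm adjustment.

## Known limitations

* Power statements hold under the generator's Gaussian two-tier noise
  model; heavy-tailed section effects or correlated background would lower
  them.
* The unpaired treatment of within-section middle-plane comparisons is
  deliberately faithful to the reproduced design; a paired or mixed-model
  analysis would be more efficient and is out of scope.
* The amplicon checker validates primer/template consistency, not probe
  specificity in tissue.
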