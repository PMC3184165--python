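# Methods

## The experimental system being modeled

A unilateral 6-OHDA lesion denervates one hemisphere's nigrostriatal
dopamine projection; chronic L-DOPA then induces dyskinesia in a subset of
animals (low- vs high-dyskinetic groups, LD/HD, plus lesion-only controls,
LC). MALDI-TOF imaging mass spectrometry acquires one spectrum per matrix
spot on a 250 µm grid over the ventral midbrain, 500–3500 Da. The analysis
quantifies prodynorphin-derived peptides per substantia-nigra (SN) region
and hemisphere, tests lesion-side fold changes against treatment group, and
correlates peak areas with cumulative dyskinesia (AIM) scores.

## Peptide mass calculus

Monoisotopic [M+H]⁺ = Σ residue masses + 18.01056 (water) + 1.00728
(proton), with −0.98402 Da for C-terminal amidation (OH→NH₂). Residue
masses are stored to five decimals; unit tests cross-check every catalog
entry against pyteomics. Truncating the computed [M+H]⁺ to its integer part
reproduces the integer peak labels in common use for Leu-Enk-Arg (712),
aNeo(1-7) (840), Dyn A(1-8) (981) and substance P (1347). Three catalog
entries carry a note field because their customary integer labels (Leu-Enk
555, Leu-Enk-Arg-Arg 867, Dyn A(1-17) 2145) do not match the computed
[M+H]⁺ (556.28, 868.48, 2147.20) under any rounding convention; the catalog
keeps full-precision values and makes no attempt to reconcile the labels.
des-Tyr metabolites are generated by removing the N-terminal tyrosine
(−163.0633 Da), with `(1-k)` range names rewritten to `(2-k)`.

Annotation is tolerance-based (default 0.3 Da — unit-resolution TOF bins),
returning all catalog matches ranked by |Δppm| with alphabetical
tie-breaks.

## Spectral processing chain

Fixed stage order: baseline → TIC normalization → alignment → peak
detection → binning → AUC integration. Each stage is idempotent on its own
output where that is meaningful (baseline, normalization).

**Baseline.** The lower convex hull of the (m/z, intensity) point set,
computed by Andrew's monotone chain (O(n), exact on collinear/degenerate
inputs where a general qhull call fails), interpolated and subtracted.
Constant and linearly ramping spectra map exactly to zero; endpoints always
map to zero.

**TIC normalization.** Each spectrum is scaled to a common target total ion
current; the default target is the mean raw TIC of the fitted spectra so
normalized intensities stay on a familiar scale.

**Alignment.** One rigid m/z shift per spectrum (no stretch: TOF drift at
this mass range is locally rigid and a single parameter is directly
testable). The shift maximizes a matched-filter score — Gaussian templates
(σ 0.2 Da) at the reference peptide masses correlated with the spectrum —
over a 0.01 Da grid within ±`max_shift` (default 1 Da), with parabolic
refinement. The shifted spectrum is rescaled to its pre-shift TIC: a rigid
axis shift must not change total counts, and this makes alignment commute
exactly with TIC normalization. Spectra containing no reference mass are
returned unshifted with a warning flag, as are estimates clamped at
±`max_shift`. Planted-shift tests require recovery within ±0.05 Da.

**Peak detection.** Noise is estimated per sample as 1.4826 × the median
absolute deviation in a sliding window (default 101 samples); the same
window provides a local median background. A strict local maximum is kept
when (apex − local background)/noise exceeds the S/N threshold (default 3).
The background subtraction in the numerator matters: after convex-hull
baseline removal, long noisy stretches retain a positive offset (the hull
hugs the noise minima), and a raw apex/noise ratio would pass essentially
every noise maximum. Integration bounds sit at the nearest flanking local
minima. Where the local noise estimate is exactly zero (noise-free
synthetic data), any positive background-subtracted apex is kept.

**Binning.** Apex m/z values pooled over all spectra (all sections of a
study, so bins are comparable across animals), sorted, and grouped by a
greedy single pass: a new bin opens when the next apex is more than `tol`
(default 0.3 Da) from the running mean of the current bin. Centers are
member means; half-widths are the largest member deviation, clipped to half
the gap to neighboring centers so bin intervals never overlap. On
well-separated clusters this coincides with single-linkage clustering,
which the tests exploit as an oracle. No re-merge pass; no deisotoping —
isotope peaks become separate bins by design, since the implied deisotoping
step of the emulated workflow is undocumented.

**Integration.** Trapezoidal AUC per spot over `center ± max(half-width,
0.25 Da)`; the 0.25 Da floor matches unit-resolution TOF peak widths.
Windows fully outside a spectrum's axis yield NaN (missing, not zero).

The chain is exposed both as functions and as sklearn transformers
(`ConvexHullBaseline`, `TICNormalizer`, `SpectrumAligner`, `PeakBinner`)
so it composes with `sklearn.pipeline.Pipeline` and model-selection
utilities; `PeakBinner.fit` learns the bin set, `transform` emits the
spots × bins area matrix.

## ROI geometry and summaries

The SN ROI is a labeled spot set per hemisphere. The medial/lateral split
is the perpendicular bisector of the segment from the ventromedial to the
dorsolateral corner; spots on the VM side (inclusive of the boundary) are
medial. This is one concrete reading of "bisecting" the VM–DL line; the
choice is pinned by a signed-distance oracle test, and swapping the corner
arguments provably swaps the labels. Summaries are arithmetic means of spot
areas per (hemisphere, region, bin) with spot counts always reported, so
medial/lateral imbalance is visible. Lesion effects are reported as
percent of the intact-side mean. Ion images place per-spot areas on the
grid unchanged (no smoothing or interpolation — rendering is presentation,
not analysis); RGB composites min-max scale each channel per image, with a
constant channel rendered at 0.5 rather than dividing by zero range.

## Statistics

Per bin, the response is the within-animal side ratio log2(lesioned ROI
mean / intact ROI mean). The ratio form matches percent-of-intact reporting
and removes animal-level intensity scaling; observations with a
non-positive side mean are dropped (log undefined). The model is OLS on
treatment group (dummy-coded, LC reference) plus analysis run as a batch
covariate; the contrast of interest (default HD vs LC) is t-tested and
Benjamini–Hochberg-adjusted across bins (step-up, monotonicity enforced; a
two-group single-run design reduces exactly to the pooled t-test). No
empirical-Bayes variance moderation is applied: at n = 4–5 animals per
group the per-bin OLS t-test is the transparent choice and is what the
recovery tests quantify. Zero-residual degenerate fits return p = 1 for a
zero effect and p = 0 otherwise rather than NaN.

Pearson correlation (two-sided t-based p) quantifies peak–behavior
relationships, with the least-squares slope and intercept reported for the
fitted line. Duplicate runs are averaged within animal before correlation
(configurable). One-way ANOVA + Tukey HSD handles multi-group comparisons;
dyskinesia time courses use a two-way mixed ANOVA (between = group,
within = session) via the standard sums-of-squares decomposition —
subjects-within-groups as the group-effect error stratum,
session × subject-within-group for session and interaction — with
per-session two-sample t-tests Bonferroni-corrected by the number of
sessions. The hand decomposition (cross-checked against pingouin in tests)
exists so degenerate zero-variance inputs yield defined p-values.

## Behavioral conventions

AIM scores are integers 0–4 in four categories (limb, axial, orolingual,
rotational/locomotor) per monitored timepoint; a session's score sums all
timepoints and categories, and the cumulative score sums all rated
sessions. The locomotor category can be excluded via the `categories`
argument (a common variant in this literature); the default includes it.
Rating sessions fall every other day of the 15-day course (days 1, 3, …,
15). Cylinder-test left-forelimb use is 100·left/(left+right); inclusion
requires strictly less than 30% (the boundary is excluded). Trajectories
are least-squares lines on (day, session score); the day to reach a
threshold score is (threshold − b)/m, so the low-dyskinetic defaults
(m = 0.68, b = 0.41) reach a high-dyskinetic onset of 29.94 in ≈43.4 days —
the formula value is returned as computed, without adjustment toward any
rounded figure.

## Synthetic-cohort generator

Defaults are the emulated study conditions: 14 animals (LC 4, LD 5, HD 5),
duplicate sections per animal, 250 µm grid (two hemispheres of 8×4 spots),
a 6×2-spot SN ROI per hemisphere whose VM–DL bisector yields a balanced 6/6
medial/lateral split, m/z 500–2200 at 0.04 Da sampling with Gaussian peaks
of σ = 0.08 Da, 30% CV lognormal (mean-one) multiplicative peak-area noise,
a decaying-exponential chemical baseline, additive white noise, a lognormal
per-spectrum TIC scale factor, and a rigid per-spectrum m/z jitter.

The planted panel couples the peptide catalog (~14 species) to 10
high-abundance spatially uniform "background" ions that dominate the TIC.
This mirrors real sections, where the ~1000 unrelated species — not the
dynorphin peaks — set the total ion current; it is also what makes
per-spectrum TIC normalization distort the planted lesion/intact folds by
well under 1%, so noiseless end-to-end runs recover the planted folds
within the 1% integration tolerance. Dynorphin species follow the nigral
pattern: enriched in the SN ROI, ventromedially weighted (medial boost
1.3), faint elsewhere.

Default lesioned-side fold changes: Dyn B HD lateral ×1.75 with medial
×1.13 (so the whole-SN mean is ×1.44 under the balanced split); aNeo
lateral ×1.54, medial ×0.98 (whole ≈ ×1.26); Leu-Enk-Arg-Arg HD ×1.70 / LD
×1.10 lateral; aNeo(1-7) HD ×1.48 / LD ×1.02 lateral. The Leu-Enk-Arg
lateral fold has no published magnitude (only its significance and
correlation are reported), so its default ×1.50 is an explicit
configuration value, not a literature-derived one. Dyn A(1-8), Dyn A(1-17),
Dyn A(10-17), bNeo, Leu-Enk, substance P, the des-Tyr forms and all
background ions are true nulls. A "conversion patch" (on by default for HD
animals) plants two dorsolateral-SN spots with locally low Dyn B (×0.4) and
high Leu-Enk-Arg (×2.5), emulating focal release-plus-bioconversion; a
knockout scenario zeroes every prodynorphin-derived species while leaving
substance P intact.

**Severity coupling.** Each treated animal draws a latent standard-normal
severity z; with coupling ρ (default 0.8), the behavioral component and the
fold component are each √ρ·z + √(1−ρ)·ε with independent ε, so their
correlation is exactly ρ. The behavioral component shifts session scores
(2 points per unit severity per session); the fold component multiplies the
lesion-lateral folds of Dyn B, aNeo and Leu-Enk-Arg by 2^(0.25·severity).
Session totals are round(max(0, m·day + b + shift + noise)) distributed
uniformly over timepoint × category cells capped at 4; sessions have 9
timepoints (a 180-minute peak-dose window at the 20-minute cadence — the
cadence is documented in the emulated protocol, the window length is this
package's choice of the standard value). LC animals score zero. Cylinder
draws guarantee the pre-treatment <30% inclusion criterion; post-treatment
left use improves in LD (+10 points), is unchanged in HD, and worsens in LC
(−5), with 3-point noise.

All randomness descends from one master seed through spawned per-animal
and per-section streams; a fixed seed reproduces the bundle bit-for-bit.

## What the generator does not emulate

Physically realistic TOF peak shapes and detector saturation, isotope
envelopes (off by default; planting them would only multiply bins, since
the pipeline deliberately does not deisotope), matrix cluster ions, spatial
autocorrelation of noise between neighboring spots, and freeze-damage
artifacts beyond the TIC-based QC trigger. Passing recovery tests therefore
demonstrates correctness of the computations under the stated noise model,
not robustness to every instrument artifact.

## Problem sizes used in verification

The test suite runs reduced configurations chosen as representative rather
than exhaustive: unit fixtures use narrow axes (500–900 Da) and small
grids; the noiseless end-to-end recovery uses one full-geometry section on
a 500–1700 Da axis; effect-estimate coverage is simulated at the design
level (log2 side ratios of 6-spot region means under 30% CV, n = 5 per
group, duplicate runs, 200 seeds); behavior–peak correlation recovery uses
the latent-variable construction directly (n = 10 treated animals, 500
seeds); and the null-FDR property runs the complete spectra-to-FDR pipeline
on 200 fully null micro-studies (6 animals, 16-spot sections, 500–900 Da at
0.1 Da). QC thresholds: TIC CV ≤ 0.5 by default (configurable; the emulated
protocol names the criterion but no number).

## Known limitations

- Processed-mode imzML and vendor raw formats are out of scope (continuous
  mode only); hemisphere labels travel in a sidecar because imzML has no
  slot for them.
- The per-bin model treats ROI means as independent observations given
  animal and run; spatial autocorrelation across spots and random animal
  effects beyond the side-ratio pairing are not modeled.
- With the two slightly different default group slopes (0.68 vs 0.81
  score/day), the session × group interaction in the mixed ANOVA is weakly
  but truly present; the null-interaction property holds under an
  equal-rate configuration.
- Mass annotation is tolerance-based only; MS/MS-level identification is
  not attempted.
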