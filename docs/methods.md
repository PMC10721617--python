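# Methods

## Scope and intent

The package reconstructs, at desk scale, the computational side of a
prospective microendoscopy study of anal precancer: how a high frame
rate fiber-bundle microendoscope's images are scored for AIN 2+, how
frame-rate and contrast degradation are synthesized and ablated, how a
feature-distribution shift between two device generations is
quantified, and how the diagnostic agreement statistics follow from a
printed site-level count table. Everything that depended on clinical
data or on trained network weights is replaced by synthetic generators
and a transparent stand-in classifier; statistics that are exactly
determined by printed inputs are recomputed exactly.

## Synthetic scenes and rendering

A scene is a homogeneous Poisson field of bright circular nuclei
(count ~ Poisson(density × area), positions uniform, radii and peak
intensities uniform over configured ranges, overlaps permitted) over a
dimmer cytoplasmic background — the geometry of proflavine-stained
epithelium, not its photochemistry. Rendering samples a moving square
window of the scene raster:

- Optics: Gaussian PSF with FWHM equal to the lateral resolution
  (4 µm default).
- Motion: the window translates at the probe speed; each frame is the
  mean of bilinear samples across its exposure window (substep count
  scales with the blur extent, speed × exposure), so the
  within-exposure blur and the inter-frame shift (speed / frame rate)
  are both reproduced and total flux is conserved.
- Fiber bundle: a multiplicative hexagonal transmission lattice
  (superposition of three plane-wave cosines, pitch 3 µm, depth 0.35)
  fixed to the probe, plus the inscribed circular field mask.
- Camera: optional gamma encoding (exponent 0.7 by default in pipeline
  runs; neither camera's true curve is public, so this is a config
  knob with no hardware claim), additive Gaussian noise clipped to
  [0, 1].

All intensities are floats on [0, 1]; quantization happens only when
writing TIFF/PNG. One master seed feeds per-frame and per-site
substreams (master × 100003 + index).

Severity drives morphology in pipeline runs: benign 150 nuclei/mm²
with 2.5–3.5 µm radii, AIN 1 300/mm² with 3.0–4.5 µm, AIN 2+ 650/mm²
with 4.0–6.5 µm and brighter staining — nuclear crowding and
enlargement, the cue every microendoscopy classifier in this domain
exploits. These are illustrative magnitudes chosen so the three tiers
overlap partially (benign/AIN 1 confusable, AIN 2+ mostly separable);
no clinical per-class score distribution is public to calibrate
against.

## Cohorts

A cohort spec fixes exact per-class counts (the default mirrors the
analysis-set composition: 11 benign, 71 AIN 1, 22 AIN 2+), per-class
Beta score distributions (means ordered benign < AIN 1 < AIN 2+),
per-class probability that the clinical impression calls HSIL, and a
QC failure rate (default 4.6 %). Degenerate (point-mass) score
distributions exist so parameter-recovery tests can demand exact
sensitivities. Condyloma acuminatum is grouped with the low-grade
(AIN 1) tier; AIN 2, AIN 3 and cancer collapse to AIN 2+.

## Degradation pipeline

Stage order: gamma inversion → n-frame averaging (selected frame plus
its n−1 predecessors, not a centered window) → fiber-core Gaussian
smoothing → noise injection → saturation preservation → gamma
re-encoding → luminance-statistics transfer. Contrast reduction acts
on the finished composite because it targets the *displayed* grayscale
distribution of the slow camera's images. Defaults:

- `n_average = 5`: 70 fps / 5 = 14 fps equivalent, 5 × 1.4 ms = 7 ms
  composite exposure.
- `smoothing_sigma = 1.0 px` at the original sampling ("small" is all
  that is known; 1 px softens the core lattice without erasing
  nuclei).
- `noise_sigma = 0.04`: calibrated so a degraded blank target shows a
  noise floor 4× the fast camera's (input sigma 0.01; averaging and
  smoothing shrink the input noise to ≈0.001, so the injected term
  dominates and the ratio lands at 4.0).
- Saturation threshold = full scale; pixels saturated in the selected
  frame are forced to full scale in the composite.
- Luminance transfer is an affine map on normalized intensity. On a
  single-channel image the CIELAB luminance channel is a monotone
  function of intensity, so matching intensity statistics keeps the
  mean/std contract exact; the output mean and std equal the target
  exactly before clipping.
- Target luminance statistics are pooled dataset-level constants
  supplied in config (default mean 0.35, std 0.12), not per-image
  matches.

The ablation harness enumerates six methods: method 1 enables every
component; methods 2–6 disable, in order, gamma handling, fiber
smoothing, noise injection, saturation preservation, contrast
reduction. Averaging always runs.

## Scoring

Frames are resampled to the reference pitch by the printed factor
(1.24/0.78 rounded to 1.6; an exact-ratio mode exists), the probe disk
is found by Otsu thresholding a strongly smoothed copy (so the
threshold separates the illuminated field from the dark exterior, not
nuclei from cytoplasm), holes are filled and the largest component's
centroid/equivalent radius define the inscribed bounding square. A
frame with no dark exterior degenerates to the inscribed circle of the
raster. The square splits at its midpoint into four quadrants (odd
sides: the top/left block takes the extra pixel so the tiling is
exact).

The quadrant classifier is pluggable (any callable raster → [0, 1]).
The included morphometry scorer segments nuclei (mean + 0.8 std
threshold, ≥4 px components, and a contrast gate rejecting
segmentations whose foreground is <1.3× the background — otherwise
flat noise yields phantom nuclei), extracts nuclear area fraction,
count density, mean area and contrast, and maps a fixed weighted sum
through a logistic. The weights are configuration constants, never
fitted at run time; a featureless quadrant scores ≈0.05. This scorer
is explicitly *not* the multi-task network used clinically and claims
no comparable accuracy — it exists so the pipeline's mechanics
(severity ordering, degradation-induced score shifts) are testable
against renderer ground truth.

Site score = mean of the four quadrant probabilities; positive iff
score ≥ 0.4 (the cutoff comparison is inclusive; tie handling is not
otherwise determined and the known example scores 0.08/0.67/0.71 are
unaffected).

Quality control replaces a three-expert majority review with an
automated proxy: contact fraction (in-field pixels above an intensity
threshold, default 0.1) and sharp fraction (16 px tiles whose mean
squared gradient beats a focus threshold); a frame fails only when
*more* than half the field is degraded (exactly half passes).

## Feature shift

Quadrants embed as 64-element vectors (morphometry block, intensity
statistics, 16-bin histogram, gradient statistics, 4×4 block means,
zero-padded). The divergence between two collections is the average
over dimensions of the univariate-Gaussian closed form — this matches
the phrase "average K–L divergence" and is stable at small sample
sizes — with a variance floor of 1e-8 per dimension and direction
KL(query ‖ reference). A Kozachenko–Leonenko k-NN estimator on the
joint space is available behind a flag (it can go slightly negative at
small n; tests tolerate −0.05). Optional standardization by the
reference set's location/scale is off by default. t-SNE is
visualization-only: smoke and determinism tests, nothing more.

## Diagnostic statistics

- Sensitivity/specificity come from the 2 (device) × 2 (impression) ×
  3 (histology) table with AIN 2+ positive; exact fractions are kept
  alongside 2-decimal rounding.
- Confidence intervals use the Wilson score interval. No interval
  method is named by the source material; Wilson is the only standard
  method whose bounds reproduce both published intervals
  (0.72–0.97 for 20/22 and 0.77–0.92 for 71/82) at the printed
  precision — under truncation to two decimals, which is how those
  bounds appear to have been printed (Wilson's 71/82 lower bound is
  0.7755). `pipeline.truncate2` encodes that convention.
- McNemar is the exact two-sided binomial form,
  p = min(1, 2·P(X ≤ min(b, c))), X ~ Bin(b+c, ½) — the only variant
  that yields p = 1.0 for the 2-vs-2 discordant comparison.
- Cohen's κ uses marginal-product expected agreement on the collapsed
  2×2 table.
- ROC positivity is score ≥ threshold, AUC equals the Mann–Whitney
  statistic with half credit for ties, PR-AUC is the step integral.
  The matched operating point takes, among thresholds reaching the
  target sensitivity, the one with maximal specificity (ties toward
  the higher threshold); an unreachable target returns the
  max-sensitivity point flagged unmatched.
- The two-proportion chi-square is Pearson's without continuity
  correction (a correction flag exists); degenerate pooled proportions
  raise rather than return NaN.
- Weber fraction is (mean fg − mean bg)/mean bg; noise floor is the
  standard deviation of a blank frame.

## Problem sizes

Tests and the acceptance script run the full pipeline at the 104-site
analysis-set scale with a 160 px (198 µm) field — large enough for
stable morphometry per quadrant, small enough that a full cohort
renders and scores in a few seconds. Cross-stage properties
(degradation direction, ablation sweep) use 8–15 site cohorts;
Monte-Carlo KL checks use 1e5 samples.

## Known limitations

- The morphometry scorer saturates near 1.0 on well-separated
  synthetic classes (synthetic AUC ≈ 1.0); real tissue heterogeneity,
  debris and focal variation would lower it substantially. Passing
  tests demonstrate mechanism, not clinical accuracy.
- The renderer's honeycomb is a smooth transmission lattice; real
  bundles show core-to-core transmission variance and dead cores.
- Gamma exponents, injected-noise law and smoothing sigma of the
  hardware are not public; all are config with the defaults above, and
  divergence values measured on synthetic data are properties of the
  synthetic study only.
- The degradation-direction property (low-severity scores rise,
  high-severity scores fall under the frame-rate/contrast degradation)
  is asserted as a direction, not a magnitude; the synthetic shift is
  larger than the clinically reported 90 %/35 % changes.
- QC is an automated proxy; its thresholds were chosen for the
  synthetic renderer and carry no claim about expert review.
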