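# Methods

## The diagnostic problem

A resected skin layer from BCC surgery must be declared clear or not
clear of tumour at its deep margin while the patient waits. The
package models that decision as a three-stage cascade — image-driven
sampling, spectrum-level classification, and a counting rule — and
provides both a simulated end-to-end pipeline and the closed-form
statistics of the final rule.

## AF segmentation

The AF image is background-thresholded (fixed intensity threshold,
config `background_threshold`, default 150 AU for the phantoms), then
flat-field corrected by dividing by a Gaussian low-pass of the
foreground (normalised convolution so background does not bleed in;
`sigma` defaults to width/10; the corrected image is rescaled to
preserve the mean foreground intensity). Division rather than
subtraction was chosen because AF intensity artefacts
(illumination, stitching) are multiplicative in nature; the choice is
configurable in so far as the raw image can be passed straight through.

Segments are 8-connected components of **below**-threshold tissue
pixels: tumour is darker than stroma, and the area fraction `A` in
`f_B = N·A` is only meaningful when segments capture part of the
tissue. Components smaller than the area of a 60 µm disc at the
configured pixel size are treated as noise (the smallest clinically
relevant tumour scale is ~100 µm). The threshold grid has 256 evenly
spaced levels between the masked minimum and maximum; ties at the
objective maximum resolve to the lowest threshold, which yields the
most conservative segments. `f_B` is the default objective; on
phantoms it detects at least as much tumour (ρ) as `f_A`, at the cost
of higher per-segment heterogeneity (ε), matching its design intent.

ρ is computed against annotated tumour pixels; ε counts only tissue
pixels (background is excluded from both numerator and denominator),
since a segment cannot meaningfully be "contaminated" by background.

## Sampling

Allocation follows the variance-area weighting with `N_min = 5` and a
total budget of 800; fractional shares are rounded by the
largest-remainder method so the total is preserved exactly. If
`k·N_min` exceeds the budget (never the case at realistic segment
counts), segments are served in decreasing-area order and a warning is
raised.

"Uniform" placement is realised as farthest-point sampling seeded at
the pixel nearest the segment centroid: deterministic, evenly
covering, and naturally avoiding round-1 locations via an exclusion
radius of 1 px (a repeated measurement requires a distinct pixel). A
pure-random mode exists for Monte-Carlo estimates (e.g. the expected
hit rate of a half-tumour segment is the tumour area fraction).
Config 1 pins the first two points at the segment's intensity minimum
and maximum (ties: lowest row-major pixel) before uniform filling.

## Raman preprocessing

All spectra live on the 400–1800 cm⁻¹ grid at 2 cm⁻¹ spacing (701
points); inputs covering that range are linearly interpolated onto it.
SNR is the height of the CH₂ band (window 1450 ± 20 cm⁻¹, local linear
baseline through the window endpoints, windowed maximum) divided by
the rms residual of a straight-line fit over the empty 1750–1800 cm⁻¹
region — detrending makes the statistic invariant to affine intensity
transforms. Retention thresholds: training > 15 (strict), validation
≥ 7, diagnosis ≥ 4.

Cosmic rays are spikes of width ≤ 2 points exceeding a 7-point running
median by more than 5 (scaled) median absolute deviations; they are
replaced by the median value and everything else is untouched. These
detector parameters are package choices; only the step itself is
prescribed.

Features are the areas of 13 bands (675, 680, 786, 870, 906, 944,
952, 1092, 1144, 1298, 1376, 1528, 1744 cm⁻¹) above a local linear
baseline, integrated by the trapezoidal rule and normalised to unit
Euclidean norm per spectrum. Band half-widths are not prescribed
anywhere; the default is ±8 cm⁻¹, narrowed to ±3 cm⁻¹ for the
adjacent 675/680 cm⁻¹ pair so their windows stay disjoint. Euclidean
(not L1) normalisation is used. Denoising projects each spectrum onto
the mean plus top-50 principal components of an independent basis of
intermediate-quality spectra (SNR 10–15); projection is idempotent and
its residual is orthogonal to the retained components by construction.

## Classifier

A single-hidden-layer network (13 → 20 → 5, tanh hidden layer,
softmax output, L2 penalty 1e-4, LBFGS) classifies feature vectors
into BCC, dermis, fat, EMI (epidermis + muscle + inflammation, merged
because their spectra are mutually similar) and surgical dye.
Training is deterministic for a fixed seed. Optimiser, activation and
regularisation are unprescribed details; these defaults are standard
for a network of this size. Class imbalance is handled by
oversampling minority classes to parity before fitting (the network
implementation exposes no loss weights); the synthetic library is
balanced, so this path is inert in the shipped experiments.
Performance is estimated by 5-fold cross-validation grouped by
patient id, so no patient's spectra straddle a fold boundary.

## Two-round diagnosis

Round 1 per segment, in order: discard spectra with SNR < 4; if more
than 80 % were discarded → Unclassified (terminal); classify the
retained spectra (after PCA denoising); one lone BCC spectrum is
ignored as an outlier; zero BCC and a unanimous class labels the
segment; zero BCC with mixed classes splits the segment into
nearest-neighbour regions of its points; strictly more than 80 % BCC
labels the segment BCC; otherwise (≥ 2 BCC but ≤ 80 %) round 2 runs.
"More than 80 %" is read strictly: 4 of 5 BCC spectra does *not*
label the segment and instead triggers round 2.

Round 2 places an equal number of new points (excluding round-1
locations), SNR-filters them, pools both rounds' retained spectra and
**always** finalises by nearest-neighbour splitting — even if the
pooled spectra are > 80 % BCC, the whole-segment BCC shortcut applies
in round 1 only. A segment with no retained spectra at all falls back
to Unclassified.

`N_BCC` counts 8-connected BCC regions of the final image, not input
segments: round-2 splitting can contribute several small BCC regions
from one segment, which is precisely the behaviour that motivated
raising the decision threshold to `N_th = 8`.

## Decision model

Closed forms as in the README; the sample-level distribution of
`N_BCC = T + F` is the exact convolution of
`T ~ Bin(n_bcc, seg_se)` and `F ~ Bin(n_nonbcc, 1 − seg_sp)` — no
Poisson or normal approximation, so the printed digits are exact. The
`N_th = 8` predictions (92.93 % / 99.93 %) use the 10-BCC-segment /
150-non-BCC-segment configuration. The per-spectrum specificity input
(96.3 %) is the model's stated input and is used as such. A seeded
Monte-Carlo simulator draws per-spectrum Bernoulli outcomes through
the segment and sample rules as an independent check of the formulas.
Assumed: independence across segments, a constant 5 spectra per
segment, and the at-least-2 simplification of the two-round rule —
the model is guidance for threshold selection, not a guarantee.

## Synthetic data: what it emulates and what it does not

Phantoms are 512 × 512 px at 40 µm/px by default (a 2 cm × 2 cm field);
the test suite and examples use 256 × 256 px at 80 µm/px — the same
field of view at half resolution — to keep runtimes at desk scale.
Stroma (mean 1000 AU) carries a multiplicative Gaussian random field
(sd 90 AU, correlation ~5 px) so that per-segment intensity variance
is non-trivial for the allocation formula; tumour blobs (mean 550 AU)
are unions of overlapping discs ("micro-nodular") or thin curved
strands ("infiltrative"), placed fully inside the elliptical tissue
support and mutually disjoint; background sits at 40 AU and a
contiguous dye arc covers 10 % of the tissue boundary. All intensity
statistics are free parameters — no public AF data constrain them —
and are documented here as package choices.

Spectrum models are Gaussian bands on a linear baseline with white
noise; the noise sd is calibrated so the CH₂ SNR statistic hits its
target in expectation (two small corrections: the windowed maximum
adds ≈1.25 noise sd to the numerator, and the 2-dof linear fit shrinks
the noise estimate by √(24/26)). All tissue classes share the CH₂
band at 1450 cm⁻¹, phenylalanine at 1004 cm⁻¹ and Amide I at 1660
cm⁻¹; the dye model has only its own four bands, so dye spectra
generally fail the CH₂-based SNR gate — dye-marked segments resolve
as Unclassified in the pipeline rather than as dye, which is the
conservative behaviour.

Consequences for interpretation: the synthetic classes are separable
by construction, so the near-perfect cross-validation rates certify
the pipeline's plumbing (features, grouping, thresholds), **not**
clinical accuracy; real per-spectrum rates (e.g. 81.8 % / 96.3 %)
enter only through the decision model's inputs. Likewise the phantom
study shows uniform placement is no worse than extrema placement under
these image statistics; with a phantom whose darkest pixels coincide
perfectly with tumour, extrema placement is artificially favoured, so
the margin between the configurations is smaller than in clinical
images. The lineshape model has no fluorescence background curvature,
no instrument drift and no inter-patient variance beyond noise.

## Numerical choices and degenerate inputs

- Threshold optimisation on a constant image is an error; an empty
  segmentation (k = 0) is a valid result.
- ρ on a tumour-free annotation and the hit rate without tumour
  segments return NaN ("not applicable") rather than raising.
- All-zero allocation weights distribute the surplus uniformly with a
  warning; a segment with fewer admissible pixels than requested
  points receives as many as fit, flagged.
- Nearest-neighbour ties resolve to the lowest point index; argmin/
  argmax ties in placement resolve to the lowest row-major pixel.
- The SNR of an exactly noise-free spectrum is reported as infinity.
- Feature extraction rejects an all-zero area vector ("featureless
  spectrum") rather than emitting NaNs.

## Problem sizes in the shipped experiments

Test and acceptance runs use: 256 × 256 phantoms (80 µm/px), 100
phantoms for the placement comparison, 50 + 50 end-to-end runs with
10 blobs of 300–500 µm radius at SNR 15, a 500-spectrum library
(100/class) for cross-validation, and 10⁶ draws for the Monte-Carlo
check of the decision model. The acceptance script's targets are
analytic and run in milliseconds.
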