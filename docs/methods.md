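# Methods

## LacO-array enrichment statistic

The tethering assay produces a two-channel confocal z-stack containing one
bright GFP punctum (the bait tethered at the LacO array).  The statistic is
computed in six steps, in order:

1. **Slice selection.**  The z slice whose maximum GFP intensity inside the
   ROI is largest (ties to the lowest index).  An all-zero stack is an error.
2. **Centre location.**  The argmax of the GFP slice after 5×5 all-ones
   (J5) smoothing, within the ROI, ties broken row-major.  Smoothing before
   the argmax suppresses single-pixel noise — the same rationale as the J5
   convolution of the mCherry channel.  How the centre is located is an
   implementation choice; this one is robust and deterministic.
3. **Radial profile.**  Integer annuli: pixel p belongs to annulus k when
   round(|p − centre|) = k, k = 0..r_max; each annulus reports the mean over
   in-bounds pixels.  Integer annuli avoid interpolation and make the
   profile an exact per-pixel binning (checked against a brute-force loop in
   the property tests).
4. **Punctum radius.**  The profile decreases inside the punctum; the radius
   is the smallest k ≥ 1 whose forward difference mean[k+1] − mean[k] is
   non-negative — the distance at which the outward derivative first stops
   decreasing.  If the profile never stops decreasing the radius truncates
   at r_max and is flagged.
5. **I_peak.**  The mCherry slice is convolved with the 5×5 all-ones kernel
   (normalized by 25; the final ratio is provably invariant to this
   constant, asserted in the tests).  The peak is the maximum smoothed pixel
   within the punctum disk (round(d) ≤ r); I_peak is the mean of its four
   edge-adjacent neighbours.  A peak on the image border is an error.
6. **I_periphery.**  The mean of the smoothed-mCherry radial-profile values
   at annuli r+1 and r+2 — just outside the punctum.  The smoothed channel
   is used for both I_peak and I_periphery so the two are on the same scale.

`interacting` is the strict call ratio > 1.

The J5 smoothing is implemented as a direct correlation with an all-ones
kernel (reflect padding) rather than a sliding-sum mean filter: sums of 25
pixel values are exact in double precision for integer-valued (camera)
images, so exact intensity ties remain exact ties and the row-major
tie-break is well defined.

**Coordinates** are 0-based (z, y, x) with pixel centres at integers; ROI
bounds are half-open.  Intensities are floating point in memory; the only
quantization is the 16-bit rounding on TIFF export.

### Properties (all asserted by the test suite)

* Zero-mCherry-amplitude, noise-free scenes give ratio = 1 exactly and a
  negative call.
* The ratio is invariant to any positive scaling of the mCherry channel and
  to the J5 normalization constant; adding a constant offset to both
  channels pulls the ratio monotonically toward 1.
* The full pipeline agrees with an independent per-pixel brute-force
  implementation to better than 1e-9 relative on randomized scenes.

### Limitations of the strict ratio > 1 call

The derivative-stops-decreasing radius rule terminates because the quantized
background of an acquired image is exactly flat; on an idealized
continuous-valued Gaussian the profile decreases forever and the radius
would truncate at r_max.  All imaging studies in the tests and the
acceptance script therefore run scenes through the package's 16-bit TIFF
export path, the form in which real data arrives.  On quantized noise-free
Gaussian puncta the rule lands at ≈3.3σ (σ = 2, 3, 4 px → r = 7, 10, 14 px),
and with noise at 5% of the amplitude the estimate stays within ±2 px of
the noise-free radius in ≥95% of seeded scenes.

Because I_peak takes the *maximum* of the smoothed mCherry within the
punctum disk, its expectation under a no-recruitment scene with noise is
strictly above the background, so the null ratio concentrates slightly
above 1 and the strict > 1 call flags essentially every noisy null scene as
interacting (a dedicated test characterizes this).  More generally, any
continuous null distribution of the ratio places about half its mass above
a point threshold.  The strict call is therefore meaningful for clean,
well-exposed scenes (where a flat mCherry channel gives ratio = 1 exactly)
and for comparing ratio distributions between conditions; it is not a
calibrated single-scene hypothesis test under noise.  The classification
study accordingly uses noise-free scenes with randomized geometry (centres,
widths σ ∈ {2,3,4} px, z positions, amplitudes), which exercises every
stage of the pipeline composition; users who need a calibrated call on
noisy data should threshold the ratio against a null distribution estimated
from control scenes.

## Synthetic scenes

A punctum is an isotropic 2-D Gaussian, amplitude A over uniform background
B, with a Gaussian z-attenuation of σ_z = σ_px slice units (this makes
brightest-slice selection non-trivial but unambiguous).  Gaussian noise of
standard deviation `noise_sd` is added after model evaluation and clipped at
zero.  Defaults: 9×64×64 stack, σ = 3 px, A_GFP = 100, A_mCh = 50, B = 10,
noise 0.  The generator does not model a microscope point-spread function,
photobleaching during acquisition, shot-noise intensity dependence, or
multiple puncta per nucleus — passing tests demonstrate correctness of the
measurement procedure on its stated model, not robustness to those effects.

## Droplet quantification

Segmentation is a global Otsu threshold (or a fixed value), 8-connected
component labelling, and a minimum-area filter (default 5 px); survivors are
relabelled consecutively and per-droplet area, centroid, equivalent diameter
and per-channel mean intensities are recorded.  The per-droplet areas always
sum to the nonzero-label pixel count, and Otsu makes the segmentation
invariant under positive affine intensity rescaling.

*Co-condensation efficiency* is object-level: a reference droplet is
colocalized when the fraction of its area overlapping the union of partner
droplets reaches `min_overlap_fraction` (default 0.5); efficiency is the
colocalized fraction of reference droplets, with the reference channel
chosen explicitly by the caller.  A pixel-based Manders-style overlap
fraction is reported alongside as a secondary readout.  *Droplet formation*
is scored per cell as count ≥ `min_droplets` (default 1); per-cell counts
are also emitted so other thresholds can be applied downstream.  Line
profiles are bilinear interpolations at evenly spaced points between two
endpoints.

The droplet generator paints hard disks (radii 4–6 px by default) at
rejection-sampled centres with a minimum separation; a separation of at
least 2·r_max + 2 px guarantees that segmentation recovers the droplet
count exactly, which the acceptance study verifies over 100 seeds together
with total area against π·Σr².

## FRAP

Normalization follows the percent-recovery convention: after subtracting
the background trace frame-by-frame, I₀ is the mean of all pre-bleach
frames (averaging reduces noise in the reference) and I_min is the
intensity at the bleach frame (0 s after bleaching, not the global
minimum); recovery(t) = 100·(I − I_min)/(I₀ − I_min).  The bleach frame
maps to exactly 0% and pre-bleach frames to 100% on average.

Fitting uses a single-exponential recovery R(t) = 100·M·(1 − e^{−k(t−t_b)})
on the post-bleach samples (trust-region least squares, M bounded to
[0, 1.05] to absorb noise overshoot, initial values from the empirical
plateau and half-rise time).  Mobile fraction M is the plateau/100, t_half
= ln2/k.  A fitted M below 0.02 flags the rate as unidentifiable (an
immobile trace carries no information about k); non-convergence is flagged
on the result, never raised.  Double-exponential and reaction–diffusion
models are out of scope.

Default simulated trace: I₀ = 100, bleach depth 0.8, M = 0.6, k = 0.1 s⁻¹,
5 pre- and 60 post-bleach frames at 1 s, constant background 5.  At 2%
intensity noise the fit recovers M with median absolute error < 0.01 and k
with median relative error ≈ 5% (100-trace study in the acceptance script).

## Pooled-screen scoring

Normalization is counts-per-hundred-thousand: 100,000 × count / column
total (each normalized column sums to 100,000 exactly).  Per-sgRNA log₂
fold change is log₂((T_late + c)/(T₀ + c)) on the normalized scale with
pseudocount c = 1 to guard zeros; replicate columns within a timepoint are
averaged before the fold change.  Gene scores are the median across the
gene's guides (robust to a single outlier guide), with the mean and guide
count also reported.  A gene is a depleted hit in a line when its median
log₂FC ≤ the cutoff (default −1, recorded in output metadata); hits in all
lines are *shared*, hits in exactly one are *line-specific*.  No
MAGeCK-style statistical testing is performed.

The simulator draws counts from a negative binomial parameterized by mean μ
and dispersion α with variance μ + αμ² (Poisson at α = 0).  T₀ abundances
are uniform; T_late expected abundances multiply the line's essential genes
by 2^effect and are then renormalized to the library size, so totals match
sequencing depth — this introduces the small compositional shift toward
neutral genes that real screens also show.  Defaults: 500 genes × 4 guides,
10 essentials per line (two lines, disjoint sets), effect −3, dispersion
0.1, 10⁶ reads per sample.  Under these conditions every essential gene
lands in the bottom decile of gene scores in ≥95% of seeded screens.

## Problem sizes

Validation studies use 9×64×64 scenes (200 for classification and radius
recovery, 50 for oracle equivalence), 256²–512² droplet fields (100 seeds),
100 FRAP traces, and 20 simulated screens of 2,000 guides — sizes at which
every study reproduces its headline number while the whole suite runs in
seconds.
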