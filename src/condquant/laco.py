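"""LacO-array tethering assay: the Ipeak/Iperiphery enrichment statistic.

The assay tethers a GFP-fused bait at a genomic LacO repeat array, producing
one bright punctum per nucleus, and asks whether an mCherry-fused prey is
recruited there.  The statistic is computed in six steps: (1) select the
z slice with the brightest GFP signal; (2) locate the punctum centre;
(3) build the radial intensity profile of the GFP channel around that centre;
(4) estimate the punctum radius r as the distance at which the outward
derivative of the profile first stops decreasing; (5) smooth the mCherry
slice with a 5x5 all-ones kernel (J5) and average the four pixels adjacent to
the smoothed peak inside the punctum disk (Ipeak); (6) average the two
smoothed-mCherry radial-profile values just outside the radius (Iperiphery).
A ratio Ipeak/Iperiphery > 1 calls the pair interacting.

Coordinates are 0-based (y, x); annuli are integer: pixel p belongs to
annulus k when round(|p - centre|) == k.  All tie-breaks are row-major /
lowest-index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import LacoScene

__all__ = [
    "RadialProfile",
    "PunctumMeasurement",
    "NoPunctumError",
    "select_brightest_slice",
    "locate_center",
    "radial_profile",
    "punctum_radius",
    "smooth_J5",
    "peak_intensity",
    "periphery_intensity",
    "measure_enrichment",
]


class NoPunctumError(ValueError):
    """Raised when an image carries no punctum signal to analyse."""


@dataclass
class RadialProfile:
    """Integer-annulus radial intensity profile around a centre pixel.

    ``mean_intensity[k]`` is the mean over in-bounds pixels at rounded
    Euclidean distance k from the centre; ``pixel_count[k]`` the number of
    such pixels.  ``truncated`` flags annuli clipped by the image border.
    """

    radii: np.ndarray
    mean_intensity: np.ndarray
    pixel_count: np.ndarray
    truncated: bool


@dataclass
class PunctumMeasurement:
    """One scene's enrichment measurement."""

    slice_index: int
    center: tuple[int, int]  # (y, x)
    radius_px: int
    i_peak: float
    i_periphery: float
    ratio: float
    interacting: bool
    flags: tuple[str, ...] = ()


def _roi_slices(shape: tuple[int, int],
                roi: tuple[int, int, int, int] | None) -> tuple[slice, slice]:
    """ROI given as half-open (y0, x0, y1, x1); default whole image."""
    ny, nx = shape
    if roi is None:
        return slice(0, ny), slice(0, nx)
    y0, x0, y1, x1 = roi
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"roi {roi} outside image bounds {shape}")
    return slice(y0, y1), slice(x0, x1)


def select_brightest_slice(scene: LacoScene,
                           roi: tuple[int, int, int, int] | None = None) -> int:
    """z index whose maximum GFP intensity inside the ROI is largest.

    Ties break to the lowest index; an all-zero stack raises
    :class:`NoPunctumError`.
    """
    ys, xs = _roi_slices(scene.gfp.shape[1:], roi)
    per_slice_max = scene.gfp[:, ys, xs].reshape(scene.gfp.shape[0], -1).max(axis=1)
    if per_slice_max.max() == 0:
        raise NoPunctumError("no punctum signal: GFP stack is all zero in the ROI")
    return int(np.argmax(per_slice_max))


def locate_center(gfp_slice: np.ndarray,
                  roi: tuple[int, int, int, int] | None = None
                  ) -> tuple[int, int]:
    """Centre pixel: argmax of the J5-smoothed GFP slice within the ROI.

    Smoothing before the argmax suppresses single-pixel noise, the same
    rationale as the J5 convolution of the mCherry channel.  A flat ROI
    (zero dynamic range) raises :class:`NoPunctumError`.
    """
    ys, xs = _roi_slices(gfp_slice.shape, roi)
    smoothed = smooth_J5(gfp_slice)[ys, xs]
    if smoothed.max() == smoothed.min():
        raise NoPunctumError("no punctum signal: ROI has zero dynamic range")
    flat = int(np.argmax(smoothed))  # row-major tie-break
    dy, dx = np.unravel_index(flat, smoothed.shape)
    return int(dy + ys.start), int(dx + xs.start)


def radial_profile(image: np.ndarray, center: tuple[int, int],
                   r_max: int) -> RadialProfile:
    """Mean intensity per integer annulus round(d) == k, k = 0..r_max."""
    ny, nx = image.shape
    cy, cx = center
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError(f"center {center} outside image {image.shape}")
    if r_max < 2:
        raise ValueError("r_max must be >= 2")
    yy, xx = np.mgrid[0:ny, 0:nx]
    k = np.rint(np.hypot(yy - cy, xx - cx)).astype(np.intp)
    inside = k <= r_max
    counts = np.bincount(k[inside], minlength=r_max + 1)
    sums = np.bincount(k[inside], weights=image[inside].astype(float),
                       minlength=r_max + 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    border = min(cy, cx, ny - 1 - cy, nx - 1 - cx)
    return RadialProfile(
        radii=np.arange(r_max + 1),
        mean_intensity=means,
        pixel_count=counts,
        truncated=r_max > border,
    )


def punctum_radius(profile: RadialProfile) -> tuple[int, bool]:
    """Radius from the GFP radial profile's outward derivative.

    Scanning outward from the centre, the profile decreases inside the
    punctum; the radius is the smallest k >= 1 at which the forward
    difference ``mean[k+1] - mean[k]`` is first non-negative (the decrease
    has stopped).  Returns ``(r, truncated)``; if the profile never stops
    decreasing, r = r_max with the truncation flag set.
    """
    m = profile.mean_intensity
    if len(m) < 3:
        raise ValueError("profile must have at least 3 annuli")
    diffs = np.diff(m)
    for k in range(1, len(diffs)):
        if diffs[k] >= 0:
            return k, False
    return int(profile.radii[-1]), True


def smooth_J5(image: np.ndarray, normalize: bool = True) -> np.ndarray:
    """5x5 all-ones (J5) convolution; reflect padding at borders.

    ``normalize=True`` divides by 25 (mean filter) for interpretable
    intensities; the enrichment ratio is invariant to this constant.
    """
    if image.shape[0] < 5 or image.shape[1] < 5:
        raise ValueError("image must be at least 5x5")
    # direct correlation (not a sliding-sum mean filter): sums of 25 pixel
    # values are exact in float64 for integer-valued images, so exact ties
    # in the smoothed image stay exact ties
    out = ndimage.correlate(image.astype(float), np.ones((5, 5)),
                            mode="reflect")
    return out / 25.0 if normalize else out


def peak_intensity(smoothed_mch: np.ndarray, center: tuple[int, int],
                   r: int) -> float:
    """Ipeak: mean of the four edge-adjacent neighbours of the smoothed peak.

    The peak is the maximum of the smoothed mCherry slice within the punctum
    disk (round(d) <= r around the centre).  A peak on the image border
    raises ``ValueError``.
    """
    if r < 1:
        raise ValueError("punctum radius must be >= 1")
    ny, nx = smoothed_mch.shape
    cy, cx = center
    yy, xx = np.mgrid[0:ny, 0:nx]
    disk = np.rint(np.hypot(yy - cy, xx - cx)) <= r
    masked = np.where(disk, smoothed_mch, -np.inf)
    py, px = np.unravel_index(int(np.argmax(masked)), masked.shape)
    if py in (0, ny - 1) or px in (0, nx - 1):
        raise ValueError("punctum too close to border: peak neighbour "
                         "out of bounds")
    neighbours = (
        smoothed_mch[py - 1, px], smoothed_mch[py + 1, px],
        smoothed_mch[py, px - 1], smoothed_mch[py, px + 1],
    )
    return float(np.mean(neighbours))


def periphery_intensity(mch_profile: RadialProfile, r: int) -> float:
    """Iperiphery: mean of the profile values at annuli r+1 and r+2."""
    m = mch_profile.mean_intensity
    if len(m) < r + 3:
        raise ValueError(
            f"profile reaches only annulus {len(m) - 1}; recompute with "
            f"r_max >= {r + 2}"
        )
    return float((m[r + 1] + m[r + 2]) / 2.0)


def measure_enrichment(scene: LacoScene, r_max: int = 20,
                       roi: tuple[int, int, int, int] | None = None
                       ) -> PunctumMeasurement:
    """Full enrichment pipeline on one scene.

    Composes slice selection, centring, GFP radial profiling, radius
    estimation, J5 smoothing of mCherry, and the Ipeak/Iperiphery ratio;
    ``interacting`` is the strict ratio > 1 call.
    """
    flags: list[str] = []
    try:
        n = select_brightest_slice(scene, roi)
    except NoPunctumError as exc:
        raise NoPunctumError(f"slice selection: {exc}") from exc
    try:
        center = locate_center(scene.gfp[n], roi)
    except NoPunctumError as exc:
        raise NoPunctumError(f"centre location: {exc}") from exc

    gfp_prof = radial_profile(scene.gfp[n], center, r_max)
    if gfp_prof.truncated:
        flags.append("profile_truncated")
    r, r_truncated = punctum_radius(gfp_prof)
    if r_truncated:
        flags.append("radius_truncated")

    smoothed = smooth_J5(scene.mch[n])
    i_peak = peak_intensity(smoothed, center, r)
    mch_prof = radial_profile(smoothed, center, max(r_max, r + 2))
    i_periphery = periphery_intensity(mch_prof, r)
    if i_periphery <= 0:
        raise ValueError("periphery intensity is zero: ratio undefined")
    ratio = i_peak / i_periphery
    return PunctumMeasurement(
        slice_index=n, center=center, radius_px=r,
        i_peak=i_peak, i_periphery=i_periphery,
        ratio=ratio, interacting=bool(ratio > 1.0),
        flags=tuple(flags),
    )
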