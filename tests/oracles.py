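"""Independent brute-force oracles: plain per-pixel loops, no vectorization.

These re-derive every quantity the package computes from first principles so
that tests can compare two fully independent routes.  They are deliberately
slow and simple.
"""

from __future__ import annotations

import math

import numpy as np


def _reflect(i: int, n: int) -> int:
    """scipy 'reflect' boundary: (d c b a | a b c d | d c b a)."""
    if i < 0:
        return -1 - i
    if i >= n:
        return 2 * n - 1 - i
    return i


def brute_smooth_j5(image: np.ndarray, normalize: bool = True) -> np.ndarray:
    ny, nx = image.shape
    out = np.zeros((ny, nx), dtype=float)
    for y in range(ny):
        for x in range(nx):
            total = 0.0
            for dy in range(-2, 3):
                for dx in range(-2, 3):
                    total += image[_reflect(y + dy, ny), _reflect(x + dx, nx)]
            out[y, x] = total / 25.0 if normalize else total
    return out


def brute_radial_profile(image: np.ndarray, center: tuple[int, int],
                         r_max: int) -> tuple[list[float], list[int]]:
    cy, cx = center
    sums = [0.0] * (r_max + 1)
    counts = [0] * (r_max + 1)
    for y in range(image.shape[0]):
        for x in range(image.shape[1]):
            k = round(math.hypot(y - cy, x - cx))
            if k <= r_max:
                sums[k] += float(image[y, x])
                counts[k] += 1
    means = [s / c if c else float("nan") for s, c in zip(sums, counts)]
    return means, counts


def brute_radius(means: list[float]) -> tuple[int, bool]:
    for k in range(1, len(means) - 1):
        if means[k + 1] - means[k] >= 0:
            return k, False
    return len(means) - 1, True


def brute_select_slice(gfp: np.ndarray) -> int:
    best, best_val = 0, -math.inf
    for z in range(gfp.shape[0]):
        m = max(float(v) for row in gfp[z] for v in row)
        if m > best_val:
            best, best_val = z, m
    return best


def brute_locate_center(gfp_slice: np.ndarray) -> tuple[int, int]:
    sm = brute_smooth_j5(gfp_slice)
    best, best_val = (0, 0), -math.inf
    for y in range(sm.shape[0]):
        for x in range(sm.shape[1]):
            if sm[y, x] > best_val:
                best, best_val = (y, x), sm[y, x]
    return best


def brute_measure(gfp: np.ndarray, mch: np.ndarray, r_max: int) -> dict:
    """Full enrichment pipeline as nested loops; mirrors the stated procedure."""
    n = brute_select_slice(gfp)
    center = brute_locate_center(gfp[n])
    gfp_means, _ = brute_radial_profile(gfp[n], center, r_max)
    r, _ = brute_radius(gfp_means)
    sm = brute_smooth_j5(mch[n])
    cy, cx = center
    peak, peak_val = None, -math.inf
    for y in range(sm.shape[0]):
        for x in range(sm.shape[1]):
            if round(math.hypot(y - cy, x - cx)) <= r and sm[y, x] > peak_val:
                peak, peak_val = (y, x), sm[y, x]
    py, px = peak
    i_peak = (sm[py - 1, px] + sm[py + 1, px] + sm[py, px - 1] + sm[py, px + 1]) / 4.0
    mch_means, _ = brute_radial_profile(sm, center, max(r_max, r + 2))
    i_periphery = (mch_means[r + 1] + mch_means[r + 2]) / 2.0
    return {
        "slice_index": n, "center": center, "radius_px": r,
        "i_peak": i_peak, "i_periphery": i_periphery,
        "ratio": i_peak / i_periphery,
    }


def brute_log2fc(normalized: np.ndarray, t0_col: int, late_col: int,
                 pseudocount: float) -> list[float]:
    out = []
    for i in range(normalized.shape[0]):
        out.append(float(np.log2((normalized[i, late_col] + pseudocount)
                                 / (normalized[i, t0_col] + pseudocount))))
    return out


def brute_gene_median(values: list[float], genes: list[str]) -> dict[str, float]:
    by_gene: dict[str, list[float]] = {}
    for v, g in zip(values, genes):
        by_gene.setdefault(g, []).append(v)
    out = {}
    for g, vs in by_gene.items():
        vs = sorted(vs)
        m = len(vs) // 2
        out[g] = vs[m] if len(vs) % 2 else (vs[m - 1] + vs[m]) / 2.0
    return out
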