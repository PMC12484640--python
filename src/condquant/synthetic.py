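"""Seeded synthetic-data generators with known ground truth.

Every generator emulates one of the raw inputs the quantification stages
consume: two-channel nuclei bearing a single bright tethering punctum
(LacO-array scenes), fields of liquid droplets in one or two channels,
single-exponential FRAP recovery traces, and negative-binomial sgRNA count
matrices with a depleted-gene subset.  All randomness flows from the integer
``seed`` carried by each spec; identical spec + seed yields bit-identical
output.  Intensities are kept as floating point and clipped at zero after
noise; quantization happens only on TIFF export (see :mod:`condquant.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PunctumSpec",
    "DropletFieldSpec",
    "FrapSpec",
    "ScreenSpec",
    "LacoScene",
    "FrapTrace",
    "make_laco_scene",
    "make_droplet_field",
    "make_frap_trace",
    "make_screen_counts",
]


# ---------------------------------------------------------------------------
# LacO tethering scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctumSpec:
    """Parameters of a single-punctum two-channel z-stack.

    The punctum is an isotropic Gaussian spot of width ``sigma_px`` (pixels)
    centred at ``center_xy`` on slice ``z_index``; its amplitude is attenuated
    on neighbouring slices by a Gaussian z-falloff with sigma_z = sigma_px
    (in slice units), which makes brightest-slice selection non-trivial but
    unambiguous.  Amplitudes and backgrounds are in arbitrary intensity units.
    """

    center_xy: tuple[float, float] = (32.0, 32.0)  # (y, x), 0-based pixels
    z_index: int = 4
    sigma_px: float = 3.0
    amplitude_gfp: float = 100.0
    amplitude_mch: float = 50.0
    background_gfp: float = 10.0
    background_mch: float = 10.0
    noise_sd: float = 0.0
    image_shape: tuple[int, int, int] = (9, 64, 64)  # (n_z, n_y, n_x)
    seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.image_shape
        if min(nz, ny, nx) < 1:
            raise ValueError("image_shape entries must all be >= 1")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be > 0")
        if self.amplitude_gfp < 0 or self.amplitude_mch < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.z_index < nz:
            raise ValueError(f"z_index {self.z_index} outside stack of {nz} slices")
        cy, cx = self.center_xy
        margin = 5.0 * self.sigma_px
        if not (margin <= cy <= ny - 1 - margin and margin <= cx <= nx - 1 - margin):
            raise ValueError(
                f"punctum at {self.center_xy} violates the {margin:.1f}-px "
                f"(5*sigma) margin inside a {ny}x{nx} image"
            )


@dataclass
class LacoScene:
    """Two-channel z-stack plus the ground truth it was rendered from."""

    gfp: np.ndarray  # (z, y, x)
    mch: np.ndarray
    truth: PunctumSpec


def _render_punctum_stack(
    spec: PunctumSpec, amplitude: float, background: float
) -> np.ndarray:
    nz, ny, nx = spec.image_shape
    cy, cx = spec.center_xy
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    lateral = np.exp(-d2 / (2.0 * spec.sigma_px**2))
    z = np.arange(nz, dtype=float)
    # z-attenuation: Gaussian with sigma_z = sigma_px (slice units)
    axial = np.exp(-((z - spec.z_index) ** 2) / (2.0 * spec.sigma_px**2))
    stack = background + amplitude * axial[:, None, None] * lateral[None, :, :]
    return stack


def make_laco_scene(spec: PunctumSpec) -> LacoScene:
    """Render a two-channel tethering scene.

    Each channel is ``background + amplitude * exp(-d^2 / (2 sigma^2))`` on the
    punctum slice, attenuated in z, plus seeded Gaussian noise clipped at 0.
    """
    spec.validate()
    gfp = _render_punctum_stack(spec, spec.amplitude_gfp, spec.background_gfp)
    mch = _render_punctum_stack(spec, spec.amplitude_mch, spec.background_mch)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gfp = gfp + rng.normal(0.0, spec.noise_sd, gfp.shape)
        mch = mch + rng.normal(0.0, spec.noise_sd, mch.shape)
        np.clip(gfp, 0.0, None, out=gfp)
        np.clip(mch, 0.0, None, out=mch)
    return LacoScene(gfp=gfp, mch=mch, truth=spec)


# ---------------------------------------------------------------------------
# Droplet fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DropletFieldSpec:
    """Parameters of a two-channel field of disk-shaped droplets.

    ``overlap_fraction`` of the channel-A droplets also carry channel-B signal
    (co-condensation ground truth).  ``min_separation_px >= 2 * max radius``
    guarantees disjoint droplets.
    """

    n_droplets: int = 20
    radius_range_px: tuple[float, float] = (4.0, 6.0)
    intensity_a: float = 100.0
    intensity_b: float = 100.0
    background: tuple[float, float] = (5.0, 5.0)
    overlap_fraction: float = 1.0
    min_separation_px: float = 30.0
    noise_sd: float = 0.0
    image_shape: tuple[int, int] = (256, 256)
    seed: int = 0
    max_attempts_per_droplet: int = 1000

    def validate(self) -> None:
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")
        lo, hi = self.radius_range_px
        if not 0 < lo <= hi:
            raise ValueError("radius_range_px must satisfy 0 < min <= max")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.image_shape) < 1:
            raise ValueError("image_shape entries must be >= 1")


@dataclass
class DropletField:
    """Two-channel droplet image plus the ground-truth droplet table."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    truth: pd.DataFrame  # columns: droplet_id, y, x, radius_px, in_b


def make_droplet_field(spec: DropletFieldSpec) -> DropletField:
    """Paint ``n_droplets`` disjoint disks at rejection-sampled centres.

    Raises ``RuntimeError`` if the packing density makes placement impossible
    within the attempt cap.
    """
    spec.validate()
    ny, nx = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.radius_range_px

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for i in range(spec.n_droplets):
        r = rng.uniform(lo, hi)
        placed = False
        for _ in range(spec.max_attempts_per_droplet):
            cy = rng.uniform(r + 1, ny - 2 - r)
            cx = rng.uniform(r + 1, nx - 2 - r)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= spec.min_separation_px**2
                for oy, ox in centers
            ):
                centers.append((cy, cx))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place droplet {i + 1}/{spec.n_droplets} with "
                f"separation {spec.min_separation_px} px in a {ny}x{nx} image: "
                "density limit exceeded"
            )

    n_in_b = int(round(spec.overlap_fraction * spec.n_droplets))
    in_b = np.zeros(spec.n_droplets, dtype=bool)
    if n_in_b > 0:
        in_b[rng.permutation(spec.n_droplets)[:n_in_b]] = True

    yy, xx = np.mgrid[0:ny, 0:nx]
    chan_a = np.full((ny, nx), float(spec.background[0]))
    chan_b = np.full((ny, nx), float(spec.background[1]))
    for (cy, cx), r, b in zip(centers, radii, in_b):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        chan_a[disk] += spec.intensity_a
        if b:
            chan_b[disk] += spec.intensity_b

    if spec.noise_sd > 0:
        chan_a = np.clip(chan_a + rng.normal(0, spec.noise_sd, chan_a.shape), 0, None)
        chan_b = np.clip(chan_b + rng.normal(0, spec.noise_sd, chan_b.shape), 0, None)

    truth = pd.DataFrame(
        {
            "droplet_id": np.arange(1, spec.n_droplets + 1),
            "y": [c[0] for c in centers],
            "x": [c[1] for c in centers],
            "radius_px": radii,
            "in_b": in_b,
        }
    )
    return DropletField(channel_a=chan_a, channel_b=chan_b, truth=truth)


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapSpec:
    """Parameters of a single-exponential FRAP recovery trace.

    Post-bleach intensity follows ``Ib + (I0 - Ib) * M * (1 - exp(-k t))``
    with ``Ib = I0 * (1 - bleach_depth)`` and t measured from the bleach
    frame.  The stored intensity column includes the constant background so
    that background subtraction during normalization is exercised.
    """

    I0: float = 100.0
    bleach_depth: float = 0.8
    mobile_fraction: float = 0.6
    rate_k: float = 0.1  # 1/s
    background_level: float = 5.0
    n_pre: int = 5
    n_post: int = 60
    dt: float = 1.0  # s
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be > 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.n_pre < 1 or self.n_post < 1:
            raise ValueError("need at least one pre- and one post-bleach frame")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class FrapTrace:
    """Time-indexed FRAP intensities.

    ``bleach_index`` is the first post-bleach frame (the "0 s after bleaching"
    sample); frames before it are pre-bleach.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    background: np.ndarray
    bleach_index: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "intensity": self.intensity,
             "background": self.background}
        )


def frap_model(t: np.ndarray, I0: float, bleach_depth: float,
               mobile_fraction: float, rate_k: float) -> np.ndarray:
    """Noise-free post-bleach recovery, t measured from the bleach frame."""
    Ib = I0 * (1.0 - bleach_depth)
    return Ib + (I0 - Ib) * mobile_fraction * (1.0 - np.exp(-rate_k * t))


def make_frap_trace(spec: FrapSpec) -> FrapTrace:
    spec.validate()
    n = spec.n_pre + spec.n_post
    time_s = np.arange(n, dtype=float) * spec.dt
    intensity = np.empty(n, dtype=float)
    intensity[: spec.n_pre] = spec.I0
    t_post = (np.arange(spec.n_post, dtype=float)) * spec.dt
    intensity[spec.n_pre:] = frap_model(
        t_post, spec.I0, spec.bleach_depth, spec.mobile_fraction, spec.rate_k
    )
    intensity = intensity + spec.background_level
    background = np.full(n, float(spec.background_level))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = np.clip(
            intensity + rng.normal(0, spec.noise_sd, n), 0, None
        )
    return FrapTrace(
        time_s=time_s, intensity=intensity, background=background,
        bleach_index=spec.n_pre,
    )


# ---------------------------------------------------------------------------
# Pooled-screen counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """Parameters of a two-timepoint pooled-screen count matrix.

    ``cell_lines`` maps each line label to its essential (depleted) gene set;
    when ``None``, two lines carrying disjoint essential sets of
    ``n_essential`` genes each are generated.  Counts are negative binomial
    with variance ``mu + dispersion * mu**2``.
    """

    n_genes: int = 500
    sgrnas_per_gene: int = 4
    n_essential: int = 10
    depletion_log2fc: float = -3.0
    library_size_per_sample: float = 1_000_000.0
    dispersion: float = 0.1
    cell_lines: Mapping[str, tuple[str, ...]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.sgrnas_per_gene < 1:
            raise ValueError("n_genes and sgrnas_per_gene must be >= 1")
        if self.n_essential > self.n_genes:
            raise ValueError("n_essential must be <= n_genes")
        if self.library_size_per_sample <= 0:
            raise ValueError("library_size_per_sample must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"GENE{i + 1:0{width}d}" for i in range(self.n_genes)]

    def resolved_cell_lines(self) -> dict[str, tuple[str, ...]]:
        if self.cell_lines is not None:
            return {k: tuple(v) for k, v in self.cell_lines.items()}
        genes = self.gene_names()
        if 2 * self.n_essential > self.n_genes:
            raise ValueError("disjoint default essential sets need "
                             "2 * n_essential <= n_genes")
        return {
            "lineA": tuple(genes[: self.n_essential]),
            "lineB": tuple(genes[self.n_essential: 2 * self.n_essential]),
        }


@dataclass
class ScreenTruth:
    """Ground truth behind a simulated screen."""

    essential_sets: dict[str, tuple[str, ...]]
    depletion_log2fc: float


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def make_screen_counts(spec: ScreenSpec) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate sgRNA counts for every cell line at T0 and T_late.

    Returns a long-form count table with columns ``sgrna``, ``gene`` and one
    count column per sample named ``{line}_T0`` / ``{line}_Tlate``, plus the
    ground truth.  T_late expected abundances apply ``2**depletion_log2fc``
    to that line's essential genes and are renormalized so column totals stay
    near ``library_size_per_sample``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    gene_col = np.repeat(genes, spec.sgrnas_per_gene)
    sgrna_col = [
        f"{g}_sg{j + 1}" for g in genes for j in range(spec.sgrnas_per_gene)
    ]
    n_rows = len(sgrna_col)
    lines = spec.resolved_cell_lines()

    base_mu = np.full(n_rows, spec.library_size_per_sample / n_rows)
    table = pd.DataFrame({"sgrna": sgrna_col, "gene": gene_col})
    for line, essentials in lines.items():
        essential_mask = np.isin(gene_col, list(essentials))
        table[f"{line}_T0"] = _nb_draw(rng, base_mu, spec.dispersion)
        late_mu = base_mu.copy()
        late_mu[essential_mask] *= 2.0**spec.depletion_log2fc
        late_mu *= spec.library_size_per_sample / late_mu.sum()
        table[f"{line}_Tlate"] = _nb_draw(rng, late_mu, spec.dispersion)

    truth = ScreenTruth(essential_sets=lines,
                        depletion_log2fc=spec.depletion_log2fc)
    return table, truth
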