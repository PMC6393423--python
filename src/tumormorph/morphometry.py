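"""Necrosis quantification and box-counting fractal dimension.

Percent intratumoral necrosis is the foreground-area ratio of a necrosis mask
to its tumor mask, in percent. The fractal dimension d_f of a binary pattern
is estimated by box counting: cover the pattern's bounding box with an
axis-aligned grid of eps x eps cells, count occupied cells N(eps) per scale,
and fit ln N(eps) against ln eps by ordinary least squares; d_f is the negated
slope. d_f is 2 for a filled planar region and 1 for a simple curve; dispersed,
boundary-hugging necrotic patterns score lower than compact interior blobs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .image import SectionImage
from .mask import BinaryMask

__all__ = [
    "FractalFit",
    "NecrosisResult",
    "SegmentationParams",
    "box_count",
    "fractal_dimension",
    "percent_necrosis",
    "segment_necrosis",
]


# ---------------------------------------------------------------------------
# Percent necrosis
# ---------------------------------------------------------------------------

def percent_necrosis(necrosis: BinaryMask, tumor: BinaryMask) -> float:
    """Percent of tumor area that is necrotic: 100 * |necrosis| / |tumor|.

    The ratio is formed in exact integer arithmetic and converted to float
    once, so the result carries no platform-dependent rounding. A necrotic
    pixel outside the tumor mask raises (it signals misaligned masks).
    """
    if necrosis.shape != tumor.shape:
        raise ValueError("necrosis and tumor masks have different shapes")
    if tumor.is_empty():
        raise ValueError("tumor mask is empty")
    if np.any(necrosis.grid & ~tumor.grid):
        raise ValueError("necrosis mask has pixels outside the tumor mask")
    return float(Fraction(100 * necrosis.foreground_count, tumor.foreground_count))


# ---------------------------------------------------------------------------
# Box counting
# ---------------------------------------------------------------------------

def box_count(mask: BinaryMask, scales) -> np.ndarray:
    """Occupied-box counts N(eps) for each box edge length in ``scales``.

    The grid is anchored at the top-left corner of the foreground bounding
    box; ragged cells at the right/bottom edges count like full cells.
    """
    if mask.is_empty():
        raise ValueError("box count undefined for an empty mask")
    scales = [int(e) for e in scales]
    min_side = min(mask.shape)
    for e in scales:
        if e < 1 or e > min_side:
            raise ValueError(f"scale {e} outside [1, {min_side}]")
    r0, r1, c0, c1 = mask.bounding_box()
    sub = mask.grid[r0 : r1 + 1, c0 : c1 + 1]
    h, w = sub.shape
    counts = np.empty(len(scales), dtype=np.int64)
    for i, e in enumerate(scales):
        nh, nw = -(-h // e), -(-w // e)
        padded = np.zeros((nh * e, nw * e), dtype=bool)
        padded[:h, :w] = sub
        occ = padded.reshape(nh, e, nw, e).any(axis=(1, 3))
        counts[i] = int(occ.sum())
    return counts


@dataclass(frozen=True)
class FractalFit:
    """Box counts per scale and the fitted dimension.

    ``d_f`` is the negated OLS slope of ln N(eps) on ln eps; ``stderr`` the
    standard error of that slope (0 for a perfect fit); ``r_squared`` the
    coefficient of determination.
    """

    scales: tuple[int, ...]
    counts: tuple[int, ...]
    d_f: float
    stderr: float
    r_squared: float


def _default_scales(min_side: int, base: int) -> list[int]:
    scales, e = [], base
    while e <= min_side // 4:
        scales.append(e)
        e *= base
    return scales


def fractal_dimension(
    mask: BinaryMask,
    scales=None,
    *,
    scale_base: int = 2,
) -> FractalFit:
    """Box-counting dimension of a binary mask.

    Default scales are powers of ``scale_base`` from ``scale_base`` up to
    ``min_side // 4`` — the upper bound keeps the fit out of the saturated
    few-box regime. For hierarchical masks built with subdivision factor b
    (e.g. Mandelbrot percolation), pass ``scale_base=b`` so the grid aligns
    with the construction levels. Requires >= 2 foreground pixels and >= 4
    scales.
    """
    if mask.foreground_count < 2:
        raise ValueError("fractal dimension needs >= 2 foreground pixels")
    if scales is None:
        if scale_base < 2:
            raise ValueError("scale_base must be >= 2")
        scales = _default_scales(min(mask.shape), scale_base)
    scales = sorted(int(e) for e in scales)
    if len(scales) < 4:
        raise ValueError(f"need >= 4 scales, have {len(scales)}")
    counts = box_count(mask, scales)
    res = stats.linregress(np.log(scales), np.log(counts))
    d_f = -float(res.slope)
    if not (-0.05 <= d_f <= 2.05):
        raise ValueError(f"fitted dimension {d_f:.3f} outside [0, 2] for a 2-D mask")
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return FractalFit(
        scales=tuple(scales),
        counts=tuple(int(c) for c in counts),
        d_f=d_f,
        stderr=stderr,
        r_squared=float(res.rvalue) ** 2,
    )


# ---------------------------------------------------------------------------
# Necrosis segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the necrosis segmenter.

    sigma_px : Gaussian smoothing scale for the nuclear-density and luminance
        maps. 8 px spans a few cell diameters: wide enough to pool nuclei
        into a density, narrow enough to keep necrosis borders.
    nuclear_blue_margin : a pixel counts as nuclear stain when its blue
        channel exceeds red by this margin (hematoxylin is blue-violet,
        eosin and necrotic debris are red-dominant).
    opening_radius_px / min_object_px : morphological cleanup of the raw
        necrotic class.
    """

    sigma_px: float = 8.0
    nuclear_blue_margin: int = 10
    opening_radius_px: int = 3
    min_object_px: int = 64


@dataclass
class NecrosisResult:
    necrosis_mask: BinaryMask
    tumor_mask: BinaryMask
    percent_necrosis: float
    degenerate: bool = False  # True when the image was single-color


def segment_necrosis(
    image: SectionImage, params: SegmentationParams = SegmentationParams()
) -> NecrosisResult:
    """Classify each tumor pixel as necrotic or viable.

    Viable tissue is recognized by nuclear density, necrosis by pallor:

    1. nuclear-density map — Gaussian-smoothed indicator of nuclear-stain
       (blue-dominant) pixels, smoothed by normalized convolution confined to
       the tumor mask so the bright background outside the section cannot
       bleed a false pallor ring into the tumor rim;
    2. pallor map — luminance, smoothed the same way;
    3. necrotic iff density below its Otsu threshold AND luminance above its
       Otsu threshold (both thresholds computed over tumor pixels and guarded
       against the unimodal, necrosis-free case);
    4. morphological opening + closing (disk) and removal of small components.
    """
    tumor = image.tumor_mask
    if tumor.is_empty():
        raise ValueError("empty tumor mask")
    if tumor.foreground_count < 1024:
        raise ValueError("tumor mask too small (< 1024 px) for segmentation")

    rgb = image.rgb.astype(np.float64)
    lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    if float(lum[tumor.grid].std()) < 1.0:
        warnings.warn("degenerate single-color section; reporting 0% necrosis")
        empty = BinaryMask(np.zeros(tumor.shape, bool), tumor.pixel_size_um)
        return NecrosisResult(empty, tumor, 0.0, degenerate=True)

    nuclear = (rgb[..., 2] - rgb[..., 0]) > params.nuclear_blue_margin

    # normalized convolution: smooth within the tumor, treating outside as
    # missing data rather than as (white) pixels
    tgrid = tumor.grid.astype(np.float64)
    w = ndimage.gaussian_filter(tgrid, params.sigma_px)
    w = np.where(w > 1e-12, w, 1.0)
    dens = ndimage.gaussian_filter(nuclear * tgrid, params.sigma_px) / w
    lum_s = ndimage.gaussian_filter(lum * tgrid, params.sigma_px) / w

    dens_t = dens[tumor.grid]
    lum_t = lum_s[tumor.grid]
    # Otsu splits any histogram; the caps keep a necrosis-free (unimodal)
    # section from being half-classified as necrotic.
    t_dens = min(float(threshold_otsu(dens_t)), 0.4 * float(np.median(dens_t)))
    t_lum = max(float(threshold_otsu(lum_t)), float(np.median(lum_t)) + 10.0)

    nec = tumor.grid & (dens < t_dens) & (lum_s > t_lum)
    selem = disk(params.opening_radius_px).astype(bool)
    nec = ndimage.binary_closing(ndimage.binary_opening(nec, structure=selem), structure=selem)
    nec &= tumor.grid
    lab, n_comp = ndimage.label(nec)
    if n_comp:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n_comp + 1))
        small = np.flatnonzero(sizes < params.min_object_px) + 1
        if small.size:
            nec &= ~np.isin(lab, small)

    nec_mask = BinaryMask(nec, tumor.pixel_size_um)
    return NecrosisResult(nec_mask, tumor, percent_necrosis(nec_mask, tumor))


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.foreground_count + b.foreground_count
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(a.grid & b.grid)) / denom
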