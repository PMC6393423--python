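"""Synthetic H&E-like tumor cross-sections with known necrotic fraction.

A section is a disk-shaped tumor on a bright background. Viable tissue is
rendered as an eosinophilic (pink) matrix densely seeded with dark
hematoxylin-stained nuclei; necrotic tissue is pale and nucleus-free — the
two cues (nuclear density, pallor) an H&E reader and the segmentation stage
both rely on. The necrosis ground truth is laid out in one of two spatial
patterns: a single compact blob grown from the tumor centroid (the pattern of
centrally infarcted tumors) or several blobs scattered near the tumor edge
(the dispersed peripheral pattern of drug-penetrated tumors). The realized
necrotic fraction is hit by a rank cut, so it is exact to one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..mask import BinaryMask

# Fixed, well-separated stain palette (RGB); any separated palette would do.
COLOR_BACKGROUND = (250, 250, 250)
COLOR_EOSIN = (240, 180, 190)
COLOR_NUCLEUS = (60, 40, 120)
COLOR_NECROSIS = (235, 220, 215)
COLOR_DAB = (130, 80, 40)

PATTERNS = ("compact_interior", "dispersed_peripheral")


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one synthetic section.

    radius_px : tumor disk radius (>= 32 so the section can be zoned).
    necrotic_fraction : target necrotic area fraction in [0, 1]; realized
        exactly up to one pixel by construction.
    pattern : 'compact_interior' or 'dispersed_peripheral'.
    nucleus_density_per_px2 : nuclei per viable pixel (default 0.02, i.e. a
        nucleus per ~50 px^2 — the near-confluent nuclear packing of a viable
        carcinoma sheet at this rendering scale).
    """

    radius_px: int
    necrotic_fraction: float
    pattern: str
    seed: int
    nucleus_density_per_px2: float = 0.02
    nucleus_radius_px: float = 2.5

    def __post_init__(self) -> None:
        if self.radius_px < 32:
            raise ValueError("radius_px must be >= 32")
        if not (0.0 <= self.necrotic_fraction <= 1.0):
            raise ValueError("necrotic_fraction must be in [0, 1]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _necrosis_truth(spec: SectionSpec, tumor: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank-cut necrosis mask hitting round(f * area) tumor pixels exactly."""
    h, w = tumor.shape
    k = int(round(spec.necrotic_fraction * tumor.sum()))
    nec = np.zeros_like(tumor)
    if k == 0:
        return nec
    c = h / 2.0 - 0.5
    yy, xx = np.mgrid[0:h, 0:w]
    r = spec.radius_px
    if spec.pattern == "compact_interior":
        score = np.hypot(yy - c, xx - c)
        score = score + 0.30 * r * _smooth_noise(rng, tumor.shape, r / 6.0)
    else:
        n_blobs = int(rng.integers(6, 11))
        ang = rng.uniform(0, 2 * np.pi, n_blobs)
        rad = rng.uniform(0.62, 0.90, n_blobs) * r
        cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
        d = np.min(
            np.hypot(yy[None] - cy[:, None, None], xx[None] - cx[:, None, None]), axis=0
        )
        score = d + 0.15 * r * _smooth_noise(rng, tumor.shape, r / 10.0)
    flat = np.where(tumor.ravel(), score.ravel(), np.inf)
    idx = np.argpartition(flat, k - 1)[:k]
    nec.ravel()[idx] = True
    return nec


def _stamp_disks(canvas: np.ndarray, centers: np.ndarray, radius: float, color) -> None:
    rr = int(np.ceil(radius))
    dy, dx = np.mgrid[-rr : rr + 1, -rr : rr + 1]
    inside = dy**2 + dx**2 <= radius**2
    dy, dx = dy[inside], dx[inside]
    h, w = canvas.shape[:2]
    rows = (centers[:, 0][:, None] + dy[None, :]).ravel()
    cols = (centers[:, 1][:, None] + dx[None, :]).ravel()
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    canvas[rows[ok], cols[ok]] = color


def gen_section(spec: SectionSpec):
    """Render one synthetic section.

    Returns a :class:`~tumormorph.image.SectionImage` whose ``truth_necrosis``
    attribute is the exact generating necrosis mask.
    """
    from ..image import SectionImage

    rng = np.random.default_rng(spec.seed)
    margin = 16
    side = 2 * (spec.radius_px + margin)
    c = side / 2.0 - 0.5
    yy, xx = np.mgrid[0:side, 0:side]
    tumor = np.hypot(yy - c, xx - c) <= spec.radius_px

    nec = _necrosis_truth(spec, tumor, rng)
    viable = tumor & ~nec

    img = np.empty((side, side, 3), dtype=np.float64)
    img[:] = COLOR_BACKGROUND
    img[viable] = COLOR_EOSIN
    img[nec] = COLOR_NECROSIS

    # nuclei only in viable tissue, kept clear of the necrosis border so the
    # pallor cue stays clean
    interior = ndimage.binary_erosion(viable, iterations=3)
    pool_r, pool_c = np.nonzero(interior if interior.any() else viable)
    if pool_r.size:
        n_nuclei = rng.poisson(spec.nucleus_density_per_px2 * viable.sum())
        n_nuclei = min(n_nuclei, pool_r.size)
        if n_nuclei:
            pick = rng.choice(pool_r.size, size=n_nuclei, replace=False)
            centers = np.column_stack([pool_r[pick], pool_c[pick]])
            _stamp_disks(img, centers, spec.nucleus_radius_px, COLOR_NUCLEUS)

    img += rng.normal(0.0, 4.0, img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)
    return SectionImage(
        rgb=rgb,
        tumor_mask=BinaryMask(tumor),
        truth_necrosis=BinaryMask(nec),
        meta={"spec": spec},
    )
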