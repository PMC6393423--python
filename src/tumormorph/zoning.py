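"""Concentric zonal partition of a tumor cross-section and Ki67 scoring.

The section is split into outer / intermediate / inner zones holding fixed
fractions of its area (20/30/50 % by default), ordered by Euclidean distance
to the tumor boundary: the pixels closest to the boundary fill the outer zone
first. Defining zones by distance rank rather than radial fraction makes the
partition meaningful for non-circular sections while reducing to concentric
annuli on a disk. Ki67 positivity (brown / DAB nuclear stain vs blue
hematoxylin counterstain) is scored per zone as positive nuclei over total
nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import SectionImage
from .mask import BinaryMask

OUTER, INTERMEDIATE, INNER = 1, 2, 3
ZONE_NAMES = {OUTER: "outer", INTERMEDIATE: "intermediate", INNER: "inner"}

__all__ = [
    "ZonePartition",
    "KiScore",
    "NucleusDetectionParams",
    "partition_zones",
    "detect_nuclei",
    "score_ki67",
    "boundary_distance",
]


def boundary_distance(tumor: BinaryMask) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest background pixel.

    The raster edge counts as background (the section is padded by one
    background ring before the transform), so a mask touching the image
    border still gets a finite boundary distance.
    """
    padded = np.pad(tumor.grid, 1)
    dist = ndimage.distance_transform_edt(padded)
    return dist[1:-1, 1:-1]


@dataclass
class ZonePartition:
    """Zone labels over tumor pixels: 1 outer, 2 intermediate, 3 inner, 0 background."""

    labels: np.ndarray
    target_fractions: tuple[float, float, float]
    realized_fractions: tuple[float, float, float]

    @property
    def tumor_area(self) -> int:
        return int((self.labels > 0).sum())

    def zone_mask(self, zone: int) -> BinaryMask:
        return BinaryMask(self.labels == zone)


def partition_zones(
    tumor: BinaryMask, fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)
) -> ZonePartition:
    """Rank-cut zonal partition by distance to the tumor boundary.

    Tumor pixels are sorted by (distance, row, column) — the lexicographic
    tie-break makes the cut bit-reproducible — and the first
    round(f_outer * A) pixels become the outer zone, the next
    round(f_mid * A) the intermediate zone, the remainder the inner zone.
    Zero fractions are allowed and yield empty zones.
    """
    if tumor.is_empty():
        raise ValueError("empty tumor mask")
    if tumor.foreground_count < 1024:
        raise ValueError("tumor mask too small (< 1024 px) to zone")
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f < 0 for f in fr):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(fr)!r}, expected 1")

    dist = boundary_distance(tumor)
    rows, cols = np.nonzero(tumor.grid)
    order = np.lexsort((cols, rows, dist[rows, cols]))
    a = tumor.foreground_count
    k1 = int(round(fr[0] * a))
    k2 = int(round(fr[1] * a))

    labels = np.zeros(tumor.shape, dtype=np.uint8)
    labels[rows[order[:k1]], cols[order[:k1]]] = OUTER
    labels[rows[order[k1 : k1 + k2]], cols[order[k1 : k1 + k2]]] = INTERMEDIATE
    labels[rows[order[k1 + k2 :]], cols[order[k1 + k2 :]]] = INNER
    realized = (k1 / a, k2 / a, (a - k1 - k2) / a)
    return ZonePartition(labels=labels, target_fractions=fr, realized_fractions=realized)


# ---------------------------------------------------------------------------
# Nucleus detection and Ki67 scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusDetectionParams:
    """Knobs of the IHC nucleus detector.

    Nuclei (blue hematoxylin or brown DAB) are darker than the eosinophilic /
    counterstained background, so candidate pixels are simply dark pixels;
    components are filtered by area, and a component is called positive when
    red exceeds blue by ``positive_margin`` on at least half its pixels.
    """

    luminance_max: float = 150.0
    min_area_px: int = 20
    max_area_px: int = 400
    positive_margin: int = 30
    positive_pixel_fraction: float = 0.5


def detect_nuclei(
    image: SectionImage, params: NucleusDetectionParams = NucleusDetectionParams()
) -> pd.DataFrame:
    """Detect stained nuclei and call each positive (brown) or negative (blue).

    Returns a DataFrame with columns x, y (centroid, 0-based pixel
    coordinates), area_px, positive (bool). Only components whose centroid
    lies inside the tumor mask are returned.
    """
    rgb = image.rgb.astype(np.int64)
    lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    candidate = (lum < params.luminance_max) & image.tumor_mask.grid
    labeled, n = ndimage.label(candidate)
    if n == 0:
        return pd.DataFrame(columns=["x", "y", "area_px", "positive"])

    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, idx)
    keep = (areas >= params.min_area_px) & (areas <= params.max_area_px)

    brown_px = (rgb[..., 0] - rgb[..., 2]) > params.positive_margin
    brown_frac = ndimage.mean(brown_px.astype(np.float64), labeled, idx)
    centroids = ndimage.center_of_mass(candidate, labeled, idx)

    records = []
    for i in np.flatnonzero(keep):
        cy, cx = centroids[i]
        ri, ci = int(round(cy)), int(round(cx))
        if not image.tumor_mask.grid[ri, ci]:
            continue
        records.append(
            {
                "x": float(cx),
                "y": float(cy),
                "area_px": int(areas[i]),
                "positive": bool(brown_frac[i] >= params.positive_pixel_fraction),
            }
        )
    return pd.DataFrame.from_records(records, columns=["x", "y", "area_px", "positive"])


@dataclass
class KiScore:
    """Per-zone Ki67 positivity.

    ``per_zone`` maps zone name -> dict(total, positive, percent); percent is
    None (undefined, not 0) for a zone without nuclei, and such zones are
    excluded from any downstream averaging. ``rejected`` counts nuclei whose
    centroid fell outside the partitioned tumor.
    """

    per_zone: dict[str, dict]
    overall_percent: float | None
    rejected: int


def score_ki67(nuclei: pd.DataFrame, partition: ZonePartition) -> KiScore:
    """Assign each nucleus to the zone containing its centroid and score zones."""
    h, w = partition.labels.shape
    counts = {z: [0, 0] for z in ZONE_NAMES.values()}  # zone -> [total, positive]
    rejected = 0
    for x, y, pos in zip(nuclei["x"], nuclei["y"], nuclei["positive"]):
        ri, ci = int(round(float(y))), int(round(float(x)))
        if not (0 <= ri < h and 0 <= ci < w):
            raise ValueError(f"nucleus centroid ({x}, {y}) outside the raster")
        z = int(partition.labels[ri, ci])
        if z == 0:
            rejected += 1
            continue
        counts[ZONE_NAMES[z]][0] += 1
        counts[ZONE_NAMES[z]][1] += int(bool(pos))

    per_zone = {}
    for name, (total, positive) in counts.items():
        per_zone[name] = {
            "total": total,
            "positive": positive,
            "percent": (100.0 * positive / total) if total else None,
        }
    tot = sum(v["total"] for v in per_zone.values())
    pos = sum(v["positive"] for v in per_zone.values())
    overall = (100.0 * pos / tot) if tot else None
    return KiScore(per_zone=per_zone, overall_percent=overall, rejected=rejected)
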