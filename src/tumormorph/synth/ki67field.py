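"""Synthetic Ki67 immunohistochemistry fields with zone-dependent positivity.

Nuclei are placed as non-overlapping disks inside a tumor mask at a
Poisson-like density; each nucleus is colored brown (DAB, Ki67-positive) with
the probability assigned to its concentric zone — outer / intermediate /
inner, holding 20/30/50 % of the tumor area — and blue (hematoxylin,
negative) otherwise. The generator returns the rendered field together with
the exact ground-truth table (position, zone, label), so detection and
zonal scoring can be validated nucleus by nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..mask import BinaryMask
from ..zoning import boundary_distance, partition_zones
from .section import COLOR_BACKGROUND, COLOR_DAB, COLOR_NUCLEUS

COLOR_TISSUE = (230, 210, 215)  # faint counterstained cytoplasm/stroma


@dataclass(frozen=True)
class KiFieldSpec:
    """Parameters of one synthetic Ki67 field.

    zone_positive_fractions : probability of Ki67 positivity for a nucleus in
        the (outer, intermediate, inner) zone, each in [0, 1].
    cell_density : expected nuclei per 1000 px^2 of tumor area.
    nucleus_radius_px : rendered nucleus radius; nuclei are kept at least one
        diameter apart (no overlap) and fully inside the tumor mask.
    """

    zone_positive_fractions: tuple[float, float, float]
    cell_density: float
    seed: int
    nucleus_radius_px: float = 3.0

    def __post_init__(self) -> None:
        if len(self.zone_positive_fractions) != 3 or any(
            not (0.0 <= f <= 1.0) for f in self.zone_positive_fractions
        ):
            raise ValueError("zone_positive_fractions must be three values in [0, 1]")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be positive")


class PlacementError(RuntimeError):
    """Raised when the requested density cannot be placed without overlap."""


def _place_nuclei(
    rng: np.random.Generator, eligible: np.ndarray, n_target: int, min_dist: float
) -> np.ndarray:
    """Dart-throwing with a spatial hash grid; error after bounded retries."""
    rows, cols = np.nonzero(eligible)
    if rows.size == 0 or n_target == 0:
        return np.empty((0, 2), dtype=np.int64)
    cell = min_dist / np.sqrt(2.0)
    grid: dict[tuple[int, int], list[tuple[int, int]]] = {}
    placed: list[tuple[int, int]] = []
    max_attempts = 60 * n_target
    attempts = 0
    while len(placed) < n_target and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(rows.size))
        r, c = int(rows[i]), int(cols[i])
        gr, gc = int(r / cell), int(c / cell)
        ok = True
        for dr in (-2, -1, 0, 1, 2):
            for dc in (-2, -1, 0, 1, 2):
                for pr, pc in grid.get((gr + dr, gc + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < min_dist**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed.append((r, c))
            grid.setdefault((gr, gc), []).append((r, c))
    if len(placed) < n_target:
        raise PlacementError(
            f"placed only {len(placed)}/{n_target} nuclei after {max_attempts} "
            "attempts; cell_density too high for non-overlapping placement"
        )
    return np.asarray(placed, dtype=np.int64)


def gen_ki67_field(spec: KiFieldSpec, tumor_mask: BinaryMask):
    """Render one Ki67 field over ``tumor_mask``.

    Returns a :class:`~tumormorph.image.SectionImage` whose ``truth_nuclei``
    table has columns x, y, zone (1 outer / 2 intermediate / 3 inner) and
    label (1 positive / 0 negative).
    """
    from ..image import SectionImage
    from .section import _stamp_disks

    if tumor_mask.is_empty():
        raise ValueError("tumor mask is empty")
    rng = np.random.default_rng(spec.seed)
    part = partition_zones(tumor_mask)

    r_nuc = spec.nucleus_radius_px
    eligible = boundary_distance(tumor_mask) > (r_nuc + 1.0)
    n_target = int(rng.poisson(spec.cell_density / 1000.0 * tumor_mask.foreground_count))
    centers = _place_nuclei(rng, eligible, n_target, min_dist=2.0 * r_nuc + 1.0)

    zones = part.labels[centers[:, 0], centers[:, 1]] if len(centers) else np.empty(0, int)
    p_by_zone = np.array([0.0, *spec.zone_positive_fractions])  # index by zone label
    labels = (rng.random(len(centers)) < p_by_zone[zones]).astype(int)

    img = np.empty((*tumor_mask.shape, 3), dtype=np.float64)
    img[:] = COLOR_BACKGROUND
    img[tumor_mask.grid] = COLOR_TISSUE
    if len(centers):
        _stamp_disks(img, centers[labels == 0], r_nuc, COLOR_NUCLEUS)
        _stamp_disks(img, centers[labels == 1], r_nuc, COLOR_DAB)
    img += rng.normal(0.0, 4.0, img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "x": centers[:, 1],
            "y": centers[:, 0],
            "zone": zones.astype(int),
            "label": labels,
        }
    )
    return SectionImage(
        rgb=rgb, tumor_mask=tumor_mask, truth_nuclei=truth, meta={"spec": spec}
    )
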