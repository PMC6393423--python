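"""Binary raster masks and their PNG round-trip.

Conventions used across the package: 0-based, row-major pixel coordinates,
origin at the top-left, each pixel a unit square. Physical scale is carried
as metadata only (default 1.3 um per pixel edge, a typical 40x slide-camera
resolution); all computations are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

DEFAULT_PIXEL_SIZE_UM = 1.3


@dataclass
class BinaryMask:
    """A 2-D foreground/background raster.

    Parameters
    ----------
    grid :
        2-D boolean array; True marks foreground.
    pixel_size_um :
        Physical edge length of one pixel, metadata only.
    """

    grid: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    _count: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size < 1:
            raise ValueError("mask grid must be a non-empty 2-D array")
        self.grid = g.astype(bool, copy=False)
        self._count = int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def foreground_count(self) -> int:
        """Number of foreground pixels (cached, O(1))."""
        return self._count

    def is_empty(self) -> bool:
        return self._count == 0

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive. Errors if empty."""
        if self.is_empty():
            raise ValueError("empty mask has no bounding box")
        rows = np.flatnonzero(self.grid.any(axis=1))
        cols = np.flatnonzero(self.grid.any(axis=0))
        return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.grid, other.grid))


def read_mask_png(
    path,
    *,
    binarize_at: int | None = None,
    channel: int | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> BinaryMask:
    """Read a single-channel 8-bit PNG (or TIFF) as a binary mask.

    Values must be exactly {0, 255} unless ``binarize_at`` is given, in which
    case ``value >= binarize_at`` is foreground. Multi-channel images are
    rejected unless ``channel`` selects one plane.
    """
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel image; pass channel= to select a plane"
            )
        arr = arr[..., channel]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    if binarize_at is None:
        bad = np.setdiff1d(np.unique(arr), [0, 255])
        if bad.size:
            raise ValueError(
                f"{path}: mask contains values other than 0/255 "
                f"(e.g. {bad[:5].tolist()}); use binarize_at= to threshold"
            )
        grid = arr == 255
    else:
        grid = arr >= binarize_at
    return BinaryMask(grid, pixel_size_um=pixel_size_um)


def write_mask_png(mask: BinaryMask, path) -> None:
    """Write a mask as a single-channel PNG with values {0, 255}."""
    arr = np.where(mask.grid, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
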