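"""RGB section images: an 8-bit histology-like raster plus its tumor mask.

Generated sections may also carry ground truth (a necrosis mask, or a nucleus
table) which downstream estimators never look at; it exists for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .mask import BinaryMask, write_mask_png


@dataclass
class SectionImage:
    """An 8-bit RGB section image with its tumor mask.

    ``truth_necrosis`` and ``truth_nuclei`` are ground-truth annotations
    attached by the synthetic generators (absent for real inputs).
    ``truth_nuclei`` columns: x, y (0-based pixel coordinates, origin
    top-left), zone (1 outer / 2 intermediate / 3 inner), label (1 positive,
    0 negative).
    """

    rgb: np.ndarray
    tumor_mask: BinaryMask
    truth_necrosis: BinaryMask | None = None
    truth_nuclei: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
            raise ValueError("rgb must be an (H, W, 3) uint8 array")
        if rgb.shape[:2] != self.tumor_mask.shape:
            raise ValueError("image and tumor mask shapes differ")
        self.rgb = rgb

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def save(self, stem: Path | str) -> list[Path]:
        """Write image (+ masks, + truth table if present) next to ``stem``.

        ``stem`` is a path without extension; writes ``<stem>.png``,
        ``<stem>_tumor_mask.png`` and, when present, ``<stem>_necrosis_truth.png``
        and ``<stem>_nuclei_truth.csv``. Returns the paths written.
        """
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        out = [stem.with_suffix(".png")]
        Image.fromarray(self.rgb, mode="RGB").save(out[0])
        p = stem.parent / f"{stem.name}_tumor_mask.png"
        write_mask_png(self.tumor_mask, p)
        out.append(p)
        if self.truth_necrosis is not None:
            p = stem.parent / f"{stem.name}_necrosis_truth.png"
            write_mask_png(self.truth_necrosis, p)
            out.append(p)
        if self.truth_nuclei is not None:
            p = stem.parent / f"{stem.name}_nuclei_truth.csv"
            self.truth_nuclei.to_csv(p, index=False)
            out.append(p)
        return out


def read_section(image_path, tumor_mask: BinaryMask) -> SectionImage:
    """Load an RGB PNG/TIFF and pair it with an externally supplied mask."""
    arr = np.asarray(Image.open(image_path).convert("RGB"))
    return SectionImage(rgb=arr, tumor_mask=tumor_mask)
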