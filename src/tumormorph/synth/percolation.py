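"""Mandelbrot percolation: random fractals of known box dimension.

The construction subdivides every retained cell into b x b children and keeps
each child independently with probability p. In the supercritical regime
(b^2 * p > 1) the surviving set, conditioned on non-extinction, has box
dimension log(b^2 p) / log b = 2 + log p / log b — which makes these masks
the natural validation substrate for a box-counting estimator: the true
dimension is known in closed form and tunable through p.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np

from ..mask import BinaryMask

MAX_SIDE = 8192


@dataclass(frozen=True)
class PercolationSpec:
    """Parameters of one percolation realization.

    base : subdivision factor b >= 2.
    retain_prob : per-child retention probability p in (0, 1]; must satisfy
        b^2 * p > 1 or the limiting dimension is undefined.
    levels : number of subdivision rounds L >= 1; output side is b**L.
    seed : RNG seed; identical specs give bit-identical masks.
    """

    base: int
    retain_prob: float
    levels: int
    seed: int

    def __post_init__(self) -> None:
        if self.base < 2:
            raise ValueError("base must be >= 2")
        if not (0.0 < self.retain_prob <= 1.0):
            raise ValueError("retain_prob must be in (0, 1]")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.base**2 * self.retain_prob <= 1.0:
            raise ValueError(
                f"subcritical process: b^2*p = {self.base**2 * self.retain_prob:.3g} <= 1, "
                "theoretical dimension undefined"
            )
        if self.base**self.levels > MAX_SIDE:
            raise ValueError(
                f"raster side {self.base**self.levels} exceeds cap {MAX_SIDE}"
            )

    @property
    def side(self) -> int:
        return self.base**self.levels

    @property
    def theoretical_dimension(self) -> float:
        return percolation_dimension(self.base, self.retain_prob)


def percolation_dimension(base: int, retain_prob: float) -> float:
    """Closed-form box dimension log(b^2 p)/log b of supercritical percolation."""
    if base**2 * retain_prob <= 1.0:
        raise ValueError("dimension undefined for b^2*p <= 1")
    return log(base**2 * retain_prob) / log(base)


def gen_percolation_mask(spec: PercolationSpec) -> BinaryMask:
    """Realize one percolation mask of side b**L.

    Starts from a single retained cell and runs L subdivision rounds; the
    retention draw is made for every child of the current grid (dead
    children included) so the output is a deterministic function of the
    seed alone, independent of survival history. An extinct realization is
    returned as an all-background mask rather than silently re-sampled;
    callers that need survivors re-seed.
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.base
    m = np.ones((1, 1), dtype=bool)
    for _ in range(spec.levels):
        side = m.shape[0] * b
        keep = rng.random((side, side)) < spec.retain_prob
        m = np.kron(m, np.ones((b, b), dtype=bool)) & keep
    return BinaryMask(m)
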