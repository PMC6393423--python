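"""Synthetic three-arm caliper cohorts for growth-curve analysis.

Each animal gets a baseline volume near the common study entry mean and a
final-day volume drawn around its arm's final mean; between the two, growth
is linear in the cube root of volume (i.e. linear in equivalent radius),
matching the boundary-driven growth picture in which tumors expand by
proliferation at their surface. Printed SEMs are converted to between-animal
SDs as SEM * sqrt(n). Each day's volume is then expressed as a caliper pair
(a, b) with aspect ratio a/b uniform in [1.0, 1.6] such that a*b^2/2
reproduces the volume exactly, emulating what a technician would record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DAYS = (0, 4, 8, 11, 15, 18, 22)  # twice-weekly schedule, day 0..22


@dataclass(frozen=True)
class Arm:
    """One treatment arm: size and final-day volume (and optional weight) targets."""

    name: str
    n: int
    final_mean_mm3: float
    final_sem_mm3: float
    weight_mean_g: float | None = None
    weight_sem_g: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each arm needs n >= 2")
        if self.final_mean_mm3 <= 0:
            raise ValueError("final mean volume must be positive")
        if self.final_sem_mm3 < 0:
            raise ValueError("final SEM must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    start_mean_mm3 / start_sem_mm3 : common study-entry volume; baseline
        draws are re-centred per arm so each arm's day-0 mean equals
        ``start_mean_mm3`` exactly (arms are randomized from one pool of
        implanted tumors, so their entry means coincide by design).
    days : measurement schedule in study days; the last entry is the
        necropsy day at which final weights are emitted.
    caliper_noise_mm : optional per-measurement SD added to each recorded
        diameter (default 0: noise-free calipers).
    """

    arms: tuple[Arm, ...]
    seed: int
    start_mean_mm3: float = 106.9
    start_sem_mm3: float = 3.1
    days: tuple[int, ...] = DEFAULT_DAYS
    caliper_noise_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("need at least one arm")
        if self.start_mean_mm3 <= 0:
            raise ValueError("start mean volume must be positive")
        if len(set(a.name for a in self.arms)) != len(self.arms):
            raise ValueError("arm names must be unique")
        days = tuple(int(d) for d in self.days)
        if len(days) < 2 or any(d < 0 for d in days) or sorted(days) != list(days):
            raise ValueError("days must be >= 2 sorted non-negative integers")
        object.__setattr__(self, "days", days)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to (0, inf) by redrawing."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError(f"could not draw a positive value from N({mean}, {sd})")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a long-format caliper table.

    Columns: group, animal_id, day, length_mm, width_mm, weight_g (weight
    empty except on the final day, and only for arms with weight targets).
    Randomness is split into one independent child stream per animal, so a
    cohort is bit-reproducible and insensitive to arm reordering elsewhere.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(sum(a.n for a in spec.arms))
    horizon = spec.days[-1] - spec.days[0]
    rows = []
    k = 0
    for arm in spec.arms:
        sd0 = spec.start_sem_mm3 * np.sqrt(arm.n)
        sdf = arm.final_sem_mm3 * np.sqrt(arm.n)
        rngs = [np.random.default_rng(streams[k + i]) for i in range(arm.n)]
        k += arm.n

        v0 = np.array([_positive_normal(r, spec.start_mean_mm3, sd0) for r in rngs])
        v0 = v0 + (spec.start_mean_mm3 - v0.mean())  # exact common entry mean
        if np.any(v0 <= 0):
            raise RuntimeError("re-centred baseline produced a non-positive volume")
        vf = np.array([_positive_normal(r, arm.final_mean_mm3, sdf) for r in rngs])

        for i, rng in enumerate(rngs):
            r0, rf = v0[i] ** (1.0 / 3.0), vf[i] ** (1.0 / 3.0)
            weight = (
                _positive_normal(rng, arm.weight_mean_g, arm.weight_sem_g * np.sqrt(arm.n))
                if arm.weight_mean_g is not None
                else np.nan
            )
            for day in spec.days:
                frac = (day - spec.days[0]) / horizon
                vol = (r0 + (rf - r0) * frac) ** 3
                q = rng.uniform(1.0, 1.6)
                b = (2.0 * vol / q) ** (1.0 / 3.0)
                a = q * b
                if spec.caliper_noise_mm > 0:
                    a = max(a + rng.normal(0, spec.caliper_noise_mm), 0.05)
                    b = max(b + rng.normal(0, spec.caliper_noise_mm), 0.05)
                    a, b = max(a, b), min(a, b)
                rows.append(
                    {
                        "group": arm.name,
                        "animal_id": f"{arm.name}_{i + 1:02d}",
                        "day": day,
                        "length_mm": a,
                        "width_mm": b,
                        "weight_g": weight if day == spec.days[-1] else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["group", "animal_id", "day", "length_mm", "width_mm", "weight_g"])
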