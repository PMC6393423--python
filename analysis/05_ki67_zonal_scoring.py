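#!/usr/bin/env python
"""Zonal Ki67 scoring: proliferation confined to the tumor periphery.

Generates Ki67 fields over a disk tumor with the outer-dominated positivity
profile the study reports (above 40% in the outer 20% region, ~30%
intermediate, lowest in the core), detects and scores nuclei per zone over
ten seeds, and checks the 20/30/50 partition geometry.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tumormorph import detect_nuclei, partition_zones, score_ki67
from tumormorph.io import write_csv
from tumormorph.synth import KiFieldSpec, gen_ki67_field
from tumormorph.mask import BinaryMask

RESULTS = Path(__file__).resolve().parent.parent / "results"
TRUE_FRACTIONS = (0.45, 0.30, 0.15)  # outer, intermediate, inner


def disk_mask(radius: int) -> BinaryMask:
    side = 2 * (radius + 16)
    c = side / 2.0 - 0.5
    yy, xx = np.mgrid[0:side, 0:side]
    return BinaryMask(np.hypot(yy - c, xx - c) <= radius)


if __name__ == "__main__":
    tumor = disk_mask(256)
    part = partition_zones(tumor)
    print("zone fractions (outer, intermediate, inner):",
          tuple(round(f, 4) for f in part.realized_fractions))

    rows = []
    for seed in range(1, 11):
        field = gen_ki67_field(
            KiFieldSpec(zone_positive_fractions=TRUE_FRACTIONS, cell_density=5.0,
                        seed=seed),
            tumor,
        )
        score = score_ki67(detect_nuclei(field), part)
        for zone, true_p in zip(("outer", "intermediate", "inner"), TRUE_FRACTIONS):
            z = score.per_zone[zone]
            rows.append({"seed": seed, "zone": zone, "total": z["total"],
                         "positive": z["positive"], "percent": z["percent"],
                         "true_percent": 100 * true_p})
    df = pd.DataFrame(rows)
    write_csv(df, RESULTS / "ki67_per_field.csv")
    summary = df.groupby("zone", sort=False)["percent"].agg(["mean", "std"])
    write_csv(summary.reset_index(), RESULTS / "ki67_summary.csv")
    print("\nrecovered Ki67 positivity by zone (10 fields):")
    print(summary.to_string())
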