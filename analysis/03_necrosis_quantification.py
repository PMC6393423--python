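#!/usr/bin/env python
"""Necrosis segmentation accuracy on synthetic sections.

Generates sections emulating the three treatment groups' published necrosis
levels — control 51.0% and rhG-CSF 37.4% as compact interior blobs,
gemcitabine 7.5% as dispersed peripheral foci — runs the segmentation stage
on ten seeds per condition, and reports recovered percent necrosis (vs the
generator's exact ground truth) with Dice overlap. Finishes with the
summary-statistics Welch t test of the 37.4 +/- 4.6 vs 7.5 +/- 3.0 contrast.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tumormorph import percent_necrosis, segment_necrosis, welch_t_from_summary
from tumormorph.io import write_csv
from tumormorph.morphometry import dice_coefficient
from tumormorph.synth import SectionSpec, gen_section

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONDITIONS = [
    ("control", 0.510, "compact_interior"),
    ("rhG-CSF", 0.374, "compact_interior"),
    ("gemcitabine", 0.075, "dispersed_peripheral"),
]

if __name__ == "__main__":
    rows = []
    for name, frac, pattern in CONDITIONS:
        for seed in range(1, 11):
            img = gen_section(SectionSpec(radius_px=256, necrotic_fraction=frac,
                                          pattern=pattern, seed=seed))
            res = segment_necrosis(img)
            rows.append({
                "group": name,
                "seed": seed,
                "true_percent": percent_necrosis(img.truth_necrosis, img.tumor_mask),
                "measured_percent": res.percent_necrosis,
                "dice": dice_coefficient(res.necrosis_mask, img.truth_necrosis),
            })
    df = pd.DataFrame(rows)
    write_csv(df, RESULTS / "necrosis_per_section.csv")
    summary = df.groupby("group", sort=False).agg(
        true_mean=("true_percent", "mean"),
        measured_mean=("measured_percent", "mean"),
        mae=("measured_percent", lambda s: np.mean(np.abs(s - df.loc[s.index, "true_percent"]))),
        min_dice=("dice", "min"),
    ).reset_index()
    write_csv(summary, RESULTS / "necrosis_summary.csv")
    print(summary.to_string(index=False))

    t = welch_t_from_summary(37.4, 4.6, 7, 7.5, 3.0, 7)
    print(f"\nrhG-CSF vs gemcitabine necrosis (printed summaries): "
          f"t = {t.statistic:.3f}, df = {t.df:.1f}, p = {t.p_two_sided:.2e}")
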