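#!/usr/bin/env python
"""Box-counting estimator validation and the necrotic-pattern d_f contrast.

Part 1 validates the estimator on Mandelbrot percolation masks whose true
dimension is known in closed form, at the two retention probabilities whose
theoretical dimensions match the study's group values (1.78 and 1.52).
Part 2 computes d_f of the necrosis masks segmented from synthetic sections:
compact interior necrosis scores near the filled-blob end, dispersed
peripheral necrosis markedly lower — the same ordering the study reports
between rhG-CSF/control and gemcitabine tumors.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tumormorph import fractal_dimension, segment_necrosis
from tumormorph.io import write_csv
from tumormorph.synth import (
    PercolationSpec,
    SectionSpec,
    gen_percolation_mask,
    gen_section,
    percolation_dimension,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    rows = []
    for p in (0.702, 0.462):
        est, seed = [], 0
        while len(est) < 20:
            seed += 1
            m = gen_percolation_mask(PercolationSpec(base=5, retain_prob=p,
                                                     levels=5, seed=seed))
            if not m.is_empty():
                est.append(fractal_dimension(m, scale_base=5).d_f)
        rows.append({"retain_prob": p,
                     "d_theory": percolation_dimension(5, p),
                     "d_f_mean": float(np.mean(est)),
                     "d_f_sd": float(np.std(est, ddof=1)),
                     "n_masks": len(est)})
    recovery = pd.DataFrame(rows)
    write_csv(recovery, RESULTS / "fractal_recovery.csv")
    print("percolation recovery:")
    print(recovery.to_string(index=False))

    rows = []
    for pattern, frac in (("compact_interior", 0.374), ("dispersed_peripheral", 0.075)):
        for seed in range(1, 6):
            img = gen_section(SectionSpec(radius_px=256, necrotic_fraction=frac,
                                          pattern=pattern, seed=seed))
            fit = fractal_dimension(segment_necrosis(img).necrosis_mask)
            rows.append({"pattern": pattern, "seed": seed, "d_f": fit.d_f,
                         "stderr": fit.stderr, "r_squared": fit.r_squared})
    contrast = pd.DataFrame(rows)
    write_csv(contrast, RESULTS / "fractal_necrosis_patterns.csv")
    print("\nnecrotic-pattern d_f (segmented masks):")
    print(contrast.groupby("pattern")["d_f"].agg(["mean", "std"]).to_string())
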