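# tumormorph

Quantitative morphometry for subcutaneous tumor xenograft studies. The
package implements, as one tested pipeline, the measurements such studies
report from calipers and stained sections:

- **Caliper growth curves.** Tumor volume from a caliper pair by the
  ellipsoid approximation `V = a·b²/2` (`a` longest, `b` shortest diameter,
  mm → mm³); per-arm, per-day summaries as mean ± SEM; exact small-sample
  Mann–Whitney U comparisons against control (the exact two-sided p is the
  fraction of the C(n₁+n₂, n₁) group labelings with U ≤ U_obs); Welch or
  pooled t tests computable from printed summaries alone
  (t = (m₁−m₂)/√(SEM₁²+SEM₂²)); one-way ANOVA.
- **Percent intratumoral necrosis** from an H&E-like RGB section: tumor
  pixels are classified necrotic when a smoothed nuclear-density map falls
  below and a smoothed luminance (pallor) map rises above their Otsu
  thresholds; percent necrosis = 100·|necrosis|/|tumor| in exact integer
  arithmetic.
- **Box-counting fractal dimension** `d_f` of a binary pattern: occupied-box
  counts N(ε) over a geometric ladder of box sizes, `d_f` = −slope of the
  OLS fit of ln N(ε) on ln ε. Compact interior necrosis scores near 2,
  dispersed boundary-hugging necrosis markedly lower.
- **Concentric zonal partition and Ki67 scoring**: the section is split into
  outer/intermediate/inner zones holding exactly 20/30/50 % of the tumor
  area, ranked by Euclidean distance to the tumor boundary; stained nuclei
  are detected, called positive (brown/DAB) or negative (blue), and scored
  per zone as 100·positive/total.
- **Synthetic-data generators** (`tumormorph.synth`) produce every input
  with known ground truth: Mandelbrot percolation masks whose box dimension
  log(b²p)/log b is known in closed form, sections with an exact necrotic
  fraction in compact or dispersed layouts, Ki67 nucleus fields with
  zone-dependent positive fractions, and multi-arm caliper cohorts
  calibrated to published group means and SEMs.

Intended users: researchers analysing (or power-simulating) xenograft
endpoint data, and anyone needing a validated box-counting estimator or
exact Mann–Whitney for small animal cohorts.

## Worked example

```python
import numpy as np
from tumormorph import fractal_dimension, segment_necrosis, percent_necrosis
from tumormorph.synth import SectionSpec, gen_section

img = gen_section(SectionSpec(radius_px=256, necrotic_fraction=0.374,
                              pattern="compact_interior", seed=7))
truth = percent_necrosis(img.truth_necrosis, img.tumor_mask)
res = segment_necrosis(img)
fit = fractal_dimension(res.necrosis_mask)
print(f"true {truth:.1f}%  measured {res.percent_necrosis:.1f}%  "
      f"d_f {fit.d_f:.3f} (r² {fit.r_squared:.4f})")
```

prints

```
true 37.4%  measured 37.1%  d_f 1.828 (r² 0.9986)
```

— the generator laid down exactly 37.4 % necrosis as a compact central
blob, the segmenter recovered it within a point, and the blob's box
dimension sits near the filled-region end of the scale, as a compact
pattern should.

The numbered scripts under `analysis/` run the full study-style analysis
(cohort simulation → growth statistics → necrosis quantification → fractal
contrast → zonal Ki67 scoring), printing what each stage found and writing
tidy CSVs under `results/`. The same stages are available as an umbrella
CLI (`tumormorph run --seed 7 --out-dir out/`, plus per-stage subcommands
such as `simulate-cohort`, `necrosis`, `fractal-dim`, `zones`,
`growth-stats`).

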