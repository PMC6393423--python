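"""End-to-end pipeline: simulate -> necrosis -> fractal -> zones -> ki67 -> growth stats.

Every stage writes its tables (fixed column order, 6-significant-digit
formatting) and rasters under one output directory, appends a record to the
run log, and the effective configuration is written back out so the run can
be reproduced from ``config_effective.yaml`` alone.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from PIL import Image

from . import cohort as cs
from . import synth
from .config import PipelineConfig, RunLog
from .io import sha256_file, write_cohort_csv, write_csv
from .mask import write_mask_png
from .morphometry import SegmentationParams, fractal_dimension, segment_necrosis
from .zoning import ZONE_NAMES, detect_nuclei, partition_zones, score_ki67


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digests(paths) -> dict:
    return {str(p): sha256_file(p) for p in paths}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on all-synthetic inputs; returns {stage: [paths]}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    produced: dict[str, list[Path]] = {}
    config.to_yaml(out / "config_effective.yaml")

    def stage(name):
        def wrap(fn):
            try:
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    paths, params = fn()
                log.record(name, params, {}, _digests(paths),
                           [str(w.message) for w in wlist])
                produced[name] = paths
            except Exception as e:  # noqa: BLE001 - abort with stage context
                log.write(out / "runlog.json")
                raise StageError(name, e) from e
        return wrap

    seed = config.seed

    @stage("simulate_cohort")
    def _():
        c = config.simulate.cohort
        spec = synth.CohortSpec(
            arms=tuple(synth.Arm(**a.model_dump()) for a in c.arms),
            seed=seed,
            start_mean_mm3=c.start_mean_mm3,
            start_sem_mm3=c.start_sem_mm3,
            days=tuple(c.days),
            caliper_noise_mm=c.caliper_noise_mm,
        )
        table = synth.gen_cohort(spec)
        return [write_cohort_csv(table, out / "cohort.csv")], c.model_dump()

    @stage("growth_stats")
    def _():
        from .io import read_cohort_csv

        table = read_cohort_csv(out / "cohort.csv")
        rep = cs.growth_report(table, config.stats.control, config.stats.alpha)
        paths = [
            write_csv(rep.per_day, out / "growth_per_day.csv"),
            write_csv(rep.final_pairwise, out / "growth_final_pairwise.csv"),
            write_csv(
                pd.DataFrame(
                    [{"group": g, "first_significant_day": d if d is not None else ""}
                     for g, d in rep.first_significant_day.items()]
                ),
                out / "growth_first_significant.csv",
            ),
        ]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        summ = cs.summarize(cs.add_volumes(table))
        for g, sub in summ.groupby("group"):
            ax.errorbar(sub["day"], sub["mean"], yerr=sub["sem"], marker="o",
                        capsize=3, label=g)
        ax.set_xlabel("day"), ax.set_ylabel("tumor volume (mm$^3$)"), ax.legend()
        fig.tight_layout()
        p = out / "growth_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return paths + [p], config.stats.model_dump()

    seg_params = SegmentationParams(**config.segmentation.model_dump())

    @stage("necrosis")
    def _():
        rows, paths = [], []
        for i, sc in enumerate(config.simulate.sections):
            spec = synth.SectionSpec(
                radius_px=sc.radius_px, necrotic_fraction=sc.necrotic_fraction,
                pattern=sc.pattern, seed=seed + i,
            )
            img = synth.gen_section(spec)
            paths += img.save(out / f"section_{sc.name}")
            res = segment_necrosis(img, seg_params)
            p = out / f"section_{sc.name}_necrosis.png"
            write_mask_png(res.necrosis_mask, p)
            paths.append(p)
            fit = fractal_dimension(res.necrosis_mask,
                                    scale_base=config.fractal.scale_base)
            rows.append(
                {"image": sc.name, "percent_necrosis": res.percent_necrosis,
                 "d_f": fit.d_f, "d_f_stderr": fit.stderr,
                 "r_squared": fit.r_squared}
            )
        paths.append(write_csv(pd.DataFrame(rows), out / "necrosis.csv"))
        return paths, config.segmentation.model_dump()

    @stage("fractal_percolation")
    def _():
        pc = config.simulate.percolation
        spec = synth.PercolationSpec(base=pc.base, retain_prob=pc.retain_prob,
                                     levels=pc.levels, seed=seed)
        mask = synth.gen_percolation_mask(spec)
        p_mask = out / "percolation_mask.png"
        write_mask_png(mask, p_mask)
        fit = fractal_dimension(mask, scale_base=pc.base)
        df = pd.DataFrame({"scale": fit.scales, "count": fit.counts})
        p_csv = write_csv(df, out / "percolation_boxcounts.csv")
        p_sum = write_csv(
            pd.DataFrame([{"d_f": fit.d_f, "stderr": fit.stderr,
                           "r_squared": fit.r_squared,
                           "d_theory": spec.theoretical_dimension}]),
            out / "percolation_fit.csv",
        )
        return [p_mask, p_csv, p_sum], pc.model_dump()

    @stage("ki67_zones")
    def _():
        kc = config.simulate.ki67
        side = 2 * (kc.radius_px + 16)
        c = side / 2.0 - 0.5
        yy, xx = np.mgrid[0:side, 0:side]
        from .mask import BinaryMask

        tumor = BinaryMask(np.hypot(yy - c, xx - c) <= kc.radius_px)
        field = synth.gen_ki67_field(
            synth.KiFieldSpec(zone_positive_fractions=kc.zone_positive_fractions,
                              cell_density=kc.cell_density, seed=seed),
            tumor,
        )
        paths = field.save(out / "ki67_field")
        part = partition_zones(tumor, config.zones.fractions)
        p_lab = out / "ki67_zones.png"
        Image.fromarray(part.labels, mode="L").save(p_lab)
        paths.append(p_lab)
        score = score_ki67(detect_nuclei(field), part)
        rows = [
            {"zone": z, "total": v["total"], "positive": v["positive"],
             "percent": v["percent"] if v["percent"] is not None else np.nan}
            for z, v in score.per_zone.items()
        ]
        paths.append(write_csv(pd.DataFrame(rows), out / "ki67_scores.csv"))
        paths.append(write_csv(
            pd.DataFrame([{"zone": ZONE_NAMES[i + 1], "realized_fraction": f}
                          for i, f in enumerate(part.realized_fractions)]),
            out / "zone_fractions.csv",
        ))
        return paths, kc.model_dump()

    log.write(out / "runlog.json")
    return produced
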