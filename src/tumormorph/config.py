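"""Pipeline configuration (validated, unknown keys rejected) and run logging."""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArmConfig(_Strict):
    name: str
    n: int = Field(ge=2)
    final_mean_mm3: float = Field(gt=0)
    final_sem_mm3: float = Field(ge=0)
    weight_mean_g: float | None = None
    weight_sem_g: float | None = None


class CohortSimConfig(_Strict):
    arms: list[ArmConfig] = [
        ArmConfig(name="control", n=6, final_mean_mm3=519.4, final_sem_mm3=62.9,
                  weight_mean_g=0.316, weight_sem_g=0.017),
        ArmConfig(name="rhG-CSF", n=7, final_mean_mm3=282.0, final_sem_mm3=30.7,
                  weight_mean_g=0.143, weight_sem_g=0.029),
        ArmConfig(name="gemcitabine", n=7, final_mean_mm3=202.6, final_sem_mm3=18.1,
                  weight_mean_g=0.129, weight_sem_g=0.018),
    ]
    start_mean_mm3: float = 106.9
    start_sem_mm3: float = 3.1
    days: list[int] = [0, 4, 8, 11, 15, 18, 22]
    caliper_noise_mm: float = 0.0


class SectionSimConfig(_Strict):
    name: str
    radius_px: int = Field(ge=32)
    necrotic_fraction: float = Field(ge=0, le=1)
    pattern: str


class PercolationSimConfig(_Strict):
    base: int = 3
    retain_prob: float = 0.85
    levels: int = 6


class Ki67SimConfig(_Strict):
    radius_px: int = 128
    zone_positive_fractions: tuple[float, float, float] = (0.45, 0.30, 0.15)
    cell_density: float = 5.0


class SimulateConfig(_Strict):
    cohort: CohortSimConfig = CohortSimConfig()
    sections: list[SectionSimConfig] = [
        SectionSimConfig(name="compact", radius_px=128, necrotic_fraction=0.374,
                         pattern="compact_interior"),
        SectionSimConfig(name="dispersed", radius_px=128, necrotic_fraction=0.075,
                         pattern="dispersed_peripheral"),
    ]
    percolation: PercolationSimConfig = PercolationSimConfig()
    ki67: Ki67SimConfig = Ki67SimConfig()


class SegmentationConfig(_Strict):
    sigma_px: float = 8.0
    nuclear_blue_margin: int = 10
    opening_radius_px: int = 3
    min_object_px: int = 64


class FractalConfig(_Strict):
    scale_base: int = 2


class ZonesConfig(_Strict):
    fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)


class StatsConfig(_Strict):
    control: str = "control"
    alpha: float = 0.05


class PipelineConfig(_Strict):
    """Full configuration of an end-to-end run; every default is the
    package's documented default."""

    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    fractal: FractalConfig = FractalConfig()
    zones: ZonesConfig = ZonesConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False),
            encoding="utf-8",
        )
        return path


class RunLog:
    """Accumulates one timestamped record per pipeline stage.

    Each record holds the stage name, the parameters used, SHA-256 digests of
    inputs and outputs (stable across platforms) and any warnings raised.
    """

    def __init__(self) -> None:
        self.stages: list[dict] = []

    def record(self, stage: str, params: dict, inputs: dict, outputs: dict,
               warnings_: list[str] | None = None) -> None:
        self.stages.append(
            {
                "stage": stage,
                "time_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
                "params": params,
                "inputs": inputs,
                "outputs": outputs,
                "warnings": warnings_ or [],
            }
        )

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({"stages": self.stages}, indent=2, default=str),
                        encoding="utf-8")
        return path
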