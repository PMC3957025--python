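"""Pipeline configuration: serializable settings and derived seeds."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from tdconnect.synthetic_cohort import CohortConfig

STAGES = ("simulate", "behavior", "glm", "dcm", "bms", "predict")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    glm_modulator: str = "rdsv"
    dcm_fast: bool = True
    dcm_family_runs: tuple[int, ...] = (1,)
    bms_draws: int = 1_000_000
    elastic_net_alpha: float = 0.3
    elastic_net_lambda: float | None = None  # None -> inner CV
    seed: int = 0
    output_dir: str = "results"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage}")
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dcm_family_runs"] = list(self.dcm_family_runs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig(**d["cohort"])
        if "dcm_family_runs" in d:
            d["dcm_family_runs"] = tuple(d["dcm_family_runs"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=False)
                if path.suffix in (".yml", ".yaml")
                else json.dumps(self.to_dict(), indent=1))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = (yaml.safe_load(path.read_text())
               if path.suffix in (".yml", ".yaml")
               else json.loads(path.read_text()))
        return cls.from_dict(raw)
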