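"""Pipeline configuration: one flat record plus the scenario parameters."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .synth import ScenarioConfig


@dataclass
class PipelineConfig:
    workdir: str = "."
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    target_region: str = "temperate_europe"
    habitat_filter: bool = True
    geography_filter: bool = True
    replicate_aggregation: str = "union"   # or "intersection"
    n_replicates: int = 4
    # SBM settings
    q_min: int = 1
    q_max: int = 8
    sbm_restarts: int = 5
    sbm_tol: float = 1e-6
    sbm_max_iter: int = 300
    sbm_seed: int = 0
    # metric settings
    tl_weighted: bool = False
    # beta-diversity settings
    beta_q: float = 0
    beta_mode: str = "presence"
    run_beta: bool = True
    n_perm: int = 999
    stats_seed: int = 0
    # stats settings
    reml: bool = True

    def validate(self) -> None:
        self.scenario.validate()
        if self.replicate_aggregation not in ("union", "intersection"):
            raise ValueError("replicate_aggregation must be union|intersection")
        if self.beta_mode not in ("presence", "reads"):
            raise ValueError("beta_mode must be presence|reads")
        if self.q_min < 1 or self.q_max < self.q_min:
            raise ValueError("invalid Q range")
        for name in ("sbm_seed", "stats_seed"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an integer")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["scenario"]["guild_proportions"] = dict(
            self.scenario.guild_proportions)
        d["scenario"]["lui_slope_per_metric"] = dict(
            self.scenario.lui_slope_per_metric)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        sc = d.pop("scenario", {})
        if "sensitive_guilds" in sc:
            sc["sensitive_guilds"] = tuple(sc["sensitive_guilds"])
        cfg = cls(scenario=ScenarioConfig(**sc), **d)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json() + "\n")
        return path
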