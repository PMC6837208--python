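"""Run configuration: a YAML-serializable bundle of phase/agent/batch settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .agents import AgentParams
from .simulate import PhaseConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a batch of simulated trials."""

    phase: PhaseConfig
    agent: AgentParams = field(default_factory=AgentParams)
    n_landscapes: int = 20
    trials_per_landscape: int = 1
    master_seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.n_landscapes < 1 or self.trials_per_landscape < 1:
            raise ValueError("batch sizes must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase"]["dims"] = list(d["phase"]["dims"])
        d["phase"]["start"] = list(d["phase"]["start"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        p = dict(d.pop("phase"))
        p["dims"] = tuple(p["dims"])
        p["start"] = tuple(p["start"])
        agent_keys = {f.name for f in fields(AgentParams)}
        a = {k: v for k, v in dict(d.pop("agent", {})).items() if k in agent_keys}
        return cls(phase=PhaseConfig(**p), agent=AgentParams(**a), **d)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
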