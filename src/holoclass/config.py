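"""Run configuration: one YAML file describing a whole pipeline run.

The file groups the optics, the simulator settings, the volume ladder, the
architecture and the training protocol; every command resolves its config
(defaults merged with the file) and writes the resolved snapshot next to its
outputs so any artifact directory is self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import ModelConfig
from .synthetic import SimulationConfig
from .training import TrainConfig
from .wave_optics import OpticalParams

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, nested per stage."""

    optics: OpticalParams = field(default_factory=OpticalParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    master_seed: int = 0
    out_dir: str = "runs"

    def resolved(self) -> dict:
        d = {
            "optics": asdict(self.optics),
            "simulation": asdict(self.simulation),
            "model": asdict(self.model),
            "training": asdict(self.training),
            "master_seed": self.master_seed,
            "out_dir": self.out_dir,
        }
        # optics are duplicated inside simulation; keep the top-level copy
        d["simulation"]["optics"] = asdict(self.simulation.optics)
        return d


def _build_section(cls, data: dict, **extra):
    if data is None:
        data = {}
    kwargs = dict(data)
    kwargs.update(extra)
    if cls is SimulationConfig and "optics" in kwargs and isinstance(kwargs["optics"], dict):
        kwargs["optics"] = OpticalParams(**kwargs["optics"])
    if cls is ModelConfig and "block_channels" in kwargs:
        kwargs["block_channels"] = tuple(kwargs["block_channels"])
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; missing sections fall back to defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    optics = _build_section(OpticalParams, raw.get("optics"))
    sim_raw = dict(raw.get("simulation") or {})
    sim_raw.setdefault("optics", asdict(optics))
    return RunConfig(
        optics=optics,
        simulation=_build_section(SimulationConfig, sim_raw),
        model=_build_section(ModelConfig, raw.get("model")),
        training=_build_section(TrainConfig, raw.get("training")),
        master_seed=int(raw.get("master_seed", 0)),
        out_dir=str(raw.get("out_dir", "runs")),
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.resolved(), sort_keys=False))
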