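"""Experiment configuration: every tunable constant in one structured file.

The configuration round-trips losslessly through YAML.  Section names map
onto the package's components: ``lif`` and ``stdp`` (neuron and plasticity
constants), ``network`` (population sizes and the motor partition),
``schedule`` (training timing), ``world`` (arena geometry) and ``rescue``
(reward magnitudes and RL hyperparameters).  Defaults equal the model's
printed constants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .ae_snn import ModuleSpec, TrainingSchedule, build_network, EmpathyNetwork
from .altruism import IntrinsicRewardModel, RescueScenario
from .gridworld import GridWorld
from .snn_core import LIFParameters, STDPParameters

__all__ = ["ExperimentConfig", "RescueConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the list of offending keys when validation fails."""


@dataclass
class RescueConfig:
    """Reward magnitudes and Q-learning hyperparameters of phase 2."""

    alpha: float = 0.1
    gamma: float = 0.9
    epsilon: float = 0.1
    epsilon_decay: float = 0.99
    relief_reward: float = 10.0
    pain_penalty: float = -1.0
    step_cost: float = -0.01
    episodes: int = 300
    max_rescue_steps: int = 40
    agentA_start: tuple[int, int] = (7, 5)
    agentB_start: tuple[int, int] = (1, 1)


@dataclass
class ExperimentConfig:
    seed: int = 0
    explore_steps: int = 400
    lif: LIFParameters = field(default_factory=LIFParameters)
    stdp: STDPParameters = field(default_factory=STDPParameters)
    network: ModuleSpec = field(default_factory=ModuleSpec)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    world: GridWorld = field(default_factory=GridWorld)
    rescue: RescueConfig = field(default_factory=RescueConfig)

    # --- construction of components -----------------------------------
    def build_network(self) -> EmpathyNetwork:
        return build_network(self.network, self.lif, self.stdp)

    def build_world(self) -> GridWorld:
        return dataclasses.replace(self.world, passage_open=False)

    def build_scenario(self, net: EmpathyNetwork) -> RescueScenario:
        r = self.rescue
        return RescueScenario(
            net=net,
            world=self.build_world(),
            agentA_start=tuple(r.agentA_start),
            agentB_start=tuple(r.agentB_start),
            reward_model=IntrinsicRewardModel(
                relief_reward=r.relief_reward,
                pain_penalty=r.pain_penalty,
                step_cost=r.step_cost,
            ),
            max_rescue_steps=r.max_rescue_steps,
        )

    # --- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def plain(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (frozenset, set)):
                return sorted(plain(v) for v in obj)
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        return plain(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ExperimentConfig":
        data = dict(data)
        sections = {
            "lif": LIFParameters,
            "stdp": STDPParameters,
            "network": ModuleSpec,
            "schedule": TrainingSchedule,
            "world": GridWorld,
            "rescue": RescueConfig,
        }
        bad: list[str] = []
        kwargs: dict[str, Any] = {}
        for key in ("seed", "explore_steps"):
            if key in data:
                kwargs[key] = data.pop(key)
        for name, typ in sections.items():
            sub = data.pop(name, {})
            names = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - names
            bad.extend(f"{name}.{k}" for k in sorted(unknown))
            sub = {k: _revive(typ, k, v) for k, v in sub.items() if k in names}
            if not bad:
                kwargs[name] = typ(**sub)
        bad.extend(sorted(data))
        if bad:
            raise ConfigError(f"invalid configuration keys: {', '.join(bad)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the resolved configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _revive(typ: type, key: str, value: Any):
    """Undo the YAML-friendly flattening for tuple/frozenset-typed fields."""
    if typ is GridWorld:
        if key in ("danger_cell", "switch_cell"):
            return tuple(value)
        if key in ("passage_cells", "walls"):
            return frozenset(tuple(v) for v in value)
    if typ is ModuleSpec and key in ("emotion_coding", "perception_coding", "motor_partition"):
        return {k: tuple(v) for k, v in value.items()}
    if typ is RescueConfig and key in ("agentA_start", "agentB_start"):
        return tuple(value)
    return value
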