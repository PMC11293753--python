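"""Run configuration: one YAML document describes a whole experiment.

The schema is strict — unknown keys are rejected before any computation —
and round-trips losslessly, so a written config re-read yields an equal
:class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .abm import ModelParams
from .controller import ControllerParams, ControlLoopConfig
from .embedding import EmbeddingSpec
from .errors import ConfigurationError

SCENARIOS = ("nominal", "uncontrolled", "controlled")


@dataclass(frozen=True)
class ScheduleParams:
    """How the random legitimacy step schedule is drawn.

    Explicit ``change_points``/``values`` override the random draw (used
    to pin an adversarial schedule)."""

    n_changes: int = 20
    low: float = 0.6
    high: float = 0.85
    initial: float = 0.82
    change_points: tuple[int, ...] | None = None
    values: tuple[float, ...] | None = None


@dataclass
class RunConfig:
    seed: int = 1
    scenario: str = "nominal"
    run_length: int = 3000
    nominal_legitimacy: float = 0.82
    nominal_propaganda: float = 0.1
    model: ModelParams = field(default_factory=ModelParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    controller: ControllerParams = field(default_factory=ControllerParams)
    loop: ControlLoopConfig = field(default_factory=ControlLoopConfig)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.run_length <= 0:
            raise ConfigurationError("run_length must be positive")


def _dataclass_from_dict(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}"
        )
    return cls(**data)


def _embedding_to_dict(spec: EmbeddingSpec) -> dict:
    return {
        "coordinates": [[c, lag] for c, lag in spec.coordinates],
        "target": spec.target,
        "Tp": spec.Tp,
    }


def _embedding_from_dict(data: dict) -> EmbeddingSpec:
    unknown = set(data) - {"coordinates", "target", "Tp"}
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in embedding")
    coords = tuple((str(c), int(lag)) for c, lag in data["coordinates"])
    return EmbeddingSpec(coords, target=data["target"], Tp=int(data.get("Tp", 1)))


def config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["loop"]["embedding"] = _embedding_to_dict(config.loop.embedding)
    for key in ("change_points", "values"):
        if d["schedule"][key] is not None:
            d["schedule"][key] = list(d["schedule"][key])
    return d


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    sections = {}
    if "model" in data:
        sections["model"] = _dataclass_from_dict(
            ModelParams, data.pop("model"), "model")
    if "schedule" in data:
        sched = dict(data.pop("schedule"))
        for key in ("change_points", "values"):
            if sched.get(key) is not None:
                sched[key] = tuple(sched[key])
        sections["schedule"] = _dataclass_from_dict(
            ScheduleParams, sched, "schedule")
    if "controller" in data:
        sections["controller"] = _dataclass_from_dict(
            ControllerParams, data.pop("controller"), "controller")
    if "loop" in data:
        loop = dict(data.pop("loop"))
        if "embedding" in loop:
            loop["embedding"] = _embedding_from_dict(loop["embedding"])
        sections["loop"] = _dataclass_from_dict(
            ControlLoopConfig, loop, "loop")
    config = _dataclass_from_dict(RunConfig, {**data, **sections}, "config")
    return config


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable digest of the full configuration (logged with every run)."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
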