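"""Pipeline configuration: YAML round-trip, validation, config hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .battery import BatteryConfig
from .grammars import DEFAULT_CANDIDATES, TARGET_GRAMMARS, get_grammar
from .glmm import GLMMSpec, MCMCConfig
from .simulate import SimConfig


@dataclass(frozen=True)
class PipelineConfig:
    grammars: tuple[str, ...] = TARGET_GRAMMARS
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    model: GLMMSpec = field(default_factory=GLMMSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    seed: int = 0
    multiresponse: bool = False

    def __post_init__(self) -> None:
        for name in tuple(self.grammars) + tuple(self.candidates):
            get_grammar(name)  # raises on unknown names
        if self.sim.n_participants < 1:
            raise ValueError("configuration requires at least one participant")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim.cross_grammar_corr is not None:
            d["sim"]["cross_grammar_corr"] = [
                [float(v) for v in row] for row in self.sim.cross_grammar_corr
            ]
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs: dict = {}
    if "grammars" in raw:
        kwargs["grammars"] = tuple(raw["grammars"])
    if "candidates" in raw:
        kwargs["candidates"] = tuple(raw["candidates"])
    if "battery" in raw:
        b = dict(raw["battery"])
        if "exposure_n" in b:
            b["exposure_n"] = tuple(b["exposure_n"])
        if "test_n_seen" in b:
            b["test_n_seen"] = tuple(b["test_n_seen"])
        kwargs["battery"] = BatteryConfig(**b)
    if "sim" in raw:
        kwargs["sim"] = SimConfig(**raw["sim"])
    if "model" in raw:
        kwargs["model"] = GLMMSpec(**raw["model"])
    if "mcmc" in raw:
        kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
    for key in ("seed", "multiresponse"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    d["config_hash"] = cfg.hash()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
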