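"""Run configuration, provenance records, and logging setup."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .integrate import DEFAULT_DT
from .model import ModelParameters

__all__ = ["RunConfig", "provenance", "write_provenance", "setup_logging"]

_PRESETS = {
    "noise": ModelParameters.noise,
    "deterministic": ModelParameters.deterministic,
}


@dataclass
class RunConfig:
    """Fully serializable description of a run.

    A stored config re-executes to identical results: deterministic
    runs exactly, stochastic runs identically for the stored seed.
    """

    preset: str = "noise"
    overrides: dict = field(default_factory=dict)
    dt: float = DEFAULT_DT
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_rate: float = 1000.0
    rule_mode: str = "eeg_threshold"
    horizon: float = 3.0
    vicinity_radius: float = 0.1
    n_trials: int = 20
    seed: int = 0
    t_end: float = 10.0
    outdir: str = "."

    def params(self) -> ModelParameters:
        if self.preset not in _PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; use one of {sorted(_PRESETS)}"
            )
        return _PRESETS[self.preset](**self.overrides)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text) -> "RunConfig":
        if hasattr(text, "read"):
            text = text.read()
        return cls(**yaml.safe_load(text))


def provenance(config: RunConfig, **extra) -> dict:
    from . import __version__

    rec = {
        "package": "spikewave",
        "version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
    }
    rec.update(extra)
    return rec


def write_provenance(path, config: RunConfig, **extra) -> None:
    with open(path, "w") as fh:
        json.dump(provenance(config, **extra), fh, indent=2, default=str)


def setup_logging(outdir, name: str = "spikewave") -> logging.Logger:
    """Per-run log file capturing solver warnings and trial failures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger(name)
    logger.setLevel(logging.INFO)
    handler = logging.FileHandler(outdir / f"{name}.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    return logger
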