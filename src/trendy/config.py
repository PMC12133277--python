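"""YAML run configuration: simulation, model, training and inference
settings behind one validated object with the benchmark defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # simulation (SDE of expression dynamics)
    V: float = 30.0
    beta: float = 1.0
    theta: float = 0.2
    sigma: float = 0.1
    dt: float = 0.01
    t_end: float = 1.0
    n_cells: int = 100
    n_genes: int = 10
    # covariance estimation
    glasso_penalty: float = 0.01
    t_pair: tuple[float, float] = (0.5, 1.0)
    # TE(k) model
    d: int = 64
    l: int = 7
    h_te1: int = 4
    h_te3: int = 8
    dropout: float = 0.1
    # training
    learning_rate: float = 0.001
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 16
    # run plumbing
    seed: int = 0
    out_dir: str = "trendy_out"
    verbosity: int = 1

    def __post_init__(self) -> None:
        checks = {
            "V": self.V > 0,
            "beta": self.beta > 0,
            "theta": self.theta > 0,
            "sigma": self.sigma >= 0,
            "dt": self.dt > 0,
            "t_end": self.t_end > 0,
            "n_cells": self.n_cells >= 1,
            "n_genes": self.n_genes >= 2,
            "glasso_penalty": self.glasso_penalty >= 0,
            "d": self.d > 0 and self.d % 4 == 0,
            "l": self.l >= 1,
            "dropout": 0 <= self.dropout < 1,
            "learning_rate": self.learning_rate > 0,
            "max_epochs": self.max_epochs >= 1,
            "patience": 1 <= self.patience < self.max_epochs,
            "batch_size": self.batch_size >= 1,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError("invalid config value(s) for: " + ", ".join(bad))
        if isinstance(self.t_pair, list):
            self.t_pair = tuple(self.t_pair)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["t_pair"] = list(self.t_pair)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are an error, missing keys default."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    return RunConfig(**raw)
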