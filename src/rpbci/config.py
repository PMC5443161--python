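"""Run configuration: YAML/JSON schema with strict validation.

Unknown keys are rejected before any computation so a typo in a config
file fails fast, not silently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import classifiers as clf
from .multiclass import DecompositionScheme
from .pstf import PSTFGrid
from .simulate import SimConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """The configuration violates the schema."""


_METHODS = ("mcs", "oao", "oaa", "dbt", "ddag")


@dataclass
class RunConfig:
    method: str = "ddag"
    ddag_order: str = "RIL"
    algorithm: str = "FLDA"
    odcs_enabled: bool = False
    odcs_m_best: int = 3
    odcs_val_folds: int = 5
    pstf_low_pass: list = field(default_factory=lambda: [1, 3])
    pstf_high_pass: list = field(default_factory=lambda: [None])
    pstf_gamma: list = field(default_factory=lambda: [1e3, 1e5])
    pstf_window: list = field(default_factory=lambda: [5, 10])
    pstf_inner_folds: int = 5
    classifier_algorithms: list = field(default_factory=lambda: list(clf.ALGORITHMS))
    rls_lambda: list = field(default_factory=lambda: list(clf.DEFAULT_RLS_LAMBDAS))
    working_fs: float = 100.0
    n_chunks: int = 10
    shuffle_chunks: bool = False
    seed: int = 0
    sim: dict | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}, got {self.method!r}")
        for a in self.classifier_algorithms + [self.algorithm]:
            if a not in clf.ALGORITHMS:
                raise ConfigError(f"unknown classification algorithm {a!r}")
        if not (1 <= self.odcs_m_best <= len(clf.ALGORITHMS)):
            raise ConfigError("odcs.m_best must lie in 1..5")
        if self.sim is not None:
            try:
                SimConfig(**self.sim)
            except TypeError as exc:
                raise ConfigError(f"invalid sim key: {exc}") from exc
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc

    # -- derived objects ---------------------------------------------------
    def scheme(self, method: str | None = None) -> DecompositionScheme:
        return DecompositionScheme(kind=method or self.method,
                                   ddag_order=self.ddag_order)

    def grid(self) -> PSTFGrid:
        return PSTFGrid(
            low_pass_candidates=tuple(self.pstf_low_pass),
            high_pass_candidates=tuple(self.pstf_high_pass),
            gamma_candidates=tuple(self.pstf_gamma),
            window_candidates=tuple(self.pstf_window),
        )

    def sim_config(self) -> SimConfig:
        return SimConfig(**(self.sim or {}))

    def to_dict(self) -> dict:
        return asdict(self)


_NESTED = {
    "odcs": {"enabled": "odcs_enabled", "m_best": "odcs_m_best",
             "val_folds": "odcs_val_folds"},
    "pstf": {"low_pass": "pstf_low_pass", "high_pass": "pstf_high_pass",
             "gamma": "pstf_gamma", "window": "pstf_window",
             "inner_folds": "pstf_inner_folds"},
    "classifiers": {"algorithms": "classifier_algorithms",
                    "rls_lambda": "rls_lambda"},
}


def load_config(path: str | Path | None = None,
                data: dict | None = None) -> RunConfig:
    """Parse and validate a YAML/JSON config file (or an in-memory dict)."""
    if data is None:
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    flat: dict = {}
    for key, value in data.items():
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub, subval in value.items():
                if sub not in _NESTED[key]:
                    raise ConfigError(f"unknown key {key}.{sub!r}")
                flat[_NESTED[key][sub]] = subval
        elif key in known:
            flat[key] = value
        else:
            raise ConfigError(f"unknown key {key!r}")
    return RunConfig(**flat)
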