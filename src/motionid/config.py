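"""Run configuration: defaults mirroring the study protocol, YAML-loadable."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .experiments import DEFAULT_N_DECOYS
from .models import HyperparameterGrid, TransformerConfig
from .synthetic import DEFAULT_SEPARATION, ProtocolSpec

__all__ = ["RunConfig", "ConfigError", "VALID_EXPERIMENTS", "VALID_MODELS"]

VALID_MODELS = ("knn", "rf", "nn", "swipeformer")
VALID_EXPERIMENTS = ("rq1", "rq2", "rq3", "rq4")


class ConfigError(ValueError):
    """Invalid configuration; the message lists every violation."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation + analysis run."""

    n_users: int = 36
    seed: int = 7
    separation: float = DEFAULT_SEPARATION
    laying_minutes: int = 10
    sitting_minutes: int = 5
    sample_rate_hz: int = 100
    n_decoys: int = DEFAULT_N_DECOYS
    models: tuple[str, ...] = ("knn", "rf", "nn")
    experiments: tuple[str, ...] = ("rq1",)
    n_targets: int | None = None  # cap on targets per experiment (reduced scale)
    transformer_epochs: int = 15

    def validate(self) -> None:
        problems = []
        if self.n_users < 2:
            problems.append("n_users must be >= 2 (authentication needs negatives)")
        if self.n_users - self.n_decoys < 2:
            problems.append("n_users must exceed n_decoys by at least 2")
        if self.separation < 0:
            problems.append("separation must be non-negative")
        if self.laying_minutes < 1 or self.sitting_minutes < 1:
            problems.append("protocol minutes must be >= 1")
        if self.sample_rate_hz < 16:
            problems.append("sample_rate_hz must be >= 16 (twice the tremor band)")
        for m in self.models:
            if m not in VALID_MODELS:
                problems.append(f"unknown model {m!r}; valid: {', '.join(VALID_MODELS)}")
        for e in self.experiments:
            if e not in VALID_EXPERIMENTS:
                problems.append(
                    f"unknown experiment {e!r}; valid: {', '.join(VALID_EXPERIMENTS)}"
                )
        if self.n_targets is not None and self.n_targets < 1:
            problems.append("n_targets must be >= 1 when given")
        if self.transformer_epochs < 0:
            problems.append("transformer_epochs must be >= 0")
        if problems:
            raise ConfigError("invalid configuration:\n- " + "\n- ".join(problems))

    @property
    def protocol(self) -> ProtocolSpec:
        return ProtocolSpec(
            laying_minutes=self.laying_minutes,
            sitting_minutes=self.sitting_minutes,
            sample_rate_hz=self.sample_rate_hz,
        )

    def grid(self) -> HyperparameterGrid:
        return HyperparameterGrid()

    def transformer_config(self, seed: int) -> TransformerConfig:
        return TransformerConfig(
            sequence_length=self.sample_rate_hz,
            epochs=self.transformer_epochs,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["experiments"] = list(self.experiments)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"{path}: unknown config key(s): {', '.join(sorted(unknown))}"
            )
        for key in ("models", "experiments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
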