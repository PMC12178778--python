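"""Pipeline configuration: YAML loading, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .expression import HVGParams
from .prioritize import PrioritizationConfig
from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs besides the input files."""

    seed: int = 0
    simulation: SimulationConfig = None  # type: ignore[assignment]
    hvg: HVGParams = field(default_factory=HVGParams)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    top_k: int = 10
    sensitivity_thresholds: tuple[int, ...] = (0, 50, 100, 200)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        elif self.simulation.seed != self.seed:
            # the master seed wins; keeps `--seed` authoritative
            self.simulation = SimulationConfig(
                **{**asdict(self.simulation), "seed": self.seed}
            )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        known = {"seed", "simulation", "hvg", "prioritization", "top_k",
                 "sensitivity_thresholds", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if seed is not None:
            raw["seed"] = seed
        kwargs = dict(raw)
        try:
            if "simulation" in kwargs:
                sim = dict(kwargs["simulation"])
                sim.setdefault("seed", kwargs.get("seed", 0))
                for key in ("n_variants_per_gene", "allele_freq_log10_range",
                            "cohort_size_range", "planted_candidates",
                            "planted_top_genes"):
                    if key in sim and sim[key] is not None:
                        sim[key] = tuple(sim[key])
                kwargs["simulation"] = SimulationConfig(**sim)
            if "hvg" in kwargs:
                kwargs["hvg"] = HVGParams(**kwargs["hvg"])
            if "prioritization" in kwargs:
                kwargs["prioritization"] = PrioritizationConfig(**kwargs["prioritization"])
            if "sensitivity_thresholds" in kwargs:
                kwargs["sensitivity_thresholds"] = tuple(kwargs["sensitivity_thresholds"])
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"invalid config: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()
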