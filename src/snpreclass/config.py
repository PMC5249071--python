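"""Run configuration: a flat, explicit record of every knob of a pipeline run.

A configuration either points at input files (panel table, risk
distribution table) or asks for the built-in stand-ins (the calibrated
synthetic reference panel; the coarse BCSC screening marginals).  The seed
is mandatory — there is no silent nondeterminism — and the manifest written
by the pipeline echoes the full configuration so any run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .panel import SnpPanel, generate_reference_panel, read_panel
from .population import RiskDistribution, bcsc_screening_marginals, read_risk_distribution
from .reclassification import DEFAULT_STRATEGIES

__all__ = ["RunConfig", "load_config", "build_panel", "build_prior_distribution"]

#: sentinel for the built-in coarse screening-population marginals
BUILTIN_MARGINALS = "bcsc-coarse"


@dataclass
class RunConfig:
    """All inputs of one end-to-end run."""

    seed: int
    panel_path: Optional[str] = None
    n_snps: int = 70
    freq_range: tuple[float, float] = (0.05, 0.5)
    or_range: tuple[float, float] = (1.03, 1.15)
    risk_distribution: str = BUILTIN_MARGINALS
    prevalence: float = 0.05
    treat_threshold: float = 0.03
    strategies: Sequence[Sequence[Optional[float]]] = field(
        default_factory=lambda: [list(s) for s in DEFAULT_STRATEGIES]
    )
    n: int = 200_000
    n_cases: int = 5000
    n_controls: int = 5000
    fh_rate: float = 0.114
    fh_relative_risk: float = 2.0
    output_dir: str = "snpreclass_out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent nondeterminism)")
        self.seed = int(self.seed)
        if self.panel_path is not None and not os.path.exists(self.panel_path):
            raise FileNotFoundError(f"panel file not found: {self.panel_path}")
        if self.risk_distribution != BUILTIN_MARGINALS and not os.path.exists(
            self.risk_distribution
        ):
            raise FileNotFoundError(
                f"risk distribution file not found: {self.risk_distribution} "
                f"(use {BUILTIN_MARGINALS!r} for the built-in marginals)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["freq_range"] = list(self.freq_range)
        d["or_range"] = list(self.or_range)
        d["strategies"] = [list(s) for s in self.strategies]
        return d


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Load a YAML configuration file; keyword overrides win over the file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"config file {path}: unknown key(s) {sorted(unknown)}")
    return RunConfig(**data)


def panel_seed_sequence(config: RunConfig) -> np.random.SeedSequence:
    """The dedicated child stream for panel generation (root stream, key 0)."""
    return np.random.SeedSequence(config.seed, spawn_key=(0,))


def analysis_seed_sequence(config: RunConfig) -> np.random.SeedSequence:
    """The dedicated child stream for the simulation stages (root, key 1)."""
    return np.random.SeedSequence(config.seed, spawn_key=(1,))


def build_panel(config: RunConfig) -> SnpPanel:
    """Load the panel file, or generate the reference panel from the config."""
    if config.panel_path is not None:
        return read_panel(config.panel_path)
    return generate_reference_panel(
        n_snps=config.n_snps,
        freq_range=tuple(config.freq_range),
        or_range=tuple(config.or_range),
        seed=np.random.default_rng(panel_seed_sequence(config)),
    )


def build_prior_distribution(config: RunConfig) -> RiskDistribution:
    if config.risk_distribution == BUILTIN_MARGINALS:
        return bcsc_screening_marginals()
    return read_risk_distribution(config.risk_distribution)


def dump_manifest(config: RunConfig, path: str | os.PathLike, **extra) -> None:
    payload = {"config": config.to_dict(), **extra}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
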