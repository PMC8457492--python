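"""Pipeline configuration: a plain YAML-compatible schema.

A single global seed fans out deterministically to every stage (design
randomization, each simulated subject, each permutation test) through
:class:`numpy.random.SeedSequence`, so stages are individually reproducible
without coupling their random streams.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .design import DesignConfig

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "AnalysisConfig",
    "PipelineConfig",
    "config_hash",
    "stage_seeds",
]


@dataclass(frozen=True)
class GroupSpec:
    """One simulated cohort group: its size and base observer preset."""

    n: int = 10
    preset: str = "sc_like"


@dataclass(frozen=True)
class CohortConfig:
    """Simulated cohort layout and per-subject parameter jitter.

    Each subject's cue weights are the preset weights plus Gaussian jitter
    (sd ``weight_jitter_sd``, truncated at 0), and the internal noise is
    jittered likewise (sd ``noise_jitter_sd``); the lapse rate is shared.
    """

    groups: dict = field(
        default_factory=lambda: {
            "EB": GroupSpec(10, "eb_like"),
            "SC": GroupSpec(10, "sc_like"),
        }
    )
    weight_jitter_sd: float = 0.1
    noise_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        groups = {
            k: (v if isinstance(v, GroupSpec) else GroupSpec(**v))
            for k, v in self.groups.items()
        }
        object.__setattr__(self, "groups", groups)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis knobs: significance level, permutation count and the two
    documented construction switches (radial sign rule, ellipse method)."""

    alpha: float = 0.05
    n_iter: int = 5000
    sign_rule: str = "speed"  # or "y": sign radial r by the vertical coordinate
    ellipse_method: str = "direct"  # or "conic": free conic fit, may reject subjects
    sigma_ceiling_factor: float = 10.0
    # fixed guess/lapse floor of the fitted curve: robustness of the slope
    # estimate against stimulus-independent errors at saturated levels
    fit_p_floor: float = 0.01


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs."""

    design: DesignConfig = field(default_factory=DesignConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.design, dict):
            object.__setattr__(self, "design", DesignConfig(**self.design))
        if isinstance(self.cohort, dict):
            object.__setattr__(self, "cohort", CohortConfig(**self.cohort))
        if isinstance(self.analysis, dict):
            object.__setattr__(self, "analysis", AnalysisConfig(**self.analysis))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the canonical YAML form of a config."""
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]


def stage_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit stage seeds from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
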