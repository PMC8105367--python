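"""Run configuration and deterministic seeding shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

DEFAULT_THRESHOLDS = {
    "corr_cutoff": 0.3,  # immune-gene Pearson cutoff vs leukocyte fraction / purity
    "rsf_p": 0.05,       # RSF permutation-importance p for pathway/gene selection
    "gene_p": 0.05,      # survival-screen p for candidate IPMG membership
    "maf": 0.05,         # minor-allele-frequency floor for SNP association
}


@dataclass
class RunConfig:
    """Constants governing a full pipeline run.

    The defaults are the study settings: a 3-year cap for the survival
    screen, a 1-year horizon for the classifier label, 1000 resamples for the
    pathway-specificity null, 5000 for the stratification control, and 1000
    balanced validation sets for model evaluation.
    """

    seed: int = 0
    survival_cap_years_screen: float = 3.0
    survival_cap_years_model: float = 1.0
    n_specificity_resamples: int = 1000
    n_cluster_resamples: int = 5000
    n_validation_sets: int = 1000
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        for name in ("n_specificity_resamples", "n_cluster_resamples", "n_validation_sets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.survival_cap_years_screen <= 0 or self.survival_cap_years_model <= 0:
            raise ValueError("survival caps must be positive")
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key, val in self.thresholds.items():
            if not (0.0 < float(val) < 1.0):
                raise ValueError(f"threshold {key}={val} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed.

    Uses numpy's SeedSequence spawn-key mechanism keyed on the stage name so
    stages can be rerun in isolation and remain independent of each other.
    The result is kept below 2**31.
    """
    key = [ord(c) for c in stage]
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded deterministically for one named stage."""
    return np.random.default_rng(child_seed(seed, stage))
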