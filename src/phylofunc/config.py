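"""Run configuration: every tunable threshold of the pipeline in one record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline thresholds, boosting hyperparameters and the RNG seed.

    Defaults are the study conventions: features dropped when below
    0.001 relative abundance in at least 90% of samples, metadata
    dropped above 10% missingness, outlier outer fence at 3x IQR,
    covariates selected when used in at least 1% of boosting
    iterations, significance called at q < 0.25.
    """

    low_abundance: float = 0.001
    prevalence: float = 0.90
    fence_multiplier: float = 3.0
    max_missing: float = 0.10
    boost_selection_fraction: float = 0.01
    q_threshold: float = 0.25
    seed: int = 0
    # boosting hyperparameters: additive stumps, slow learning, row subsampling
    boost_n_estimators: int = 1000
    boost_learning_rate: float = 0.01
    boost_subsample: float = 0.5
    # "split_fraction": covariate used in >= threshold of iterations;
    # "influence": normalized squared-error gain share >= threshold
    selection_mode: str = "split_fraction"
    # impute missing feature cells with the feature's mean across samples
    # ("feature") or the sample's mean across features ("sample")
    impute_mode: str = "feature"

    def __post_init__(self) -> None:
        if not 0 <= self.low_abundance < 1:
            raise ValueError("low_abundance must be in [0, 1)")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if self.fence_multiplier <= 0:
            raise ValueError("fence_multiplier must be positive")
        if not 0 <= self.max_missing < 1:
            raise ValueError("max_missing must be in [0, 1)")
        if not 0 < self.boost_selection_fraction <= 1:
            raise ValueError("boost_selection_fraction must be in (0, 1]")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if self.boost_n_estimators < 1:
            raise ValueError("boost_n_estimators must be >= 1")
        if not 0 < self.boost_subsample <= 1:
            raise ValueError("boost_subsample must be in (0, 1]")
        if self.selection_mode not in ("split_fraction", "influence"):
            raise ValueError("selection_mode must be 'split_fraction' or 'influence'")
        if self.impute_mode not in ("feature", "sample"):
            raise ValueError("impute_mode must be 'feature' or 'sample'")
        self.seed = int(self.seed)
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
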