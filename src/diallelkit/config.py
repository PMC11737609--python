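"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Traits carried through the analysis stages by default (the generator
#: writes more; see simulate.TRAIT_COLUMNS).
DEFAULT_ANALYSIS_TRAITS = ("GY", "FD1", "FD2", "FD3", "ED", "AD", "SD", "PH", "EH", "ER")

DEFAULT_CHECKS = ("WE1101", "Duma43", "DK8031", "DH04")


@dataclass
class RunConfig:
    """Everything needed for a reproducible simulate-to-summaries run.

    Defaults mirror the motivating study: 21 parents (210 hybrids), two
    environments, two replicates, alpha-lattice blocks, four commercial
    checks, SNP QC at MAF > 0.05 and missingness < 10%, fivefold CV.
    """

    p: int = 21
    n_env: int = 2
    n_rep: int = 2
    block_size: int = 10
    checks: tuple[str, ...] = DEFAULT_CHECKS
    seed: int = 1

    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    n_causal: int = 200

    maf_min: float = 0.05
    max_missing: float = 0.10
    cv_folds: int = 5

    outlier_threshold: float = 3.5
    traits: tuple[str, ...] = DEFAULT_ANALYSIS_TRAITS
    marker_traits: tuple[str, ...] = ("GY",)
    top_n: int = 15
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for any stochastic step")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError(f"maf_min must be in [0, 0.5), got {self.maf_min}")
        if not (0.0 < self.max_missing <= 1.0):
            raise ValueError(f"max_missing must be in (0, 1], got {self.max_missing}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("checks", "traits", "marker_traits", "maf_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
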