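"""Analysis configuration shared by all pipeline stages.

Thresholds mirror the study design they encode: raw per-probe significance at
0.05 (no FDR by default, Benjamini–Hochberg available as an opt-in), the
top-500 signature, 1-kb DMR merging, the 0.2 delta-beta longitudinal cutoff,
the 20–80% "dynamic CpG" band and the tenfold minimum sequencing coverage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    #: per-probe significance level for ANOVA and Tukey calls
    alpha_sig: float = 0.05
    #: number of most-significant probes forming the clustering signature
    top_k: int = 500
    #: maximum gap (bp) between significant CpGs merged into one DMR
    merge_distance_bp: int = 1000
    #: |delta beta| that must be *exceeded* to call a longitudinal change
    delta_beta_cutoff: float = 0.2
    #: inclusive bounds of the intermediate-methylation "dynamic" band
    dynamic_low: float = 0.2
    dynamic_high: float = 0.8
    #: minimum per-sample coverage for a CpG to enter capture-mode analyses
    min_coverage: int = 10
    #: treat min_coverage as strict (>) instead of inclusive (>=)
    coverage_exclusive: bool = False
    #: probes with SNP minor allele frequency strictly above this are dropped
    maf_cutoff: float = 0.01
    #: apply Benjamini–Hochberg to per-probe ANOVA p-values
    bh_correct: bool = False
    #: contamination verdict: implied per-ICR alphas must have CV below this
    #: to count as uniform (i.e. genuine somatic admixture)
    contamination_cv_threshold: float = 0.5
    #: estimated somatic fraction above which a sample is suspect
    contamination_alpha_threshold: float = 0.1
    #: robust z-score on ICR-mean principal components that flags an outlier
    outlier_z_threshold: float = 3.5
    #: number of principal components examined for outliers
    n_components: int = 2
    #: seed for any randomised step (e.g. random-probe control draws)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_sig < 1:
            raise ValueError("alpha_sig must be in (0, 1)")
        if not self.dynamic_low < self.dynamic_high:
            raise ValueError("dynamic_low must be < dynamic_high")
        for name in ("top_k", "merge_distance_bp", "min_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("delta_beta_cutoff", "maf_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)
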