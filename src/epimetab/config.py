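"""Pipeline configuration: every threshold in one place.

Defaults are the published analysis cutoffs: genes with mean TPM < 1 excluded;
differential expression at FDR < 0.05 with |FC| >= 1.5 (microarray profile:
|log2FC| > 1, FDR < 0.05); recurrence across >= 8 cohorts; differential
methylation at P < 0.05 with |delta-beta| > 0.2 under both the tumor-vs-normal
and the top/bottom-decile driver-expression contrasts; integration at
delta-beta > 0.2 with Spearman r < -0.2; log-rank significance at P < 0.05;
mutated-arm minimum of 20 samples; enrichment at P < 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # expression filtering / calling
    min_mean_tpm: float = 1.0
    de_fdr: float = 0.05
    de_fc: float = 1.5
    geo_logfc: float = 1.0
    recurrence_min_cancers: int = 8
    # regularized-t engine
    prior_df: float = 10.0
    window_size: int = 101
    expr_pseudocount: float = 1.0
    welch: bool = False
    # differential methylation
    dm_p: float = 0.05
    dm_delta_beta: float = 0.2
    extreme_fraction: float = 0.10
    promoter_window_bp: int = 1500
    require_same_direction: bool = True
    # integration
    integration_delta_beta: float = 0.2
    integration_r: float = -0.2
    include_normals_in_correlation: bool = False
    # survival
    survival_p: float = 0.05
    cox_ties: str = "breslow"
    # mutation stratification
    mutation_min_group: int = 20
    min_group_both_arms: bool = False
    # enrichment
    enrichment_p: float = 0.05
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ["min_mean_tpm", "de_fdr", "de_fc", "geo_logfc",
                    "recurrence_min_cancers", "dm_p", "dm_delta_beta",
                    "survival_p", "mutation_min_group", "enrichment_p",
                    "window_size", "promoter_window_bp"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be > 0")
        if not 0 < self.extreme_fraction < 0.5:
            raise ValueError("extreme_fraction must be in (0, 0.5)")
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.integration_r >= 0:
            raise ValueError("integration_r is an anticorrelation cutoff; must be < 0")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.cox_ties not in ("breslow", "efron"):
            raise ValueError("cox_ties must be 'breslow' or 'efron'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat key: value YAML file; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
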