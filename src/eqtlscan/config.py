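"""Pipeline configuration.

All tunable thresholds of the analysis live in :class:`PipelineConfig`.
The defaults are the production settings: a ±100 kb cis window, emission
p-value thresholds of 0.02 (cis) and 1e-6 (trans), significance at
BH FDR <= 0.05, MAF filter > 0.01, LD pruning at r^2 < 0.2 with a
50-SNP/5-SNP sliding window, expression filters of >= 200 total counts
and < 70-of-75 zero samples, the n >= 7 cis-hotspot rule, the
99th-percentile trans-hotspot rule with 100,000 permutations, and a
kappa threshold of 0.4 for term clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    cis_window: int = 100_000          # bp, inclusive on both sides of the gene body
    p_cis: float = 0.02                # cis emission p-value threshold
    p_trans: float = 1e-6              # trans emission p-value threshold
    fdr_max: float = 0.05              # BH FDR significance cutoff
    maf_min: float = 0.01              # keep strictly MAF > maf_min
    ld_r2_max: float = 0.2             # prune pairs with r^2 >= this
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    min_gene_total: int = 200          # keep genes with row sum >= this
    zero_sample_limit: int | None = None  # None -> ceil(70/75 * n) at run time
    cis_hotspot_min_genes: int = 7
    trans_hotspot_percentile: float = 99.0
    n_permutations: int = 100_000
    kappa_min: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cis", "p_trans", "fdr_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.cis_window < 0:
            raise ConfigError(f"cis_window must be >= 0, got {self.cis_window}")
        if not (0.0 < self.trans_hotspot_percentile < 100.0):
            raise ConfigError(
                "trans_hotspot_percentile must be in (0, 100), got "
                f"{self.trans_hotspot_percentile}"
            )
        if not (0.0 <= self.maf_min < 0.5):
            raise ConfigError(f"maf_min must be in [0, 0.5), got {self.maf_min}")
        if self.ld_window_snps < 2:
            raise ConfigError("ld_window_snps must be >= 2")
        if self.ld_step_snps < 1:
            raise ConfigError("ld_step_snps must be >= 1")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)},
                fh,
                sort_keys=False,
            )

    def zero_limit_for(self, n_samples: int) -> int:
        """Zero-count sample limit, rescaled when the cohort is not 75.

        The production filter removes genes with zero counts in >= 70 of
        75 samples;
        for other cohort sizes the default keeps the same fraction,
        rounded up.
        """
        if self.zero_sample_limit is not None:
            return self.zero_sample_limit
        import math

        return math.ceil(70 / 75 * n_samples)
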