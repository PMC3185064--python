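"""Pipeline configuration: every numeric threshold in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and switches governing the discovery pipeline.

    Defaults reflect the protocol the pipeline implements: libraries must
    exceed 50,000 raw tags (strict); tags must reach >= 2 counts in >= 3
    libraries; ubiquitous expression means detection in strictly more than
    90% of libraries; tissue exclusivity requires >= 10 TPM in exactly one
    tissue; heatmap display caps at 300 TPM; differential expression uses
    BH-adjusted p < 0.05 with >= 2-fold change and >= 5 libraries per
    group.  Every boundary's strictness is fixed, but the value itself is
    configurable.
    """

    min_library_depth: int = 50_000        # strictly greater than
    tag_min_count: int = 2                 # >= counts ...
    tag_min_libraries: int = 3             # ... in >= this many libraries
    ubiquitous_fraction: float = 0.90      # strictly more than this fraction
    exclusive_min_tpm: float = 10.0
    tissue_mean_tpm: float = 20.0          # detection floor for atlas summaries
    heatmap_cap: float = 300.0             # display-only TPM ceiling
    de_alpha: float = 0.05
    de_min_fold: float = 2.0
    de_min_group_size: int = 5
    n_permutations: int = 10_000
    rng_seed: int = 0
    density_window: float = 1e8            # bp per density unit (100 Mb)
    require_catg_prefix: bool = True       # match CATG+tag 14-mers, not bare 10-mers
    tpm_full_library_denominator: bool = True
    exclusive_tolerance: float = 0.0       # TPM allowed in non-exclusive tissues

    def __post_init__(self) -> None:
        numeric = {k: v for k, v in asdict(self).items()
                   if isinstance(v, (int, float)) and not isinstance(v, bool)}
        for key, value in numeric.items():
            if value < 0:
                raise ValueError(f"{key} must be >= 0, got {value}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
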