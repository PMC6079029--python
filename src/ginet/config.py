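"""Pipeline-wide thresholds with YAML override support."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class PipelineConfig:
    """Defaults for every stage; all distances in bp.

    ``maf_min``/``hwe_alpha``/``call_rate_min`` drive variant QC;
    ``cis_flank`` bounds the instrument's SNP universe; ``neighbour_radius``
    defines which GIs are conditioned on; ``trans_min_dist`` defines trans
    candidates; ``f_threshold`` is the weak-instrument cut; ``alpha`` the
    family-wise level for Bonferroni control.
    """

    maf_min: float = 0.01
    hwe_alpha: float = 1e-4
    call_rate_min: float = 0.95
    cis_flank: int = 100_000
    neighbour_radius: int = 1_000_000
    trans_min_dist: int = 10_000_000
    f_threshold: float = 10.0
    alpha: float = 0.05
    k_factors: int = 5
    cv_folds: int = 5
    train_frac: float = 1.0 / 3.0
    seed: int = 2018

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
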