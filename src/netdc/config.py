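"""Pipeline configuration with validated defaults.

Defaults follow the published analysis settings this pipeline mirrors:
drop the first 10 volumes, band-pass 0.01-0.08 Hz, 6 mm FWHM smoothing,
degree-centrality threshold r > 0.25, cluster forming threshold p < 0.001,
cluster-level FDR q < 0.05, 1,000 label permutations, linear SVM with C = 1,
and a top-20% weight-map fraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError

_CONNECTIVITY_CHOICES = (6, 18, 26)


@dataclass
class PipelineConfig:
    n_drop: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    fwhm_mm: float = 6.0
    r_threshold: float = 0.25
    use_absolute_r: bool = False     # count |r| > threshold instead of r > threshold
    weighted_dc: bool = False        # sum supra-threshold r instead of counting
    voxel_p: float = 0.001
    cluster_q: float = 0.05
    connectivity: int = 26
    n_permutations: int = 1000
    svm_C: float = 1.0
    top_fraction: float = 0.20
    rng_seed: int = 0
    pair_folds: bool = True          # leave one subject from EACH group out per fold
    standardize_features: bool = False
    patient_only_correlations: bool = True
    assoc_bh_correction: bool = False
    # Head-motion exclusion rule; recorded as metadata (realignment is upstream
    # of this pipeline) and applied only as a phenotype include-flag filter.
    motion_limit_mm: float = 2.5
    motion_limit_deg: float = 2.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_drop < 0:
            raise ConfigurationError(f"n_drop must be >= 0, got {self.n_drop}")
        if not (0 <= self.band_low_hz < self.band_high_hz):
            raise ConfigurationError(
                f"band must satisfy 0 <= low < high, got ({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.fwhm_mm < 0:
            raise ConfigurationError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")
        if not (-1 < self.r_threshold < 1):
            raise ConfigurationError(f"r_threshold must lie in (-1, 1), got {self.r_threshold}")
        if not (0 < self.voxel_p < 1):
            raise ConfigurationError(f"voxel_p must lie in (0, 1), got {self.voxel_p}")
        if not (0 < self.cluster_q < 1):
            raise ConfigurationError(f"cluster_q must lie in (0, 1), got {self.cluster_q}")
        if self.connectivity not in _CONNECTIVITY_CHOICES:
            raise ConfigurationError(
                f"connectivity must be one of {_CONNECTIVITY_CHOICES}, got {self.connectivity}"
            )
        if self.n_permutations < 1:
            raise ConfigurationError(f"n_permutations must be >= 1, got {self.n_permutations}")
        if self.svm_C <= 0:
            raise ConfigurationError(f"svm_C must be > 0, got {self.svm_C}")
        if not (0 < self.top_fraction <= 1):
            raise ConfigurationError(f"top_fraction must lie in (0, 1], got {self.top_fraction}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
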