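"""Pipeline configuration: defaults, YAML loading, provenance hashing.

Defaults mirror the study conditions: a 1 mg/L CdCl2 spike, an 80 h assay
at 25 degC with the P subsample at 37 h when no activity peak is found,
999 permutations for distance-based tests, Cd categories with bounds at
1 and 2 mg/kg, and a prevalence/detection occurrence threshold of
0.001 / 1-in-100 relative abundance for core-taxon calls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash", "provenance_line"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs shared across pipeline stages.

    Attributes
    ----------
    random_seed : int
        Seed for every randomized stage; identical seed + inputs gives
        identical outputs.
    alpha : float
        Significance level for BH-adjusted calls.
    n_permutations : int
        Permutations for PERMANOVA-style tests.
    pseudo_count : float
        Added to counts before taking logs in the differential-abundance
        model.
    cd_low_high_bound, cd_medium_high_bound : float
        Category bounds in mg/kg; low [0, b1), medium [b1, b2), high [b2, inf).
        Left-closed so every concentration maps to exactly one category.
    spike_dose : float
        CdCl2 amendment, mg/L.
    assay_hours : float
        Calorimetry assay duration.
    fallback_peak_hour : float
        P-subsample time when no activity peak qualifies.
    peak_smooth_window : int
        Moving-average window (points) applied before peak detection.
    peak_min_prominence : float
        Minimum peak prominence (mW) for a peak to qualify.
    prevalence_threshold : float
        Fraction of a group's samples a taxon must occur in.
    detection_threshold : float
        Relative abundance at which a taxon counts as present (1/100).
    rarefy : bool
        Subsample all libraries to the minimum depth before diversity
        analysis. Off by default; depth-evening is ambiguous in practice.
    """

    random_seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 999
    pseudo_count: float = 0.5
    cd_low_high_bound: float = 1.0
    cd_medium_high_bound: float = 2.0
    spike_dose: float = 1.0
    assay_hours: float = 80.0
    fallback_peak_hour: float = 37.0
    peak_smooth_window: int = 5
    peak_min_prominence: float = 0.05
    prevalence_threshold: float = 0.001
    detection_threshold: float = 0.01
    rarefy: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.cd_low_high_bound < self.cd_medium_high_bound:
            raise ValueError("Cd category bounds must be strictly increasing")
        for name in (
            "n_permutations",
            "pseudo_count",
            "cd_low_high_bound",
            "spike_dose",
            "assay_hours",
            "fallback_peak_hour",
            "prevalence_threshold",
            "detection_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def cd_category_bounds(self) -> tuple[float, float]:
        return (self.cd_low_high_bound, self.cd_medium_high_bound)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    CLI flags map to the overrides and therefore win over file values.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(loaded) - {f.name for f in dataclasses.fields(PipelineConfig)}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_line(config: PipelineConfig, stage: str) -> str:
    return f"soilcd stage={stage} seed={config.random_seed} config={config_hash(config)}"
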