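"""Pipeline configuration: every tunable constant, YAML-loadable.

A flat YAML file can override any default; unknown keys raise so typos
do not silently fall back to defaults.  Species-specific published bout
thresholds (seconds) are shipped for real-data use; synthetic runs refit
their own threshold from the data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .allometry import DEFAULT_COEFFICIENTS, AllometricCoefficients
from .fmr import FMRConfig
from .respiration import DetectionConfig


@dataclass
class BoutConfig:
    dive_threshold_m: float = 2.0
    min_bout_s: float = 3600.0
    transition_min: float = 0.0
    min_intervals_for_fit: int = 10
    #: published per-species defaults (s), used only when a deployment has
    #: too few post-foraging intervals to refit: 5.5 min for blue and
    #: krill-feeding humpback whales, 5.6 min for fish-feeding humpbacks,
    #: 6.0 min for Antarctic minke whales
    species_thresholds_s: dict = field(
        default_factory=lambda: {
            "blue": 330.0,
            "humpback": 330.0,
            "humpback_fish": 336.0,
            "minke": 360.0,
        }
    )


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bouts: BoutConfig = field(default_factory=BoutConfig)
    fmr: FMRConfig = field(default_factory=FMRConfig)
    allometry: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))

    def coefficients_for(self, species: str) -> AllometricCoefficients:
        try:
            return self.allometry[species]
        except KeyError:
            raise KeyError(f"no allometric coefficients configured for species {species!r}")


def load_config(path=None) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, overlaying a YAML file if given."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in raw.items():
        if section == "allometry":
            for sp, coeffs in values.items():
                cfg.allometry[sp] = AllometricCoefficients(**coeffs)
            continue
        if not hasattr(cfg, section):
            raise KeyError(f"unknown config section {section!r}")
        target = getattr(cfg, section)
        for key, val in values.items():
            if not hasattr(target, key):
                raise KeyError(f"unknown config key {section}.{key}")
            if key == "eo2_range":
                val = tuple(val)
            setattr(target, key, val)
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    """Write the full configuration (defaults included) to YAML."""
    data = {
        "detection": asdict(cfg.detection),
        "bouts": asdict(cfg.bouts),
        "fmr": {**asdict(cfg.fmr), "eo2_range": list(cfg.fmr.eo2_range)},
        "allometry": {sp: asdict(c) for sp, c in cfg.allometry.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
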