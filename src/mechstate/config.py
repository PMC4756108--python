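"""Run configuration: every analysis threshold in one serializable place.

Defaults are the method's published operating points: event-detection
inflexion thresholds of +/-2 mm/s (diameter) and +/-1 mS/s (admittance),
adaptive 10th-percentile change thresholds for diameter, fixed
+/-0.57 mS/s change slopes for admittance, and +/-10 mmHg/s pressure
thresholds.  Nothing is hard-coded elsewhere, so the percentile
orientation and the smoothing window can be swept in sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import ConfigError
from .preprocess import PreprocessConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    # Event-detection inflexion thresholds (first opening / final closure).
    diameter_open_threshold: float = 2.0     # mm/s
    diameter_close_threshold: float = -2.0   # mm/s
    admittance_open_threshold: float = 1.0   # mS/s
    admittance_close_threshold: float = -1.0  # mS/s

    # Change thresholds.
    adaptive_percentile: float = 10.0
    percentile_orientation: str = "magnitude"  # or "literal"
    admittance_change_slope: float = 0.57      # mS/s, fixed
    pressure_increase_threshold: float = 10.0  # mmHg/s
    pressure_decrease_threshold: float = -10.0

    # Concordance.
    pad_fraction: float = 0.1
    min_phase_samples: int = 5

    # Run plumbing.
    out_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.preprocess, dict):
            self.preprocess = PreprocessConfig(**self.preprocess)
        if self.percentile_orientation not in ("magnitude", "literal"):
            raise ConfigError(
                f"percentile_orientation must be 'magnitude' or 'literal', "
                f"got {self.percentile_orientation!r}"
            )
        if not (self.diameter_open_threshold > 0 > self.diameter_close_threshold):
            raise ConfigError("diameter event thresholds must straddle zero")
        if not (self.admittance_open_threshold > 0 > self.admittance_close_threshold):
            raise ConfigError("admittance event thresholds must straddle zero")
        if self.pad_fraction < 0:
            raise ConfigError("pad_fraction must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
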