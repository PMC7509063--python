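"""Run configuration: YAML-backed, validated, and echoed to the log.

Every switch covering a genuinely open methodological choice has an explicit
default here so a run log records the resolved decision: the confidence
cut-off interpretation (window seconds vs sample-rate product), the dynamic
segment mode (cumulative prefix vs increment only), the ITR logarithm
convention, and the band-pass design.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import yaml

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


_VALID = {
    "threshold_mode": ("seconds", "product"),
    "segment_mode": ("cumulative", "increment"),
    "itr_convention": ("bits", "paper_nat"),
    "grid_mode": ("greedy", "product"),
    "noise_model": ("white", "pink"),
}


@dataclass
class RunConfig:
    # data
    dataset_path: str | None = None
    frequencies: list = field(default_factory=list)   # empty -> 12-class keypad
    phases: list | None = None
    fs: float = 256.0
    # synthetic generation
    n_subjects: int = 10
    n_trials_per_class: int = 15
    n_channels: int = 8
    duration_s: float = 4.0
    snr_db: list | None = None
    lapse_rate: float = 0.05
    noise_model: str = "pink"
    seed: int = 0
    # methods / decoding
    methods: list = field(default_factory=lambda: ["cca", "msi", "iist"])
    n_harmonics: int = 3
    n_donors: int = 4
    itw_s: float = 0.5
    twi_s: float = 0.5
    threshold_mode: str = "seconds"
    segment_mode: str = "cumulative"
    grid_mode: str = "greedy"
    tc_mode: str = "bucketed"          # or "constant"
    tc_constant: float = 1.5
    # evaluation
    n_folds: int = 3
    cv_seed: int = 0
    itr_convention: str = "bits"
    gaze_shift_s: float = 1.0
    # filtering
    band_low_hz: float = 6.0
    band_high_hz: float = 80.0
    filter_order: int = 4

    def validate(self) -> "RunConfig":
        for key, allowed in _VALID.items():
            if getattr(self, key) not in allowed:
                raise ConfigError(f"{key} must be one of {allowed}, "
                                  f"got {getattr(self, key)!r}")
        if self.tc_mode not in ("bucketed", "constant"):
            raise ConfigError("tc_mode must be 'bucketed' or 'constant'")
        if self.n_harmonics < 1 or self.n_folds < 2:
            raise ConfigError("n_harmonics >= 1 and n_folds >= 2 required")
        if self.itw_s <= 0 or self.twi_s <= 0:
            raise ConfigError("window parameters must be positive")
        if not 0 <= self.lapse_rate <= 1:
            raise ConfigError("lapse_rate must lie in [0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    def log_resolved(self) -> None:
        """Echo every resolved switch so runs are auditable."""
        for key, value in asdict(self).items():
            logger.info("config %s = %r", key, value)
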