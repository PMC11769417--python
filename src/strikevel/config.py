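"""Analysis configuration: defaults, YAML loading, and overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class ThresholdConfig:
    """How the strike-recognition threshold is obtained.

    ``fixed`` uses ``value`` directly (2 m/s² was found adequate for
    gravity-free smartphone accelerometer noise); ``adaptive`` estimates
    mean + k·SD of the norm over the baseline window of each recording.
    """

    mode: str = "fixed"  # "fixed" | "adaptive"
    value: float = 2.0   # m/s², used in fixed mode
    k: float = 3.0       # SD multiplier, used in adaptive mode

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"threshold.mode must be 'fixed' or 'adaptive', got {self.mode!r}")
        if self.value <= 0:
            raise ValueError("threshold.value must be positive")


@dataclass
class ValidityConfig:
    """Per-strike validity rules applied to segmented strikes."""

    min_samples: int = 3
    min_duration_s: float = 0.04
    max_duration_s: float = 0.6


@dataclass
class AnalysisConfig:
    """Full configuration for analysing one recording session.

    Parameters
    ----------
    threshold : ThresholdConfig
        Strike-onset threshold settings.
    baseline_seconds : float
        Leading noise-only window recorded with the athlete stationary in
        guard position; used for adaptive thresholding and excluded from
        peak search. Default 5 s.
    n_strikes : int
        Number of strikes expected per recording. Default 5.
    min_separation_s : float
        Minimum time between detected impact peaks. Strikes are separated
        by >= 10 s rest in the test protocol, so 1 s is conservative.
    max_lookback_s : float
        Bound on the backward scan from the impact peak to the onset
        crossing. Default 0.6 s (a strike fits well inside a 600 ms
        window around the peak).
    subtract_gravity : bool
        If True and the baseline norm suggests the trace includes
        gravity (median in [8.5, 11] m/s²), subtract the median baseline
        norm from the norm series (floored at 0). Off by default: data
        are never silently altered, only a warning is emitted.
    """

    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    baseline_seconds: float = 5.0
    n_strikes: int = 5
    min_separation_s: float = 1.0
    max_lookback_s: float = 0.6
    subtract_gravity: bool = False

    def __post_init__(self) -> None:
        if self.baseline_seconds < 0:
            raise ValueError("baseline_seconds must be non-negative")
        if self.n_strikes < 1:
            raise ValueError("n_strikes must be >= 1")
        if self.min_separation_s <= 0 or self.max_lookback_s <= 0:
            raise ValueError("min_separation_s and max_lookback_s must be positive")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        """Build a config from a (possibly flat, dotted-key) mapping.

        Accepts both nested mappings (``{"threshold": {"mode": ...}}``)
        and flat dotted keys (``{"threshold.mode": ...}``).
        """
        nested: dict[str, Any] = {}
        for key, value in data.items():
            parts = key.split(".")
            cursor = nested
            for part in parts[:-1]:
                cursor = cursor.setdefault(part, {})
                if not isinstance(cursor, dict):
                    raise ValueError(f"conflicting config key {key!r}")
            if isinstance(value, Mapping):
                cursor.setdefault(parts[-1], {}).update(value)
            else:
                cursor[parts[-1]] = value

        kwargs: dict[str, Any] = dict(nested)
        if "threshold" in kwargs:
            kwargs["threshold"] = ThresholdConfig(**kwargs["threshold"])
        if "validity" in kwargs:
            kwargs["validity"] = ValidityConfig(**kwargs["validity"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def replace(self, **overrides: Any) -> "AnalysisConfig":
        """Return a copy with dotted-key or top-level overrides applied."""
        base = self.to_dict()
        for key, value in overrides.items():
            parts = key.split(".")
            cursor = base
            for part in parts[:-1]:
                cursor = cursor[part]
            cursor[parts[-1]] = value
        return AnalysisConfig.from_dict(base)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
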