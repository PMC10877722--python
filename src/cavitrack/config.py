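"""Configuration dataclasses for the simulation / detection / evaluation pipeline.

Every stage of the pipeline is parameterised by a small frozen dataclass so a
full run is reproducible from (config, seed) alone.  Configs round-trip
through plain dicts and therefore through YAML/JSON files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Mean grand-total bubble counts produced by the detection program at the
#: anchor temperatures of the study (°C -> expected count).  Counts rise
#: roughly geometrically with water temperature.
DEFAULT_MEAN_ANCHORS: tuple[tuple[float, float], ...] = (
    (20.0, 0.12),
    (30.0, 0.71),
    (40.0, 6.4),
    (50.0, 28.0),
    (60.0, 97.5),
)

DEFAULT_TEMPERATURES: tuple[float, ...] = tuple(float(t) for t in range(20, 65, 5))


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic trial generator.

    Defaults emulate the shock-tube study design: 9 water temperatures from
    20 to 60 °C in 5 °C steps, 5 trials per temperature, and a 50-frame
    100,000 fps recording window per trial.
    """

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    trials_per_temperature: int = 5
    frames_per_trial: int = 50
    frame_rate: float = 100_000.0
    image_size: tuple[int, int] = (128, 256)  # (height, width) px
    mean_anchor_table: tuple[tuple[float, float], ...] = DEFAULT_MEAN_ANCHORS
    dispersion: float = 5.0  # negative-binomial shape theta
    bubble_radius_range: tuple[float, float] = (3.0, 8.0)  # px
    lifetime_range: tuple[int, int] = (5, 25)  # frames a bubble persists
    bubble_contrast: float = 60.0  # intensity drop below background
    background_level: float = 150.0  # 8-bit intensity
    noise_sd: float = 3.0  # additive Gaussian sensor noise
    n_artifacts: int = 3  # static bright blobs (light reflections)
    artifact_radius_range: tuple[float, float] = (5.0, 10.0)
    artifact_contrast: float = 60.0  # intensity rise above background
    max_rendered_bubbles: int = 120  # frame capacity for non-overlapping discs
    radius_ramp: bool = False  # optional grow/shrink of discs over lifetime
    seed: int | None = None

    def __post_init__(self) -> None:
        t = tuple(self.temperatures)
        if len(t) == 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ConfigError("temperatures must be nonempty and strictly increasing")
        if self.trials_per_temperature < 1:
            raise ConfigError("trials_per_temperature must be a positive integer")
        if self.frames_per_trial < 1:
            raise ConfigError("frames_per_trial must be a positive integer")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ConfigError("image_size must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        for name in ("bubble_radius_range", "lifetime_range", "artifact_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < min <= max")
        if not (0.0 <= self.background_level <= 255.0):
            raise ConfigError("background_level must lie in [0, 255]")
        if self.background_level - self.bubble_contrast < 0.0:
            raise ConfigError("bubble_contrast would push discs below intensity 0")
        if self.background_level + self.artifact_contrast > 255.0:
            raise ConfigError("artifact_contrast would push blobs above intensity 255")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_artifacts < 0:
            raise ConfigError("n_artifacts must be >= 0")
        anchors = tuple(self.mean_anchor_table)
        if len(anchors) < 2:
            raise ConfigError("mean_anchor_table needs at least two anchors")
        temps = [a for a, _ in anchors]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ConfigError("anchor temperatures must be strictly increasing")
        if any(c <= 0 for _, c in anchors):
            raise ConfigError("anchor counts must be > 0")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the per-frame circle detector."""

    radius_range: tuple[float, float] = (3.0, 8.0)  # (rmin, rmax) px
    sensitivity: float = 0.5  # normalised Hough accumulator threshold, (0, 1]
    smoothing_sigma: float = 1.0  # Gaussian pre-smoothing, px
    artifact_quantile: float = 0.98  # quantile defining "static bright" pixels
    min_contrast: float = 12.0  # required |core intensity - background|, 8-bit units

    def __post_init__(self) -> None:
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ConfigError("radius_range must satisfy 0 < rmin <= rmax")
        if rmin < 2:
            raise ConfigError("rmin must be >= 2 px for a meaningful circle")
        if not (0.0 < self.sensitivity <= 1.0):
            raise ConfigError("sensitivity must lie in (0, 1]")
        if self.smoothing_sigma < 0:
            raise ConfigError("smoothing_sigma must be >= 0")
        if not (0.0 < self.artifact_quantile < 1.0):
            raise ConfigError("artifact_quantile must lie in (0, 1)")
        if self.min_contrast < 0:
            raise ConfigError("min_contrast must be >= 0")


@dataclass(frozen=True)
class TrackingParams:
    """Parameters of the greedy nearest-neighbour frame-to-frame linker."""

    gate_radius: float = 16.0  # max centre displacement per linked step (2*rmax)
    max_gap: int = 1  # frames a track may go undetected and still extend

    def __post_init__(self) -> None:
        if self.gate_radius <= 0:
            raise ConfigError("gate_radius must be > 0")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")


@dataclass(frozen=True)
class EvaluationParams:
    """Cross-validation / bootstrap settings."""

    test_fraction: float = 0.3
    repeats: int = 10
    bootstrap_samples: int = 10
    models_per_sample: int = 10
    k_values: tuple[int, ...] = (1, 2, 3, 5, 7)
    svm_cost: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigError("test_fraction must lie in (0, 1)")
        for name in ("repeats", "bootstrap_samples", "models_per_sample"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if any(k < 1 for k in self.k_values):
            raise ConfigError("k_values must be positive")
        if self.svm_cost <= 0:
            raise ConfigError("svm_cost must be > 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration binding all stages together."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)
    schemes: tuple[int, ...] = (1, 2, 3, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s not in (1, 2, 3, 4) for s in self.schemes):
            raise ConfigError("schemes must be a subset of {1,2,3,4}")


# ---------------------------------------------------------------------------
# dict / YAML round-tripping


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: Any) -> dict[str, Any]:
    """Convert any pipeline dataclass to a plain (YAML/JSON-safe) dict."""
    return _to_plain(config)


def _tupled(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_tupled(v) for v in value)
    return value


def _from_dict(cls: type, data: dict[str, Any]) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**{k: _tupled(v) for k, v in data.items()})


def synthetic_config_from_dict(data: dict[str, Any]) -> SyntheticConfig:
    return _from_dict(SyntheticConfig, data)


def pipeline_config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    parts: dict[str, Any] = {}
    sub = {
        "synthetic": SyntheticConfig,
        "detection": DetectionParams,
        "tracking": TrackingParams,
        "evaluation": EvaluationParams,
    }
    for key, value in data.items():
        if key in sub:
            parts[key] = _from_dict(sub[key], value or {})
        else:
            parts[key] = _tupled(value)
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(parts) - names
    if unknown:
        raise ConfigError(f"unknown PipelineConfig fields: {sorted(unknown)}")
    return PipelineConfig(**parts)


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return pipeline_config_from_dict(data)


def config_hash(config: Any) -> str:
    """Stable short hash of a config, for output manifests."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]
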