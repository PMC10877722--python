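"""Synthetic shock-induced cavitation trials with full ground truth.

The generator emulates the shock-tube study design: at each water
temperature a trial's grand-total bubble count is drawn from a negative
binomial whose mean follows a log-linear interpolation of the detection
program's mean counts at 20/30/40/50/60 °C.  Optionally each trial is
rendered as a 50-frame grayscale image series in which every bubble is a
dark disc that appears and vanishes inside the recording window, static
bright blobs mimic light reflections from the chamber, and i.i.d. Gaussian
noise mimics the sensor.

Everything is reproducible from a :class:`numpy.random.Generator`; the
ground truth (per-bubble geometry and lifetime) is retained so detection and
tracking can be validated end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import SyntheticConfig

__all__ = [
    "GroundTruthBubble",
    "TrialRecord",
    "ImageSeries",
    "SyntheticTrial",
    "mean_count_curve",
    "sample_trial_count",
    "render_trial",
    "generate_dataset",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping bubble placement is infeasible."""


@dataclass(frozen=True)
class GroundTruthBubble:
    """True geometry and lifetime of one simulated bubble.

    ``center`` is (x, y) in pixel coordinates (x = column, y = row);
    ``first_frame``/``last_frame`` are 0-based inclusive frame indices.
    """

    center: tuple[float, float]
    radius: float
    first_frame: int
    last_frame: int

    def __post_init__(self) -> None:
        if not (0 <= self.first_frame <= self.last_frame):
            raise ValueError("need 0 <= first_frame <= last_frame")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class TrialRecord:
    """One trial's grand-total bubble count with its provenance."""

    trial_id: str
    temperature: float
    n_bubbles: int
    source: str  # "synthetic" | "detected"

    def __post_init__(self) -> None:
        if self.n_bubbles < 0 or int(self.n_bubbles) != self.n_bubbles:
            raise ValueError("n_bubbles must be a non-negative integer")
        if self.source not in ("synthetic", "detected"):
            raise ValueError("source must be 'synthetic' or 'detected'")


@dataclass
class ImageSeries:
    """Ordered grayscale frames of one trial plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width) uint8
    temperature: float
    frame_rate: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        """Time span covered by the series (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate


@dataclass
class SyntheticTrial:
    """A generated trial: record, ground-truth bubbles, optional rendering."""

    record: TrialRecord
    bubbles: list[GroundTruthBubble] = field(default_factory=list)
    series: ImageSeries | None = None


def mean_count_curve(
    temperature: float,
    anchors: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Expected grand-total bubble count at ``temperature``.

    Interpolates ln(count) linearly in temperature through the anchor table
    (default: the detection program's mean counts at 20..60 °C), i.e. counts
    grow geometrically between anchors.  Exact at anchor temperatures; no
    extrapolation outside the anchor span.
    """
    anchors = tuple(anchors) if anchors is not None else SyntheticConfig().mean_anchor_table
    temps = np.array([a for a, _ in anchors], dtype=float)
    counts = np.array([c for _, c in anchors], dtype=float)
    if np.any(counts <= 0):
        raise ValueError("anchor counts must be > 0")
    if not (temps[0] <= temperature <= temps[-1]):
        raise ValueError(
            f"temperature {temperature} outside anchor span [{temps[0]}, {temps[-1]}]"
        )
    return float(np.exp(np.interp(temperature, temps, np.log(counts))))


def sample_trial_count(
    temperature: float,
    dispersion: float,
    rng: np.random.Generator,
    anchors: Sequence[tuple[float, float]] | None = None,
) -> int:
    """Draw one trial's bubble count.

    Negative binomial with mean mu = mean_count_curve(T) and shape theta
    (variance mu + mu^2/theta); theta -> inf recovers Poisson(mu).  A
    mean-parameterised NB is the standard overdispersed count model and
    accommodates the near-zero means at 20-30 °C.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    mu = mean_count_curve(temperature, anchors)
    if mu == 0.0:
        return 0
    p = dispersion / (dispersion + mu)
    return int(rng.negative_binomial(dispersion, p))


def _disc_coverage(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Soft-edged disc coverage in [0,1] on a bounding-box patch."""
    h, w = shape
    cx, cy = center
    x0 = max(int(math.floor(cx - radius - 1)), 0)
    x1 = min(int(math.ceil(cx + radius + 2)), w)
    y0 = max(int(math.floor(cy - radius - 1)), 0)
    y1 = min(int(math.ceil(cy + radius + 2)), h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return cov, (slice(y0, y1), slice(x0, x1))


def _check_inside(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> None:
    h, w = shape
    cx, cy = center
    if not (radius <= cx <= w - 1 - radius and radius <= cy <= h - 1 - radius):
        raise PlacementError(
            f"disc at ({cx:.1f}, {cy:.1f}) r={radius:.1f} falls outside a {h}x{w} frame"
        )


def render_trial(
    temperature: float,
    true_bubbles: Sequence[GroundTruthBubble],
    config: SyntheticConfig,
    rng: np.random.Generator,
    artifacts: Sequence[tuple[tuple[float, float], float]] | None = None,
    trial_id: str = "",
) -> ImageSeries:
    """Render one trial as an 8-bit grayscale image series.

    Bubbles are discs ``bubble_contrast`` darker than the background, drawn
    only during their [first_frame, last_frame] lifetime; ``artifacts``
    (centre, radius pairs, drawn by the caller or sampled here) are bright
    blobs identical in every frame; Gaussian noise is i.i.d. per pixel per
    frame and the result is clipped to [0, 255].
    """
    h, w = config.image_size
    shape = (h, w)
    for b in true_bubbles:
        _check_inside(shape, b.center, b.radius)
        if b.last_frame >= config.frames_per_trial:
            raise PlacementError("bubble lifetime exceeds frames_per_trial")

    if artifacts is None:
        artifacts = sample_artifacts(config, rng)

    base = np.full(shape, config.background_level, dtype=float)
    for (ax, ay), ar in artifacts:
        cov, sl = _disc_coverage(shape, (ax, ay), ar)
        base[sl] += config.artifact_contrast * cov

    n_frames = config.frames_per_trial
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for f in range(n_frames):
        img = base.copy()
        for b in true_bubbles:
            if b.first_frame <= f <= b.last_frame:
                r = b.radius
                if config.radius_ramp and b.last_frame > b.first_frame:
                    # grow to full size mid-life, then shrink (collapse)
                    phase = (f - b.first_frame) / (b.last_frame - b.first_frame)
                    r = max(1.0, b.radius * math.sin(math.pi * min(max(phase, 0.02), 0.98)))
                cov, sl = _disc_coverage(shape, b.center, r)
                img[sl] -= config.bubble_contrast * cov
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageSeries(
        frames=frames,
        temperature=temperature,
        frame_rate=config.frame_rate,
        trial_id=trial_id,
    )


def sample_artifacts(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[tuple[float, float], float]]:
    """Sample static bright blob positions/radii (light reflections)."""
    h, w = config.image_size
    out: list[tuple[tuple[float, float], float]] = []
    for _ in range(config.n_artifacts):
        ar = rng.uniform(*config.artifact_radius_range)
        ax = rng.uniform(ar + 1, w - 2 - ar)
        ay = rng.uniform(ar + 1, h - 2 - ar)
        out.append(((float(ax), float(ay)), float(ar)))
    return out


#: Frames of temporal guard between one bubble's death and another's birth
#: below which the two must also be spatially separated (otherwise the
#: tracker could link the newcomer onto the dead bubble's track).
_TEMPORAL_GUARD = 4


def _place_bubbles(
    n: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    keep_out: Sequence[tuple[tuple[float, float], float]] = (),
    max_attempts_per_bubble: int = 5000,
) -> list[GroundTruthBubble]:
    """Sample ``n`` bubble geometries with rejection on ambiguous placement.

    Two bubbles whose lifetimes overlap must not overlap spatially (their
    centres are resampled until separated by at least a 2 px gap and by more
    than rmin + rmax), so every concurrent bubble has a distinct boundary.
    A bubble born within ``_TEMPORAL_GUARD`` frames of another's collapse
    must additionally sit outside the tracker's default gating radius, so a
    newcomer is never mistaken for the reappearance of a dead bubble.
    Temporally distant bubbles may reuse space — the frame could not hold
    the highest-temperature trials' bubble counts concurrently otherwise.
    ``keep_out`` lists (centre, radius) discs (artifacts) bubbles must avoid.
    """
    h, w = config.image_size
    rmin, rmax = config.bubble_radius_range
    lmin, lmax = config.lifetime_range
    lmax = min(lmax, config.frames_per_trial)
    lmin = min(lmin, lmax)
    margin = rmax + 1.0
    if w - 1 - 2 * margin <= 0 or h - 1 - 2 * margin <= 0:
        raise PlacementError("image too small for the configured bubble radii")

    floor_sep = rmin + rmax + 0.5
    gate_sep = 2.0 * rmax + 1.0
    placed: list[GroundTruthBubble] = []
    for i in range(n):
        r = float(rng.uniform(rmin, rmax))
        lifetime = int(rng.integers(lmin, lmax + 1))
        first = int(rng.integers(0, config.frames_per_trial - lifetime + 1))
        last = first + lifetime - 1
        ok = False
        for attempt in range(max_attempts_per_bubble):
            if attempt > 0 and attempt % 500 == 0:
                # crowded temporal slot: redraw the lifetime window too
                lifetime = int(rng.integers(lmin, lmax + 1))
                first = int(rng.integers(0, config.frames_per_trial - lifetime + 1))
                last = first + lifetime - 1
            cx = float(rng.uniform(margin, w - 1 - margin))
            cy = float(rng.uniform(margin, h - 1 - margin))
            ok = all(
                math.hypot(cx - ox, cy - oy) > r + orad + 2.0
                for (ox, oy), orad in keep_out
            )
            for b in placed:
                if not ok:
                    break
                concurrent = b.first_frame <= last and first <= b.last_frame
                gap = max(b.first_frame - last, first - b.last_frame)
                near_in_time = not concurrent and gap <= _TEMPORAL_GUARD
                if concurrent:
                    sep = max(b.radius + r + 2.0, floor_sep)
                elif near_in_time:
                    sep = max(b.radius + r + 2.0, gate_sep)
                else:
                    continue
                if math.hypot(cx - b.center[0], cy - b.center[1]) <= sep:
                    ok = False
            if ok:
                break
        if not ok:
            raise PlacementError(
                f"could not place bubble {i + 1}/{n} without ambiguity; "
                "frame capacity exceeded"
            )
        placed.append(
            GroundTruthBubble(
                center=(cx, cy), radius=r, first_frame=first, last_frame=last
            )
        )
    return placed


def generate_dataset(
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
    render: bool = False,
) -> list[SyntheticTrial]:
    """Generate the full trial grid of the study design.

    ``trials_per_temperature`` trials at each configured temperature; each
    trial's count is drawn by :func:`sample_trial_count`; bubble geometries
    and lifetimes are sampled uniformly within the configured ranges.  With
    ``render=True`` every trial also gets an :class:`ImageSeries` (rendered
    counts are truncated at ``config.max_rendered_bubbles``, the number of
    non-overlapping discs the frame can hold; the recorded ground-truth
    count is then the rendered count).

    Fully reproducible: the same config and seed yield identical records,
    geometries and frames.
    """
    config = config if config is not None else SyntheticConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trials: list[SyntheticTrial] = []
    for temperature in config.temperatures:
        for j in range(config.trials_per_temperature):
            trial_id = f"T{temperature:g}_{j + 1}"
            n = sample_trial_count(
                temperature, config.dispersion, rng, config.mean_anchor_table
            )
            if render:
                n_render = min(n, config.max_rendered_bubbles)
                artifacts = sample_artifacts(config, rng)
                bubbles = _place_bubbles(n_render, config, rng, keep_out=artifacts)
                series = render_trial(
                    temperature, bubbles, config, rng,
                    artifacts=artifacts, trial_id=trial_id,
                )
                record = TrialRecord(trial_id, temperature, n_render, "synthetic")
                trials.append(SyntheticTrial(record, bubbles, series))
            else:
                record = TrialRecord(trial_id, temperature, n, "synthetic")
                trials.append(SyntheticTrial(record, [], None))
    return trials
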