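"""Per-frame bubble detection: ROI cropping, artifact suppression, circle finding.

Mirrors the image-processing stage of the bubble detection program: every
frame of a trial is cropped to the chamber interior, static bright
structures (light reflections) are masked using temporal statistics, the
frame is denoised, and bubbles are found with a circular Hough transform on
the gradient image.  Detection is polarity-agnostic: dark and bright discs
both produce gradient edges.

Coordinate convention: 0-based pixel indices, x = column, y = row; ROI
rectangles are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import canny, peak_local_max
from skimage.transform import hough_circle

from .config import DetectionParams
from .synthetic import ImageSeries

__all__ = [
    "RegionOfInterest",
    "Detection",
    "crop_to_roi",
    "build_artifact_mask",
    "preprocess_frame",
    "detect_circles",
    "detect_series",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned crop rectangle; (x0, y0) is the top-left pixel."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @classmethod
    def full_frame(cls, shape: tuple[int, ...]) -> "RegionOfInterest":
        h, w = shape[-2], shape[-1]
        return cls(0, 0, w, h)


@dataclass(frozen=True)
class Detection:
    """One circle hit in one frame, in ROI coordinates."""

    frame_index: int
    center: tuple[float, float]  # (x, y)
    radius: float
    score: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.score <= 0:
            raise ValueError("score must be > 0")


def crop_to_roi(series: ImageSeries, roi: RegionOfInterest) -> ImageSeries:
    """Crop every frame identically; metadata is preserved.

    Detection coordinates downstream are relative to the ROI origin.
    """
    _, h, w = series.frames.shape
    if roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise ValueError(f"ROI {roi} exceeds frame bounds ({h}x{w})")
    frames = series.frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return ImageSeries(
        frames=frames.copy(),
        temperature=series.temperature,
        frame_rate=series.frame_rate,
        trial_id=series.trial_id,
    )


def build_artifact_mask(series: ImageSeries, artifact_quantile: float = 0.98) -> np.ndarray:
    """Boolean mask of static bright structures (light reflections).

    A pixel is masked when its temporal median intensity exceeds the
    ``artifact_quantile`` quantile of the whole-series intensity
    distribution.  Transient dark bubbles barely move the temporal median,
    whereas stationary reflections sit in the bright tail in every frame.
    The mask is shared by all frames.
    """
    if series.n_frames < 3:
        raise ValueError("artifact mask needs >= 3 frames for temporal statistics")
    frames = series.frames.astype(float)
    median = np.median(frames, axis=0)
    threshold = np.quantile(frames, artifact_quantile)
    return median > threshold


def preprocess_frame(
    frame: np.ndarray, mask: np.ndarray, params: DetectionParams
) -> np.ndarray:
    """Suppress masked artifacts and denoise one frame.

    Masked pixels are replaced by the frame's median intensity (flat
    background), then Gaussian smoothing with ``params.smoothing_sigma`` is
    applied.  Returns a float image clipped to [0, 255].
    """
    from scipy.ndimage import gaussian_filter

    frame = np.asarray(frame, dtype=float)
    if mask.shape != frame.shape:
        raise ValueError("mask shape must match frame shape")
    out = frame.copy()
    if np.any(mask):
        out[mask] = np.median(frame)
    if params.smoothing_sigma > 0:
        out = gaussian_filter(out, params.smoothing_sigma)
    return np.clip(out, 0.0, 255.0)


def detect_circles(frame: np.ndarray, params: DetectionParams) -> list[Detection]:
    """Find circular bubbles in one (preprocessed) frame.

    Circular Hough transform over the configured radius range on the edge
    map of the frame; accumulator peaks with normalised vote fraction above
    ``params.sensitivity`` are kept.  Non-maximum suppression removes any
    detection whose centre lies within rmin of a stronger one; ties are
    broken by scan order (smaller y, then smaller x).  Results are sorted by
    descending score.
    """
    frame = np.asarray(frame, dtype=float)
    rmin, rmax = params.radius_range
    if rmin < 2:
        raise ValueError("rmin must be >= 2 px")
    h, w = frame.shape
    if h < 2 * rmax or w < 2 * rmax:
        raise ValueError("frame smaller than twice the maximum radius")
    if np.ptp(frame) == 0:
        return []

    edges = canny(frame / 255.0, sigma=1.0)
    if not np.any(edges):
        return []
    radii = np.arange(int(np.floor(rmin)), int(np.ceil(rmax)) + 1)
    accum = hough_circle(edges, radii, normalize=True, full_output=False)

    candidates: list[tuple[float, int, int, float]] = []  # (score, y, x, r)
    for acc, r in zip(accum, radii):
        peaks = peak_local_max(
            acc,
            min_distance=max(int(np.floor(rmin)) // 2, 1),
            threshold_abs=params.sensitivity,
            exclude_border=False,
        )
        for y, x in peaks:
            candidates.append((float(acc[y, x]), int(y), int(x), float(r)))

    # NMS across radii: strongest first, ties by scan order
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    background = float(np.median(frame))
    kept: list[Detection] = []
    for score, y, x, r in candidates:
        # suppress candidates near a stronger detection (within rmin) and
        # candidates whose circle substantially overlaps a stronger one:
        # physical bubbles are disjoint, so overlapping circles are duplicates
        if any(
            np.hypot(d.center[0] - x, d.center[1] - y)
            < max(rmin, d.radius + r - 2.0)
            for d in kept
        ):
            continue
        if not _core_contrast_ok(frame, x, y, r, background, params.min_contrast):
            continue
        kept.append(Detection(frame_index=0, center=(float(x), float(y)), radius=r, score=score))
    return kept


def _core_contrast_ok(
    frame: np.ndarray, x: int, y: int, r: float, background: float, min_contrast: float
) -> bool:
    """Photometric validation of a circle candidate.

    The Hough accumulator has satellite ("caustic") peaks at distance
    r_true +/- r_accumulator from every genuine circle; those candidates
    enclose plain background.  A real bubble's core — the inner half of the
    circle — deviates from the frame background by roughly the full bubble
    contrast, so candidates whose core mean sits within ``min_contrast`` of
    the background are rejected.  Polarity-agnostic (absolute deviation).
    """
    if min_contrast <= 0:
        return True
    h, w = frame.shape
    core = max(r / 2.0, 1.5)
    x0, x1 = max(int(x - core), 0), min(int(x + core) + 1, w)
    y0, y1 = max(int(y - core), 0), min(int(y + core) + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= core * core
    if not np.any(inside):
        return False
    return abs(float(frame[y0:y1, x0:x1][inside].mean()) - background) >= min_contrast


def detect_series(
    series: ImageSeries,
    params: DetectionParams | None = None,
    roi: RegionOfInterest | None = None,
) -> list[list[Detection]]:
    """Run crop -> artifact mask -> preprocess -> detect on every frame.

    Returns one detection list per frame (ROI coordinates, frame_index set).
    """
    params = params if params is not None else DetectionParams()
    if roi is not None:
        series = crop_to_roi(series, roi)
    if series.n_frames >= 3:
        mask = build_artifact_mask(series, params.artifact_quantile)
    else:
        mask = np.zeros(series.frames.shape[1:], dtype=bool)
    per_frame: list[list[Detection]] = []
    for f in range(series.n_frames):
        frame = preprocess_frame(series.frames[f], mask, params)
        dets = [replace(d, frame_index=f) for d in detect_circles(frame, params)]
        per_frame.append(dets)
    return per_frame
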