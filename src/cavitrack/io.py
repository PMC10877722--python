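"""Readers and writers binding the pipeline stages together on disk.

File dialects: 8-bit grayscale multi-page TIFF (preferred) or zero-padded
numbered PNG sequences for image series; comma-separated UTF-8 CSVs with a
header row for all tables; JSON manifests recording the config hash, master
seed and file list of each run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import config_hash, config_to_dict
from .detection import Detection
from .knn import LabeledPoint
from .synthetic import GroundTruthBubble, ImageSeries, SyntheticTrial, TrialRecord
from .tracking import BubbleTrack

__all__ = [
    "write_series_tiff",
    "write_series_png",
    "read_series",
    "write_trial_records",
    "read_trial_records",
    "write_ground_truth",
    "read_ground_truth",
    "write_detections",
    "write_tracks",
    "write_manifest",
    "labeled_points_from_records",
]

TRIAL_COLUMNS = ["trial_id", "temperature_C", "n_bubbles", "source"]


def write_series_tiff(series: ImageSeries, path: str | Path) -> Path:
    """Write a trial's frames as one 8-bit grayscale multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, series.frames.astype(np.uint8))
    return path


def write_series_png(series: ImageSeries, directory: str | Path) -> list[Path]:
    """Write a trial's frames as a zero-padded numbered PNG sequence."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(series.frames):
        p = directory / f"frame_{i:04d}.png"
        iio.imwrite(p, frame.astype(np.uint8))
        paths.append(p)
    return paths


def read_series(
    path: str | Path,
    temperature: float = float("nan"),
    frame_rate: float = 100_000.0,
    trial_id: str = "",
) -> ImageSeries:
    """Read an image series from a multi-page TIFF file or a PNG directory.

    Frame order is page order for TIFF and lexicographic file order for a
    PNG sequence.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return ImageSeries(
        frames=frames.astype(np.uint8),
        temperature=temperature,
        frame_rate=frame_rate,
        trial_id=trial_id or path.stem,
    )


def write_trial_records(records: Iterable[TrialRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "temperature_C": r.temperature,
                "n_bubbles": r.n_bubbles,
                "source": r.source,
            }
            for r in records
        ],
        columns=TRIAL_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_trial_records(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return [
        TrialRecord(
            trial_id=str(row.trial_id),
            temperature=float(row.temperature_C),
            n_bubbles=int(row.n_bubbles),
            source=str(row.source),
        )
        for row in df.itertuples()
    ]


def write_ground_truth(trials: Sequence[SyntheticTrial], path: str | Path) -> Path:
    """Ground-truth bubble table: trial_id,bubble_id,x,y,radius,first_frame,last_frame."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        for i, b in enumerate(trial.bubbles, start=1):
            rows.append(
                {
                    "trial_id": trial.record.trial_id,
                    "bubble_id": i,
                    "x": b.center[0],
                    "y": b.center[1],
                    "radius": b.radius,
                    "first_frame": b.first_frame,
                    "last_frame": b.last_frame,
                }
            )
    pd.DataFrame(
        rows,
        columns=["trial_id", "bubble_id", "x", "y", "radius", "first_frame", "last_frame"],
    ).to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> dict[str, list[GroundTruthBubble]]:
    df = pd.read_csv(path)
    out: dict[str, list[GroundTruthBubble]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.trial_id), []).append(
            GroundTruthBubble(
                center=(float(row.x), float(row.y)),
                radius=float(row.radius),
                first_frame=int(row.first_frame),
                last_frame=int(row.last_frame),
            )
        )
    return out


def write_detections(
    detections_by_trial: dict[str, Sequence[Sequence[Detection]]], path: str | Path
) -> Path:
    """Per-frame detections CSV: trial_id,frame,x,y,radius,score."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial_id, per_frame in detections_by_trial.items():
        for dets in per_frame:
            for d in dets:
                rows.append(
                    {
                        "trial_id": trial_id,
                        "frame": d.frame_index,
                        "x": d.center[0],
                        "y": d.center[1],
                        "radius": d.radius,
                        "score": d.score,
                    }
                )
    pd.DataFrame(rows, columns=["trial_id", "frame", "x", "y", "radius", "score"]).to_csv(
        path, index=False
    )
    return path


def write_tracks(tracks_by_trial: dict[str, Sequence[BubbleTrack]], path: str | Path) -> Path:
    """Tracks CSV: trial_id,track_id,frame,x,y,radius."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial_id, tracks in tracks_by_trial.items():
        for t in tracks:
            for d in t.detections:
                rows.append(
                    {
                        "trial_id": trial_id,
                        "track_id": t.track_id,
                        "frame": d.frame_index,
                        "x": d.center[0],
                        "y": d.center[1],
                        "radius": d.radius,
                    }
                )
    pd.DataFrame(rows, columns=["trial_id", "track_id", "frame", "x", "y", "radius"]).to_csv(
        path, index=False
    )
    return path


def write_manifest(
    directory: str | Path, config, seed: int, files: Sequence[str | Path]
) -> Path:
    """JSON manifest recording config hash + seed + relative file list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "config": config_to_dict(config),
        "files": sorted(str(Path(f).relative_to(directory)) for f in files),
    }
    path = directory / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def labeled_points_from_records(
    records: Sequence[TrialRecord], scheme
) -> list[LabeledPoint]:
    """Turn trial records into (temperature, level) classifier points."""
    from .levels import assign_level

    return [
        LabeledPoint(x=r.temperature, label=assign_level(r.n_bubbles, scheme))
        for r in records
    ]
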