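"""Linking per-frame detections into identity-stable bubble tracks.

Each physical bubble must be counted exactly once per trial even though it
appears in many consecutive frames.  Tracks carry an identification number
assigned in order of first appearance; the grand total for a trial is the
number of distinct tracks.

Matching is greedy nearest-neighbour with a gating radius: per frame,
candidate (track, detection) pairs closer than ``gate_radius`` are linked in
ascending distance order, each side used at most once.  A track that goes
undetected for more than ``max_gap`` frames is closed; a bubble reappearing
later becomes a new identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import DetectionParams, TrackingParams
from .detection import Detection, RegionOfInterest, detect_series
from .synthetic import ImageSeries, TrialRecord

__all__ = ["BubbleTrack", "link_detections", "grand_total", "count_trial"]


@dataclass
class BubbleTrack:
    """One bubble's linked detections; ``track_id`` orders first appearances."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.detections[-1].frame_index


def link_detections(
    per_frame: Sequence[Sequence[Detection]],
    params: TrackingParams | None = None,
) -> list[BubbleTrack]:
    """Greedily link detections over frames into tracks.

    ``per_frame`` holds the detections of frame 0, 1, ... in order; every
    detection's ``frame_index`` must match its slot (unsorted input is an
    error).  Unmatched detections open new tracks; IDs are assigned
    chronologically, ties within a frame broken by descending score then
    scan order (smaller y, then smaller x).
    """
    params = params if params is not None else TrackingParams()
    for f, dets in enumerate(per_frame):
        for d in dets:
            if d.frame_index != f:
                raise ValueError(
                    f"detection frame_index {d.frame_index} does not match frame {f}; "
                    "input must be grouped by frame in order"
                )

    tracks: list[BubbleTrack] = []
    active: list[BubbleTrack] = []
    next_id = 1
    for f, dets in enumerate(per_frame):
        # close tracks that have gone stale
        active = [t for t in active if f - t.last_frame <= params.max_gap + 1]

        # candidate pairs within the gate, ascending distance;
        # deterministic tie-break on (track id, detection order)
        pairs: list[tuple[float, int, int]] = []
        for ti, t in enumerate(active):
            lx, ly = t.detections[-1].center
            for di, d in enumerate(dets):
                dist = math.hypot(d.center[0] - lx, d.center[1] - ly)
                if dist <= params.gate_radius:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            active[ti].detections.append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)

        # new tracks: descending score, then scan order
        newborn = [
            (di, d) for di, d in enumerate(dets) if di not in used_dets
        ]
        newborn.sort(key=lambda item: (-item[1].score, item[1].center[1], item[1].center[0]))
        for _, d in newborn:
            t = BubbleTrack(track_id=next_id, detections=[d])
            next_id += 1
            tracks.append(t)
            active.append(t)
    return tracks


def grand_total(tracks: Sequence[BubbleTrack]) -> int:
    """Number of distinct bubbles in a trial (each counted once)."""
    return len(tracks)


def count_trial(
    series: ImageSeries,
    roi: RegionOfInterest | None = None,
    detection_params: DetectionParams | None = None,
    tracking_params: TrackingParams | None = None,
) -> TrialRecord:
    """Full per-trial pipeline: crop, mask, preprocess, detect, link, count."""
    per_frame = detect_series(series, detection_params, roi)
    tracks = link_detections(per_frame, tracking_params)
    return TrialRecord(
        trial_id=series.trial_id,
        temperature=series.temperature,
        n_bubbles=grand_total(tracks),
        source="detected",
    )
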