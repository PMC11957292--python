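"""Single-cell tracking with a moving, reshaping square region of interest.

Each cell found in the first frame seeds one track. For every subsequent
frame a square ROI is drawn around the previous centroid, sized from the
previous major-axis length, and the segmentation chain is re-run inside the
crop. Exactly one qualifying region extends the track; zero regions or two
or more regions (cell loss, division, or cell-cell contact) stop it, and
only the points collected before the stop event are kept. There is no gap
closing and no re-acquisition after loss: analysis targets sparsely seeded
cells with no contacts, and a contact deliberately ends the track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .segmentation import (
    CellRegion,
    FrameImage,
    SegmentationConfig,
    segment_frame,
)

logger = logging.getLogger(__name__)


class StopReason(str, Enum):
    END_OF_STACK = "end_of_stack"
    NO_CENTROID = "no_centroid"
    MULTIPLE_CENTROIDS = "multiple_centroids"
    ROI_DEGENERATE = "roi_degenerate"


@dataclass(frozen=True)
class TrackingConfig:
    """ROI sizing, track-length filtering and timing.

    roi_scale multiplies the previous major-axis length to give the ROI
    side, so the window always holds the whole cell with room to move.
    merge_area_factor flags a cell-cell contact that produced a single
    merged component: if the matched region's area jumps by more than this
    factor between consecutive frames the track is stopped as a contact.
    """

    roi_scale: float = 2.0
    min_track_duration_min: float = 60.0
    frame_interval_s: float = 60.0
    merge_area_factor: float = 1.8

    def __post_init__(self) -> None:
        if not self.roi_scale > 1:
            raise ValueError("roi_scale must be > 1")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.merge_area_factor > 1:
            raise ValueError("merge_area_factor must be > 1")


@dataclass(frozen=True)
class TrackPoint:
    frame_index: int
    time_s: float
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]
    area_um2: float
    major_axis_um: float


@dataclass
class Track:
    track_id: int
    points: list[TrackPoint] = field(default_factory=list)
    stop_reason: StopReason | None = None

    @property
    def stopped(self) -> bool:
        return self.stop_reason is not None

    @property
    def duration_s(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return self.points[-1].time_s - self.points[0].time_s


def initialize_tracks(
    first_frame_regions: list[CellRegion],
    frame_interval_s: float = 60.0,
) -> list[Track]:
    """One track per region segmented in the full first frame."""
    if not first_frame_regions:
        logger.warning("no regions in first frame: starting zero tracks")
    tracks = []
    for tid, region in enumerate(first_frame_regions):
        pt = TrackPoint(
            frame_index=0,
            time_s=0.0,
            centroid_px=region.centroid_px,
            centroid_um=region.centroid_um,
            area_um2=region.area_um2,
            major_axis_um=region.major_axis_length_um,
        )
        tracks.append(Track(track_id=tid, points=[pt]))
    return tracks


def make_roi(
    centroid_px: tuple[float, float],
    major_axis_len_px: float,
    roi_scale: float,
    frame_shape: tuple[int, int],
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Square ROI ((x0, y0), (side_x, side_y)) around a centroid.

    side = ceil(roi_scale * major_axis_length). The window is translated
    (not shrunk) to stay inside the frame; if the side exceeds a frame
    dimension it is clipped to the frame along that dimension.
    """
    if not major_axis_len_px > 0:
        raise ValueError("roi_degenerate: non-positive major-axis length")
    h, w = frame_shape
    side = int(np.ceil(roi_scale * major_axis_len_px))
    side_x, side_y = min(side, w), min(side, h)
    x0 = int(round(centroid_px[0])) - side_x // 2
    y0 = int(round(centroid_px[1])) - side_y // 2
    x0 = min(max(x0, 0), w - side_x)
    y0 = min(max(y0, 0), h - side_y)
    return (x0, y0), (side_x, side_y)


def step_track(
    track: Track,
    next_frame: FrameImage,
    seg_config: SegmentationConfig,
    trk_config: TrackingConfig,
) -> Track:
    """Advance a track by one frame, or stop it.

    Segments inside the ROI built from the last point. Exactly one
    qualifying region appends a point; zero stops with no_centroid; two or
    more stop with multiple_centroids. A single region whose area jumped by
    more than merge_area_factor, or whose centroid strayed beyond half the
    ROI side, is treated as a contact/mismatch rather than the tracked cell.
    """
    if track.stopped:
        raise RuntimeError(f"track {track.track_id} already stopped")
    last = track.points[-1]
    ps = next_frame.pixel_size
    try:
        (x0, y0), (sx, sy) = make_roi(
            last.centroid_px,
            last.major_axis_um / ps,
            trk_config.roi_scale,
            next_frame.pixels.shape,
        )
    except ValueError:
        track.stop_reason = StopReason.ROI_DEGENERATE
        return track
    crop = next_frame.pixels[y0 : y0 + sy, x0 : x0 + sx]
    crop_img = FrameImage(
        pixels=crop, pixel_size=ps, frame_index=next_frame.frame_index
    )
    regions = segment_frame(crop_img, seg_config)
    if len(regions) == 0:
        track.stop_reason = StopReason.NO_CENTROID
        return track
    if len(regions) >= 2:
        track.stop_reason = StopReason.MULTIPLE_CENTROIDS
        return track
    region = regions[0]
    cx = region.centroid_px[0] + x0
    cy = region.centroid_px[1] + y0
    # contact that merged into a single big component
    if region.area_um2 > trk_config.merge_area_factor * last.area_um2:
        track.stop_reason = StopReason.MULTIPLE_CENTROIDS
        return track
    # identity sanity guard: the one region must be near the previous centroid
    half_side = max(sx, sy) / 2.0
    if np.hypot(cx - last.centroid_px[0], cy - last.centroid_px[1]) > half_side:
        track.stop_reason = StopReason.NO_CENTROID
        return track
    track.points.append(
        TrackPoint(
            frame_index=next_frame.frame_index,
            time_s=next_frame.frame_index * trk_config.frame_interval_s,
            centroid_px=(cx, cy),
            centroid_um=(cx * ps, cy * ps),
            area_um2=region.area_um2,
            major_axis_um=region.major_axis_length_um,
        )
    )
    return track


def track_all(
    stack,
    seg_config: SegmentationConfig,
    trk_config: TrackingConfig,
) -> list[Track]:
    """Seed tracks on frame 0 and advance each until a stop or stack end.

    `stack` is a FrameStack (io module) or any sequence of FrameImage.
    Deterministic given the inputs.
    """
    frames = list(stack)
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")
    regions0 = segment_frame(frames[0], seg_config)
    tracks = initialize_tracks(regions0, trk_config.frame_interval_s)
    for frame in frames[1:]:
        for track in tracks:
            if not track.stopped:
                step_track(track, frame, seg_config, trk_config)
    for track in tracks:
        if not track.stopped:
            track.stop_reason = StopReason.END_OF_STACK
        logger.info(
            "track %d: %d points, stop=%s",
            track.track_id,
            len(track.points),
            track.stop_reason.value,
        )
    return tracks


def filter_tracks(
    tracks: list[Track], min_track_duration_min: float = 60.0
) -> list[Track]:
    """Keep tracks strictly longer than the minimum duration (default 1 h)."""
    return [t for t in tracks if t.duration_s > min_track_duration_min * 60.0]
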