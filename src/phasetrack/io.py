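"""Formats and configuration: TIFF stacks, tracks/features CSV, JSON config."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .segmentation import FrameImage, SegmentationConfig
from .tracking import StopReason, Track, TrackingConfig, TrackPoint

TRACK_COLUMNS = [
    "track_id",
    "frame",
    "time_s",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "area_um2",
    "major_axis_um",
    "stop_reason",
]


@dataclass
class FrameStack:
    """Ordered grayscale frames plus acquisition calibration."""

    frames: list[FrameImage]
    pixel_size: float = 0.65
    frame_interval_s: float = 60.0

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> FrameImage:
        return self.frames[i]


def read_stack(
    path, pixel_size: float = 0.65, frame_interval_s: float = 60.0
) -> FrameStack:
    """Read a single- or multi-page grayscale TIFF into floating intensities."""
    pages = tifffile.imread(path)
    arr = np.asarray(pages)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout {arr.shape}; expected 2-D grayscale pages"
        )
    frames = [
        FrameImage(pixels=arr[i].astype(float), pixel_size=pixel_size, frame_index=i)
        for i in range(arr.shape[0])
    ]
    return FrameStack(frames, pixel_size, frame_interval_s)


def write_stack(path, stack: FrameStack | list[FrameImage]) -> None:
    frames = list(stack)
    data = np.stack([f.pixels for f in frames]).astype(np.float32)
    tifffile.imwrite(path, data)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tidy per-point table; stop_reason filled on the last row of each track."""
    rows = []
    for t in tracks:
        for i, p in enumerate(t.points):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": p.frame_index,
                    "time_s": p.time_s,
                    "x_px": p.centroid_px[0],
                    "y_px": p.centroid_px[1],
                    "x_um": p.centroid_um[0],
                    "y_um": p.centroid_um[1],
                    "area_um2": p.area_um2,
                    "major_axis_um": p.major_axis_um,
                    "stop_reason": (
                        t.stop_reason.value
                        if (i == len(t.points) - 1 and t.stop_reason)
                        else ""
                    ),
                }
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(path, tracks: list[Track]) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.17g")


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracks CSV is missing column(s): {missing}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        points = [
            TrackPoint(
                frame_index=int(r.frame),
                time_s=float(r.time_s),
                centroid_px=(float(r.x_px), float(r.y_px)),
                centroid_um=(float(r.x_um), float(r.y_um)),
                area_um2=float(r.area_um2),
                major_axis_um=float(r.major_axis_um),
            )
            for r in grp.itertuples()
        ]
        reason = str(grp.iloc[-1]["stop_reason"])
        tracks.append(
            Track(
                track_id=int(tid),
                points=points,
                stop_reason=StopReason(reason) if reason else None,
            )
        )
    return tracks


def write_features(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValueError("features CSV is missing column(s): ['cell_id']")
    return df


@dataclass
class RunConfig:
    """Serializable bundle of all pipeline parameters.

    JSON round-trip preserves every field; unknown keys in a config file
    are rejected so that typos fail loudly.
    """

    pixel_size: float = 0.65
    frame_interval_s: float = 60.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    turn_thresholds_deg: tuple[float, ...] = (90.0, 60.0, 30.0)
    normalization_hours: float = 30.0
    cv_k: int = 10
    cv_seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        seg = d.pop("segmentation", {})
        trk = d.pop("tracking", {})
        seg_known = {f.name for f in dataclasses.fields(SegmentationConfig)}
        trk_known = {f.name for f in dataclasses.fields(TrackingConfig)}
        for sub, allowed, name in ((seg, seg_known, "segmentation"), (trk, trk_known, "tracking")):
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown {name} config key(s): {sorted(bad)}")
        if "turn_thresholds_deg" in d:
            d["turn_thresholds_deg"] = tuple(d["turn_thresholds_deg"])
        return cls(
            segmentation=SegmentationConfig(**seg),
            tracking=TrackingConfig(**trk),
            **d,
        )
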