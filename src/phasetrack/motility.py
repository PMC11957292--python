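"""The ten trajectory motility parameters.

From a centroid trajectory sampled at a constant interval the module
computes: migration speed; frequency of turns below 90/60/30 degrees;
migration distance between turns below 90/60/30 degrees; sum of turn
angles; quiescent time; and total migration length.

Conventions, fixed here and used everywhere:

* A turn angle is the angle in [0, 180] degrees between consecutive
  displacement vectors. When a step has zero displacement (speed 0 over one
  interval) the adjacent turn angle is set to 0 and flagged, and flagged
  angles are excluded from the turn-frequency counts and from the distance
  between turns.
* "Below" a threshold is strict (<); quiescence (speed below the cell's own
  mean step speed) is also strict. Ties go to the non-event side.
* Turn frequencies, the sum of turn angles and the total migration length
  grow with observation time, so they are normalized to a 30 h window:
  (raw / duration_h) * 30. Quiescent time is reported raw (seconds) plus as
  a fraction of the track; migration distance between turns is raw (um).
* Only tracks longer than 1 h enter population analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NORMALIZATION_HOURS = 30.0
TURN_THRESHOLDS_DEG = (90.0, 60.0, 30.0)

#: canonical column order of the ten parameters in feature tables
PARAMETER_NAMES = [
    "mean_speed_um_s",
    "freq_turns_below_90",
    "freq_turns_below_60",
    "freq_turns_below_30",
    "md_between_turns_90",
    "md_between_turns_60",
    "md_between_turns_30",
    "sum_turn_angles_deg",
    "quiescent_time_s",
    "total_migration_length_um",
]


@dataclass(frozen=True)
class Trajectory:
    """Centroid positions (um) at uniformly spaced times (s)."""

    positions_um: np.ndarray
    times_s: np.ndarray
    cell_id: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        t = np.asarray(self.times_s, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions_um must be (n, 2)")
        if t.shape != (pos.shape[0],):
            raise ValueError("times_s length must match positions")
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "times_s", t)

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclass(frozen=True)
class MotilityProfile:
    """The ten per-cell motility parameters plus bookkeeping.

    md_between_turns_* are NaN when the track has no qualifying turn below
    the threshold (undefined, excluded from population averages).
    """

    cell_id: int
    mean_speed_um_s: float
    freq_turns_below_90: float
    freq_turns_below_60: float
    freq_turns_below_30: float
    md_between_turns_90: float
    md_between_turns_60: float
    md_between_turns_30: float
    sum_turn_angles_deg: float
    quiescent_time_s: float
    quiescent_fraction: float
    total_migration_length_um: float
    track_duration_h: float

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in PARAMETER_NAMES}
        d["cell_id"] = self.cell_id
        d["quiescent_fraction"] = self.quiescent_fraction
        d["track_duration_h"] = self.track_duration_h
        return d


def step_displacements(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval displacement vectors r_i = p_i - p_{i-1} and speeds |r_i|/dt."""
    if len(traj.times_s) < 2:
        raise ValueError("need >= 2 positions for displacements")
    disp = np.diff(traj.positions_um, axis=0)
    speeds = np.linalg.norm(disp, axis=1) / traj.dt_s
    return disp, speeds


def turn_angles(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Turn angles (degrees in [0, 180]) between consecutive displacements.

    Returns (angles, zero_step_flags). theta_i = atan2(|r_i x r_{i+1}|,
    r_i . r_{i+1}); if either adjacent displacement is the zero vector the
    angle is set to 0 and flagged.
    """
    if len(traj.times_s) < 3:
        raise ValueError("need >= 3 positions for turn angles")
    disp, _ = step_displacements(traj)
    a, b = disp[:-1], disp[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    theta = np.degrees(np.arctan2(np.abs(cross), dot))
    zero_step = (np.linalg.norm(a, axis=1) == 0) | (np.linalg.norm(b, axis=1) == 0)
    theta[zero_step] = 0.0
    return theta, zero_step


def _duration_h(traj: Trajectory) -> float:
    dur = traj.duration_s / 3600.0
    if dur <= 0:
        raise ValueError("zero-duration trajectory: normalization undefined")
    return dur


def _per_30h(raw: float, traj: Trajectory) -> float:
    return raw / _duration_h(traj) * NORMALIZATION_HOURS


def freq_turns_below(traj: Trajectory, threshold_deg: float) -> float:
    """Turns strictly below the threshold, normalized to a count per 30 h.

    Angles adjacent to a zero-displacement step are excluded from the count.
    """
    theta, zero_step = turn_angles(traj)
    raw = int(np.sum((theta < threshold_deg) & ~zero_step))
    return _per_30h(raw, traj)


def raw_turn_count_below(traj: Trajectory, threshold_deg: float) -> int:
    theta, zero_step = turn_angles(traj)
    return int(np.sum((theta < threshold_deg) & ~zero_step))


def md_between_turns(traj: Trajectory, threshold_deg: float) -> float:
    """Mean migration distance per turn below the threshold (um).

    Total path length divided by the number of qualifying turns; NaN when
    the trajectory has no turn below the threshold.
    """
    count = raw_turn_count_below(traj, threshold_deg)
    if count == 0:
        return float("nan")
    disp, _ = step_displacements(traj)
    path = float(np.linalg.norm(disp, axis=1).sum())
    return path / count


def sum_turn_angles(traj: Trajectory) -> float:
    """Sum of turn angles, degrees per 30 h (zero-step angles contribute 0)."""
    theta, _ = turn_angles(traj)
    return _per_30h(float(theta.sum()), traj)


def quiescent_time(traj: Trajectory) -> tuple[float, float]:
    """(seconds, fraction) with speed strictly below the cell's mean step speed."""
    _, speeds = step_displacements(traj)
    threshold = speeds.mean()
    quiet_s = traj.dt_s * int(np.sum(speeds < threshold))
    return quiet_s, quiet_s / traj.duration_s


def total_migration_length(traj: Trajectory) -> float:
    """Summed centroid displacements, um per 30 h."""
    disp, _ = step_displacements(traj)
    return _per_30h(float(np.linalg.norm(disp, axis=1).sum()), traj)


def mean_speed(traj: Trajectory) -> float:
    _, speeds = step_displacements(traj)
    return float(speeds.mean())


def profile(traj: Trajectory) -> MotilityProfile:
    """All ten parameters for one trajectory.

    By construction total_migration_length per 30 h equals
    mean_speed * 108000 s (both are the path length divided by the
    duration, rescaled).
    """
    quiet_s, quiet_frac = quiescent_time(traj)
    return MotilityProfile(
        cell_id=traj.cell_id,
        mean_speed_um_s=mean_speed(traj),
        freq_turns_below_90=freq_turns_below(traj, 90.0),
        freq_turns_below_60=freq_turns_below(traj, 60.0),
        freq_turns_below_30=freq_turns_below(traj, 30.0),
        md_between_turns_90=md_between_turns(traj, 90.0),
        md_between_turns_60=md_between_turns(traj, 60.0),
        md_between_turns_30=md_between_turns(traj, 30.0),
        sum_turn_angles_deg=sum_turn_angles(traj),
        quiescent_time_s=quiet_s,
        quiescent_fraction=quiet_frac,
        total_migration_length_um=total_migration_length(traj),
        track_duration_h=traj.duration_s / 3600.0,
    )


def trajectory_from_track(track, cell_id: int | None = None) -> Trajectory:
    """Build a Trajectory from a tracking.Track (um coordinates)."""
    pos = np.array([p.centroid_um for p in track.points], dtype=float)
    t = np.array([p.time_s for p in track.points], dtype=float)
    return Trajectory(pos, t, cell_id=track.track_id if cell_id is None else cell_id)
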