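"""Ground-truthed synthetic trajectories, populations and rendered stacks.

Trajectories follow a persistent random walk: the heading evolves by
wrapped-normal increments whose concentration kappa sets directional
persistence (kappa = 0: uniform new heading each step, mean turn angle 90
degrees; kappa -> inf: straight line), and the step length is the current
speed times the frame interval. Speed follows either a two-state Markov
chain (transient high-speed bursts over a slow baseline, the cancer-like
phenotype) or a constant level with Gaussian jitter (the temporally
homogeneous fibroblast-like phenotype).

Scenes render each cell as an elliptical body with a bright halo rim and
optional low-contrast protrusions on a uniform background with additive
Gaussian noise — the appearance of spread adherent cells in 10x phase
contrast, acquired every minute at 0.65 um/pixel. Per-frame ground-truth
centroids accompany every rendered stack.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .motility import PARAMETER_NAMES, Trajectory, profile
from .segmentation import FrameImage


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one simulated cell population.

    Speeds are um/s; switch probabilities are per step (per frame
    interval). kappa is the concentration of the wrapped-normal heading
    kernel (heading increment sd = 1/sqrt(kappa) radians for kappa > 0).
    """

    n_cells: int = 50
    duration_min: float = 180.0
    dt_s: float = 60.0
    speed_model: str = "two_state"  # "two_state" | "constant"
    v_high: float = 0.06
    v_low: float = 0.013
    p_high_to_low: float = 0.25
    p_low_to_high: float = 0.05
    v_const: float = 0.015
    v_noise_sd: float = 0.004
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_model not in ("two_state", "constant"):
            raise ValueError("speed_model must be 'two_state' or 'constant'")
        if self.speed_model == "two_state" and not self.v_high > self.v_low >= 0:
            raise ValueError("need v_high > v_low >= 0")
        for p in (self.p_high_to_low, self.p_low_to_high):
            if not 0 <= p <= 1:
                raise ValueError("switch probabilities must be in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_cells < 1 or self.duration_min <= 0 or self.dt_s <= 0:
            raise ValueError("invalid population size or timing")

    @property
    def expected_mean_speed(self) -> float:
        """Stationary mean step speed implied by the speed model."""
        if self.speed_model == "constant":
            return self.v_const
        denom = self.p_high_to_low + self.p_low_to_high
        if denom == 0:
            return self.v_low
        pi_high = self.p_low_to_high / denom
        return pi_high * self.v_high + (1 - pi_high) * self.v_low

    @property
    def expected_mean_turn_angle_deg(self) -> float:
        """Mean turn angle implied by the heading kernel.

        Exact (90 degrees) for kappa = 0; for kappa > 0 the half-normal
        mean sd*sqrt(2/pi), a close approximation while wrapping is rare.
        """
        if self.kappa == 0:
            return 90.0
        sigma = 1.0 / np.sqrt(self.kappa)
        return float(np.degrees(sigma * np.sqrt(2.0 / np.pi)))


def cancer_like_spec(**overrides) -> PopulationSpec:
    """Two-speed-mode, weakly persistent population (fibrosarcoma-like).

    Bursty speed (0.06/0.013 um/s high/low, ~1/6 of time in the fast
    state, mean ~0.021 um/s) and a broad turn-angle distribution.
    """
    return replace(PopulationSpec(speed_model="two_state", kappa=0.5), **overrides)


def fibroblast_like_spec(**overrides) -> PopulationSpec:
    """Homogeneous slow, directionally persistent population (3T3-like).

    Constant-mode speed near 0.015 um/s and turn angles concentrated
    near zero.
    """
    return replace(
        PopulationSpec(speed_model="constant", v_const=0.015, kappa=8.0), **overrides
    )


def simulate_trajectory(
    spec: PopulationSpec,
    seed: int | None = None,
    start_um: tuple[float, float] = (0.0, 0.0),
    cell_id: int = 0,
) -> tuple[Trajectory, dict]:
    """One persistent-random-walk trajectory plus its ground-truth record."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_steps = int(round(spec.duration_min * 60.0 / spec.dt_s))
    heading = rng.uniform(0.0, 2.0 * np.pi)
    if spec.speed_model == "two_state":
        denom = spec.p_high_to_low + spec.p_low_to_high
        pi_high = spec.p_low_to_high / denom if denom > 0 else 0.0
        state_high = rng.random() < pi_high
    pos = [np.asarray(start_um, dtype=float)]
    speeds = []
    for _ in range(n_steps):
        if spec.kappa == 0:
            heading = rng.uniform(0.0, 2.0 * np.pi)
        else:
            heading += rng.normal(0.0, 1.0 / np.sqrt(spec.kappa))
        if spec.speed_model == "two_state":
            if state_high:
                if rng.random() < spec.p_high_to_low:
                    state_high = False
            else:
                if rng.random() < spec.p_low_to_high:
                    state_high = True
            v = spec.v_high if state_high else spec.v_low
        else:
            v = max(0.0, spec.v_const + rng.normal(0.0, spec.v_noise_sd))
        speeds.append(v)
        step = v * spec.dt_s
        pos.append(pos[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
    times = np.arange(n_steps + 1) * spec.dt_s
    traj = Trajectory(np.asarray(pos), times, cell_id=cell_id)
    truth = {
        "cell_id": cell_id,
        "expected_mean_speed": spec.expected_mean_speed,
        "realized_mean_speed": float(np.mean(speeds)),
        "expected_mean_turn_angle_deg": spec.expected_mean_turn_angle_deg,
        "kappa": spec.kappa,
        "speed_model": spec.speed_model,
    }
    return traj, truth


def simulate_population(
    spec_a: PopulationSpec,
    spec_b: PopulationSpec,
    label_a: object = 1,
    label_b: object = 2,
) -> pd.DataFrame:
    """Labelled feature table of motility profiles for two populations.

    Trajectories are simulated per spec (seeds derived from spec.seed) and
    profiled through the motility module; the result is one row per cell
    with the ten parameters and a label column.
    """
    rows = []
    for spec, label in ((spec_a, label_a), (spec_b, label_b)):
        ss = np.random.SeedSequence(spec.seed)
        child_seeds = ss.generate_state(spec.n_cells)
        for i in range(spec.n_cells):
            traj, _ = simulate_trajectory(
                spec, seed=int(child_seeds[i] % 2**31), cell_id=i
            )
            d = profile(traj).as_dict()
            d["label"] = label
            rows.append(d)
    return pd.DataFrame(rows)


def simulate_feature_table(
    n_per_class: int = 50,
    informative_pair: tuple[str, str] = ("freq_turns_below_30", "sum_turn_angles_deg"),
    effect: float = 2.0,
    seed: int = 0,
    label_a: object = 1,
    label_b: object = 2,
) -> pd.DataFrame:
    """Feature table where only one parameter pair carries class signal.

    Every one of the ten parameters is drawn as standard normal noise;
    the two informative columns are shifted by `effect` standard
    deviations in the positive class. Used to calibrate the pair search:
    the informative pair should rank first.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for label, shift in ((label_a, effect), (label_b, 0.0)):
        data = {c: rng.normal(0.0, 1.0, n_per_class) for c in PARAMETER_NAMES}
        for c in informative_pair:
            if c not in data:
                raise KeyError(f"unknown parameter: {c}")
            data[c] = data[c] + shift
        df = pd.DataFrame(data)
        df["label"] = label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------- rendering


@dataclass(frozen=True)
class SceneSpec:
    """How to draw cells into phase-contrast-like frames.

    Intensities are arbitrary units on a uniform background; the halo rim
    is the bright band phase optics put around a spread cell and is what
    the gradient-based segmentation keys on. Semi-axes default to a cell
    of ~1600 um2 spreading area, matching the scale of spread
    fibrosarcoma/fibroblast cells.
    """

    frame_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.65
    semi_axis_a_um: float = 26.0
    semi_axis_b_um: float = 20.0
    interior_offset: float = 10.0
    halo_amplitude: float = 60.0
    halo_width_px: float = 2.0
    protrusion_count: int = 0
    protrusion_contrast: float = 5.0
    protrusion_length_um: float = 12.0
    background_level: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.semi_axis_a_um <= 0 or self.semi_axis_b_um <= 0:
            raise ValueError("semi-axes must be positive")
        h, w = self.frame_shape
        need = 2 * (self.semi_axis_a_um / self.pixel_size + self.halo_width_px + 2)
        if need > min(h, w):
            raise ValueError("cells do not fit in the frame")


def _draw_cell(
    frame: np.ndarray,
    cx_px: float,
    cy_px: float,
    scene: SceneSpec,
    orientation: float,
    protrusion_angles: np.ndarray,
) -> None:
    a_px = scene.semi_axis_a_um / scene.pixel_size
    b_px = scene.semi_axis_b_um / scene.pixel_size
    r_out = a_px + scene.halo_width_px + 1
    h, w = frame.shape
    x0, x1 = int(np.floor(cx_px - r_out)) - 1, int(np.ceil(cx_px + r_out)) + 2
    y0, y1 = int(np.floor(cy_px - r_out)) - 1, int(np.ceil(cy_px + r_out)) + 2
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx_px, yy - cy_px
    c, s = np.cos(orientation), np.sin(orientation)
    u = (c * dx + s * dy) / a_px
    v = (-s * dx + c * dy) / b_px
    rho = np.hypot(u, v)
    interior = rho < 1.0
    # rim thickness measured along the minor axis, the tighter direction
    rim_frac = scene.halo_width_px / b_px
    rim = (rho >= 1.0) & (rho < 1.0 + rim_frac)
    frame[y0:y1, x0:x1][interior] += scene.interior_offset
    frame[y0:y1, x0:x1][rim] += scene.halo_amplitude
    for ang in protrusion_angles:
        # a thin, dim ray past the rim: low-contrast protrusion
        L = scene.protrusion_length_um / scene.pixel_size
        t = np.linspace(0, 1, int(L) * 2 + 4)
        px = cx_px + (a_px + t * L) * np.cos(ang)
        py = cy_px + (b_px + t * L) * np.sin(ang)
        ix, iy = np.round(px).astype(int), np.round(py).astype(int)
        ok = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        frame[iy[ok], ix[ok]] += scene.protrusion_contrast


def render_scene(
    trajectories: list[Trajectory], scene: SceneSpec
) -> tuple[list[FrameImage], pd.DataFrame]:
    """Render trajectories into a frame stack with ground truth.

    All trajectories must share the same time base and stay far enough
    from the frame border for the whole cell to fit. Returns the frames
    and a tidy table (cell_id, frame, x_px, y_px, x_um, y_um).
    """
    if not trajectories:
        raise ValueError("no trajectories to render")
    n_frames = len(trajectories[0].times_s)
    for tr in trajectories:
        if len(tr.times_s) != n_frames:
            raise ValueError("trajectories must share the same time base")
    h, w = scene.frame_shape
    ps = scene.pixel_size
    margin = scene.semi_axis_a_um / ps + scene.halo_width_px + 2
    rng = np.random.default_rng(scene.seed)
    orientations = rng.uniform(0, np.pi, len(trajectories))
    prot_angles = [
        rng.uniform(0, 2 * np.pi, scene.protrusion_count) for _ in trajectories
    ]
    frames: list[FrameImage] = []
    truth_rows = []
    for f in range(n_frames):
        frame = np.full((h, w), scene.background_level, dtype=float)
        for k, tr in enumerate(trajectories):
            x_um, y_um = tr.positions_um[f]
            cx, cy = x_um / ps, y_um / ps
            if not (margin <= cx <= w - 1 - margin and margin <= cy <= h - 1 - margin):
                raise ValueError(
                    f"trajectory {k} leaves the renderable area at frame {f}"
                )
            _draw_cell(frame, cx, cy, scene, orientations[k], prot_angles[k])
            truth_rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": f,
                    "x_px": cx,
                    "y_px": cy,
                    "x_um": x_um,
                    "y_um": y_um,
                }
            )
        if scene.noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.noise_sd, frame.shape)
        frames.append(FrameImage(pixels=frame, pixel_size=ps, frame_index=f))
    return frames, pd.DataFrame(truth_rows)
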