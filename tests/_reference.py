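"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions (double loops, explicit
set operations, textbook formulas), deliberately not sharing code with the
package, so that agreement is evidence and not tautology.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def sobel_magnitude_loop(img: np.ndarray) -> np.ndarray:
    """Double-loop 3x3 Sobel magnitude with edge replication."""
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    h, w = img.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            gx = gy = 0.0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    gx += kx[dy + 1][dx + 1] * img[yy, xx]
                    gy += kx[dx + 1][dy + 1] * img[yy, xx]
            out[y, x] = math.hypot(gx, gy)
    return out


def footprint_offsets(footprint: np.ndarray) -> list[tuple[int, int]]:
    r_y = footprint.shape[0] // 2
    r_x = footprint.shape[1] // 2
    offs = []
    for y in range(footprint.shape[0]):
        for x in range(footprint.shape[1]):
            if footprint[y, x]:
                offs.append((y - r_y, x - r_x))
    return offs


def dilate_by_shifts(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Dilation as the union of the mask shifted by every footprint offset."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    for dy, dx in footprint_offsets(footprint):
        yy, xx = ys + dy, xs + dx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        out[yy[ok], xx[ok]] = True
    return out


def erode_outside_true(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Erosion keeping a pixel iff all in-frame footprint positions are true.

    Out-of-frame positions count as foreground (matches the package's
    border convention for ROI-clipped cells). Implemented by padding with
    foreground and intersecting the shifted planes.
    """
    r_y = footprint.shape[0] // 2
    r_x = footprint.shape[1] // 2
    h, w = mask.shape
    padded = np.ones((h + 2 * r_y, w + 2 * r_x), dtype=bool)
    padded[r_y : r_y + h, r_x : r_x + w] = mask
    out = np.ones_like(mask, dtype=bool)
    for dy, dx in footprint_offsets(footprint):
        out &= padded[r_y + dy : r_y + dy + h, r_x + dx : r_x + dx + w]
    return out


def fill_holes_bfs(mask: np.ndarray) -> np.ndarray:
    """Hole filling by 4-connected BFS of the background from the border."""
    h, w = mask.shape
    outside = np.zeros((h, w), dtype=bool)
    q: deque[tuple[int, int]] = deque()
    for y in range(h):
        for x in (0, w - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    for x in range(w):
        for y in (0, h - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    while q:
        y, x = q.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and not mask[yy, xx] and not outside[yy, xx]:
                outside[yy, xx] = True
                q.append((yy, xx))
    return ~outside


def centroid_enumerated(mask: np.ndarray, pixel_mode: bool) -> tuple[float, float]:
    sx = sy = n = 0
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x]:
                sx += x
                sy += y
                n += 1
    cx, cy = sx / n, sy / n
    if pixel_mode:
        rnd = lambda v: math.copysign(math.floor(abs(v) + 0.5), v)
        return rnd(cx), rnd(cy)
    return cx, cy


def turn_angle_arccos(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two displacement vectors via arccos, degrees."""
    na, nb = math.hypot(*a), math.hypot(*b)
    if na == 0 or nb == 0:
        return 0.0
    c = (a[0] * b[0] + a[1] * b[1]) / (na * nb)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def motility_brute_force(pos: np.ndarray, dt: float) -> dict:
    """All ten parameters by explicit loops over the trajectory."""
    n = len(pos)
    disp = [(pos[i + 1][0] - pos[i][0], pos[i + 1][1] - pos[i][1]) for i in range(n - 1)]
    norms = [math.hypot(*d) for d in disp]
    speeds = [v / dt for v in norms]
    duration_s = (n - 1) * dt
    duration_h = duration_s / 3600.0
    angles, zero_flags = [], []
    for i in range(len(disp) - 1):
        z = norms[i] == 0 or norms[i + 1] == 0
        zero_flags.append(z)
        angles.append(0.0 if z else turn_angle_arccos(np.array(disp[i]), np.array(disp[i + 1])))
    out = {"mean_speed_um_s": sum(speeds) / len(speeds)}
    path = sum(norms)
    for thr in (90, 60, 30):
        cnt = sum(1 for a, z in zip(angles, zero_flags) if (not z) and a < thr)
        out[f"freq_turns_below_{thr}"] = cnt / duration_h * 30.0
        out[f"md_between_turns_{thr}"] = path / cnt if cnt else float("nan")
    out["sum_turn_angles_deg"] = sum(angles) / duration_h * 30.0
    mean_v = sum(speeds) / len(speeds)
    quiet = sum(1 for v in speeds if v < mean_v) * dt
    out["quiescent_time_s"] = quiet
    out["quiescent_fraction"] = quiet / duration_s
    out["total_migration_length_um"] = path / duration_h * 30.0
    return out


def mahalanobis_sq_loop(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    inv = np.linalg.inv(cov)
    d = x - mean
    total = 0.0
    for i in range(len(d)):
        for j in range(len(d)):
            total += d[i] * inv[i, j] * d[j]
    return total


def welch_textbook(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    from scipy.stats import t as tdist

    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p
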