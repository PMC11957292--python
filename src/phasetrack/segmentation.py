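"""Single-frame cell segmentation for phase-contrast images.

The chain: Sobel gradient magnitude -> fixed-threshold binarization ->
octagonal dilation -> hole filling -> repeated diamond erosion -> connected
components -> convex hull smoothing of each component. Phase contrast
renders adherent cells as a low-contrast body surrounded by a bright halo
rim, so the cell-spreading area is bounded by strong intensity gradients;
the convex hull smooths the ragged edge mask into a cell outline against
which the centroid and major axis are measured.

Coordinate convention: 0-based, x rightward (columns), y downward (rows),
pixel centers at integer coordinates. Micron coordinates are pixel
coordinates multiplied by the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError


# 3x3 first-derivative (Sobel) kernels; x rightward, y downward.
SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T


@dataclass(frozen=True)
class FrameImage:
    """One grayscale frame with its physical calibration.

    pixels are arbitrary intensity units; pixel_size is um/pixel
    (default 0.65, a 10x phase-contrast objective on a standard camera).
    """

    pixels: np.ndarray
    pixel_size: float = 0.65
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2-D, got {px.ndim}-D")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"frame extent must be >= 16x16, got {px.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the segmentation chain.

    edge_threshold is the gradient-magnitude cutoff, in the same units as
    the intensity gradient. It is adjusted once per acquisition setup and
    then held fixed across frames and cell types; ``None`` requests an
    automatic Otsu threshold on the gradient map (a convenience extension,
    not part of the published chain). min_area_um2 rejects edge-noise blobs
    well below any spread cell (reported spreading areas are ~1900-2250 um2,
    so 200 um2 is an order of magnitude margin).
    """

    edge_threshold: float | None = None
    dilation_radius_px: int = 3
    erosion_radius_px: int = 5
    erosion_repeats: int = 2
    min_area_um2: float = 200.0
    centroid_mode: Literal["pixel", "subpixel"] = "pixel"

    def __post_init__(self) -> None:
        if self.edge_threshold is not None and self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")
        if self.dilation_radius_px < 1 or self.erosion_radius_px < 1:
            raise ValueError("structuring-element radii must be >= 1")
        if self.erosion_repeats < 1:
            raise ValueError("erosion_repeats must be >= 1")
        if not self.min_area_um2 > 0:
            raise ValueError("min_area_um2 must be positive")
        if self.centroid_mode not in ("pixel", "subpixel"):
            raise ValueError("centroid_mode must be 'pixel' or 'subpixel'")


@dataclass
class CellRegion:
    """One segmented cell: filled convex hull support plus derived geometry.

    mask is in the coordinate frame of the image that was segmented (a full
    frame or an ROI crop); hull vertices are (x, y) pixel coordinates of the
    convex polygon, ordered counter-clockwise in image coordinates.
    """

    mask: np.ndarray
    hull: np.ndarray
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]
    area_um2: float
    equivalent_diameter_um: float
    major_axis_length_um: float
    major_axis_orientation_deg: float
    pixel_size: float = 0.65
    label: int = field(default=0)


def octagon_footprint(radius: int) -> np.ndarray:
    """Octagonal structuring element.

    Origin-to-side distance along the horizontal/vertical axes is `radius`;
    the corners are cut at |x| + |y| <= radius + radius // 2. For the default
    radius 3 the pixel set is {max(|x|,|y|) <= 3 and |x|+|y| <= 4}, frozen
    here and in the tests.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    cut = r + r // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.maximum(np.abs(xx), np.abs(yy)) <= r) & (np.abs(xx) + np.abs(yy) <= cut)


def diamond_footprint(radius: int) -> np.ndarray:
    """Diamond structuring element: |x| + |y| <= radius (origin to vertex)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return np.abs(xx) + np.abs(yy) <= r


def compute_edge_magnitude(image: FrameImage | np.ndarray) -> np.ndarray:
    """Gradient-magnitude map: sqrt(Gx^2 + Gy^2) of the 3x3 Sobel kernels.

    Borders are handled by edge replication, so a constant image maps to an
    exactly zero gradient everywhere, including the border.
    """
    px = image.pixels if isinstance(image, FrameImage) else np.asarray(image, dtype=float)
    if px.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {px.ndim}-D")
    gx = ndimage.correlate(px, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(px, SOBEL_Y, mode="nearest")
    return np.hypot(gx, gy)


def binarize_edges(gradmap: np.ndarray, edge_threshold: float) -> np.ndarray:
    """Edge mask: true exactly where gradient magnitude > threshold (strict)."""
    if edge_threshold < 0:
        raise ValueError("edge_threshold must be >= 0")
    return np.asarray(gradmap) > edge_threshold


def refine_mask(edge_mask: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Turn the thin edge mask into solid cell-spreading areas.

    In order: dilation by the octagon footprint, flood fill of enclosed
    holes, then `erosion_repeats` erosions by the diamond footprint.
    Erosion treats out-of-frame pixels as foreground so that a cell clipped
    by the frame (or ROI) border is not eaten from the border side.
    """
    mask = np.asarray(edge_mask, dtype=bool)
    octa = octagon_footprint(config.dilation_radius_px)
    diam = diamond_footprint(config.erosion_radius_px)
    out = ndimage.binary_dilation(mask, structure=octa)
    out = ndimage.binary_fill_holes(out)
    for _ in range(config.erosion_repeats):
        out = ndimage.binary_erosion(out, structure=diam, border_value=1)
    return out


def _hull_vertices(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        h = ConvexHull(pts)
        return pts[h.vertices]
    except QhullError:
        # degenerate (collinear) pixel set: hull is the segment end points
        order = np.lexsort((ys, xs))
        return pts[[order[0], order[-1]]]


def _fill_hull(component: np.ndarray) -> np.ndarray:
    """Pixels whose centers lie inside (or on) the convex hull of the set."""
    ys, xs = np.nonzero(component)
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return component.copy()
    # half-plane test against each hull facet: A @ p + b <= 0 inside
    eqs = hull.equations  # (nfacet, 3): a*x + b*y + c <= 0 inside
    yy, xx = np.nonzero(np.ones_like(component, dtype=bool))
    grid = np.column_stack([xx, yy]).astype(float)
    inside = np.all(grid @ eqs[:, :2].T + eqs[:, 2] <= 1e-9, axis=1)
    return inside.reshape(component.shape)


def _round_half_away(v: float) -> int:
    return int(np.sign(v) * np.floor(np.abs(v) + 0.5))


def centroid_of_mask(
    mask: np.ndarray, centroid_mode: str = "pixel"
) -> tuple[float, float]:
    """Arithmetic-mean (x, y) of the true pixels; pixel mode rounds half away from zero."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("degenerate region: empty mask")
    cx, cy = float(xs.mean()), float(ys.mean())
    if centroid_mode == "pixel":
        return float(_round_half_away(cx)), float(_round_half_away(cy))
    return cx, cy


def centroid_of_region(
    region: CellRegion, centroid_mode: str = "pixel"
) -> tuple[float, float]:
    """Centroid of a segmented cell, from the filled-hull pixel set."""
    return centroid_of_mask(region.mask, centroid_mode)


def major_axis_of_mask(mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Major axis of the equal-second-moments ellipse of the pixel set.

    Returns (length_um, orientation_deg). Length is 4*sqrt(largest
    eigenvalue) of the central second moments (pixel units) scaled to um;
    orientation is the angle between the major axis and the +x axis in
    [-90, 90), positive toward +y (downward in image coordinates).
    """
    ys, xs = np.nonzero(mask)
    if xs.size < 2:
        raise ValueError("degenerate region: major axis needs >= 2 pixels")
    x = xs - xs.mean()
    y = ys - ys.mean()
    n = xs.size
    cov = np.array(
        [[x @ x / n, x @ y / n], [x @ y / n, y @ y / n]]
    )
    evals, evecs = np.linalg.eigh(cov)
    length_px = 4.0 * np.sqrt(max(evals[-1], 0.0))
    vx, vy = evecs[:, -1]
    theta = np.degrees(np.arctan2(vy, vx))
    while theta >= 90.0:
        theta -= 180.0
    while theta < -90.0:
        theta += 180.0
    return length_px * pixel_size, theta


def major_axis(region: CellRegion) -> tuple[float, float]:
    """Major-axis length (um) and orientation (deg) of a segmented cell."""
    return major_axis_of_mask(region.mask, region.pixel_size)


def extract_cells(
    solid_mask: np.ndarray, image: FrameImage, config: SegmentationConfig
) -> list[CellRegion]:
    """Connected components -> convex-hull-smoothed cell regions.

    Components are 8-connected; those with filled-hull area >= min_area_um2
    are kept and returned sorted by descending area.
    """
    mask = np.asarray(solid_mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    ps = image.pixel_size
    min_px = config.min_area_um2 / ps**2
    regions: list[CellRegion] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp_crop = labels[sl] == lab
        if comp_crop.sum() < min_px:
            continue
        filled_crop = _fill_hull(comp_crop)
        filled = np.zeros_like(mask)
        filled[sl] = filled_crop
        area_px = int(filled.sum())
        if area_px < min_px:
            continue
        ys, xs = np.nonzero(comp_crop)
        hull = _hull_vertices(xs + sl[1].start, ys + sl[0].start)
        cx, cy = centroid_of_mask(filled, config.centroid_mode)
        if area_px >= 2:
            maj_um, orient = major_axis_of_mask(filled, ps)
        else:
            maj_um, orient = ps, 0.0
        area_um2 = area_px * ps**2
        regions.append(
            CellRegion(
                mask=filled,
                hull=hull,
                centroid_px=(cx, cy),
                centroid_um=(cx * ps, cy * ps),
                area_um2=area_um2,
                equivalent_diameter_um=2.0 * np.sqrt(area_um2 / np.pi),
                major_axis_length_um=maj_um,
                major_axis_orientation_deg=orient,
                pixel_size=ps,
                label=lab,
            )
        )
    regions.sort(key=lambda r: -r.area_um2)
    return regions


def auto_edge_threshold(gradmap: np.ndarray) -> float:
    """Otsu threshold on the gradient-magnitude histogram (convenience default)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(gradmap, dtype=float)))


def segment_frame(
    image: FrameImage, config: SegmentationConfig
) -> list[CellRegion]:
    """Full segmentation chain on one frame (or ROI crop)."""
    grad = compute_edge_magnitude(image)
    thr = config.edge_threshold
    if thr is None:
        thr = auto_edge_threshold(grad)
    edges = binarize_edges(grad, thr)
    solid = refine_mask(edges, config)
    return extract_cells(solid, image, config)
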