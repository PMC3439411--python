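"""Cell shape kinematics: segmentation, circularity, tracking, local stretch.

The circularity index CI = 4 pi A / P^2 equals 1 for a circle and tends to 0
for elongated shapes; its decline with stretch quantifies how much of the
global tissue deformation reaches the resident cells.  Local (mid-zone)
stretch is estimated independently by tracking virtual fiducial markers and
projecting marker-pair separations on the loading axis.

Coordinate convention: raster origin top-left, 0-based pixel indices,
x (columns) rightward along the loading axis, y (rows) downward; angles in
degrees from +x toward +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import Polygon

from .errors import (
    InsufficientDataError,
    InvalidPolygonError,
    InvalidSeedError,
    UnstablePairError,
)
from .stats import linear_trend


@dataclass(frozen=True)
class CellOutline:
    """Closed planar polygon outlining one cell in one frame."""

    cell_id: int
    frame: int
    vertices: np.ndarray  # (n, 2) array of (x, y) pixel coordinates

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise InvalidPolygonError("outline needs at least 3 (x, y) vertices")

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(Polygon(self.vertices).centroid.coords[0])


@dataclass(frozen=True)
class CircularityTrajectory:
    """Mean circularity per stretch level with its linear trend."""

    stretch: np.ndarray
    mean_ci: np.ndarray
    per_cell_ci: pd.DataFrame  # rows: cell_id, columns: frame index
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class MarkerTrack:
    """Per-frame positions of one tracked fiducial marker.

    ``positions`` holds one (x, y) row per frame; rows from ``lost_frame``
    onward are NaN when the marker was lost (correlation below the floor or
    search window out of frame).  Lost trajectories are truncated, never
    interpolated.
    """

    marker_id: int
    positions: np.ndarray
    lost_frame: int | None = None

    def alive_at(self, frame: int) -> bool:
        return self.lost_frame is None or frame < self.lost_frame


def circularity(outline: CellOutline | np.ndarray) -> float:
    """Circularity index CI = 4 pi Area / Perimeter^2 of a simple polygon.

    Area by the shoelace formula, perimeter by summed edge lengths; CI lies
    in (0, 1] up to discretization of the boundary.

    Raises
    ------
    InvalidPolygonError
        For fewer than 3 vertices or a self-intersecting outline.
    """
    verts = outline.vertices if isinstance(outline, CellOutline) else np.asarray(outline, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise InvalidPolygonError("need at least 3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise InvalidPolygonError("outline is self-intersecting or degenerate")
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    perimeter = float(np.hypot(edges[:, 0], edges[:, 1]).sum())
    if perimeter == 0:
        raise InvalidPolygonError("zero-perimeter outline")
    return float(4.0 * math.pi * area / perimeter**2)


def _polygonize(region_mask: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray | None:
    """Subpixel boundary polygon of a binary region, smoothed along the contour.

    Marching-squares contours of binary rasters carry staircase noise that
    biases the perimeter high (and hence CI low); a small circular Gaussian
    smoothing of the vertex coordinates removes it without shrinking the
    region appreciably.
    """
    from skimage.measure import find_contours

    padded = np.pad(region_mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    if len(contour) < 8:
        return None
    closed = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    if smooth_sigma > 0:
        closed = np.column_stack(
            [gaussian_filter1d(closed[:, i], smooth_sigma, mode="wrap") for i in range(2)]
        )
    # contour is (row, col) = (y, x); subtract padding
    return np.column_stack([closed[:, 1], closed[:, 0]]) - 1.0


def outlines_from_labels(
    labels: np.ndarray, frame: int = 0, min_area: int = 20, max_area: int | None = None
) -> list[CellOutline]:
    """Boundary outlines of every labeled region (label ids become cell ids)."""
    from skimage.measure import regionprops

    outlines = []
    for prop in regionprops(np.asarray(labels)):
        if prop.area < min_area or (max_area is not None and prop.area > max_area):
            continue
        sub = np.zeros(prop.image.shape, dtype=bool)
        sub[prop.image] = True
        verts = _polygonize(sub)
        if verts is None:
            continue
        verts = verts + np.array([prop.bbox[1], prop.bbox[0]], dtype=float)
        outlines.append(CellOutline(cell_id=int(prop.label), frame=frame, vertices=verts))
    return outlines


def segment_cells(
    image: np.ndarray, min_area: int = 20, max_area: int | None = None, frame: int = 0
) -> list[CellOutline]:
    """Segment a grayscale raster into cell outlines.

    Global Otsu threshold, connected components, area filter, boundary
    polygonization.  An empty result (no component surviving the filter) is
    returned as an empty list, not an error.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as cc_label

    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return []
    binary = img > threshold_otsu(img)
    if not binary.any() or binary.all():
        return []
    return outlines_from_labels(cc_label(binary), frame=frame, min_area=min_area, max_area=max_area)


def match_cells(
    frames: Sequence[Sequence[CellOutline]], gating_radius: float = 40.0
) -> list[list[CellOutline]]:
    """Track cells across frames by nearest-centroid assignment.

    For each consecutive frame pair, candidate matches within the gating
    radius are assigned greedily by increasing centroid distance (ties broken
    by lowest cell label), so the assignment is injective.  Only chains that
    persist through every frame are returned; unmatched cells drop out.
    """
    if len(frames) < 2:
        raise InsufficientDataError("need at least 2 frames to match")
    chains = [[cell] for cell in frames[0]]
    for nxt in frames[1:]:
        if gating_radius <= 0 or not nxt:
            return []
        prev_cells = [chain[-1] for chain in chains]
        cand = []
        for i, p in enumerate(prev_cells):
            pc = p.centroid
            for j, q in enumerate(nxt):
                d = float(np.hypot(*(pc - q.centroid)))
                if d <= gating_radius:
                    cand.append((d, p.cell_id, q.cell_id, i, j))
        cand.sort()
        used_prev: set[int] = set()
        used_next: set[int] = set()
        new_chains = []
        for d, _, _, i, j in cand:
            if i in used_prev or j in used_next:
                continue
            used_prev.add(i)
            used_next.add(j)
            new_chains.append(chains[i] + [nxt[j]])
        chains = new_chains
        if not chains:
            return []
    return chains


def ci_trajectory(
    matched: Sequence[Sequence[CellOutline]], stretches: Sequence[float]
) -> CircularityTrajectory:
    """Mean circularity per frame and its ordinary-least-squares trend on stretch.

    The headline slope is fit to the per-frame *mean* CI; the per-cell CI
    table is retained for inspection.
    """
    stretches = np.asarray(stretches, dtype=float)
    if len(matched) < 1 or len(stretches) < 2:
        raise InsufficientDataError("need >= 2 frames with >= 1 matched cell")
    n_frames = len(stretches)
    table = {}
    for chain in matched:
        if len(chain) != n_frames:
            raise ValueError("every chain must span all frames")
        table[chain[0].cell_id] = [circularity(c) for c in chain]
    per_cell = pd.DataFrame.from_dict(table, orient="index", columns=list(range(n_frames)))
    per_cell.index.name = "cell_id"
    mean_ci = per_cell.mean(axis=0).to_numpy()
    slope, intercept, r2 = linear_trend(stretches, mean_ci)
    return CircularityTrajectory(
        stretch=stretches,
        mean_ci=mean_ci,
        per_cell_ci=per_cell,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
    )


def track_fiducials(
    frames: Sequence[np.ndarray],
    seeds: np.ndarray,
    template_radius: int = 8,
    search_radius: int = 15,
    corr_floor: float = 0.5,
) -> list[MarkerTrack]:
    """Track virtual fiducial markers by normalized cross-correlation.

    Each marker's template is the frame-0 patch around its seed; in every
    later frame the template is matched inside a window around the previous
    position and the correlation peak is refined to subpixel precision by a
    parabolic fit.  A marker whose peak correlation drops below
    ``corr_floor``, or whose search window leaves the raster, is flagged lost
    from that frame onward (truncated, never interpolated).
    """
    from skimage.feature import match_template

    frames = [np.asarray(f, dtype=float) for f in frames]
    h, w = frames[0].shape
    seeds = np.asarray(seeds, dtype=float)
    tracks = []
    for mid, seed in enumerate(seeds):
        x0, y0 = seed
        if not (0 <= x0 < w and 0 <= y0 < h):
            raise InvalidSeedError(f"seed {seed} outside the {w}x{h} raster")
        cx, cy = int(round(x0)), int(round(y0))
        r = template_radius
        if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
            raise InvalidSeedError(f"seed {seed} too close to the border for radius {r}")
        template = frames[0][cy - r : cy + r + 1, cx - r : cx + r + 1]
        positions = np.full((len(frames), 2), np.nan)
        positions[0] = seed
        lost_frame = None
        prev = np.array([float(cx), float(cy)])
        for t in range(1, len(frames)):
            px, py = int(round(prev[0])), int(round(prev[1]))
            half = r + search_radius
            x_lo, x_hi = px - half, px + half + 1
            y_lo, y_hi = py - half, py + half + 1
            if x_lo < 0 or y_lo < 0 or x_hi > w or y_hi > h:
                lost_frame = t
                break
            window = frames[t][y_lo:y_hi, x_lo:x_hi]
            corr = match_template(window, template)
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[peak] < corr_floor:
                lost_frame = t
                break
            dy, dx = _parabolic_refine(corr, peak)
            pos = np.array(
                [x_lo + peak[1] + dx + r, y_lo + peak[0] + dy + r], dtype=float
            )
            positions[t] = pos
            prev = pos
        tracks.append(MarkerTrack(marker_id=mid, positions=positions, lost_frame=lost_frame))
    return tracks


def _parabolic_refine(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Subpixel offset of a correlation peak by separable 3-point parabola fit."""
    offsets = []
    for axis in range(2):
        i = peak[axis]
        if i == 0 or i == corr.shape[axis] - 1:
            offsets.append(0.0)
            continue
        idx = list(peak)
        idx[axis] = i - 1
        c_m = corr[tuple(idx)]
        idx[axis] = i + 1
        c_p = corr[tuple(idx)]
        c_0 = corr[peak]
        denom = c_m - 2.0 * c_0 + c_p
        offsets.append(0.0 if denom == 0 else float(0.5 * (c_m - c_p) / denom))
    return offsets[0], offsets[1]


def local_stretch(
    pairs: Sequence[tuple[MarkerTrack, MarkerTrack]], axis: float = 0.0
) -> np.ndarray:
    """Per-frame local stretch from marker-pair separations along the loading axis.

    For each pair, the current pair separation projected on the axis
    (``axis`` in degrees from +x) is divided by its frame-0 projection;
    frames average over all pairs still tracked.  Frames with no surviving
    pair are NaN.

    Raises
    ------
    UnstablePairError
        If a pair's initial projected separation is below 2 px.
    """
    if not pairs:
        raise InsufficientDataError("need at least one marker pair")
    u = np.array([math.cos(math.radians(axis)), math.sin(math.radians(axis))])
    n_frames = len(pairs[0][0].positions)
    ratios = np.full((len(pairs), n_frames), np.nan)
    for idx, (ta, tb) in enumerate(pairs):
        sep0 = abs(float((tb.positions[0] - ta.positions[0]) @ u))
        if sep0 < 2.0:
            raise UnstablePairError(
                f"pair ({ta.marker_id}, {tb.marker_id}) initial projected separation "
                f"{sep0:.2f} px < 2 px"
            )
        for t in range(n_frames):
            if ta.alive_at(t) and tb.alive_at(t):
                ratios[idx, t] = abs(float((tb.positions[t] - ta.positions[t]) @ u)) / sep0
    with np.errstate(invalid="ignore"):
        return np.nanmean(ratios, axis=0)


# --------------------------------------------------------------------------
# external interfaces
# --------------------------------------------------------------------------


def read_tracings(path: str | Path) -> dict[int, list[CellOutline]]:
    """Ingest external cell tracings from a CSV of
    ``cell_id, frame, vertex_index, x_px, y_px``; returns outlines per frame."""
    table = pd.read_csv(path)
    frames: dict[int, list[CellOutline]] = {}
    for (cid, frame), sub in table.groupby(["cell_id", "frame"], sort=True):
        sub = sub.sort_values("vertex_index")
        verts = sub[["x_px", "y_px"]].to_numpy(dtype=float)
        frames.setdefault(int(frame), []).append(
            CellOutline(cell_id=int(cid), frame=int(frame), vertices=verts)
        )
    return frames


def write_ci_trajectory(traj: CircularityTrajectory, path: str | Path) -> None:
    """Write the trajectory CSV (``frame, stretch, mean_ci, n_cells``) and a
    sibling ``<name>.fit.csv`` with the linear-fit summary row."""
    path = Path(path)
    n_cells = len(traj.per_cell_ci)
    pd.DataFrame(
        {
            "frame": np.arange(len(traj.stretch)),
            "stretch": traj.stretch,
            "mean_ci": traj.mean_ci,
            "n_cells": n_cells,
        }
    ).to_csv(path, index=False)
    pd.DataFrame(
        [{"slope": traj.slope, "intercept": traj.intercept, "r2": traj.r_squared, "n_cells": n_cells}]
    ).to_csv(path.with_suffix(".fit.csv"), index=False)
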