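"""Geometric front-arrival predictor of interface patterns.

Growth-matched swarming colonies expand at a constant front speed, so the
territory claimed by each seed is the set of points it reaches first, and
boundaries between territories are loci of equal arrival time.  For equal
speeds and delays this is exactly the Voronoi tessellation of the seed
points; a delay shifts the boundary into a hyperbola branch, unequal
speeds bend it into an Apollonius circle, and a line source paired with a
point source yields a parabola.  This module evaluates arrival times on a
grid, labels each cell by its first-arriving seed and extracts the
interface curves between territories, flagging each one visible or hidden
from the adhesion elements of the two adjacent seeds.  It is the fast,
PDE-free oracle used by the inverse-design algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point
from skimage import measure

from .adhesion import NULL, Element, parse_element, visible_interface

__all__ = [
    "SeedSpec",
    "GridSpec",
    "LabelField",
    "InterfaceCurve",
    "arrival_time",
    "label_and_interfaces",
    "interface_angle",
    "interfaces_to_geojson",
]


@dataclass(frozen=True)
class SeedSpec:
    """A seeded inoculum for the geometric predictor.

    ``position`` is an (x, y) point in mm, or a polyline (sequence of
    points) for a line source; ``delay`` the swarming-onset delay in h;
    ``speed`` the front expansion speed in mm/h; ``element`` the adhesion
    element carried (defaults to the null element).
    """

    position: tuple[float, float] | Sequence[tuple[float, float]]
    element: Element = NULL
    delay: float = 0.0
    speed: float = 1.0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if self.speed <= 0:
            raise ValueError("speed must be strictly positive")
        if isinstance(self.element, str):
            object.__setattr__(self, "element", parse_element(self.element))

    @property
    def geometry(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.ndim == 1:
            return Point(pos)
        return LineString(pos)


@dataclass(frozen=True)
class GridSpec:
    """Regular evaluation grid: extent (mm) and spacing (mm, default 0.1)."""

    extent: tuple[float, float] = (40.0, 40.0)
    dx: float = 0.1
    origin: tuple[float, float] = (0.0, 0.0)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        nx = int(round(self.extent[0] / self.dx)) + 1
        ny = int(round(self.extent[1] / self.dx)) + 1
        x = self.origin[0] + self.dx * np.arange(nx)
        y = self.origin[1] + self.dx * np.arange(ny)
        return x, y


@dataclass
class LabelField:
    """Winning-seed index per grid cell, with first/second arrival times.

    Only the two best arrival times are stored (memory stays O(grid) for
    any number of seeds); per-seed arrival grids are recomputed on demand
    during interface extraction.
    """

    labels: np.ndarray          # (ny, nx) int, first-arriving seed
    best_t: np.ndarray          # (ny, nx) h, first arrival
    second_t: np.ndarray        # (ny, nx) h, second-best arrival
    second_l: np.ndarray        # (ny, nx) int, second-best seed
    grid: GridSpec

    def cell_centre(self, i: int, j: int) -> tuple[float, float]:
        return (self.grid.origin[0] + j * self.grid.dx,
                self.grid.origin[1] + i * self.grid.dx)


@dataclass
class InterfaceCurve:
    """One extracted interface trace between two seed territories."""

    points: np.ndarray          # (n, 2) mm
    seed_a: int
    seed_b: int
    visible: bool

    @property
    def geometry(self) -> LineString:
        return LineString(self.points)


def arrival_time(point: tuple[float, float], seed: SeedSpec) -> float:
    """Time (h) at which ``seed``'s front reaches ``point``.

    ``delay + dist(point, seed geometry) / speed`` with Euclidean distance
    to the point or to the nearest point of the polyline.
    """
    d = seed.geometry.distance(Point(point))
    return seed.delay + d / seed.speed


def _arrival_grid(seed: SeedSpec, grid: GridSpec) -> np.ndarray:
    x, y = grid.coords()
    pos = np.asarray(seed.position, dtype=float)
    if pos.ndim == 1:
        d = np.hypot(x[None, :] - pos[0], y[:, None] - pos[1])
    else:
        xx, yy = np.meshgrid(x, y)
        pts = shapely.points(xx.ravel(), yy.ravel())
        d = shapely.distance(pts, seed.geometry).reshape(yy.shape)
    return seed.delay + d / seed.speed


def label_and_interfaces(
    seeds: Sequence[SeedSpec],
    grid: GridSpec | None = None,
    *,
    min_curve_points: int = 2,
) -> tuple[LabelField, list[InterfaceCurve]]:
    """Label the grid by first-arriving seed and extract interface curves.

    Every grid cell is labelled ``argmin_k arrival_time`` (ties broken by
    lowest seed index).  For every pair of labels that touch, the zero
    level set of the arrival-time difference is traced with sub-cell
    accuracy and clipped to the locus where those two seeds are jointly
    first; each resulting curve carries a visible/hidden flag computed
    from the two seeds' adhesion elements (geometry never influences the
    flag).

    Raises
    ------
    ValueError
        For fewer than two seeds or duplicate seed geometries.
    """
    if grid is None:
        grid = GridSpec()
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    seen: dict[bytes, int] = {}
    for i, s in enumerate(seeds):
        key = shapely.normalize(s.geometry).wkb
        if key in seen:
            raise ValueError(
                f"duplicate seed geometry (seeds {seen[key]} and {i})")
        seen[key] = i

    # incremental best / second-best arrival tracking: memory O(grid)
    best_t = _arrival_grid(seeds[0], grid)
    labels = np.zeros_like(best_t, dtype=np.int32)
    second_t = np.full_like(best_t, np.inf)
    second_l = np.full_like(labels, -1)
    for k in range(1, len(seeds)):
        tk = _arrival_grid(seeds[k], grid)
        beats_first = tk < best_t
        beats_second = ~beats_first & (tk < second_t)
        second_t = np.where(beats_first, best_t, second_t)
        second_l = np.where(beats_first, labels, second_l)
        best_t = np.where(beats_first, tk, best_t)
        second_t = np.where(beats_second, tk, second_t)
        second_l = np.where(beats_second, k, second_l)
        labels = np.where(beats_first, k, labels)
    lf = LabelField(labels, best_t, second_t, second_l, grid)

    # adjacent label pairs (4-connectivity)
    pairs: set[tuple[int, int]] = set()
    for a, b in zip(labels[:, :-1].ravel(), labels[:, 1:].ravel()):
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    for a, b in zip(labels[:-1, :].ravel(), labels[1:, :].ravel()):
        if a != b:
            pairs.add((min(a, b), max(a, b)))

    curves: list[InterfaceCurve] = []
    for a, b in sorted(pairs):
        Ta = _arrival_grid(seeds[a], grid)
        Tb = _arrival_grid(seeds[b], grid)
        diff = Ta - Tb
        # best arrival among all seeds other than a and b, for clipping
        # large finite sentinel where a and b are jointly first: inf would
        # poison the linear interpolation below
        far = 1e30
        oth = np.where(~np.isin(labels, (a, b)), best_t,
                       np.where(~np.isin(second_l, (a, b)), second_t, far))
        vis = visible_interface(seeds[a].element, seeds[b].element)
        for contour in measure.find_contours(diff, 0.0):
            # contour rows are (i, j) index coordinates
            t_ab = ndimage.map_coordinates(Ta, contour.T, order=1)
            t_oth = ndimage.map_coordinates(oth, contour.T, order=1)
            # a point belongs to the a|b interface only where a and b are
            # jointly first (small tolerance for interpolation)
            keep = t_ab <= t_oth + 0.5 * grid.dx / min(
                seeds[a].speed, seeds[b].speed
            )
            for run in _true_runs(keep):
                seg = contour[run]
                if len(seg) < min_curve_points:
                    continue
                pts = np.column_stack([
                    grid.origin[0] + seg[:, 1] * grid.dx,
                    grid.origin[1] + seg[:, 0] * grid.dx,
                ])
                curves.append(InterfaceCurve(pts, a, b, vis))
    return lf, curves


def _true_runs(mask: np.ndarray) -> list[slice]:
    """Maximal runs of consecutive True entries."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(slice(start, i))
            start = None
    if start is not None:
        runs.append(slice(start, len(mask)))
    return runs


def interface_angle(
    trace: np.ndarray,
    seed_axis: tuple[tuple[float, float], tuple[float, float]],
) -> tuple[float, float]:
    """Angle (degrees) between each interface leg and the seed axis.

    The trace is split at its vertex -- the point of minimum distance to
    the line through the two seeding positions -- into two legs; each leg
    is fitted with a least-squares line (principal direction, robust to
    steep legs) and the acute angle between that line and the seed axis is
    returned, in degrees, one value per leg.  A perpendicular-bisector
    interface gives (90, 90).

    Raises
    ------
    ValueError
        If either leg has fewer than two distinct points.
    """
    trace = np.asarray(trace, dtype=float)
    p0 = np.asarray(seed_axis[0], dtype=float)
    p1 = np.asarray(seed_axis[1], dtype=float)
    axis = p1 - p0
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("degenerate seed axis")
    axis /= norm
    # signed distance of trace points to the axis line
    d = (trace - p0) @ np.array([-axis[1], axis[0]])
    k = int(np.argmin(np.abs(d)))
    legs = [trace[: k + 1], trace[k:]]
    angles = []
    for leg in legs:
        if len(leg) < 2 or np.allclose(leg, leg[0]):
            raise ValueError("interface leg has fewer than two distinct points")
        centred = leg - leg.mean(axis=0)
        # principal direction = least-squares line through the leg
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        direction = vt[0]
        cosang = abs(float(direction @ axis))
        angles.append(float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))))
    return angles[0], angles[1]


def interfaces_to_geojson(curves: Sequence[InterfaceCurve]) -> dict:
    """GeoJSON FeatureCollection of interface LineStrings (units: mm)."""
    feats = []
    for c in curves:
        feats.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in c.points],
            },
            "properties": {
                "seed_a": int(c.seed_a),
                "seed_b": int(c.seed_b),
                "visible": bool(c.visible),
            },
        })
    return {"type": "FeatureCollection", "units": "mm", "features": feats}
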