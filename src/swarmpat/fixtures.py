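"""Synthetic fixtures and the shared file formats.

Everything the tests and demos need is generated programmatically and
deterministically from an RNG seed: random Voronoi tessellations,
triangular-lattice target sets, the Escher-style triangles-to-cubes-to-
hexagons transmutation pattern, 16-segment glyph patterns, clustered
(Thomas) and completely spatially random bivariate point patterns,
synthetic Hill+Gaussian profiles with noise, and the standard two-colony
layout at 9-mm spacing.

File formats (all plain text): seed CSV (x_mm, y_mm, element, delay_h,
speed), pattern GeoJSON (LineString edges with a ``desired`` property),
profile CSV (x_mm, intensity...), point-pattern CSV (x_um, y_um, type),
trajectory TIFF (one page per strain and phase) with a CSV index.
Coordinates are 2-D Cartesian, origin bottom-left, y up; plates in mm,
point patterns in um; geometry files carry an explicit ``units`` field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, box
from shapely.ops import voronoi_diagram

from .adhesion import format_element, parse_element
from .design import InterfacePattern, PatternEdge, Tessellation
from .fronts import SeedSpec
from .pde import FieldState
from .stats import hill_gauss

__all__ = [
    "random_voronoi_tessellation",
    "voronoi_pattern",
    "random_lattice_targets",
    "escher_transmutation_pattern",
    "thomas_point_pattern",
    "csr_point_pattern",
    "synthetic_profile",
    "two_colony_seeds",
    "seeds_to_csv",
    "seeds_from_csv",
    "pattern_to_file",
    "pattern_from_file",
    "profile_to_csv",
    "points_to_csv",
    "points_from_csv",
    "trajectory_to_tiff",
]

log = logging.getLogger("swarmpat")


# -- generators ---------------------------------------------------------------

def random_voronoi_tessellation(
    n: int = 50,
    extent: tuple[float, float] = (40.0, 40.0),
    seed: int = 0,
    min_separation: float = 0.5,
) -> tuple[Tessellation, np.ndarray]:
    """Voronoi tessellation of n uniform points in a rectangle (faces clipped).

    Points closer than ``min_separation`` to each other are resampled so
    faces have usable area.  Returns the tessellation (all face
    adjacencies flagged visible) and the generating points.
    """
    rng = np.random.default_rng(seed)
    W, H = extent
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform((0, 0), (W, H))
        if all(np.hypot(*(p - q)) >= min_separation for q in pts):
            pts.append(p)
    points = np.array(pts)
    dom = box(0, 0, W, H)
    cells = voronoi_diagram(MultiPoint(points), envelope=dom)
    faces = []
    for cell in cells.geoms:
        clipped = cell.intersection(dom)
        if clipped.area > 1e-9:
            faces.append(clipped)
    tess = Tessellation.from_faces(faces, (0.0, 0.0, W, H))
    return tess, points


def voronoi_pattern(tess: Tessellation) -> InterfacePattern:
    """All interior face boundaries of a tessellation as visible edges."""
    edges: list[PatternEdge] = []
    for _, _, d in tess.adjacency.edges(data=True):
        geoms = getattr(d["shared"], "geoms", [d["shared"]])
        for g in geoms:
            coords = list(g.coords)
            for a, b in zip(coords[:-1], coords[1:]):
                if a != b:
                    edges.append(PatternEdge(a, b, "visible"))
    return InterfacePattern(edges, tess.domain)


def random_lattice_targets(
    nrows: int,
    ncols: int,
    n_regions: int = 6,
    seed: int = 0,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Random realizable target edges on a triangular lattice.

    Triangles are partitioned into ``n_regions`` connected regions
    (nearest of n random source triangles by dual-graph distance, ties by
    source order); the target set is every lattice edge between two
    different regions.  Such region boundaries are exactly the patterns a
    doublet assignment can realize: each region is hidden-connected and
    the region-adjacency quotient is planar, hence four-colourable.
    """
    import networkx as nx

    from .design import lattice_adjacency

    rng = np.random.default_rng(seed)
    adj = lattice_adjacency(nrows, ncols)
    nodes = sorted(adj.nodes())
    sources = [nodes[i] for i in rng.choice(len(nodes), n_regions,
                                            replace=False)]
    dist = {s: nx.single_source_shortest_path_length(adj, s)
            for s in sources}
    region = {v: min(range(n_regions), key=lambda k: (dist[sources[k]][v], k))
              for v in nodes}
    return [tuple(e) for e in sorted(adj.edges())
            if region[e[0]] != region[e[1]]]


def escher_transmutation_pattern(
    n_cols: int = 3,
    side: float = 4.0,
    margin: float = 3.0,
) -> InterfacePattern:
    """Escher-style vertical transmutation: triangles -> cubes -> hexagons.

    Three stacked bands built on one hexagonal lattice of edge length
    ``side`` (mm): the bottom band subdivides each hexagon into its six
    equilateral triangles, the middle band into three rhombi (the classic
    cube illusion), and the top band keeps plain hexagons, so the bands
    tile seamlessly along their junctions.
    """
    edges: list[PatternEdge] = []
    w = np.sqrt(3.0) * side          # hexagon width (pointy-top)
    rows = 3

    def hex_centre(q: int, r: int) -> tuple[float, float]:
        return (margin + w * (q + 0.5 * (r % 2)) + w / 2,
                margin + 1.5 * side * r + side)

    def hex_corners(cx: float, cy: float) -> np.ndarray:
        ang = np.pi / 180.0 * (60.0 * np.arange(6) + 30.0)
        return np.column_stack([cx + side * np.cos(ang),
                                cy + side * np.sin(ang)])

    def add(p, q):
        p, q = tuple(np.round(p, 9)), tuple(np.round(q, 9))
        if p != q:
            edges.append(PatternEdge(p, q, "visible"))

    for r in range(rows):
        for qq in range(n_cols):
            cx, cy = hex_centre(qq, r)
            corners = hex_corners(cx, cy)
            for i in range(6):
                add(corners[i], corners[(i + 1) % 6])
            if r == 0:
                # six triangles: all three long diagonals
                for i in range(3):
                    add(corners[i], corners[i + 3])
            elif r == 1:
                # three rhombi: spokes to alternating corners
                for i in (0, 2, 4):
                    add((cx, cy), corners[i])
    xs = [e.p0[0] for e in edges] + [e.p1[0] for e in edges]
    ys = [e.p0[1] for e in edges] + [e.p1[1] for e in edges]
    domain = (0.0, 0.0, max(xs) + margin, max(ys) + margin)
    return InterfacePattern(edges, domain)


def thomas_point_pattern(
    n_parents: int = 30,
    offspring_per_type: int = 8,
    sigma: float = 2.0,
    window: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate Thomas cluster process with shared parents.

    Each of ``n_parents`` uniform parents spawns Poisson(``offspring_per_
    type``) children of each type, displaced by an isotropic Gaussian of
    standard deviation ``sigma`` (um).  Sharing parents across the two
    types yields strong short-range cross-type clustering, emulating the
    mixed adhesive aggregates found at interfaces.  Children falling
    outside the window are dropped.
    """
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window
    parents = rng.uniform((x0, y0), (x1, y1), size=(n_parents, 2))
    out = []
    for _type in range(2):
        pts = []
        for p in parents:
            k = rng.poisson(offspring_per_type)
            pts.append(p + rng.normal(0.0, sigma, size=(k, 2)))
        pts = np.vstack(pts)
        keep = ((pts[:, 0] >= x0) & (pts[:, 0] <= x1)
                & (pts[:, 1] >= y0) & (pts[:, 1] <= y1))
        out.append(pts[keep])
    return out[0], out[1]


def csr_point_pattern(
    n_per_type: int = 250,
    window: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent completely-spatially-random (binomial) point sets."""
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window
    a = rng.uniform((x0, y0), (x1, y1), size=(n_per_type, 2))
    b = rng.uniform((x0, y0), (x1, y1), size=(n_per_type, 2))
    return a, b


def synthetic_profile(
    z: float = 1.0,
    k_a: float = 3.0,
    n: float = 6.0,
    y: float = 0.0,
    a: float = 0.3,
    b: float = 1.0,
    noise: float = 0.01,
    x: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hill+Gaussian profile with additive Gaussian noise (fraction of range)."""
    rng = np.random.default_rng(seed)
    if x is None:
        x = np.linspace(0.05, 6.0, 240)
    f = hill_gauss(x, z, k_a, n, y, a, b)
    span = float(f.max() - f.min()) or 1.0
    return x, f + rng.normal(0.0, noise * span, size=x.shape)


def two_colony_seeds(
    elements: tuple[str, str] = ("Nb2", "Ag2"),
    spacing: float = 9.0,
    centre: tuple[float, float] = (20.0, 20.0),
    delay: tuple[float, float] = (0.0, 0.0),
    speed: tuple[float, float] = (1.0, 1.0),
) -> list[SeedSpec]:
    """The standard interface assay: two colonies 9 mm apart on one axis."""
    cx, cy = centre
    return [
        SeedSpec((cx - spacing / 2, cy), parse_element(elements[0]),
                 delay[0], speed[0]),
        SeedSpec((cx + spacing / 2, cy), parse_element(elements[1]),
                 delay[1], speed[1]),
    ]


# -- file formats -------------------------------------------------------------

_CSV_FLOAT = "%.9g"


def seeds_to_csv(seeds: Sequence[SeedSpec], path: str | Path) -> None:
    rows = []
    for s in seeds:
        pos = np.asarray(s.position, float).ravel()
        rows.append({
            "x_mm": pos[0], "y_mm": pos[1],
            "element": format_element(s.element),
            "delay_h": s.delay, "speed": s.speed,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_CSV_FLOAT)


def seeds_from_csv(path: str | Path) -> list[SeedSpec]:
    df = pd.read_csv(path)
    seeds = []
    for i, row in df.iterrows():
        try:
            el = parse_element(str(row["element"]))
        except ValueError as exc:
            raise ValueError(
                f"{path}: row {i}: bad element {row['element']!r}: {exc}"
            ) from exc
        seeds.append(SeedSpec(
            (float(row["x_mm"]), float(row["y_mm"])), el,
            float(row.get("delay_h", 0.0)), float(row.get("speed", 1.0)),
        ))
    return seeds


def pattern_to_file(pattern: InterfacePattern, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pattern.to_geojson(), indent=1,
                                     sort_keys=True))


def pattern_from_file(path: str | Path) -> InterfacePattern:
    return InterfacePattern.from_geojson(json.loads(Path(path).read_text()))


def profile_to_csv(x: np.ndarray, intensities: dict[str, np.ndarray],
                   path: str | Path) -> None:
    df = pd.DataFrame({"x_mm": x, **intensities})
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def points_to_csv(points_a: np.ndarray, points_b: np.ndarray,
                  path: str | Path) -> None:
    df = pd.concat([
        pd.DataFrame({"x_um": points_a[:, 0], "y_um": points_a[:, 1],
                      "type": "a"}),
        pd.DataFrame({"x_um": points_b[:, 0], "y_um": points_b[:, 1],
                      "type": "b"}),
    ], ignore_index=True)
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def points_from_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    a = df[df["type"] == "a"][["x_um", "y_um"]].to_numpy(float)
    b = df[df["type"] == "b"][["x_um", "y_um"]].to_numpy(float)
    return a, b


def trajectory_to_tiff(traj: Sequence[FieldState], stem: str | Path) -> None:
    """Snapshots as multi-page TIFF (free then bound planes per strain)
    plus a CSV index (time, extent, dx)."""
    import tifffile

    stem = Path(stem)
    pages, rows = [], []
    for state in traj:
        for i in range(state.rho.shape[0]):
            pages.append(state.rho[i].astype(np.float32))
            pages.append(state.bound[i].astype(np.float32))
        rows.append({"t_h": state.t, "dx_mm": state.dx,
                     "n_strains": state.rho.shape[0],
                     "shape": "x".join(map(str, state.rho.shape[1:]))})
    tifffile.imwrite(stem.with_suffix(".tif"),
                     np.stack([np.atleast_2d(p) for p in pages]),
                     photometric="minisblack")
    pd.DataFrame(rows).to_csv(stem.with_suffix(".csv"), index=False,
                              float_format=_CSV_FLOAT)
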