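"""Inverse design: from a target interface pattern to seeds and elements.

Given a planar target pattern P of straight interface edges, each flagged
*visible* (an interface must form there) or *hidden* (tiles may meet there
without a visible boundary), find a seeding configuration S -- positions
plus adhesion elements, using at most the four doublet elements and the
null element -- whose first-arrival territories reproduce P.

The pipeline rests on four ideas:

1.  Equal-speed point seeds generate the Voronoi tessellation of the seed
    set, so any pattern that *is* a Voronoi tessellation needs one seed per
    tile plus a proper tile colouring.
2.  Adjacent tiles must receive elements with a visible interface between
    them; on the doublet palette "visible iff different", so a proper
    four-colouring -- guaranteed to exist for planar maps -- suffices.
    Tiles joined by hidden edges are contracted to a single colour first.
3.  A pattern that is not a Voronoi tessellation is realized through the
    generalized inverse Voronoi construction: mirrored seed pairs placed
    symmetrically about every target edge pin that edge as a union of
    Voronoi edges; all extra (subtile) edges fall inside original tiles
    and are hidden by giving every subtile seed its tile's element.
4.  Visible edges with *open* ends (not meeting another visible edge) are
    isolated with the null element, which forms no visible interface with
    anything: one flank of the open edge keeps the surrounding tile's
    element, the other flank gets a different doublet enclosed by a thin
    null-element wrap, so the visible boundary terminates where the null
    territory begins.

The module also contains the three regular tilings (seeds at tile
circumcentres), a solver for targets constrained to a regular triangular
lattice, and a 16-segment display pattern generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString, Point, Polygon, box
from shapely.ops import polygonize_full, unary_union

from .adhesion import DOUBLETS, NULL, Element, parse_element, visible_interface
from .fronts import GridSpec, SeedSpec, label_and_interfaces

__all__ = [
    "PatternError",
    "ColouringError",
    "InterfacePattern",
    "Tessellation",
    "DesignSolution",
    "GIVPResult",
    "regular_tiling",
    "colour_tiles",
    "inverse_voronoi",
    "solve_pattern",
    "triangular_lattice",
    "triangular_lattice_design",
    "segment_display_pattern",
    "verify_design",
]


class PatternError(ValueError):
    """The target pattern cannot be processed as posed."""


class ColouringError(RuntimeError):
    """No valid element assignment exists (or the search cap was hit)."""


# -- pattern and tessellation containers -------------------------------------

@dataclass(frozen=True)
class PatternEdge:
    p0: tuple[float, float]
    p1: tuple[float, float]
    desired: str = "visible"    # "visible" | "hidden"

    def __post_init__(self) -> None:
        if self.desired not in ("visible", "hidden"):
            raise PatternError(f"unknown desired flag {self.desired!r}")
        if self.p0 == self.p1:
            raise PatternError("zero-length pattern edge")

    @property
    def line(self) -> LineString:
        return LineString([self.p0, self.p1])


@dataclass
class InterfacePattern:
    """Planar straight-line target pattern with per-edge visible/hidden flags.

    ``domain`` is the (xmin, ymin, xmax, ymax) plate rectangle in mm.
    Edges must intersect only at shared endpoints.
    """

    edges: list[PatternEdge]
    domain: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        dom = box(*self.domain)
        for e in self.edges:
            if not dom.buffer(1e-9).contains(e.line):
                raise PatternError("pattern edge outside the domain")

    @property
    def visible_union(self) -> MultiLineString:
        lines = [e.line for e in self.edges if e.desired == "visible"]
        return MultiLineString(lines) if lines else MultiLineString([])

    @property
    def hidden_union(self) -> MultiLineString:
        lines = [e.line for e in self.edges if e.desired == "hidden"]
        return MultiLineString(lines) if lines else MultiLineString([])

    def open_endpoints(self) -> list[tuple[float, float]]:
        """Endpoints of visible edges not incident to another visible edge."""
        deg: dict[tuple[float, float], int] = {}
        for e in self.edges:
            if e.desired != "visible":
                continue
            for p in (_key(e.p0), _key(e.p1)):
                deg[p] = deg.get(p, 0) + 1
        return [p for p, d in deg.items() if d == 1]

    def to_geojson(self) -> dict:
        feats = [{
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [list(e.p0), list(e.p1)]},
            "properties": {"desired": e.desired},
        } for e in self.edges]
        return {"type": "FeatureCollection", "units": "mm",
                "domain": list(self.domain), "features": feats}

    @classmethod
    def from_geojson(cls, gj: Mapping) -> "InterfacePattern":
        edges = []
        for feat in gj["features"]:
            geom = feat["geometry"]
            if geom["type"] != "LineString":
                raise PatternError("pattern features must be LineStrings")
            desired = feat.get("properties", {}).get("desired", "visible")
            coords = geom["coordinates"]
            for p0, p1 in zip(coords[:-1], coords[1:]):
                edges.append(PatternEdge(tuple(p0), tuple(p1), desired))
        return cls(edges, tuple(gj["domain"]))


def _key(p, nd: int = 9) -> tuple[float, float]:
    return (round(float(p[0]), nd), round(float(p[1]), nd))


@dataclass
class Tessellation:
    """Faces tiling a rectangle, with the face-adjacency graph.

    ``adjacency`` is a networkx graph on face indices whose edges carry
    ``shared`` (the common boundary geometry) and ``desired``
    ("visible" | "hidden") attributes.
    """

    faces: list[Polygon]
    adjacency: nx.Graph
    domain: tuple[float, float, float, float]

    @classmethod
    def from_faces(
        cls,
        faces: Sequence[Polygon],
        domain: tuple[float, float, float, float],
        desired_of=None,
        min_shared: float = 1e-9,
    ) -> "Tessellation":
        """Build the adjacency graph from face geometry.

        ``desired_of(shared_geometry) -> str`` classifies each shared
        boundary; the default marks everything visible.
        """
        g = nx.Graph()
        g.add_nodes_from(range(len(faces)))
        tree = shapely.STRtree(list(faces))
        for i, f in enumerate(faces):
            for j in tree.query(f):
                j = int(j)
                if j <= i:
                    continue
                shared = f.boundary.intersection(faces[j].boundary)
                if shared.length > min_shared:
                    desired = (desired_of(shared) if desired_of is not None
                               else "visible")
                    g.add_edge(i, j, shared=shared, desired=desired)
        return cls(list(faces), g, domain)


@dataclass
class DesignSolution:
    """Seeds plus the face->element provenance and solver diagnostics."""

    seeds: list[SeedSpec]
    provenance: dict[int, Element]
    diagnostics: dict = field(default_factory=dict)

    @property
    def elements_used(self) -> set[Element]:
        return {s.element for s in self.seeds}

    def seed_table(self):
        """(x_mm, y_mm, element, delay_h, speed) records."""
        return [
            {"x_mm": float(np.asarray(s.position, float).ravel()[0]),
             "y_mm": float(np.asarray(s.position, float).ravel()[1]),
             "element": str(s.element),
             "delay_h": s.delay,
             "speed": s.speed}
            for s in self.seeds
        ]


# -- exact four-colouring (DSATUR ordering + backtracking) -------------------

def four_colour(graph: nx.Graph, n_colours: int = 4,
                max_steps: int = 2_000_000) -> dict:
    """Proper colouring with at most ``n_colours`` colours, or raise.

    Exact backtracking search expanding the most saturated vertex first
    (DSATUR).  Planar graphs always admit 4 colours; the step cap guards
    against pathological non-planar inputs.
    """
    if any(u == v for u, v in graph.edges()):
        raise ColouringError(
            "self-loop: a hidden group is adjacent to itself across a "
            "desired-visible edge; the pattern needs null isolation "
            "(handled by solve_pattern)"
        )
    colours: dict = {}
    nodes = list(graph.nodes())
    if not nodes:
        return colours
    steps = 0

    def pick():
        best, key = None, None
        for v in nodes:
            if v in colours:
                continue
            sat = len({colours[u] for u in graph[v] if u in colours})
            k = (sat, graph.degree(v))
            if best is None or k > key:
                best, key = v, k
        return best

    def backtrack() -> bool:
        nonlocal steps
        v = pick()
        if v is None:
            return True
        steps += 1
        if steps > max_steps:
            raise ColouringError("colouring search cap exceeded")
        used = {colours[u] for u in graph[v] if u in colours}
        for c in range(n_colours):
            if c in used:
                continue
            colours[v] = c
            if backtrack():
                return True
            del colours[v]
        return False

    if not backtrack():
        raise ColouringError(
            f"graph is not {n_colours}-colourable (needs more adhesins)"
        )
    return colours


def colour_tiles(
    tess: Tessellation,
    hidden_groups: Sequence[Sequence[int]] | None = None,
) -> dict[int, Element]:
    """Assign one of the four doublet elements to every face.

    Faces joined by hidden edges (either given explicitly as
    ``hidden_groups`` -- a partition of face indices -- or read from the
    adjacency ``desired`` flags) are contracted to a single node; the
    quotient map is then properly coloured with at most four colours and
    colours are mapped to the four doublets in fixed lexicographic order,
    so every desired-visible edge separates different doublets and every
    hidden edge joins identical ones.

    Raises
    ------
    ColouringError
        If some hidden group is adjacent to itself across a visible edge
        (needs null isolation, see :func:`solve_pattern`), or no
        4-colouring exists.
    """
    if hidden_groups is None:
        hidden = nx.Graph()
        hidden.add_nodes_from(tess.adjacency.nodes())
        hidden.add_edges_from(
            (u, v) for u, v, d in tess.adjacency.edges(data=True)
            if d.get("desired") == "hidden"
        )
        hidden_groups = [sorted(c) for c in nx.connected_components(hidden)]
    group_of: dict[int, int] = {}
    for gi, grp in enumerate(hidden_groups):
        for f in grp:
            group_of[f] = gi
    missing = set(tess.adjacency.nodes()) - set(group_of)
    if missing:
        raise PatternError(f"hidden_groups do not cover faces {sorted(missing)}")

    quotient = nx.Graph()
    quotient.add_nodes_from(range(len(hidden_groups)))
    for u, v, d in tess.adjacency.edges(data=True):
        if d.get("desired", "visible") != "visible":
            continue
        gu, gv = group_of[u], group_of[v]
        if gu == gv:
            raise ColouringError(
                "hidden group adjacent to itself across a desired-visible "
                "edge: unsatisfiable without null isolation (solve_pattern)"
            )
        quotient.add_edge(gu, gv)
    gcol = four_colour(quotient)
    return {f: DOUBLETS[gcol[group_of[f]]] for f in tess.adjacency.nodes()}


# -- regular tilings ----------------------------------------------------------

def regular_tiling(kind: str, extent: tuple[float, float],
                   pitch: float) -> DesignSolution:
    """Seeds for a regular triangular, square or hexagonal tiling.

    Seeds sit at the tile circumcentres.  Triangular and square tilings
    have bipartite face-adjacency graphs and alternate one complementary
    singlet pair (Nb2 / Ag2); the hexagonal face graph contains odd cycles
    and is 3-chromatic, so it cycles through three of the four doublets.
    ``pitch`` is the tile edge length in mm.

    Raises
    ------
    PatternError
        For an invalid pitch or an extent below one full period.
    """
    if pitch <= 0:
        raise PatternError("pitch must be strictly positive")
    W, H = extent
    singlet = {0: parse_element("Nb2"), 1: parse_element("Ag2")}
    faces: list[Polygon] = []
    seeds: list[SeedSpec] = []
    prov: dict[int, Element] = {}

    if kind == "square":
        nx_, ny_ = int(W // pitch), int(H // pitch)
        if nx_ < 2 or ny_ < 2:
            raise PatternError("extent below one full period")
        for j in range(ny_):
            for i in range(nx_):
                x0, y0 = i * pitch, j * pitch
                faces.append(box(x0, y0, x0 + pitch, y0 + pitch))
                el = singlet[(i + j) % 2]
                c = (x0 + pitch / 2, y0 + pitch / 2)
                prov[len(faces) - 1] = el
                seeds.append(SeedSpec(c, el))
    elif kind == "triangular":
        ht = pitch * np.sqrt(3) / 2.0
        ncols, nrows = int(2 * W // pitch) - 1, int(H // ht)
        if ncols < 2 or nrows < 1:
            raise PatternError("extent below one full period")
        for r in range(nrows):
            for c in range(ncols):
                x0, y0 = c * pitch / 2.0, r * ht
                up = (r + c) % 2 == 0
                if up:
                    poly = Polygon([(x0, y0), (x0 + pitch, y0),
                                    (x0 + pitch / 2, y0 + ht)])
                    centre = (x0 + pitch / 2, y0 + ht / 3)
                else:
                    poly = Polygon([(x0, y0 + ht), (x0 + pitch, y0 + ht),
                                    (x0 + pitch / 2, y0)])
                    centre = (x0 + pitch / 2, y0 + 2 * ht / 3)
                faces.append(poly)
                el = singlet[0 if up else 1]
                prov[len(faces) - 1] = el
                seeds.append(SeedSpec(centre, el))
    elif kind == "hexagonal":
        # pointy-top hexagons, side length = pitch, axial coordinates (q, r)
        side = pitch
        whex = np.sqrt(3) * side
        palette = [DOUBLETS[0], DOUBLETS[1], DOUBLETS[2]]
        nq = int(W // whex) + 2
        nr = int(H // (1.5 * side)) + 2
        if W < 2 * whex or H < 3 * side:
            raise PatternError("extent below one full period")
        idx = 0
        for r in range(nr):
            for q in range(-(r // 2), nq):
                cx = whex * (q + r / 2.0)
                cy = 1.5 * side * r
                if not (-whex <= cx <= W + whex and -side <= cy <= H + side):
                    continue
                ang = np.pi / 180.0 * (60.0 * np.arange(6) + 30.0)
                poly = Polygon(np.column_stack([cx + side * np.cos(ang),
                                                cy + side * np.sin(ang)]))
                el = palette[(q - r) % 3]
                faces.append(poly)
                prov[idx] = el
                seeds.append(SeedSpec((cx, cy), el))
                idx += 1
    else:
        raise PatternError(f"unknown tiling kind {kind!r}")

    n_elements = len({str(s.element) for s in seeds})
    adhesins = set().union(*[set(s.element.adhesins) for s in seeds])
    return DesignSolution(
        seeds, prov,
        diagnostics={"kind": kind, "faces": len(faces),
                     "elements": n_elements, "adhesins": len(adhesins),
                     "face_polygons": faces},
    )


# -- generalized inverse Voronoi ---------------------------------------------

@dataclass
class GIVPResult:
    """Output of the generalized inverse Voronoi construction."""

    tessellation: Tessellation
    positions: np.ndarray            # (n, 2) seed positions, mm
    face_index: np.ndarray           # (n,) original-face provenance
    h_per_edge: list[float]
    diagnostics: dict = field(default_factory=dict)


def _edge_clearance(e: PatternEdge, others: Iterable[PatternEdge],
                    domain) -> float:
    """Distance from e to the nearest non-incident edge or domain wall."""
    ln = e.line
    ends = {_key(e.p0), _key(e.p1)}
    d = box(*domain).exterior.distance(ln)
    clear = d if d > 0 else np.inf
    for o in others:
        if o is e:
            continue
        if {_key(o.p0), _key(o.p1)} & ends:
            continue
        clear = min(clear, ln.distance(o.line))
    return float(clear)


def _mirrored_pairs(e: PatternEdge, h: float,
                    skip_near: Sequence[tuple[tuple[float, float], float]] = (),
                    margin_start: float | None = None,
                    margin_end: float | None = None):
    """Sample mirrored seed-pair positions about an edge.

    Yields (p_plus, p_minus, n) with the pair offset h/2 either side of
    the edge at spacing h along it, clipped ``margin`` short of each
    vertex and skipping stations within the given exclusion discs.
    """
    p0 = np.asarray(e.p0, float)
    p1 = np.asarray(e.p1, float)
    L = float(np.hypot(*(p1 - p0)))
    u = (p1 - p0) / L
    n = np.array([-u[1], u[0]])
    m0 = h / 2.0 if margin_start is None else margin_start
    m1 = h / 2.0 if margin_end is None else margin_end
    ts = np.arange(m0, L - m1 + 1e-9, h)
    if len(ts) == 0 and L > m0 + m1:
        ts = np.array([L / 2.0])
    for t in ts:
        p = p0 + t * u
        if any(np.hypot(*(p - np.asarray(c))) < rad for c, rad in skip_near):
            continue
        yield p + (h / 2.0) * n, p - (h / 2.0) * n, n


def inverse_voronoi(
    pattern: InterfacePattern,
    *,
    h_min: float = 0.2,
    h_max: float = 1.0,
) -> GIVPResult:
    """Seeds whose Voronoi diagram contains every (closed) target edge.

    For each target edge, mirrored seed pairs symmetric about the edge
    line are placed at spacing h and offset h/2, with
    ``h = clamp(min(edge length, clearance to non-incident edges) / 2,
    h_min, h_max)``; the pair bisectors tile the edge as Voronoi edges.
    Every face of the target subdivision additionally receives an interior
    representative seed if no pair seed landed in it.  Seeds carry the
    index of the face containing them, so a subsequent colouring can make
    all added (subtile) edges hidden by giving same-face seeds one
    element.

    Open (dangling) edges are not handled here -- use
    :func:`solve_pattern`.

    Raises
    ------
    PatternError
        If a feature is closer than the resolvable spacing (h < h_min
        would be required).
    """
    dom = box(*pattern.domain)
    lines = [e.line for e in pattern.edges] + [dom.exterior]
    merged = unary_union(lines)
    polys, cuts, dangles, invalid = polygonize_full(merged)
    faces = [p for p in polys.geoms if p.area > 1e-12]
    if any(True for _ in cuts.geoms) or any(True for _ in dangles.geoms):
        raise PatternError(
            "pattern has open (dangling or slit) edges; use solve_pattern"
        )
    tess = Tessellation.from_faces(
        faces, pattern.domain,
        desired_of=lambda shared: _classify_shared(shared, pattern),
    )
    prepared = [shapely.prepared.prep(f) for f in faces]

    positions: list[np.ndarray] = []
    face_idx: list[int] = []
    hs: list[float] = []
    for e in pattern.edges:
        clear = _edge_clearance(e, pattern.edges, pattern.domain)
        h = min(e.line.length, clear) / 2.0
        h = min(h, h_max)
        if h < h_min:
            raise PatternError(
                f"edge {e.p0}-{e.p1} needs pair spacing {h:.3g} mm below the "
                f"resolvable minimum {h_min} mm; refine h_min or simplify"
            )
        hs.append(h)
        for pp, pm, _ in _mirrored_pairs(e, h):
            for p in (pp, pm):
                fi = _containing_face(p, prepared)
                if fi is not None:
                    positions.append(p)
                    face_idx.append(fi)
    # interior representative for faces without a seed
    have = set(face_idx)
    for i, f in enumerate(faces):
        if i not in have:
            rp = f.representative_point()
            positions.append(np.array([rp.x, rp.y]))
            face_idx.append(i)
    return GIVPResult(
        tess, np.array(positions), np.array(face_idx, dtype=int), hs,
        diagnostics={"n_faces": len(faces), "n_seeds": len(positions)},
    )


def _containing_face(p: np.ndarray, prepared) -> int | None:
    pt = Point(p)
    for i, prep in enumerate(prepared):
        if prep.contains(pt):
            return i
    return None


def _classify_shared(shared, pattern: InterfacePattern) -> str:
    """Label a face-to-face shared boundary visible or hidden."""
    vis = pattern.visible_union
    hid = pattern.hidden_union
    geoms = getattr(shared, "geoms", [shared])
    votes = set()
    for g in geoms:
        if g.length == 0:
            continue
        mid = g.interpolate(0.5, normalized=True)
        dv = mid.distance(vis) if not vis.is_empty else np.inf
        dh = mid.distance(hid) if not hid.is_empty else np.inf
        if min(dv, dh) > 1e-6:
            votes.add("hidden")       # domain wall or added edge
        else:
            votes.add("visible" if dv <= dh else "hidden")
    if votes == {"visible"}:
        return "visible"
    if "visible" in votes:
        raise PatternError(
            "two faces share both visible and hidden boundary: "
            "unsatisfiable without refinement"
        )
    return "hidden"


# -- full pipeline with open-interface isolation ------------------------------

def solve_pattern(
    pattern: InterfacePattern,
    *,
    h_min: float = 0.2,
    h_max: float = 0.4,
) -> DesignSolution:
    """Solve the general inverse problem, open ends and hidden edges included.

    Closed edges go through the generalized inverse Voronoi construction
    and hidden-group four-colouring.  Visible edges that dangle (open
    ends, or slits entirely interior to a face) are realized locally: the
    flank on one side keeps the containing face's doublet, the other
    flank receives a different doublet laid as a thin strip of seeds, and
    a wrap of null-element seeds encloses that strip's far side and its
    open ends, so no visible boundary extends beyond the target edge.
    At most the four doublets plus the null element are used.

    Raises
    ------
    PatternError, ColouringError
        Propagated from the pipeline stages.
    """
    dom = box(*pattern.domain)
    lines = [e.line for e in pattern.edges] + [dom.exterior]
    merged = unary_union(lines)
    polys, cuts, dangles, invalid = polygonize_full(merged)
    faces = [p for p in polys.geoms if p.area > 1e-12]
    slit_lines = unary_union([g for g in list(cuts.geoms) + list(dangles.geoms)])

    tess = Tessellation.from_faces(
        faces, pattern.domain,
        desired_of=lambda shared: _classify_shared(shared, pattern),
    )
    face_elem = colour_tiles(tess)
    prepared = [shapely.prepared.prep(f) for f in faces]

    seeds: list[SeedSpec] = []
    # (a) mirrored pairs along closed *visible* shared boundaries
    vis = pattern.visible_union
    open_pts = pattern.open_endpoints()
    n_pairs = 0
    for i, j, d in tess.adjacency.edges(data=True):
        if d["desired"] != "visible":
            continue
        for seg in _as_segments(d["shared"]):
            pe = PatternEdge(tuple(seg.coords[0]), tuple(seg.coords[-1]))
            clear = _edge_clearance(pe, pattern.edges, pattern.domain)
            h = float(np.clip(min(pe.line.length, clear) / 2.0, h_min, h_max))
            for pp, pm, n in _mirrored_pairs(pe, h):
                fi_p = _containing_face(pp, prepared)
                fi_m = _containing_face(pm, prepared)
                if fi_p is None or fi_m is None:
                    continue
                seeds.append(SeedSpec(tuple(pp), face_elem[fi_p]))
                seeds.append(SeedSpec(tuple(pm), face_elem[fi_m]))
                n_pairs += 1

    # (b) open / slit visible edges: flank strip + null wrap
    null_used = False
    if not slit_lines.is_empty:
        vis_slits = [
            s for s in _as_segments(slit_lines)
            if not vis.is_empty and s.interpolate(0.5, normalized=True)
            .distance(vis) < 1e-6
        ]
        comps = _connected_components(vis_slits)
        for comp in comps:
            null_used |= _seed_open_component(
                comp, prepared, face_elem, open_pts, seeds,
                h_min=h_min, h_max=h_max, pattern=pattern,
            )

    # (c) every face gets at least one interior seed
    covered = set()
    for s in seeds:
        fi = _containing_face(np.asarray(s.position, float), prepared)
        if fi is not None and s.element == face_elem.get(fi):
            covered.add(fi)
    for i, f in enumerate(faces):
        if i not in covered:
            rp = f.representative_point()
            seeds.append(SeedSpec((rp.x, rp.y), face_elem[i]))

    # deduplicate coincident stations (strokes sharing vertices can emit
    # the same point twice); a null seed wins any element conflict since
    # it is inert
    by_pos: dict[tuple[float, float], SeedSpec] = {}
    for s in seeds:
        key = _key(np.asarray(s.position, float))
        prev = by_pos.get(key)
        if prev is None or (s.element == NULL and prev.element != NULL):
            by_pos[key] = s
    seeds = list(by_pos.values())

    colours_used = len({str(e) for e in face_elem.values()})
    return DesignSolution(
        seeds, dict(face_elem),
        diagnostics={
            "n_faces": len(faces),
            "colours_used": colours_used,
            "null_used": null_used,
            "n_pair_stations": n_pairs,
            "face_polygons": faces,
        },
    )


def _as_segments(geom) -> list[LineString]:
    """Decompose any linear geometry into 2-point segments."""
    out: list[LineString] = []
    geoms = getattr(geom, "geoms", [geom])
    for g in geoms:
        if g.is_empty or g.length == 0:
            continue
        coords = list(g.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            if a != b:
                out.append(LineString([a, b]))
    return out


def _connected_components(segments: list[LineString]) -> list[list[LineString]]:
    g = nx.Graph()
    for k, s in enumerate(segments):
        g.add_node(k)
    for a, b in itertools.combinations(range(len(segments)), 2):
        if segments[a].distance(segments[b]) < 1e-9:
            g.add_edge(a, b)
    return [[segments[k] for k in sorted(c)] for c in nx.connected_components(g)]


def _seed_open_component(
    comp: list[LineString],
    prepared,
    face_elem: dict[int, Element],
    open_pts: list[tuple[float, float]],
    seeds: list[SeedSpec],
    *,
    h_min: float,
    h_max: float,
    pattern: InterfacePattern,
) -> bool:
    """Place flank, strip and null-wrap seeds for one open component."""
    # containing face and its element
    mid = comp[0].interpolate(0.5, normalized=True)
    fi = _containing_face(np.array([mid.x, mid.y]), prepared)
    e_face = face_elem.get(fi, DOUBLETS[0]) if fi is not None else DOUBLETS[0]
    e_strip = next(d for d in DOUBLETS if d != e_face)
    open_set = {_key(p) for p in open_pts}

    # vertex degrees within the component, for cap decisions
    deg: dict[tuple[float, float], int] = {}
    for s in comp:
        for p in (_key(s.coords[0]), _key(s.coords[-1])):
            deg[p] = deg.get(p, 0) + 1

    # orient segments into consistent chains so flank sides agree at corners
    directed = _orient_component(comp)

    comp_union = unary_union(comp)
    for p0, p1 in directed:
        p0a, p1a = np.asarray(p0, float), np.asarray(p1, float)
        L = float(np.hypot(*(p1a - p0a)))
        u = (p1a - p0a) / L
        n = np.array([-u[1], u[0]])     # left of travel = strip side
        others = [e for e in pattern.edges
                  if _key(e.p0) != _key(p0) or _key(e.p1) != _key(p1)]
        pe = PatternEdge(tuple(p0), tuple(p1))
        clear = _edge_clearance(pe, pattern.edges, pattern.domain)
        h = float(np.clip(min(L, clear) / 2.0, h_min, h_max))

        open0 = _key(p0) in open_set
        open1 = _key(p1) in open_set
        m0 = h if open0 else h / 2.0
        m1 = h if open1 else h / 2.0
        ts = np.arange(m0, L - m1 + 1e-9, h)
        if len(ts) == 0:
            ts = np.array([L / 2.0])
        for t in ts:
            p = p0a + t * u
            seeds.append(SeedSpec(tuple(p + (h / 2.0) * n), e_strip))
            seeds.append(SeedSpec(tuple(p - (h / 2.0) * n), e_face))
            seeds.append(SeedSpec(tuple(p + (3.0 * h / 2.0) * n), NULL))
        # caps: null seeds beyond open ends and at high-degree vertices
        for p_end, outward, is_open in ((p0a, -u, open0), (p1a, u, open1)):
            if is_open:
                for q in (p_end + h * outward,
                          p_end + h * 0.7071 * (outward + n),
                          p_end + h * n):
                    seeds.append(SeedSpec(tuple(q), NULL))
            elif deg.get(_key(p_end), 0) >= 3:
                seeds.append(SeedSpec(tuple(p_end + h * n), NULL))
    return True


def _orient_component(comp: list[LineString]) -> list[tuple[tuple, tuple]]:
    """Direct segments so consecutive chain segments share travel direction."""
    g = nx.Graph()
    segs = {}
    for k, s in enumerate(comp):
        a, b = _key(s.coords[0]), _key(s.coords[-1])
        g.add_edge(a, b, idx=k)
        segs[k] = (a, b)
    directed: dict[int, tuple[tuple, tuple]] = {}
    for sub in nx.connected_components(g):
        sg = g.subgraph(sub)
        # start from a leaf if one exists
        start = next((v for v in sg if sg.degree(v) == 1), next(iter(sub)))
        visited_edges = set()
        stack = [start]
        order: dict[tuple, tuple | None] = {start: None}
        while stack:
            v = stack.pop()
            for w in sg[v]:
                k = sg[v][w]["idx"]
                if k in visited_edges:
                    continue
                visited_edges.add(k)
                directed[k] = (v, w)
                if w not in order:
                    order[w] = v
                    stack.append(w)
    return [directed[k] for k in sorted(directed)]


# -- triangular-lattice constrained design ------------------------------------

def triangular_lattice(nrows: int, ncols: int, pitch: float = 3.0):
    """Geometry of a triangular lattice of up/down triangles.

    Triangle (r, c) for r in [0, nrows), c in [0, ncols) spans
    x in [c*pitch/2, c*pitch/2 + pitch]; it points up when (r + c) is
    even.  Returns (polygons, centres) keyed by (r, c).
    """
    ht = pitch * np.sqrt(3) / 2.0
    polys: dict[tuple[int, int], Polygon] = {}
    centres: dict[tuple[int, int], tuple[float, float]] = {}
    for r in range(nrows):
        for c in range(ncols):
            x0, y0 = c * pitch / 2.0, r * ht
            if (r + c) % 2 == 0:     # up-pointing: base at the row bottom
                polys[(r, c)] = Polygon(
                    [(x0, y0), (x0 + pitch, y0), (x0 + pitch / 2, y0 + ht)])
                centres[(r, c)] = (x0 + pitch / 2, y0 + ht / 3)
            else:                    # down-pointing: base at the row top
                polys[(r, c)] = Polygon(
                    [(x0, y0 + ht), (x0 + pitch, y0 + ht),
                     (x0 + pitch / 2, y0)])
                centres[(r, c)] = (x0 + pitch / 2, y0 + 2 * ht / 3)
    return polys, centres


def lattice_adjacency(nrows: int, ncols: int) -> nx.Graph:
    """Dual adjacency of the triangular lattice (shared-edge neighbours)."""
    g = nx.Graph()
    for r in range(nrows):
        for c in range(ncols):
            g.add_node((r, c))
            if c + 1 < ncols:
                g.add_edge((r, c), (r, c + 1), horizontal=False)
            # up triangle (r, c) shares its base with down triangle (r-1, c)
            if (r + c) % 2 == 0 and r - 1 >= 0:
                g.add_edge((r, c), (r - 1, c), horizontal=True)
    return g


def triangular_lattice_design(
    targets: Iterable[tuple[tuple[int, int], tuple[int, int]]],
    nrows: int,
    ncols: int,
    *,
    strategy: str = "contraction",
) -> dict[tuple[int, int], Element]:
    """Doublet assignment on a triangular lattice realizing target edges.

    Seeding is restricted to triangle centres; ``targets`` lists adjacent
    triangle pairs whose shared lattice edge must be visible; all other
    lattice edges must stay hidden.  ``strategy="contraction"`` (default)
    contracts hidden-connected groups and four-colours the quotient --
    provably sufficient whenever the instance is satisfiable with
    doublets.  ``strategy="sequential"`` is a row-sequential greedy
    alternative (non-horizontal interfaces row by row, then horizontal
    constraints), which can fail on satisfiable instances.

    Raises
    ------
    ColouringError
        Explicit failure report when the target set is unsatisfiable
        (a hidden group adjacent to itself across a target edge) or the
        greedy strategy gets stuck.
    """
    adj = lattice_adjacency(nrows, ncols)
    tset = {frozenset(t) for t in targets}
    for t in tset:
        a, b = sorted(t)
        if not adj.has_edge(a, b):
            raise PatternError(f"target {a}-{b} is not a lattice edge")

    if strategy == "contraction":
        hidden = nx.Graph()
        hidden.add_nodes_from(adj.nodes())
        hidden.add_edges_from(
            (u, v) for u, v in adj.edges() if frozenset((u, v)) not in tset)
        groups = [sorted(c) for c in nx.connected_components(hidden)]
        gid = {f: i for i, grp in enumerate(groups) for f in grp}
        quotient = nx.Graph()
        quotient.add_nodes_from(range(len(groups)))
        for u, v in adj.edges():
            if frozenset((u, v)) in tset:
                if gid[u] == gid[v]:
                    raise ColouringError(
                        f"unsatisfiable target set: triangles {u} and {v} are "
                        "joined by hidden edges but must form a visible "
                        "interface"
                    )
                quotient.add_edge(gid[u], gid[v])
        col = four_colour(quotient)
        return {f: DOUBLETS[col[gid[f]]] for f in adj.nodes()}

    if strategy == "sequential":
        assign: dict[tuple[int, int], Element] = {}
        for r in range(nrows):
            for c in range(ncols):
                node = (r, c)
                choices = list(DOUBLETS)
                ok_choices = []
                for cand in choices:
                    good = True
                    for nb in adj[node]:
                        if nb not in assign:
                            continue
                        want_visible = frozenset((node, nb)) in tset
                        is_visible = cand != assign[nb]
                        if want_visible != is_visible:
                            good = False
                            break
                    if good:
                        ok_choices.append(cand)
                if not ok_choices:
                    raise ColouringError(
                        f"sequential strategy stuck at triangle {node}; "
                        "try strategy='contraction'"
                    )
                assign[node] = ok_choices[0]
        return assign

    raise ValueError(f"unknown strategy {strategy!r}")


def verify_lattice_design(
    assignment: Mapping[tuple[int, int], Element],
    targets: Iterable[tuple[tuple[int, int], tuple[int, int]]],
    nrows: int,
    ncols: int,
) -> bool:
    """Edge-by-edge check of a lattice assignment via visible_interface."""
    adj = lattice_adjacency(nrows, ncols)
    tset = {frozenset(t) for t in targets}
    for u, v in adj.edges():
        want = frozenset((u, v)) in tset
        got = visible_interface(assignment[u], assignment[v])
        if want != got:
            return False
    return True


# -- 16-segment display -------------------------------------------------------

# segment endpoints on a unit glyph box (x in [0, 1], y in [0, 1])
_SEG_GEOM: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "a1": ((0.0, 1.0), (0.5, 1.0)), "a2": ((0.5, 1.0), (1.0, 1.0)),
    "b": ((1.0, 1.0), (1.0, 0.5)), "c": ((1.0, 0.5), (1.0, 0.0)),
    "d1": ((0.0, 0.0), (0.5, 0.0)), "d2": ((0.5, 0.0), (1.0, 0.0)),
    "e": ((0.0, 0.5), (0.0, 0.0)), "f": ((0.0, 1.0), (0.0, 0.5)),
    "g1": ((0.0, 0.5), (0.5, 0.5)), "g2": ((0.5, 0.5), (1.0, 0.5)),
    "h": ((0.0, 1.0), (0.5, 0.5)), "i": ((0.5, 1.0), (0.5, 0.5)),
    "j": ((1.0, 1.0), (0.5, 0.5)), "k": ((0.0, 0.0), (0.5, 0.5)),
    "l": ((0.5, 0.5), (0.5, 0.0)), "m": ((0.5, 0.5), (1.0, 0.0)),
}

_SEG_FONT: dict[str, frozenset[str]] = {
    " ": frozenset(),
    "A": frozenset({"a1", "a2", "b", "c", "e", "f", "g1", "g2"}),
    "F": frozenset({"a1", "a2", "e", "f", "g1"}),
    "O": frozenset({"a1", "a2", "b", "c", "d1", "d2", "e", "f"}),
    "U": frozenset({"b", "c", "d1", "d2", "e", "f"}),
    "X": frozenset({"h", "j", "k", "m"}),
    "\\": frozenset({"h", "m"}),
    "/": frozenset({"j", "k"}),
    "o": frozenset({"c", "d1", "d2", "e", "g1", "g2"}),
    "f": frozenset({"a1", "e", "f", "g1"}),
    "u": frozenset({"c", "d1", "d2", "e"}),
    "0": frozenset({"a1", "a2", "b", "c", "d1", "d2", "e", "f", "j", "k"}),
    "1": frozenset({"b", "c"}),
    "H": frozenset({"b", "c", "e", "f", "g1", "g2"}),
    "L": frozenset({"d1", "d2", "e", "f"}),
    "T": frozenset({"a1", "a2", "i", "l"}),
}


def segment_display_pattern(
    text: str,
    *,
    glyph_size: tuple[float, float] = (6.0, 10.0),
    spacing: float = 3.0,
    origin: tuple[float, float] = (5.0, 5.0),
    margin: float = 5.0,
) -> InterfacePattern:
    """Open-interface pattern spelling ``text`` on a 16-segment display.

    Each character's active segments (from a fixed 16-segment font table)
    become desired-visible edges; glyphs advance left to right.  All
    dimensions in mm.

    Raises
    ------
    PatternError
        For a character missing from the font table.
    """
    w, hgt = glyph_size
    edges: list[PatternEdge] = []
    x = origin[0]
    for ch in text:
        if ch not in _SEG_FONT:
            raise PatternError(f"character {ch!r} not in the 16-segment font")
        for seg in sorted(_SEG_FONT[ch]):
            (u0, v0), (u1, v1) = _SEG_GEOM[seg]
            edges.append(PatternEdge(
                (x + u0 * w, origin[1] + v0 * hgt),
                (x + u1 * w, origin[1] + v1 * hgt),
            ))
        x += w + spacing
    x_end = x - spacing if text else origin[0]
    domain = (0.0, 0.0, x_end + margin, origin[1] + hgt + margin)
    return InterfacePattern(edges, domain)


# -- end-to-end verification ---------------------------------------------------

def verify_design(
    solution: DesignSolution,
    pattern: InterfacePattern,
    *,
    grid_dx: float = 0.1,
    sample_step: float = 0.1,
) -> dict:
    """Predict the solution's interfaces and compare them with the target.

    Runs the front-arrival predictor on the solution seeds (equal speeds
    and delays) and reports:

    - ``coverage``: fraction of points sampled along desired-visible
      edges lying within ``tol = 2 * grid_dx`` of a predicted visible
      interface;
    - ``spurious``: fraction of predicted visible interface points
      farther than ``tol`` from any desired-visible edge;
    - the corresponding maximum distances.
    """
    x0, y0, x1, y1 = pattern.domain
    grid = GridSpec(extent=(x1 - x0, y1 - y0), dx=grid_dx, origin=(x0, y0))
    _, curves = label_and_interfaces(solution.seeds, grid)
    vis_pred = [c for c in curves if c.visible]
    tol = 2.0 * grid_dx
    target = pattern.visible_union

    pred_pts = (np.vstack([c.points for c in vis_pred])
                if vis_pred else np.empty((0, 2)))
    if target.is_empty:
        cov, d_cov = 1.0, 0.0
    else:
        samples = []
        for line in getattr(target, "geoms", [target]):
            nseg = max(2, int(np.ceil(line.length / sample_step)) + 1)
            for t in np.linspace(0, 1, nseg):
                p = line.interpolate(t, normalized=True)
                samples.append((p.x, p.y))
        samples = np.asarray(samples)
        if len(pred_pts) == 0:
            cov, d_cov = 0.0, np.inf
        else:
            from scipy.spatial import cKDTree
            d, _ = cKDTree(pred_pts).query(samples)
            cov = float(np.mean(d <= tol))
            d_cov = float(d.max())
    if len(pred_pts) == 0:
        spur, d_spur = 0.0, 0.0
    elif target.is_empty:
        spur, d_spur = 1.0, np.inf
    else:
        dists = shapely.distance(
            shapely.points(pred_pts[:, 0], pred_pts[:, 1]), target)
        spur = float(np.mean(dists > tol))
        d_spur = float(dists.max())
    return {
        "coverage": cov,
        "coverage_max_dist": d_cov,
        "spurious": spur,
        "spurious_max_dist": d_spur,
        "tol": tol,
        "n_predicted_visible_curves": len(vis_pred),
    }
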