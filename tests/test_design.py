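"""Inverse design: tilings, four-colouring, generalized inverse Voronoi,
open-interface isolation, lattice-constrained solving, display glyphs."""

import networkx as nx
import numpy as np
import pytest
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import LineString, MultiLineString

from swarmpat import adhesion as ad
from swarmpat import design as dz
from swarmpat import fixtures as fx
from swarmpat import fronts


# -- exact four-colouring -----------------------------------------------------

def test_four_colour_basics():
    assert len(set(dz.four_colour(nx.path_graph(6)).values())) == 2
    assert len(set(dz.four_colour(nx.cycle_graph(5)).values())) == 3
    assert len(set(dz.four_colour(nx.complete_graph(4)).values())) == 4


def test_four_colour_rejects_k5():
    with pytest.raises(dz.ColouringError):
        dz.four_colour(nx.complete_graph(5))


def test_four_colour_rejects_self_loop():
    g = nx.Graph()
    g.add_edge(0, 0)
    with pytest.raises(dz.ColouringError, match="null isolation"):
        dz.four_colour(g)


# -- colour_tiles -------------------------------------------------------------

def proper(tess, cmap):
    return all(
        ad.visible_interface(cmap[u], cmap[v])
        for u, v, d in tess.adjacency.edges(data=True)
        if d["desired"] == "visible"
    )


def test_colour_tiles_bipartite_grid():
    faces = [shapely.box(i * 10.0, j * 10.0, (i + 1) * 10.0, (j + 1) * 10.0)
             for i in range(2) for j in range(2)]
    tess = dz.Tessellation.from_faces(faces, (0, 0, 20, 20))
    cmap = dz.colour_tiles(tess)
    assert len({str(e) for e in cmap.values()}) == 2
    assert proper(tess, cmap)


def test_colour_tiles_random_voronoi_within_four_doublets():
    tess, _ = fx.random_voronoi_tessellation(50, (40, 40), seed=3)
    cmap = dz.colour_tiles(tess)
    used = {str(e) for e in cmap.values()}
    assert used <= {str(d) for d in ad.DOUBLETS}
    assert proper(tess, cmap)


def test_colour_tiles_hidden_groups_share_element():
    faces = [shapely.box(i * 10.0, 0.0, (i + 1) * 10.0, 10.0)
             for i in range(4)]
    tess = dz.Tessellation.from_faces(faces, (0, 0, 40, 10))
    tess.adjacency[1][2]["desired"] = "hidden"
    cmap = dz.colour_tiles(tess)
    assert cmap[1] == cmap[2]
    assert cmap[0] != cmap[1] and cmap[2] != cmap[3]


def test_colour_tiles_self_adjacent_group_unsatisfiable():
    faces = [shapely.box(i * 10.0, 0.0, (i + 1) * 10.0, 10.0)
             for i in range(2)]
    tess = dz.Tessellation.from_faces(faces, (0, 0, 20, 10))
    with pytest.raises(dz.ColouringError, match="null isolation"):
        dz.colour_tiles(tess, hidden_groups=[[0, 1]])


def test_four_clique_groups_need_exactly_four_colours():
    # four mutually adjacent regions: centre triangle-ish arrangement
    faces = [shapely.box(0, 0, 10, 10), shapely.box(10, 0, 20, 10),
             shapely.box(0, 10, 10, 20), shapely.box(10, 10, 20, 20)]
    tess = dz.Tessellation.from_faces(faces, (0, 0, 20, 20))
    # make the two diagonals adjacent too (K4 quotient via explicit graph)
    tess.adjacency.add_edge(0, 3, desired="visible", shared=None)
    tess.adjacency.add_edge(1, 2, desired="visible", shared=None)
    cmap = dz.colour_tiles(tess)
    assert len({str(e) for e in cmap.values()}) == 4


# -- regular tilings ----------------------------------------------------------

def adjacency_of_faces(faces, domain):
    return dz.Tessellation.from_faces(faces, domain)


def test_square_tiling_checkerboard_of_one_singlet_pair():
    sol = dz.regular_tiling("square", (30.0, 30.0), 5.0)
    used = {str(s.element) for s in sol.seeds}
    assert used == {"Nb2", "Ag2"}           # one adhesin pair
    tess = adjacency_of_faces(sol.diagnostics["face_polygons"],
                              (0, 0, 30, 30))
    assert proper(tess, sol.provenance)


def test_triangular_tiling_two_coloured():
    sol = dz.regular_tiling("triangular", (30.0, 30.0), 5.0)
    assert len({str(s.element) for s in sol.seeds}) == 2
    tess = adjacency_of_faces(sol.diagnostics["face_polygons"],
                              (0, 0, 30, 30))
    assert nx.is_bipartite(tess.adjacency)
    assert proper(tess, sol.provenance)


def test_hexagonal_tiling_needs_three_doublets():
    sol = dz.regular_tiling("hexagonal", (40.0, 40.0), 5.0)
    used = {str(s.element) for s in sol.seeds}
    assert len(used) == 3
    assert used <= {str(d) for d in ad.DOUBLETS}    # two adhesin pairs
    assert sol.diagnostics["adhesins"] == 4
    tess = adjacency_of_faces(sol.diagnostics["face_polygons"],
                              (0, 0, 40, 40))
    assert not nx.is_bipartite(tess.adjacency)      # odd cycles: needs > 2
    assert proper(tess, sol.provenance)


def test_regular_tiling_rejects_bad_input():
    with pytest.raises(dz.PatternError):
        dz.regular_tiling("square", (30.0, 30.0), -1.0)
    with pytest.raises(dz.PatternError):
        dz.regular_tiling("square", (4.0, 4.0), 5.0)
    with pytest.raises(dz.PatternError):
        dz.regular_tiling("penrose", (30.0, 30.0), 5.0)


# -- generalized inverse Voronoi ----------------------------------------------

def voronoi_edge_lines(points, domain):
    """Finite Voronoi edges; seeds are mirrored across the domain walls so
    every ridge inside the domain is finite (bounded-Voronoi trick)."""
    x0, y0, x1, y1 = domain
    pts = np.unique(np.round(points, 9), axis=0)
    mirrored = [pts]
    for refl in (
        lambda p: np.column_stack([2 * x0 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([2 * x1 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y0 - p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y1 - p[:, 1]]),
    ):
        mirrored.append(refl(pts))
    vor = Voronoi(np.vstack(mirrored))
    segs = []
    for (i, j) in vor.ridge_vertices:
        if i >= 0 and j >= 0:
            segs.append(LineString([vor.vertices[i], vor.vertices[j]]))
    return MultiLineString(segs)


def containment_distance(pattern, positions):
    """Largest distance from a target-edge sample to the seed Voronoi edges."""
    ridges = voronoi_edge_lines(positions, pattern.domain)
    worst = 0.0
    for e in pattern.edges:
        line = e.line
        for t in np.linspace(0.05, 0.95, 40):
            p = line.interpolate(t, normalized=True)
            worst = max(worst, p.distance(ridges))
    return worst


def test_givp_single_segment_mirror_pairs():
    pat = dz.InterfacePattern([dz.PatternEdge((0, 10), (30, 10))],
                              (0, 0, 30, 20))
    res = dz.inverse_voronoi(pat)
    assert containment_distance(pat, res.positions) < 0.05
    # mirrored about the segment: reflecting the seed set across y=10
    # reproduces it
    refl = res.positions * np.array([1.0, -1.0]) + np.array([0.0, 20.0])
    d = np.abs(res.positions[:, None, :] - refl[None, :, :]).sum(-1).min(1)
    assert d.max() < 1e-9


def test_givp_t_junction_contains_all_segments():
    pat = dz.InterfacePattern(
        [dz.PatternEdge((15, 0), (15, 10)), dz.PatternEdge((0, 10), (15, 10)),
         dz.PatternEdge((30, 10), (15, 10))], (0, 0, 30, 20))
    res = dz.inverse_voronoi(pat)
    assert containment_distance(pat, res.positions) < 0.15
    # subtile seeds inherit their face: every face index present
    assert set(res.face_index) == set(range(res.diagnostics["n_faces"]))


def test_givp_rejects_dangling_edges():
    pat = dz.InterfacePattern([dz.PatternEdge((10, 10), (20, 10))],
                              (0, 0, 30, 20))
    with pytest.raises(dz.PatternError, match="solve_pattern"):
        dz.inverse_voronoi(pat)


def test_givp_rejects_unresolvable_feature():
    pat = dz.InterfacePattern(
        [dz.PatternEdge((0, 10.0), (30, 10.0)),
         dz.PatternEdge((0, 10.05), (30, 10.05))], (0, 0, 30, 20))
    with pytest.raises(dz.PatternError, match="resolvable"):
        dz.inverse_voronoi(pat)


# -- solve_pattern ------------------------------------------------------------

def check(sol, pat, coverage=0.95, spurious=0.05, grid_dx=0.1):
    v = dz.verify_design(sol, pat, grid_dx=grid_dx)
    assert v["coverage"] >= coverage, v
    assert v["spurious"] <= spurious, v
    return v


def test_solve_closed_pattern_matches_colouring_path():
    pat = dz.InterfacePattern(
        [dz.PatternEdge((0, 10), (30, 10)), dz.PatternEdge((15, 0), (15, 10))],
        (0, 0, 30, 20))
    sol = dz.solve_pattern(pat)
    assert not sol.diagnostics["null_used"]
    assert {str(s.element) for s in sol.seeds} <= {str(d) for d in ad.DOUBLETS}
    check(sol, pat)


def test_solve_open_segment_uses_null_and_stays_local():
    pat = dz.InterfacePattern([dz.PatternEdge((10, 10), (20, 10))],
                              (0, 0, 30, 20))
    sol = dz.solve_pattern(pat)
    assert sol.diagnostics["null_used"]
    used = {str(s.element) for s in sol.seeds}
    assert "n" in used
    assert used - {"n"} <= {str(d) for d in ad.DOUBLETS}
    check(sol, pat, coverage=0.90, spurious=0.02)


def test_solve_t_junction_open_ends():
    pat = dz.InterfacePattern(
        [dz.PatternEdge((15, 5), (15, 12)), dz.PatternEdge((8, 12), (15, 12)),
         dz.PatternEdge((22, 12), (15, 12))], (0, 0, 30, 24))
    sol = dz.solve_pattern(pat)
    assert sol.diagnostics["null_used"]
    check(sol, pat, coverage=0.90)


@pytest.mark.parametrize("seed", [0, 1])
def test_solve_random_voronoi_pattern_end_to_end(seed):
    """Randomized closed patterns: every desired edge appears, nothing
    spurious, at most the four doublets."""
    tess, _ = fx.random_voronoi_tessellation(8, (30.0, 30.0), seed=seed)
    pat = fx.voronoi_pattern(tess)
    sol = dz.solve_pattern(pat)
    assert sol.diagnostics["colours_used"] <= 4
    check(sol, pat)


def test_solve_escher_transmutation():
    pat = fx.escher_transmutation_pattern(n_cols=2)
    sol = dz.solve_pattern(pat)
    assert sol.diagnostics["colours_used"] <= 4
    check(sol, pat, coverage=0.97)


def test_solve_single_glyph_display():
    pat = dz.segment_display_pattern("U")
    sol = dz.solve_pattern(pat)
    assert sol.diagnostics["null_used"]
    check(sol, pat, coverage=0.95, spurious=0.03)


def test_two_distinct_solutions_same_square_pattern():
    """Different seeds can generate the same pattern: a singlet
    checkerboard and a doublet checkerboard both realize the square grid."""
    pitch, n = 10.0, 3
    edges = []
    for k in range(1, n):
        edges.append(dz.PatternEdge((k * pitch, 0), (k * pitch, n * pitch)))
        edges.append(dz.PatternEdge((0, k * pitch), (n * pitch, k * pitch)))
    pat = dz.InterfacePattern(edges, (0, 0, n * pitch, n * pitch))

    def checkerboard(e0, e1):
        return [fronts.SeedSpec(((i + 0.5) * pitch, (j + 0.5) * pitch),
                                ad.parse_element(e0 if (i + j) % 2 else e1))
                for i in range(n) for j in range(n)]

    for e0, e1 in (("Nb2", "Ag2"), ("Nb2+Nb3", "Ag2+Ag3")):
        sol = dz.DesignSolution(checkerboard(e0, e1), {})
        check(sol, pat)


# -- triangular lattice -------------------------------------------------------

def test_lattice_no_targets_single_element():
    asg = dz.triangular_lattice_design([], 4, 6)
    assert len({str(e) for e in asg.values()}) == 1


def test_lattice_all_edges_two_coloured():
    targets = [tuple(e) for e in dz.lattice_adjacency(6, 8).edges()]
    asg = dz.triangular_lattice_design(targets, 6, 8)
    assert len({str(e) for e in asg.values()}) == 2
    assert dz.verify_lattice_design(asg, targets, 6, 8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_lattice_random_region_targets_verified_edge_by_edge(seed):
    targets = fx.random_lattice_targets(20, 20, 6, seed=seed)
    asg = dz.triangular_lattice_design(targets, 20, 20)
    assert dz.verify_lattice_design(asg, targets, 20, 20)
    assert {str(e) for e in asg.values()} <= {str(d) for d in ad.DOUBLETS}


def test_lattice_unsatisfiable_target_reported():
    """One target edge inside a hexagonal cycle of hidden edges cannot be
    realized with doublets only."""
    targets = [((0, 1), (0, 2))]
    with pytest.raises(dz.ColouringError, match="unsatisfiable"):
        dz.triangular_lattice_design(targets, 2, 4)


def test_lattice_sequential_strategy():
    targets = [tuple(e) for e in dz.lattice_adjacency(6, 8).edges()]
    asg = dz.triangular_lattice_design(targets, 6, 8, strategy="sequential")
    assert dz.verify_lattice_design(asg, targets, 6, 8)


def test_lattice_rejects_non_lattice_target():
    with pytest.raises(dz.PatternError):
        dz.triangular_lattice_design([((0, 0), (5, 5))], 2, 4)


# -- 16-segment display -------------------------------------------------------

def test_display_u_active_segments():
    pat = dz.segment_display_pattern("U", glyph_size=(1.0, 1.0),
                                     origin=(0.0, 0.0), margin=0.5)
    # U = both verticals on each side plus the bottom: 6 segments
    assert len(pat.edges) == 6
    xs = {e.p0 for e in pat.edges} | {e.p1 for e in pat.edges}
    assert (0.0, 1.0) in xs and (1.0, 1.0) in xs    # open top corners
    assert len(pat.open_endpoints()) == 2


def test_display_empty_text():
    pat = dz.segment_display_pattern("")
    assert pat.edges == []


def test_display_unsupported_character():
    with pytest.raises(dz.PatternError, match="font"):
        dz.segment_display_pattern("@")


def test_display_multi_glyph_text_accepted_by_solver():
    pat = dz.segment_display_pattern("U of A")
    assert len({e for e in pat.edges}) == len(pat.edges)
    sol = dz.solve_pattern(pat)
    assert sol.diagnostics["null_used"]
    check(sol, pat, coverage=0.95, spurious=0.03)


# -- pattern I/O --------------------------------------------------------------

def test_pattern_geojson_roundtrip():
    pat = dz.InterfacePattern(
        [dz.PatternEdge((1, 2), (3, 4), "visible"),
         dz.PatternEdge((3, 4), (5, 2), "hidden")], (0, 0, 10, 10))
    gj = pat.to_geojson()
    back = dz.InterfacePattern.from_geojson(gj)
    assert [(e.p0, e.p1, e.desired) for e in back.edges] == \
        [(e.p0, e.p1, e.desired) for e in pat.edges]
    assert back.domain == pat.domain


def test_pattern_rejects_out_of_domain_edge():
    with pytest.raises(dz.PatternError):
        dz.InterfacePattern([dz.PatternEdge((0, 0), (20, 20))], (0, 0, 10, 10))
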