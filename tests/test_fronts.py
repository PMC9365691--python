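"""Geometric front-arrival predictor vs closed-form interface loci."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from swarmpat import adhesion as ad
from swarmpat import fronts, pde

GRID = fronts.GridSpec((40.0, 40.0), 0.1)


def seed(pos, element="n", delay=0.0, speed=1.0):
    return fronts.SeedSpec(pos, ad.parse_element(element), delay, speed)


def all_points(curves, visible=None):
    keep = [c for c in curves
            if visible is None or c.visible is visible]
    return np.vstack([c.points for c in keep])


@pytest.mark.parametrize("point, pos, delay, speed, want", [
    ((5.0, 5.0), (5.0, 5.0), 0.0, 1.0, 0.0),
    ((8.0, 5.0), (5.0, 9.0), 0.5, 2.5, 0.5 + 2.0),      # 3-4-5 triangle
])
def test_arrival_time_point_seed(point, pos, delay, speed, want):
    assert fronts.arrival_time(point, seed(pos, delay=delay, speed=speed)) \
        == pytest.approx(want)


def test_arrival_time_line_source_perpendicular_distance():
    line = seed([(0.0, 0.0), (10.0, 0.0)], speed=2.0)
    assert fronts.arrival_time((4.0, 6.0), line) == pytest.approx(3.0)
    # beyond the segment span: distance to the nearest endpoint
    assert fronts.arrival_time((13.0, 4.0), line) == pytest.approx(2.5)


def test_equal_seeds_give_perpendicular_bisector():
    s = [seed((10.0, 20.0), "Nb2"), seed((30.0, 20.0), "Ag2")]
    labels, curves = fronts.label_and_interfaces(s, GRID)
    pts = all_points(curves)
    assert np.abs(pts[:, 0] - 20.0).max() < 1e-9
    assert curves[0].visible
    a1, a2 = fronts.interface_angle(pts[np.argsort(pts[:, 1])],
                                    ((10, 20), (30, 20)))
    assert a1 == pytest.approx(90.0, abs=0.1)
    assert a2 == pytest.approx(90.0, abs=0.1)


def test_voronoi_oracle_equivalence():
    """Equal-parameter point seeds label every cell exactly like a
    nearest-neighbour (Voronoi) assignment."""
    rng = np.random.default_rng(11)
    pos = rng.uniform(5, 35, size=(12, 2))
    s = [seed(tuple(p)) for p in pos]
    lf, _ = fronts.label_and_interfaces(s, GRID)
    xs, ys = GRID.coords()
    xx, yy = np.meshgrid(xs, ys)
    _, nearest = cKDTree(pos).query(np.column_stack([xx.ravel(), yy.ravel()]))
    assert (lf.labels.ravel() == nearest).mean() > 0.999  # ties excepted


def test_delay_gives_hyperbola_branch():
    """Equal speeds, one delayed seed: the interface is the hyperbola
    |r-s1| - |r-s2| = -v*tau, shifted toward the delayed colony."""
    tau, v = 1.0, 1.5
    s = [seed((10.0, 20.0), "Nb2", delay=tau, speed=v),
         seed((30.0, 20.0), "Ag2", speed=v)]
    _, curves = fronts.label_and_interfaces(s, GRID)
    pts = all_points(curves)
    d1 = np.hypot(pts[:, 0] - 10, pts[:, 1] - 20)
    d2 = np.hypot(pts[:, 0] - 30, pts[:, 1] - 20)
    assert np.abs(d1 - d2 + v * tau).max() < 0.05
    assert pts[:, 0].max() < 20.0           # whole branch on delayed side


def test_speed_ratio_gives_apollonius_circle():
    s = [seed((10.0, 20.0), speed=2.0), seed((30.0, 20.0), speed=1.0)]
    _, curves = fronts.label_and_interfaces(s, GRID)
    pts = all_points(curves)
    ratio = (np.hypot(pts[:, 0] - 10, pts[:, 1] - 20)
             / np.hypot(pts[:, 0] - 30, pts[:, 1] - 20))
    np.testing.assert_allclose(ratio, 2.0, rtol=5e-4)
    # the slower colony is engulfed: interface closes behind it
    assert pts[:, 0].max() > 30.0


def test_line_and_point_give_parabola():
    line = seed([(5.0, 5.0), (35.0, 5.0)])
    focus = seed((20.0, 15.0))
    _, curves = fronts.label_and_interfaces([line, focus], GRID)
    pts = all_points(curves)
    centre = pts[(pts[:, 0] > 8) & (pts[:, 0] < 32)]
    resid = np.hypot(centre[:, 0] - 20, centre[:, 1] - 15) - (centre[:, 1] - 5)
    assert np.abs(resid).max() < 0.01


def test_six_alternating_seeds_give_hexagonal_star():
    """Six alternating Nb2/Ag2 colonies on a circle: six straight radial
    interfaces with hexagonal symmetry."""
    angles = np.deg2rad(60.0 * np.arange(6))
    s = [seed((20 + 8 * np.cos(a), 20 + 8 * np.sin(a)),
              "Nb2" if i % 2 == 0 else "Ag2")
         for i, a in enumerate(angles)]
    _, curves = fronts.label_and_interfaces(s, GRID)
    vis = [c for c in curves if c.visible]
    # the six neighbouring-colony boundaries are all present; any extra
    # adjacency is confined to the central junction point
    adjacent = {(min(c.seed_a, c.seed_b), max(c.seed_a, c.seed_b))
                for c in vis}
    want = {(min(i, (i + 1) % 6), max(i, (i + 1) % 6)) for i in range(6)}
    assert want <= adjacent
    for c in vis:
        if (min(c.seed_a, c.seed_b), max(c.seed_a, c.seed_b)) not in want:
            centre_dist = np.hypot(c.points[:, 0] - 20.0,
                                   c.points[:, 1] - 20.0)
            assert centre_dist.max() < 0.5
            continue
        pts = c.points - np.array([20.0, 20.0])
        r = np.hypot(pts[:, 0], pts[:, 1])
        core = pts[(r > 1.0) & (r < 7.0)]
        if len(core) < 5:
            continue
        theta = np.unwrap(np.arctan2(core[:, 1], core[:, 0]))
        spread = theta.max() - theta.min()
        assert spread < np.deg2rad(3.0)     # straight radial ray
        mid = np.rad2deg(np.median(theta)) % 360
        assert min(mid % 60, 60 - mid % 60) < 31.0  # at sector bisectors


def test_hyperbola_leg_angle_matches_asymptote():
    """Leg angles of the delayed-seed hyperbola approach the closed-form
    asymptote angle arccos(v*tau/d); the exact hyperbola sampled over the
    same window is the tight oracle."""
    tau, v, d = 2.0, 1.5, 20.0
    s = [seed((10.0, 20.0), delay=tau, speed=v),
         seed((30.0, 20.0), speed=v)]
    _, curves = fronts.label_and_interfaces(s, fronts.GridSpec((40, 40), 0.05))
    pts = all_points(curves)
    far = pts[np.abs(pts[:, 1] - 20.0) > 10.0]      # asymptotic regime
    a1, a2 = fronts.interface_angle(far[np.argsort(far[:, 1])],
                                    ((10, 20), (30, 20)))
    # exact branch: (x-20)^2/a^2 - (y-20)^2/b^2 = 1, x < 20
    a_h = v * tau / 2.0
    b_h = np.sqrt((d / 2.0) ** 2 - a_h ** 2)
    ys = np.sort(far[:, 1])
    exact = np.column_stack(
        [20.0 - a_h * np.sqrt(1.0 + (ys - 20.0) ** 2 / b_h ** 2), ys])
    e1, e2 = fronts.interface_angle(exact, ((10, 20), (30, 20)))
    assert a1 == pytest.approx(e1, abs=0.5)
    assert a2 == pytest.approx(e2, abs=0.5)
    asymptote = np.degrees(np.arccos(v * tau / d))
    assert a1 == pytest.approx(asymptote, abs=5.0)
    assert a2 == pytest.approx(asymptote, abs=5.0)


def test_interface_angle_decreases_with_delay():
    angles = []
    for ratio in (1.0, 10.0, 1000.0, 10.0**6):
        tau = pde.delay_from_dilution(ratio, 2.0)
        s = [seed((10.0, 20.0), delay=tau, speed=1.5),
             seed((30.0, 20.0), speed=1.5)]
        _, curves = fronts.label_and_interfaces(s, GRID)
        pts = all_points(curves)
        a1, a2 = fronts.interface_angle(pts[np.argsort(pts[:, 1])],
                                        ((10, 20), (30, 20)))
        angles.append((a1 + a2) / 2.0)
    assert all(x > y for x, y in zip(angles[:-1], angles[1:]))
    assert angles[0] == pytest.approx(90.0, abs=0.5)


def test_predictor_matches_pde_midline():
    """The argmin-arrival bisector agrees with the continuum-model density
    crossing within two grid cells for a matched two-seed problem."""
    params = pde.ModelParams(extent=(20.0, 10.0), dx=0.1)
    seeds_pde = [pde.SeedInit((5.5, 5.0), 0), pde.SeedInit((14.5, 5.0), 1)]
    state = pde.simulate(seeds_pde, params, ["Nb2", "Ag2"], t_end=2.5)[-1]
    row = state.rho.shape[1] // 2
    d = state.total[0][row] - state.total[1][row]
    j = np.flatnonzero(np.sign(d[:-1]) != np.sign(d[1:]))[0]
    x_pde = (j + d[j] / (d[j] - d[j + 1])) * state.dx

    s = [seed((5.5, 5.0), "Nb2"), seed((14.5, 5.0), "Ag2")]
    _, curves = fronts.label_and_interfaces(
        s, fronts.GridSpec((20.0, 10.0), 0.1))
    x_geo = all_points(curves)[:, 0].mean()
    assert abs(x_pde - x_geo) <= 2 * 0.1


def test_visibility_flag_depends_only_on_elements():
    pos = [(10.0, 20.0), (30.0, 20.0)]
    for e1, e2, want in [("Nb2", "Ag2", True), ("Nb2", "Ag3", False),
                         ("n", "Nb2+Ag3", False)]:
        s = [seed(pos[0], e1), seed(pos[1], e2)]
        _, curves = fronts.label_and_interfaces(s, GRID)
        assert all(c.visible is want for c in curves)


def test_duplicate_and_single_seeds_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        fronts.label_and_interfaces(
            [seed((5.0, 5.0)), seed((5.0, 5.0))], GRID)
    with pytest.raises(ValueError):
        fronts.label_and_interfaces([seed((5.0, 5.0))], GRID)


def test_degenerate_angle_trace_rejected():
    with pytest.raises(ValueError):
        fronts.interface_angle(np.array([[1.0, 1.0], [1.0, 1.0]]),
                               ((0, 0), (1, 0)))


def test_interfaces_geojson_structure():
    s = [seed((10.0, 20.0), "Nb2"), seed((30.0, 20.0), "Ag2")]
    _, curves = fronts.label_and_interfaces(s, GRID)
    gj = fronts.interfaces_to_geojson(curves)
    assert gj["type"] == "FeatureCollection" and gj["units"] == "mm"
    f = gj["features"][0]
    assert f["geometry"]["type"] == "LineString"
    assert set(f["properties"]) == {"seed_a", "seed_b", "visible"}
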