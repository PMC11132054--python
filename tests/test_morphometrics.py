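"""Polygon, polyline, curvature, angle and percent-change metrics."""

import numpy as np
import pytest

import antheridyn as ad
from antheridyn.exceptions import GeometryError, InputError
from antheridyn.morphometrics import polyline_centroid


def fan_area(pts, center):
    """Triangulation oracle: sum of triangle areas fanned from an interior
    point; exact for polygons star-shaped about that point."""
    total = 0.0
    n = len(pts)
    for i in range(n):
        a, b = pts[i] - center, pts[(i + 1) % n] - center
        total += abs(a[0] * b[1] - a[1] * b[0]) / 2.0
    return total


@pytest.mark.parametrize(
    "pts,expected",
    [
        ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
        ([(0, 0), (4, 0), (4, 3)], 6.0),
    ],
)
def test_polygon_area_known_shapes(pts, expected):
    assert ad.polygon_area(pts) == pytest.approx(expected, abs=1e-12)
    # closed-ring input (repeated first vertex) gives the same area
    assert ad.polygon_area(pts + pts[:1]) == pytest.approx(expected, abs=1e-12)


def test_polygon_area_matches_triangulation_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        # jittered grid keeps every angular gap below pi: star-shaped
        # about the origin, so fanning from the origin is exact
        ang = 2 * np.pi * (np.arange(12) + rng.uniform(0, 0.45, 12)) / 12
        radii = rng.uniform(1.0, 5.0, 12)
        pts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
        assert ad.polygon_area(pts) == pytest.approx(
            fan_area(pts, np.zeros(2)), abs=1e-9
        )


def test_polygon_area_is_orientation_independent():
    pts = np.array([(0, 0), (4, 0), (4, 3), (0, 3)], float)
    assert ad.polygon_area(pts) == ad.polygon_area(pts[::-1])


def test_polygon_area_rejects_self_intersection():
    bowtie = [(0, 0), (2, 2), (2, 0), (0, 2)]
    with pytest.raises(GeometryError):
        ad.polygon_area(bowtie)


@pytest.mark.parametrize(
    "pts,expected",
    [
        ([(0, 0), (3, 0), (3, 4)], 7.0),
        ([(0, 0), (1, 1)], np.sqrt(2)),
    ],
)
def test_arclength_known_polylines(pts, expected):
    assert ad.polyline_arclength(np.asarray(pts, float)) == pytest.approx(expected)


def test_arclength_of_dense_circle_sampling():
    t = np.linspace(0, 2 * np.pi, 721)
    pts = 10.0 * np.column_stack([np.cos(t), np.sin(t)])
    assert ad.polyline_arclength(pts) == pytest.approx(2 * np.pi * 10, rel=1e-4)


def test_arclength_additive_under_concatenation():
    rng = np.random.default_rng(3)
    pts = rng.uniform(-5, 5, (9, 2))
    whole = ad.polyline_arclength(pts)
    assert whole == pytest.approx(
        ad.polyline_arclength(pts[:5]) + ad.polyline_arclength(pts[4:])
    )


@pytest.mark.parametrize(
    "before,after,expected",
    [(100.0, 116.9, 16.9), (7.0, 7.0, 0.0), (100.0, 90.6, -9.4)],
)
def test_percent_change(before, after, expected):
    assert ad.percent_change(before, after) == pytest.approx(expected)


def test_percent_change_inverse_relation():
    b, a = 13.0, 17.5
    fwd = ad.percent_change(b, a)
    back = ad.percent_change(a, b)
    assert (1 + fwd / 100) * (1 + back / 100) == pytest.approx(1.0)
    with pytest.raises(InputError):
        ad.percent_change(0.0, 1.0)


def _rect_cell(rot_deg=0.0):
    """Axis-aligned rectangular cell: outer wall y=1 (x 0..2), inner y=0,
    laterals at x=0 and x=2; width 1, length 2, ratio 0.5."""
    def rot(pts):
        phi = np.deg2rad(rot_deg)
        m = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        return np.asarray(pts, float) @ m.T

    return ad.JacketCellPolygon(
        inner=ad.WallPolyline(rot([(0, 0), (1, 0), (2, 0)]), "inner", "c"),
        outer=ad.WallPolyline(rot([(0, 1), (1, 1), (2, 1)]), "outer", "c"),
        lateral_a=ad.WallPolyline(rot([(0, 0), (0, 1)]), "lateral_a", "c"),
        lateral_b=ad.WallPolyline(rot([(2, 0), (2, 1)]), "lateral_b", "c"),
        cell_id="c",
    )


def test_cell_width_length_rectangle():
    w, l, r = ad.cell_width_length(_rect_cell())
    assert (w, l, r) == pytest.approx((1.0, 2.0, 0.5), abs=1e-12)


def test_cell_width_length_rigid_invariant():
    w, l, r = ad.cell_width_length(_rect_cell(rot_deg=30.0))
    assert (w, l, r) == pytest.approx((1.0, 2.0, 0.5), abs=1e-9)


def test_cell_area_extension_square_scaling():
    def square(s):
        return ad.JacketCellPolygon(
            inner=ad.WallPolyline([(0, 0), (s, 0)], "inner", "q"),
            outer=ad.WallPolyline([(0, s), (s, s)], "outer", "q"),
            lateral_a=ad.WallPolyline([(0, 0), (0, s)], "lateral_a", "q"),
            lateral_b=ad.WallPolyline([(s, 0), (s, s)], "lateral_b", "q"),
            cell_id="q",
        )

    assert ad.cell_area_extension(square(1.0), square(1.1)) == pytest.approx(
        21.0, abs=1e-9
    )
    assert ad.cell_area_extension(square(1.0), square(1.0)) == 0.0


def _arc(radius, ang_lo, ang_hi, n, center=(0.0, 0.0)):
    t = np.linspace(ang_lo, ang_hi, n)
    return np.asarray(center) + radius * np.column_stack([np.cos(t), np.sin(t)])


def test_curvature_semicircle_signed_half():
    # lower semicircle of radius 2 bulging toward a reference point below
    pts = _arc(2.0, np.pi, 2 * np.pi, 41)
    kappa = ad.wall_curvature(ad.WallPolyline(pts, "inner", "c"), (0.0, -10.0))
    assert kappa == pytest.approx(0.5, abs=1e-9)
    # same wall, reference mirrored across the chord: sign flips only
    kappa_out = ad.wall_curvature(ad.WallPolyline(pts, "inner", "c"), (0.0, 10.0))
    assert kappa_out == pytest.approx(-0.5, abs=1e-9)


def test_curvature_collinear_wall_is_zero():
    pts = np.column_stack([np.linspace(0, 5, 9), np.zeros(9)])
    assert ad.wall_curvature(ad.WallPolyline(pts, "outer", "c"), (1.0, 3.0)) == 0.0


def test_curvature_under_noise_within_one_percent():
    radius = 10.0
    rng = np.random.default_rng(11)
    pts = _arc(radius, 0.3, 2.2, 200)
    pts = pts + rng.normal(0, 0.01 * radius, pts.shape)
    kappa = ad.wall_curvature(ad.WallPolyline(pts, "inner", "c"), (0.0, 0.0))
    assert abs(abs(kappa) - 1 / radius) < 0.01 / radius


def test_curvature_needs_three_points():
    with pytest.raises(InputError):
        ad.wall_curvature(ad.WallPolyline([(0, 0), (1, 0)], "inner", "c"), (0, 1))


def test_wall_angle_perpendicular_and_straight():
    a = ad.WallPolyline([(0, 0), (1, 0)], "outer", "a")
    b = ad.WallPolyline([(0, 0), (0, 1)], "outer", "b")
    assert ad.wall_angle(a, b) == pytest.approx(90.0)
    c = ad.WallPolyline([(0, 0), (-1, 0)], "outer", "c")
    assert ad.wall_angle(a, c) == pytest.approx(180.0)
    far = ad.WallPolyline([(5, 5), (6, 5)], "outer", "d")
    with pytest.raises(InputError):
        ad.wall_angle(a, far)


def test_wall_angle_recovers_prescribed_junction_angle_under_noise():
    """An unbiased estimate: over repeated 0.05 µm landmark noise the
    junction angle comes back within 0.5 degrees RMS."""
    true_angle = 118.0
    n = 7
    rng = np.random.default_rng(21)
    da, db = np.deg2rad(0.0), np.deg2rad(true_angle)
    ta = np.linspace(0, 16.0, n)
    wall_a = np.column_stack([ta * np.cos(da), ta * np.sin(da)])
    wall_b = np.column_stack([ta * np.cos(db), ta * np.sin(db)])
    errors = []
    for _ in range(30):
        noise_a = rng.normal(0, 0.05, wall_a.shape)
        noise_b = rng.normal(0, 0.05, wall_b.shape)
        noise_b[0] = noise_a[0]  # the junction is one tracked point
        got = ad.wall_angle(
            ad.WallPolyline(wall_a + noise_a, "outer", "a"),
            ad.WallPolyline(wall_b + noise_b, "outer", "b"),
        )
        errors.append(got - true_angle)
    errors = np.asarray(errors)
    assert np.sqrt((errors ** 2).mean()) < 0.5
    assert abs(errors.mean()) < 0.25


def test_apex_extension_series_growth_and_timing():
    times = np.arange(5) / 15.0
    walls = [
        ad.WallPolyline([(0, 0), (length, 0)], "", "")
        for length in (100, 102, 104, 107.3, 105)
    ]
    lengths, pct, elapsed = ad.apex_extension_series(walls, times)
    assert lengths[0] == 100
    assert pct == pytest.approx(7.3)
    assert elapsed == pytest.approx(3 / 15)
    # constant series: no growth, maximum at the first frame
    const = [ad.WallPolyline([(0, 0), (5, 0)], "", "")] * 3
    _, pct0, dt0 = ad.apex_extension_series(const, times[:3])
    assert pct0 == 0.0 and dt0 == 0.0


def test_metrics_invariant_under_rigid_transform(template, quiet_scenario):
    """The metric table is unchanged when both frames are moved by the
    same rotation + translation.  Organ width is the one exception by
    definition: it is the x-extent in the *normalized* frame, so it is
    only invariant through the registration step."""
    after, _ = ad.apply_burst_deformation(template, quiet_scenario, seed=5)
    table = ad.burst_metrics(template.geometry, after)
    phi = np.deg2rad(25.0)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    move = lambda g: g.with_points(g.points @ rot.T + np.array([3.0, -8.0]))
    table_moved = ad.burst_metrics(move(template.geometry), move(after))
    keep = table["metric"] != "organ_width_change"
    np.testing.assert_allclose(
        table.loc[keep, "value"].to_numpy(),
        table_moved.loc[keep, "value"].to_numpy(),
        rtol=1e-9, atol=1e-9,
    )


def test_polyline_centroid_is_sampling_independent():
    coarse = np.array([(0.0, 0.0), (10.0, 0.0)])
    fine = np.column_stack([np.linspace(0, 10, 57), np.zeros(57)])
    np.testing.assert_allclose(
        polyline_centroid(coarse), polyline_centroid(fine), atol=1e-12
    )
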