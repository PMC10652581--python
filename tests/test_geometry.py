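"""Geometric constructions: axes, reference/cut lines, checkpoints,
osteophyte trapezoid and post-operative rectangles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneegap.errors import (
    AnnotationError,
    ContourError,
    GeometryError,
    ParameterError,
)
from kneegap.geometry import (
    AnnotatedView,
    Line2D,
    Point2D,
    PolyContour,
    build_cut_plan,
    build_femoral_cut,
    build_femoral_reference,
    build_tibial_cut,
    cut_thickness,
    fit_femoral_axis,
    fit_tibial_axis,
    lateral_angle_deg,
    max_inscribed_circle,
    mirror_view,
    osteophyte_trapezoid,
    postop_measures,
    release_gap,
    release_gap_from_borders,
    rigid_transform_view,
    tibial_checkpoints,
)

from conftest import grid_incircle_oracle


def rectangle(x0, y0, x1, y1):
    return PolyContour(
        [Point2D(x0, y0), Point2D(x1, y0), Point2D(x1, y1), Point2D(x0, y1)]
    )


# ---------------------------------------------------------------------------
# Line2D primitives
# ---------------------------------------------------------------------------


@given(
    st.floats(-100, 100),
    st.floats(-100, 100),
    st.floats(-10, 10).filter(lambda v: abs(v) > 1e-6),
    st.floats(-10, 10).filter(lambda v: abs(v) > 1e-6),
)
def test_line_direction_canonical(ax, ay, dx, dy):
    """Directions normalise to unit length with y >= 0 regardless of the
    vector handed in."""
    line = Line2D(Point2D(ax, ay), (dx, dy))
    ux, uy = line.direction
    assert math.hypot(ux, uy) == pytest.approx(1.0, abs=1e-9)
    assert uy > 0 or (uy == 0 and ux >= 0)
    flipped = Line2D(Point2D(ax, ay), (-dx, -dy))
    assert flipped.direction == pytest.approx(line.direction)


def test_point_line_distance_basics():
    horizontal = Line2D(Point2D(0, 3), (1, 0))
    assert cut_thickness(Point2D(5, 3), horizontal) == pytest.approx(0.0)
    assert cut_thickness(Point2D(0, 0), horizontal) == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# maximum inscribed circle / axis fitting
# ---------------------------------------------------------------------------


def test_incircle_of_rectangle_is_halfwidth():
    shaft = rectangle(-10, 0, 10, 100)
    c = max_inscribed_circle(shaft, (30, 70))
    assert c.radius == pytest.approx(10.0, abs=0.02)
    assert c.center.x == pytest.approx(0.0, abs=0.02)


def test_incircle_matches_grid_oracle_on_tapered_shaft():
    taper = PolyContour(
        [Point2D(-12, 0), Point2D(12, 0), Point2D(8, 60), Point2D(-8, 60)]
    )
    window = (5, 40)
    c = max_inscribed_circle(taper, window)
    _, r_oracle = grid_incircle_oracle(taper, window)
    assert c.radius == pytest.approx(r_oracle, abs=0.1)
    assert c.radius >= r_oracle - 1e-9  # optimiser at least as good as the grid


def test_incircle_window_outside_contour_errors():
    shaft = rectangle(-10, 0, 10, 100)
    with pytest.raises(GeometryError):
        max_inscribed_circle(shaft, (200, 250))


def test_incircle_requires_closed_contour():
    open_contour = PolyContour([Point2D(0, 0), Point2D(1, 0), Point2D(1, 1)], closed=False)
    with pytest.raises(ContourError):
        max_inscribed_circle(open_contour, (0, 1))


def test_femoral_axis_of_straight_shaft_is_midline():
    shaft = rectangle(-16, 0, 16, 160)
    axis = fit_femoral_axis(shaft, (100, 140), (20, 60))
    assert axis.direction[1] == pytest.approx(1.0, abs=1e-6)
    assert abs(axis.anchor.x) < 0.05


def test_femoral_axis_overlapping_windows_rejected():
    shaft = rectangle(-16, 0, 16, 160)
    with pytest.raises(ParameterError):
        fit_femoral_axis(shaft, (20, 80), (60, 140))


def test_femoral_axis_degenerate_centers_rejected():
    shaft = rectangle(-16, 0, 16, 160)
    with pytest.raises(GeometryError):
        fit_femoral_axis(shaft, (50.0, 50.4), (50.5, 50.9))


def test_tibial_axis_recovers_7_degree_tilt():
    """A rectangular shaft rotated by 7° must give back a 7° axis."""
    base = rectangle(-15, -160, 15, 0)
    tilted = base.transformed(
        lambda p: Point2D(
            math.cos(math.radians(7)) * p.x - math.sin(math.radians(7)) * p.y,
            math.sin(math.radians(7)) * p.x + math.cos(math.radians(7)) * p.y,
        )
    )
    axis = fit_tibial_axis(tilted)
    expected = (-math.sin(math.radians(7)), math.cos(math.radians(7)))
    angle = math.degrees(
        math.acos(
            min(1.0, abs(axis.direction[0] * expected[0] + axis.direction[1] * expected[1]))
        )
    )
    assert angle < 0.1


# ---------------------------------------------------------------------------
# femoral reference and cut lines
# ---------------------------------------------------------------------------


def condyle_block(medial_y, lateral_y):
    """Simple femur-like hexagon with condylar bottom vertices at the given
    heights (medial at +10, lateral at -10)."""
    return PolyContour(
        [
            Point2D(-12, 60),
            Point2D(12, 60),
            Point2D(12, 5),
            Point2D(10, medial_y),
            Point2D(-10, lateral_y),
            Point2D(-12, 5),
        ]
    )


VERTICAL_AXIS = Line2D(Point2D(0, 0), (0, 1))


def test_reference_line_rises_5_degrees_toward_lateral():
    contour = condyle_block(0.0, 0.0)
    ref, contact, side = build_femoral_reference(VERTICAL_AXIS, contour, aldfa_deg=85)
    dx, dy = ref.direction
    # 5° above horizontal; canonical normalisation makes the direction
    # point medially with positive slope component
    assert math.degrees(math.atan2(dy, abs(dx))) == pytest.approx(5.0, abs=1e-9)
    assert lateral_angle_deg(ref, VERTICAL_AXIS) == pytest.approx(85.0, abs=1e-9)


def test_contact_on_more_distal_medial_condyle():
    contour = condyle_block(-2.0, 0.0)  # medial condyle 2 mm more distal
    ref, contact, side = build_femoral_reference(VERTICAL_AXIS, contour, aldfa_deg=85)
    assert side == "medial"
    assert contact == Point2D(10, -2.0)
    assert ref.distance_to(contact) == pytest.approx(0.0, abs=1e-12)


def test_contact_tie_resolves_to_medial():
    # at aLDFA 90° the sweep is horizontal so equal condyle heights tie
    contour = condyle_block(0.0, 0.0)
    _, contact, side = build_femoral_reference(VERTICAL_AXIS, contour, aldfa_deg=90)
    assert side == "medial"
    assert contact == Point2D(10, 0.0)


def test_femoral_cut_offset_geometry():
    horizontal = Line2D(Point2D(0, 0), (1, 0))
    cut = build_femoral_cut(horizontal, 9)
    assert cut.anchor == Point2D(0.0, 9.0)
    with pytest.raises(ParameterError):
        build_femoral_cut(horizontal, 0)
    tilted = Line2D(Point2D(0, 0), (math.cos(math.radians(5)), math.sin(math.radians(5))))
    cut5 = build_femoral_cut(tilted, 9)
    assert tilted.distance_to(cut5.anchor) == pytest.approx(9.0, abs=1e-12)
    # the thickness measured back from a point on the reference equals the offset
    assert cut_thickness(Point2D(0, 0), cut5) == pytest.approx(9.0, abs=1e-12)


# ---------------------------------------------------------------------------
# tibial checkpoints / cut
# ---------------------------------------------------------------------------


def flat_plateau_tibia(x_lat=-20.0, x_med=20.0, dip=None):
    surface = [Point2D(x_lat, 0)]
    if dip is not None:
        surface += [Point2D(dip[0] - 2, 0), Point2D(*dip), Point2D(dip[0] + 2, 0)]
    surface += [Point2D(x_med, 0)]
    return PolyContour(surface + [Point2D(x_med, -80), Point2D(x_lat, -80)])


def test_tl_at_three_eighths_from_lateral_edge():
    t_m, t_l = tibial_checkpoints(VERTICAL_AXIS, flat_plateau_tibia())
    assert t_l.x == pytest.approx(-20 + 0.375 * 40, abs=1e-9)  # -5
    assert t_l.y == pytest.approx(0.0, abs=1e-9)


def test_tl_fraction_scales_with_plateau_width():
    t_m, t_l = tibial_checkpoints(VERTICAL_AXIS, flat_plateau_tibia(-4.0, 4.0))
    assert t_l.x - (-4.0) == pytest.approx(0.375 * 8.0, abs=1e-9)  # 3 mm


def test_tm_is_lowest_medial_surface_vertex():
    t_m, _ = tibial_checkpoints(VERTICAL_AXIS, flat_plateau_tibia(dip=(12.0, -1.8)))
    assert t_m == Point2D(12.0, -1.8)


def test_narrow_plateau_rejected():
    sliver = PolyContour(
        [Point2D(-0.3, 0), Point2D(0.3, 0), Point2D(0.3, -40), Point2D(-0.3, -40)]
    )
    with pytest.raises(GeometryError):
        tibial_checkpoints(VERTICAL_AXIS, sliver)


def test_tibial_cut_placement_and_distance():
    cut = build_tibial_cut(VERTICAL_AXIS, Point2D(-5, 0), 10)
    assert cut.anchor.y == pytest.approx(-10.0)
    assert cut.direction == pytest.approx((1.0, 0.0))
    tilted_axis = Line2D(Point2D(0, 0), (math.sin(math.radians(7)), math.cos(math.radians(7))))
    cut7 = build_tibial_cut(tilted_axis, Point2D(-5, 0), 10)
    assert cut7.distance_to(Point2D(-5, 0)) == pytest.approx(10.0, abs=1e-12)
    assert cut7.angle_to(tilted_axis) == pytest.approx(90.0, abs=1e-9)
    with pytest.raises(ParameterError):
        build_tibial_cut(VERTICAL_AXIS, Point2D(-5, 0), -1)


# ---------------------------------------------------------------------------
# osteophyte trapezoid / release gap
# ---------------------------------------------------------------------------


def test_unit_square_trapezoid():
    trap = osteophyte_trapezoid(
        Point2D(0, 1), Point2D(1, 1), Point2D(1, 0), Point2D(0, 0)
    )
    assert (trap.x_len, trap.y_len, trap.z_len, trap.w_len) == (1, 1, 1, 1)
    assert trap.area == pytest.approx(1.0)
    assert release_gap(trap) == pytest.approx(2.0)


def test_trapezoid_hand_computed_shoelace():
    trap = osteophyte_trapezoid(
        Point2D(0, 10), Point2D(6, 9), Point2D(6, 1), Point2D(0, 0)
    )
    assert trap.x_len == pytest.approx(math.sqrt(37))
    assert trap.y_len == pytest.approx(8.0)
    assert trap.z_len == pytest.approx(math.sqrt(37))
    assert trap.w_len == pytest.approx(10.0)
    assert trap.area == pytest.approx(54.0)


def test_trapezoid_coincident_points_rejected():
    p = Point2D(0, 0)
    with pytest.raises(GeometryError):
        osteophyte_trapezoid(p, p, Point2D(1, 1), Point2D(2, 2))


def test_self_intersecting_cycle_warns_and_uses_simple_area():
    with pytest.warns(UserWarning):
        trap = osteophyte_trapezoid(
            Point2D(0, 1), Point2D(1, 0), Point2D(1, 1), Point2D(0, 0)
        )
    assert trap.area == pytest.approx(1.0)


def test_release_gap_zero_for_collinear_checkpoints():
    # a perfectly flat "osteophyte" (all checkpoints on the cortex line)
    # gains no gap; the degenerate cycle itself warns
    with pytest.warns(UserWarning):
        trap = osteophyte_trapezoid(
            Point2D(0, 0), Point2D(1, 0), Point2D(3, 0), Point2D(4, 0)
        )
    assert release_gap(trap) == pytest.approx(0.0, abs=1e-12)


def test_release_gap_from_cohort_mean_borders():
    """At the whole-cohort mean border lengths the osteophyte release gains
    about 4.6 mm of gap."""
    assert release_gap_from_borders(5.638, 10.181, 5.394, 16.6) == pytest.approx(4.613)


def test_release_gap_tip_mode_is_outer_minus_inner_border():
    assert release_gap_from_borders(1, 5, 1, 4, mode="tip") == pytest.approx(1.0)


@given(
    st.lists(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=4, max_size=4
    )
)
def test_release_gap_nonnegative_property(coords):
    pts = [Point2D(x, y) for x, y in coords]
    if min(
        pts[i].distance_to(pts[j]) for i in range(4) for j in range(i + 1, 4)
    ) < 1e-6:
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trap = osteophyte_trapezoid(*pts)
    assert release_gap(trap) >= -1e-9
    assert trap.x_len + trap.y_len + trap.z_len >= trap.w_len - 1e-9


# ---------------------------------------------------------------------------
# post-operative rectangles
# ---------------------------------------------------------------------------


def rect_corners(cx, cy, long_mm, short_mm, short_jitter=0.0):
    half_l, half_s = long_mm / 2, short_mm / 2
    return (
        Point2D(cx - half_l, cy + half_s + short_jitter / 2),
        Point2D(cx + half_l, cy + half_s - short_jitter / 2),
        Point2D(cx + half_l, cy - half_s + short_jitter / 2),
        Point2D(cx - half_l, cy - half_s - short_jitter / 2),
    )


def postop_view(view="AP", rects=None):
    return AnnotatedView(
        view=view, phase="postop", laterality="right", implant_rectangles=rects
    )


def test_joint_gap_is_shorter_border():
    rects = {"joint_space": rect_corners(0, 0, 60, 18)}
    m = postop_measures(postop_view(rects=rects))
    assert m.joint_gap == pytest.approx(18.0)
    assert m.femoral_cut_line.anchor.y > m.tibial_cut_line.anchor.y


def test_joint_gap_averages_unequal_shorter_borders():
    # shorter borders 17.8 and 18.2 -> mean 18.0
    corners = (
        Point2D(-30, 8.9),
        Point2D(30, 9.1),
        Point2D(30, -9.1),
        Point2D(-30, -8.9),
    )
    m = postop_measures(postop_view(rects={"joint_space": corners}))
    assert m.joint_gap == pytest.approx(18.0, abs=1e-9)


def test_posterior_condyle_is_lateral_view_element():
    rects = {
        "joint_space": rect_corners(0, 0, 60, 18),
        "posterior_condyle": rect_corners(0, -30, 40, 9),
    }
    with pytest.raises(AnnotationError):
        postop_measures(postop_view(view="AP", rects=rects))
    m = postop_measures(postop_view(view="lateral", rects=rects))
    assert m.post_condyle == pytest.approx(9.0)


def test_missing_rectangle_is_annotation_error():
    with pytest.raises(AnnotationError):
        postop_measures(postop_view(rects={}))


def test_rotated_corner_order_auto_corrected_with_warning():
    c = rect_corners(0, 0, 60, 18)
    rotated = (c[1], c[2], c[3], c[0])  # shorter edge listed first
    with pytest.warns(UserWarning):
        m = postop_measures(postop_view(rects={"joint_space": rotated}))
    assert m.joint_gap == pytest.approx(18.0)


# ---------------------------------------------------------------------------
# frame invariances
# ---------------------------------------------------------------------------


def plan_lengths(view):
    plan = build_cut_plan(view)
    pts = view.osteophyte_points
    trap = osteophyte_trapezoid(pts["F1"], pts["F2"], pts["T2"], pts["T1"])
    return np.array(
        [plan.femoral_cut, plan.tibial_cut, trap.x_len, trap.y_len, trap.z_len, trap.w_len]
    )


def test_measurements_invariant_under_rigid_motion(default_knee):
    view, _ = default_knee
    base = plan_lengths(view)
    rng = np.random.default_rng(11)
    for _ in range(3):
        moved = rigid_transform_view(
            view,
            rotation_deg=rng.uniform(-12, 12),
            tx=rng.uniform(-40, 40),
            ty=rng.uniform(-40, 40),
        )
        assert np.max(np.abs(plan_lengths(moved) - base)) < 1e-6


def test_uniform_scaling_scales_measured_lengths(default_knee):
    """Scaling the coordinates by s scales every *measured* length by s
    exactly (the pre-calibration contract).  The constructed resection
    offsets are parameters, not measurements, so they are excluded."""
    view, _ = default_knee
    s = 1.4
    from kneegap.geometry import _transformed_view

    scaled = _transformed_view(view, lambda p: Point2D(p.x * s, p.y * s))
    measured = plan_lengths(view)[2:]  # trapezoid borders
    assert np.allclose(plan_lengths(scaled)[2:], s * measured, atol=1e-6)
    # point-to-line thickness scales with its inputs
    line = Line2D(Point2D(0, 3), (1, 0))
    line_s = Line2D(Point2D(0, 3 * s), (1, 0))
    assert cut_thickness(Point2D(4, 0), line) * s == pytest.approx(
        cut_thickness(Point2D(4 * s, 0), line_s)
    )


def test_mirrored_left_knee_measures_like_right(default_knee):
    view, _ = default_knee
    mirrored_back = mirror_view(mirror_view(view))
    assert np.allclose(plan_lengths(mirror_view(view)), plan_lengths(view), atol=1e-9)
    assert np.allclose(plan_lengths(mirrored_back), plan_lengths(view), atol=1e-12)
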