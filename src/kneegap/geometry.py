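"""Landmark geometry for 2-D knee radiograph planning.

All constructions operate on coordinate annotations of antero-posterior
(AP) or lateral knee films, expressed in millimetres in a canonical frame:

* ``y`` increases proximally (up the limb),
* ``x`` increases medially,
* canonical laterality is a RIGHT knee; left knees are mirrored about the
  y axis on load so that "medial"/"lateral" language is unambiguous.

The constructions mirror a conventional measured-resection templating
workflow: the femoral anatomic axis is the line through the centres of two
maximum inscribed circles of the shaft (simulating the intramedullary rod),
the distal cut reference is a line at the anatomic lateral distal femoral
angle (aLDFA, default 85°) swept into first contact with the distal condylar
margin, and the initial cut lines sit at fixed resection offsets (9 mm
femoral, 10 mm tibial).  Marginal osteophytes are summarised by a
quadrilateral through four checkpoints F1, F2, T2, T1 whose border lengths
w, x, y, z quantify osteophyte size; the soft-tissue gap gained by removing
them is the excess of the outer (over-the-tips) rim over the inner
(along-cortex) chord.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import shapely
from scipy.optimize import minimize
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    AnnotationError,
    ContourError,
    GeometryError,
    ParameterError,
)

__all__ = [
    "Point2D",
    "Line2D",
    "PolyContour",
    "Circle",
    "Marker",
    "AnnotatedView",
    "OsteophyteTrapezoid",
    "CutPlan",
    "PostopMeasures",
    "max_inscribed_circle",
    "fit_femoral_axis",
    "fit_tibial_axis",
    "build_femoral_reference",
    "build_femoral_cut",
    "tibial_checkpoints",
    "build_tibial_cut",
    "cut_thickness",
    "lateral_angle_deg",
    "osteophyte_trapezoid",
    "release_gap",
    "release_gap_from_borders",
    "postop_measures",
    "build_cut_plan",
    "mirror_view",
    "rigid_transform_view",
]

Side = Literal["medial", "lateral"]

# Default jig constants of the planning construction.
DEFAULT_ALDFA_DEG = 85.0
DEFAULT_FEMORAL_OFFSET_MM = 9.0
DEFAULT_TIBIAL_OFFSET_MM = 10.0
DEFAULT_TIBIAL_LATERAL_FRACTION = 3.0 / 8.0

#: Osteophyte checkpoint names in trapezoid cycle order.
OSTEOPHYTE_POINT_NAMES = ("F1", "F2", "T2", "T1")


# ---------------------------------------------------------------------------
# primitive types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Point2D:
    """A point in the canonical film frame, in millimetres."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ParameterError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


def _canonical_direction(dx: float, dy: float) -> tuple[float, float]:
    """Normalise to unit length with dy >= 0 (ties broken by dx >= 0)."""
    norm = math.hypot(dx, dy)
    if norm < 1e-12:
        raise GeometryError("degenerate direction vector")
    dx, dy = dx / norm, dy / norm
    if dy < 0 or (dy == 0 and dx < 0):
        dx, dy = -dx, -dy
    return dx, dy


@dataclass(frozen=True)
class Line2D:
    """An infinite line given by an anchor point and a unit direction.

    The direction is normalised so its y component is >= 0 (ties broken
    toward positive x), which makes line equality and angle measurements
    independent of construction order.
    """

    anchor: Point2D
    direction: tuple[float, float]

    def __post_init__(self):
        dx, dy = self.direction
        object.__setattr__(self, "direction", _canonical_direction(dx, dy))

    @classmethod
    def from_points(cls, p: Point2D, q: Point2D) -> "Line2D":
        return cls(p, (q.x - p.x, q.y - p.y))

    @property
    def normal(self) -> tuple[float, float]:
        """Unit normal with positive y (the 'proximal' side for near-
        horizontal cut lines); ties broken toward positive x."""
        dx, dy = self.direction
        nx, ny = -dy, dx
        if ny < 0 or (ny == 0 and nx < 0):
            nx, ny = -nx, -ny
        return nx, ny

    def distance_to(self, p: Point2D) -> float:
        """Unsigned perpendicular distance from ``p`` to the line."""
        dx, dy = self.direction
        rx, ry = p.x - self.anchor.x, p.y - self.anchor.y
        return abs(dx * ry - dy * rx)

    def signed_offset(self, p: Point2D) -> float:
        """Offset of ``p`` along the canonical normal (positive = proximal)."""
        nx, ny = self.normal
        return nx * (p.x - self.anchor.x) + ny * (p.y - self.anchor.y)

    def project(self, p: Point2D) -> Point2D:
        dx, dy = self.direction
        t = dx * (p.x - self.anchor.x) + dy * (p.y - self.anchor.y)
        return Point2D(self.anchor.x + t * dx, self.anchor.y + t * dy)

    def parallel_at(self, offset: float) -> "Line2D":
        """The parallel line displaced ``offset`` mm along the canonical
        normal (positive offsets move proximally for cut-like lines)."""
        nx, ny = self.normal
        return Line2D(
            Point2D(self.anchor.x + offset * nx, self.anchor.y + offset * ny),
            self.direction,
        )

    def angle_to(self, other: "Line2D") -> float:
        """Acute angle between the two lines, in degrees."""
        d1, d2 = self.direction, other.direction
        c = abs(d1[0] * d2[0] + d1[1] * d2[1])
        return math.degrees(math.acos(min(1.0, c)))


@dataclass(frozen=True)
class Circle:
    center: Point2D
    radius: float

    def __post_init__(self):
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise ParameterError(f"circle radius must be positive, got {self.radius}")


class PolyContour:
    """A bone outline as an ordered polyline, optionally closed.

    Closed contours must be simple polygons with positive area; this is
    enforced eagerly because every downstream construction assumes it.
    """

    def __init__(self, vertices: Sequence[Point2D], closed: bool = True):
        self.vertices: tuple[Point2D, ...] = tuple(
            v if isinstance(v, Point2D) else Point2D(*v) for v in vertices
        )
        self.closed = bool(closed)
        if self.closed:
            if len(self.vertices) < 3:
                raise ContourError("closed contour needs at least 3 vertices")
            poly = _ShapelyPolygon([(v.x, v.y) for v in self.vertices])
            if not poly.is_valid:
                raise ContourError("contour is self-intersecting or degenerate")
            if poly.area <= 0:
                raise ContourError("contour encloses no area")
            self._polygon = poly

    @property
    def polygon(self) -> _ShapelyPolygon:
        if not self.closed:
            raise ContourError("operation requires a closed contour")
        return self._polygon

    def as_array(self) -> np.ndarray:
        return np.array([[v.x, v.y] for v in self.vertices], dtype=float)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        a = self.as_array()
        return a[:, 0].min(), a[:, 1].min(), a[:, 0].max(), a[:, 1].max()

    def transformed(self, fn) -> "PolyContour":
        return PolyContour([fn(v) for v in self.vertices], closed=self.closed)


@dataclass(frozen=True)
class Marker:
    """Calibration marker: its measured extent in annotation units and its
    true physical extent in millimetres."""

    measured_units: float
    true_mm: float


@dataclass
class AnnotatedView:
    """One radiograph's coordinate annotation.

    ``osteophyte_points`` maps the checkpoint names F1/F2/T2/T1 to points;
    ``implant_rectangles`` maps rectangle names (``joint_space``,
    ``posterior_condyle``) to 4-tuples of corner points on post-operative
    films.
    """

    view: Literal["AP", "lateral"]
    phase: Literal["preop", "postop"]
    laterality: Literal["left", "right"]
    femur_contour: PolyContour | None = None
    tibia_contour: PolyContour | None = None
    osteophyte_points: Mapping[str, Point2D] | None = None
    implant_rectangles: Mapping[str, tuple[Point2D, ...]] | None = None
    marker: Marker | None = None
    calibrated: bool = False
    mirrored: bool = False

    def validate(self) -> None:
        problems: list[str] = []
        if self.view not in ("AP", "lateral"):
            problems.append(f"view must be AP or lateral, got {self.view!r}")
        if self.phase not in ("preop", "postop"):
            problems.append(f"phase must be preop or postop, got {self.phase!r}")
        if self.laterality not in ("left", "right"):
            problems.append(f"laterality must be left or right, got {self.laterality!r}")
        if self.phase == "preop" and self.view == "AP":
            if self.femur_contour is None:
                problems.append("preop AP view requires femur_contour")
            if self.tibia_contour is None:
                problems.append("preop AP view requires tibia_contour")
        if self.phase == "postop" and not self.implant_rectangles:
            problems.append("postop view requires implant_rectangles")
        if self.osteophyte_points is not None:
            missing = [n for n in OSTEOPHYTE_POINT_NAMES if n not in self.osteophyte_points]
            if missing:
                problems.append(f"osteophyte_points missing {missing}")
        if problems:
            raise AnnotationError("; ".join(problems))


@dataclass(frozen=True)
class OsteophyteTrapezoid:
    """The osteophyte quadrilateral F1-F2-T2-T1 and its border lengths.

    Border naming: ``w`` is the inner rim F1-T1 along the cortex, ``y`` the
    outer rim F2-T2 between the osteophyte tips, ``x`` the femoral side
    F1-F2 and ``z`` the tibial side T1-T2.
    """

    F1: Point2D
    F2: Point2D
    T2: Point2D
    T1: Point2D
    x_len: float
    y_len: float
    z_len: float
    w_len: float
    area: float


@dataclass
class CutPlan:
    """Constructed reference and cut lines with their measured thicknesses."""

    f_axis: Line2D
    f_ref: Line2D
    f_cut: Line2D
    f_contact: Point2D
    f_contact_side: Side
    t_axis: Line2D
    t_cut: Line2D
    t_m: Point2D
    t_l: Point2D
    femoral_cut: float
    tibial_cut: float
    aldfa_deg: float = DEFAULT_ALDFA_DEG
    femoral_offset_mm: float = DEFAULT_FEMORAL_OFFSET_MM
    tibial_offset_mm: float = DEFAULT_TIBIAL_OFFSET_MM


@dataclass
class PostopMeasures:
    """Joint-gap and posterior-condyle measurements from a post-op film."""

    joint_gap: float | None
    post_condyle: float | None
    femoral_cut_line: Line2D | None
    tibial_cut_line: Line2D | None


# ---------------------------------------------------------------------------
# maximum inscribed circle and axis fitting
# ---------------------------------------------------------------------------


def max_inscribed_circle(
    contour: PolyContour,
    window: tuple[float, float],
    tol: float = 0.01,
) -> Circle:
    """Largest circle inside ``contour`` whose centre lies in the axial window.

    ``window`` is a (lo, hi) interval along the bone axis (canonical y).
    The circle itself may extend beyond the window; only its centre is
    constrained.  The centre is found by maximising the distance to the
    contour boundary, seeded by a coarse grid and polished with a
    Nelder-Mead search to within ``tol`` mm on the radius.
    """
    poly = contour.polygon  # raises on open contour
    lo, hi = window
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
        raise ParameterError(f"invalid window {window}")
    minx, miny, maxx, maxy = poly.bounds
    strip = shapely.box(minx - 1.0, lo, maxx + 1.0, hi)
    region = poly.intersection(strip)
    if region.is_empty or region.area < 1e-9:
        raise GeometryError("window does not intersect the contour interior")

    boundary = poly.exterior

    def _grid_candidates(x0, y0, x1, y1, step, top=6):
        xs = np.arange(x0, x1 + step / 2, step)
        ys = np.arange(y0, y1 + step / 2, step)
        gx, gy = np.meshgrid(xs, ys)
        gx, gy = gx.ravel(), gy.ravel()
        inside = shapely.contains_xy(region, gx, gy)
        if not inside.any():
            return []
        gx, gy = gx[inside], gy[inside]
        d = shapely.distance(boundary, shapely.points(gx, gy))
        order = np.argsort(d)[::-1][:top]
        return [(np.array([gx[i], gy[i]]), float(d[i])) for i in order]

    rx0, ry0, rx1, ry1 = region.bounds
    span = max(rx1 - rx0, ry1 - ry0)
    # the boundary-distance landscape can have several local maxima, so
    # polish the best few grid seeds rather than a single one
    candidates = _grid_candidates(rx0, ry0, rx1, ry1, max(span / 60.0, tol))
    if not candidates:
        rep = region.representative_point()
        r0 = boundary.distance(rep)
        if r0 <= 0:
            raise GeometryError("window restricts the contour to a sliver")
        candidates = [(np.array([rep.x, rep.y]), r0)]

    def neg_radius(p: np.ndarray) -> float:
        pt = _ShapelyPoint(p[0], p[1])
        if not region.covers(pt):
            return 1e6
        return -boundary.distance(pt)

    best_pt, best_r = candidates[0]
    for seed_pt, seed_r in candidates:
        res = minimize(
            neg_radius,
            seed_pt,
            method="Nelder-Mead",
            options={"xatol": tol / 10.0, "fatol": tol / 10.0, "maxiter": 400},
        )
        if -res.fun > best_r:
            best_pt, best_r = res.x, -res.fun
    if best_r <= 0:
        raise GeometryError("no inscribed circle found inside the window")
    return Circle(Point2D(float(best_pt[0]), float(best_pt[1])), float(best_r))


def fit_femoral_axis(
    contour: PolyContour,
    diaphysis_window: tuple[float, float],
    metaphysis_window: tuple[float, float],
) -> Line2D:
    """Anatomic femoral axis through the centres of two shaft incircles.

    This simulates the intramedullary rod of the distal cutting jig.  The
    two axial windows must be disjoint, and the resulting incircle centres
    at least 1 mm apart.
    """
    (a0, a1), (b0, b1) = diaphysis_window, metaphysis_window
    if min(a1, b1) > max(a0, b0):
        raise ParameterError("diaphysis and metaphysis windows overlap")
    c1 = max_inscribed_circle(contour, diaphysis_window)
    c2 = max_inscribed_circle(contour, metaphysis_window)
    if c1.center.distance_to(c2.center) < 1.0:
        raise GeometryError("incircle centers closer than 1 mm; axis degenerate")
    return Line2D.from_points(c2.center, c1.center)


def fit_tibial_axis(
    contour: PolyContour,
    window_fractions: tuple[tuple[float, float], tuple[float, float]] = (
        (0.25, 0.40),
        (0.60, 0.75),
    ),
) -> Line2D:
    """Anatomic tibial axis by the same two-incircle construction.

    The windows are placed at fixed fractions of the bone's axial extent,
    measured from the distal end, defaulting to 25-40 % and 60-75 % so both
    fall on the shaft for ordinary proximal-tibia outlines.
    """
    _, ymin, _, ymax = contour.bounds
    h = ymax - ymin
    (f0, f1), (f2, f3) = window_fractions
    w_distal = (ymin + f0 * h, ymin + f1 * h)
    w_proximal = (ymin + f2 * h, ymin + f3 * h)
    return fit_femoral_axis(contour, w_proximal, w_distal)


# ---------------------------------------------------------------------------
# femoral reference / cut construction
# ---------------------------------------------------------------------------


def _rotate(vx: float, vy: float, deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return vx * c - vy * s, vx * s + vy * c


def _medial_normal(axis: Line2D) -> tuple[float, float]:
    """Unit vector perpendicular to the axis pointing medially (+x side)."""
    dx, dy = axis.direction  # proximal by normalisation
    return dy, -dx


def build_femoral_reference(
    f_axis: Line2D,
    femur_contour: PolyContour,
    aldfa_deg: float = DEFAULT_ALDFA_DEG,
    tie_tol: float = 0.1,
) -> tuple[Line2D, Point2D, Side]:
    """Distal cut reference line at the aLDFA to the femoral axis.

    The line is oriented ``aldfa_deg`` from the proximal axis direction,
    opening on the lateral side (for a vertical axis and the default 85°
    it rises 5° above horizontal toward the lateral side), then swept from
    distal to proximal until it first touches the distal condylar margin.
    Returns the line, the contact point, and which condyle made contact.
    When both condyles reach the line within ``tie_tol`` mm, the medial
    contact is chosen.
    """
    poly = femur_contour.polygon
    ax, ay = f_axis.direction
    # rotate the proximal axis direction by +aLDFA (counter-clockwise moves
    # the proximal direction toward the lateral, -x, side in the canonical
    # right-knee frame)
    drx, dry = _rotate(ax, ay, aldfa_deg)
    ref_dir = (drx, dry)

    # sweep normal: perpendicular to the reference, pointing proximally
    nx, ny = -dry, drx
    if ny < 0 or (ny == 0 and nx < 0):
        nx, ny = -nx, -ny

    # verify the axis passes through the bone at all
    _, ymin, _, ymax = femur_contour.bounds
    span = (ymax - ymin) + poly.length
    a = f_axis.anchor
    probe = shapely.linestrings(
        [
            [a.x - span * ax, a.y - span * ay],
            [a.x + span * ax, a.y + span * ay],
        ]
    )
    if not poly.intersects(probe):
        raise GeometryError("femoral axis does not intersect the contour")

    verts = femur_contour.as_array()
    sweep = verts @ np.array([nx, ny])
    mnx, mny = _medial_normal(f_axis)
    side_val = (verts - a.as_array()) @ np.array([mnx, mny])

    medial = side_val >= 0
    lateral = ~medial
    best: dict[Side, tuple[float, int]] = {}
    for name, mask in (("medial", medial), ("lateral", lateral)):
        if mask.any():
            idx = np.flatnonzero(mask)
            j = idx[np.argmin(sweep[idx])]
            best[name] = (float(sweep[j]), int(j))
    if not best:
        raise GeometryError("no condylar margin found distal to the axis")

    if "medial" in best and (
        "lateral" not in best or best["medial"][0] <= best["lateral"][0] + tie_tol
    ):
        side: Side = "medial"
    else:
        side = "lateral"
    contact = femur_contour.vertices[best[side][1]]
    return Line2D(contact, ref_dir), contact, side


def build_femoral_cut(
    f_ref: Line2D, offset_mm: float = DEFAULT_FEMORAL_OFFSET_MM
) -> Line2D:
    """Initial distal femoral cut line: parallel to the reference,
    ``offset_mm`` proximal to it (simulating the distal resection
    thickness)."""
    if not (offset_mm > 0 and math.isfinite(offset_mm)):
        raise ParameterError(f"femoral offset must be positive, got {offset_mm}")
    return f_ref.parallel_at(offset_mm)


def lateral_angle_deg(f_ref: Line2D, f_axis: Line2D) -> float:
    """Angle between reference line and femoral axis on the lateral side.

    Measured between the proximal axis direction and the lateral-pointing
    direction of the reference line; this is the aLDFA of the construction.
    """
    ax, ay = f_axis.direction
    rx, ry = f_ref.direction
    if rx > 0:
        rx, ry = -rx, -ry  # point the reference direction laterally (-x)
    c = ax * rx + ay * ry
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# tibial checkpoints and cut
# ---------------------------------------------------------------------------


def _upper_envelope_v(u_edges: np.ndarray, v_edges: np.ndarray, u: float) -> float:
    """Max v of the contour boundary at perpendicular position ``u``.

    ``u_edges``/``v_edges`` are closed vertex loops in the axis-aligned
    (u = across, v = along axis) frame.
    """
    best = -math.inf
    n = len(u_edges)
    for i in range(n):
        u0, u1 = u_edges[i], u_edges[(i + 1) % n]
        v0, v1 = v_edges[i], v_edges[(i + 1) % n]
        if u0 == u1:
            if u0 == u:
                best = max(best, v0, v1)
            continue
        t = (u - u0) / (u1 - u0)
        if 0.0 <= t <= 1.0:
            best = max(best, v0 + t * (v1 - v0))
    if not math.isfinite(best):
        raise GeometryError(f"no plateau surface at position u={u:.3f}")
    return best


def tibial_checkpoints(
    t_axis: Line2D,
    tibia_contour: PolyContour,
    lateral_fraction: float = DEFAULT_TIBIAL_LATERAL_FRACTION,
) -> tuple[Point2D, Point2D]:
    """Plateau checkpoints T_M and T_L.

    Working in the axis-aligned frame (u across the plateau, positive
    medial; v along the axis), the plateau surface is the upper envelope of
    the contour.  T_M is the lowest (most distal) surface vertex on the
    medial half; T_L is the surface point at ``lateral_fraction`` (default
    3/8) of the total plateau width from the lateral edge.
    """
    if not 0.0 < lateral_fraction < 1.0:
        raise ParameterError(f"lateral fraction must be in (0,1), got {lateral_fraction}")
    d = np.array(t_axis.direction)
    m = np.array(_medial_normal(t_axis))
    rel = tibia_contour.as_array() - t_axis.anchor.as_array()
    u = rel @ m
    v = rel @ d
    u_min, u_max = float(u.min()), float(u.max())
    width = u_max - u_min
    if width < 1.0:
        raise GeometryError(f"tibial plateau narrower than 1 mm ({width:.3f} mm)")

    u_star = u_min + lateral_fraction * width
    v_star = _upper_envelope_v(u, v, u_star)
    a = t_axis.anchor.as_array()
    tl_xy = a + u_star * m + v_star * d
    t_l = Point2D(float(tl_xy[0]), float(tl_xy[1]))

    # medial-half vertices lying on the upper envelope
    u_mid = 0.5 * (u_min + u_max)
    best_idx, best_v = None, math.inf
    for i in range(len(u)):
        if u[i] < u_mid:
            continue
        if v[i] >= _upper_envelope_v(u, v, float(u[i])) - 1e-6 and v[i] < best_v:
            best_idx, best_v = i, float(v[i])
    if best_idx is None:
        raise GeometryError("no medial plateau surface vertex found")
    t_m = tibia_contour.vertices[best_idx]
    return t_m, t_l


def build_tibial_cut(
    t_axis: Line2D,
    t_l: Point2D,
    offset_mm: float = DEFAULT_TIBIAL_OFFSET_MM,
) -> Line2D:
    """Initial proximal tibial cut: perpendicular to the anatomic axis, at a
    perpendicular distance ``offset_mm`` distal to the checkpoint T_L."""
    if not (offset_mm > 0 and math.isfinite(offset_mm)):
        raise ParameterError(f"tibial offset must be positive, got {offset_mm}")
    dx, dy = t_axis.direction  # proximal
    anchor = Point2D(t_l.x - offset_mm * dx, t_l.y - offset_mm * dy)
    return Line2D(anchor, (dy, -dx))


def cut_thickness(checkpoint: Point2D, cut_line: Line2D) -> float:
    """Resection thickness: unsigned perpendicular distance from a condylar
    checkpoint to the cut line."""
    return cut_line.distance_to(checkpoint)


# ---------------------------------------------------------------------------
# osteophyte trapezoid
# ---------------------------------------------------------------------------


def _shoelace_area(pts: Sequence[Point2D]) -> float:
    s = 0.0
    n = len(pts)
    for i in range(n):
        p, q = pts[i], pts[(i + 1) % n]
        s += p.x * q.y - q.x * p.y
    return abs(s) / 2.0


def osteophyte_trapezoid(
    F1: Point2D, F2: Point2D, T2: Point2D, T1: Point2D
) -> OsteophyteTrapezoid:
    """Build the osteophyte quadrilateral from its four checkpoints.

    Borders: x = |F1F2| (femoral osteophyte side), y = |F2T2| (outer rim,
    tip to tip), z = |T1T2| (tibial osteophyte side), w = |F1T1| (inner rim
    along the cortex).  The area is the shoelace area of the F1-F2-T2-T1
    cycle; a self-intersecting cycle is re-ordered to its simple polygon
    with a warning.
    """
    pts = {"F1": F1, "F2": F2, "T2": T2, "T1": T1}
    names = list(pts)
    for i in range(4):
        for j in range(i + 1, 4):
            a, b = pts[names[i]], pts[names[j]]
            if a.distance_to(b) < 1e-9:
                raise GeometryError(
                    f"degenerate trapezoid: {names[i]} and {names[j]} coincide"
                )
    cycle = [F1, F2, T2, T1]
    ring = _ShapelyPolygon([(p.x, p.y) for p in cycle])
    if ring.is_valid and ring.area > 0:
        area = _shoelace_area(cycle)
    else:
        warnings.warn(
            "osteophyte checkpoint cycle F1-F2-T2-T1 self-intersects; "
            "using the simple re-ordering for the area",
            stacklevel=2,
        )
        cx = sum(p.x for p in cycle) / 4.0
        cy = sum(p.y for p in cycle) / 4.0
        ordered = sorted(cycle, key=lambda p: math.atan2(p.y - cy, p.x - cx))
        area = _shoelace_area(ordered)
    return OsteophyteTrapezoid(
        F1=F1,
        F2=F2,
        T2=T2,
        T1=T1,
        x_len=F1.distance_to(F2),
        y_len=F2.distance_to(T2),
        z_len=T1.distance_to(T2),
        w_len=F1.distance_to(T1),
        area=area,
    )


def release_gap_from_borders(
    x_len: float, y_len: float, z_len: float, w_len: float, mode: str = "path"
) -> float:
    """Gap gained by osteophyte removal, from the four border lengths.

    ``mode='path'`` (default): the outer rim is the three-segment path over
    the osteophyte tips, so the gain is (x + y + z) - w, which is >= 0 by
    the triangle inequality.  ``mode='tip'`` uses only the tip-to-tip
    border: y - w (may be negative; exposed because the outer/inner-rim
    wording admits this reading).
    """
    if mode == "path":
        return x_len + y_len + z_len - w_len
    if mode == "tip":
        return y_len - w_len
    raise ParameterError(f"unknown release-gap mode {mode!r}")


def release_gap(trap: OsteophyteTrapezoid, mode: str = "path") -> float:
    """Gap gained by removing the osteophytes summarised by ``trap``."""
    return release_gap_from_borders(trap.x_len, trap.y_len, trap.z_len, trap.w_len, mode)


# ---------------------------------------------------------------------------
# post-operative measurements
# ---------------------------------------------------------------------------


def _rectangle_measures(
    corners: Sequence[Point2D], parallel_tol_deg: float = 2.0
) -> tuple[float, Line2D, Line2D]:
    """Shorter-border mean and the two longer borders of a near-rectangle.

    By annotation convention the first listed edge is a longer border; if
    the corners arrive rotated (shorter edge first) the orientation is
    auto-corrected with a warning.
    """
    if len(corners) != 4:
        raise AnnotationError(f"rectangle needs 4 corners, got {len(corners)}")
    p = list(corners)
    lengths = [p[i].distance_to(p[(i + 1) % 4]) for i in range(4)]
    pair_a = (lengths[0] + lengths[2]) / 2.0  # edges 0-1 and 2-3
    pair_b = (lengths[1] + lengths[3]) / 2.0  # edges 1-2 and 3-0
    if pair_a >= pair_b:
        long_edges = [(p[0], p[1]), (p[2], p[3])]
        short_mean = pair_b
    else:
        warnings.warn(
            "rectangle annotated with the shorter border first; orientation "
            "auto-corrected",
            stacklevel=3,
        )
        long_edges = [(p[1], p[2]), (p[3], p[0])]
        short_mean = pair_a
    l1 = Line2D.from_points(*long_edges[0])
    l2 = Line2D.from_points(*long_edges[1])
    if l1.angle_to(l2) > parallel_tol_deg:
        raise AnnotationError(
            f"longer borders deviate from parallel by more than "
            f"{parallel_tol_deg}° ({l1.angle_to(l2):.2f}°)"
        )
    # order the longer borders proximal (femoral) first
    if l1.anchor.y < l2.anchor.y:
        l1, l2 = l2, l1
    return short_mean, l1, l2


def postop_measures(view: AnnotatedView) -> PostopMeasures:
    """Joint-gap and posterior-condyle thickness from a post-op annotation.

    The joint gap is the mean of the two shorter borders of the joint-space
    rectangle (longer borders are the femoral and tibial cut lines).  The
    posterior condylar thickness is a lateral-view element; asking for it
    on an AP film is an annotation error.
    """
    if view.phase != "postop":
        raise AnnotationError("postop_measures requires a postop view")
    rects = view.implant_rectangles or {}
    if view.view == "AP" and "posterior_condyle" in rects:
        raise AnnotationError(
            "posterior condyle is a lateral-view element; found on AP film"
        )

    joint_gap = None
    fem_line = tib_line = None
    if "joint_space" in rects:
        joint_gap, fem_line, tib_line = _rectangle_measures(rects["joint_space"])
        if joint_gap <= 0:
            raise AnnotationError("joint-space rectangle has zero shorter border")
    elif view.view == "AP":
        raise AnnotationError("postop AP view is missing the joint_space rectangle")

    post_condyle = None
    if view.view == "lateral":
        if "posterior_condyle" not in rects:
            raise AnnotationError(
                "postop lateral view is missing the posterior_condyle rectangle"
            )
        post_condyle, _, _ = _rectangle_measures(rects["posterior_condyle"])
        if post_condyle <= 0:
            raise AnnotationError("posterior condylar rectangle has zero shorter border")

    return PostopMeasures(
        joint_gap=joint_gap,
        post_condyle=post_condyle,
        femoral_cut_line=fem_line,
        tibial_cut_line=tib_line,
    )


# ---------------------------------------------------------------------------
# full plan assembly
# ---------------------------------------------------------------------------


def _default_femur_windows(contour: PolyContour) -> tuple[tuple[float, float], tuple[float, float]]:
    """Diaphysis and metaphysis windows at fixed fractions of the visible
    femoral extent (65-85 % and 35-50 % from the distal end)."""
    _, ymin, _, ymax = contour.bounds
    h = ymax - ymin
    return (ymin + 0.65 * h, ymin + 0.85 * h), (ymin + 0.35 * h, ymin + 0.50 * h)


def build_cut_plan(
    view: AnnotatedView,
    aldfa_deg: float = DEFAULT_ALDFA_DEG,
    femoral_offset_mm: float = DEFAULT_FEMORAL_OFFSET_MM,
    tibial_offset_mm: float = DEFAULT_TIBIAL_OFFSET_MM,
    tibial_lateral_fraction: float = DEFAULT_TIBIAL_LATERAL_FRACTION,
    femur_windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> CutPlan:
    """Run the full pre-operative construction on an AP annotation.

    Axis fitting -> distal femoral reference at the aLDFA -> initial cut
    lines at the configured resection offsets -> cut thicknesses measured
    from the contact checkpoints.  Freshly built plans therefore report
    femoral_cut == femoral_offset_mm and tibial_cut == tibial_offset_mm
    until an overlay adjustment replaces a cut line.
    """
    view.validate()
    if view.phase != "preop" or view.view != "AP":
        raise AnnotationError("cut plan construction requires a preop AP view")
    femur, tibia = view.femur_contour, view.tibia_contour
    if femur_windows is None:
        femur_windows = _default_femur_windows(femur)
    f_axis = fit_femoral_axis(femur, femur_windows[0], femur_windows[1])
    f_ref, contact, side = build_femoral_reference(f_axis, femur, aldfa_deg)
    f_cut = build_femoral_cut(f_ref, femoral_offset_mm)
    t_axis = fit_tibial_axis(tibia)
    t_m, t_l = tibial_checkpoints(t_axis, tibia, tibial_lateral_fraction)
    t_cut = build_tibial_cut(t_axis, t_l, tibial_offset_mm)
    return CutPlan(
        f_axis=f_axis,
        f_ref=f_ref,
        f_cut=f_cut,
        f_contact=contact,
        f_contact_side=side,
        t_axis=t_axis,
        t_cut=t_cut,
        t_m=t_m,
        t_l=t_l,
        femoral_cut=cut_thickness(contact, f_cut),
        tibial_cut=cut_thickness(t_l, t_cut),
        aldfa_deg=aldfa_deg,
        femoral_offset_mm=femoral_offset_mm,
        tibial_offset_mm=tibial_offset_mm,
    )


# ---------------------------------------------------------------------------
# view transforms
# ---------------------------------------------------------------------------


def _transform_point_map(points, fn):
    if points is None:
        return None
    return {k: fn(v) for k, v in points.items()}


def _transform_rect_map(rects, fn):
    if rects is None:
        return None
    return {k: tuple(fn(p) for p in corners) for k, corners in rects.items()}


def _transformed_view(view: AnnotatedView, fn, **changes) -> AnnotatedView:
    return replace(
        view,
        femur_contour=view.femur_contour.transformed(fn) if view.femur_contour else None,
        tibia_contour=view.tibia_contour.transformed(fn) if view.tibia_contour else None,
        osteophyte_points=_transform_point_map(view.osteophyte_points, fn),
        implant_rectangles=_transform_rect_map(view.implant_rectangles, fn),
        **changes,
    )


def mirror_view(view: AnnotatedView) -> AnnotatedView:
    """Mirror about the y axis (left knee -> canonical right-knee frame)."""
    return _transformed_view(
        view, lambda p: Point2D(-p.x, p.y), mirrored=not view.mirrored
    )


def rigid_transform_view(
    view: AnnotatedView, rotation_deg: float = 0.0, tx: float = 0.0, ty: float = 0.0
) -> AnnotatedView:
    """Rotate (about the origin) and translate every coordinate; used to
    exercise the rigid-motion invariance of all measurements."""
    a = math.radians(rotation_deg)
    c, s = math.cos(a), math.sin(a)

    def fn(p: Point2D) -> Point2D:
        return Point2D(c * p.x - s * p.y + tx, s * p.x + c * p.y + ty)

    return _transformed_view(view, fn)
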