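import numpy as np
import pytest
import shapely
from hypothesis import HealthCheck, settings

from kneegap.calibration import apply_scale, scale_from_marker
from kneegap.geometry import Point2D, PolyContour
from kneegap.simulate import KneeSimConfig, simulate_knee

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def grid_incircle_oracle(contour: PolyContour, window, step=0.05):
    """Brute-force maximum-inscribed-circle: scan a regular grid of interior
    points restricted to the axial window and maximise the distance to the
    contour boundary.  Independent of the optimisation in the package."""
    poly = contour.polygon
    lo, hi = window
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx + step / 2, step)
    ys = np.arange(max(miny, lo), min(maxy, hi) + step / 2, step)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    inside = shapely.contains_xy(poly, gx, gy)
    gx, gy = gx[inside], gy[inside]
    d = shapely.distance(poly.exterior, shapely.points(gx, gy))
    i = int(np.argmax(d))
    return (gx[i], gy[i]), float(d[i])


def random_star_polygon(rng, n_vertices=12, mean_radius=12.0, spread=0.5):
    """Random simple (star-shaped) polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = mean_radius * rng.uniform(1 - spread, 1 + spread, n_vertices)
    pts = [Point2D(r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles)]
    return PolyContour(pts)


@pytest.fixture(scope="session")
def default_knee():
    """Calibrated default synthetic knee annotation plus its ground truth."""
    view, truth = simulate_knee(KneeSimConfig(seed=0))
    scale = scale_from_marker(view.marker.measured_units, view.marker.true_mm)
    return apply_scale(view, scale), truth


@pytest.fixture(scope="session")
def magnified_knee():
    """Synthetic knee at 1.15x magnification, not yet calibrated."""
    return simulate_knee(KneeSimConfig(seed=2, magnification=1.15))
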