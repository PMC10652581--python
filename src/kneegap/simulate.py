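"""Synthetic data generators.

Two generators make the whole pipeline testable without any patient data:

* :func:`simulate_measurements` draws tabular per-knee measurement records
  whose marginal means/SDs match the published training-cohort
  descriptives, whose osteophyte borders are mutually correlated, and
  whose joint gap follows the published linear equation plus Gaussian
  noise.  Because measurements are physical lengths, each marginal is a
  zero-truncated normal whose underlying parameters are moment-matched so
  the *truncated* distribution has exactly the configured mean and SD;
  the border correlation is imposed through a Gaussian copula so the
  matched marginals are preserved.

* :func:`simulate_knee` builds a parametric right-knee AP annotation
  (femur and tibia contours, osteophyte checkpoints, optional
  magnification marker) with analytically known ground truth, so every
  geometric operation can be checked against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import fsolve
from scipy.special import ndtr
from scipy.stats import truncnorm

from .errors import GenerationError, ParameterError
from .geometry import (
    AnnotatedView,
    Marker,
    Point2D,
    PolyContour,
    _transformed_view,
    mirror_view,
    rigid_transform_view,
)
from .prediction import DEFAULT_EQUATION, GapEquation

__all__ = [
    "TRAINING_MEANS",
    "TRAINING_SDS",
    "TabularSimConfig",
    "simulate_measurements",
    "KneeSimConfig",
    "simulate_knee",
    "split_train_test",
]

#: Training-cohort marginal means (mm) of the seven predictors.
TRAINING_MEANS: Mapping[str, float] = MappingProxyType(
    {
        "x": 5.632,
        "y": 10.034,
        "z": 5.419,
        "w": 16.518,
        "tibial_cut": 10.66,
        "femoral_cut": 7.174,
        "post_condyle": 8.6,
    }
)

#: Training-cohort marginal SDs (mm).
TRAINING_SDS: Mapping[str, float] = MappingProxyType(
    {
        "x": 2.81,
        "y": 5.66,
        "z": 3.92,
        "w": 8.08,
        "tibial_cut": 4.49,
        "femoral_cut": 3.3,
        "post_condyle": 3.88,
    }
)

_BORDERS = ("x", "y", "z", "w")
_CUTS = ("tibial_cut", "femoral_cut", "post_condyle")


# ---------------------------------------------------------------------------
# tabular simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TabularSimConfig:
    """Study conditions for the tabular measurement simulation.

    Defaults reproduce the training-cohort descriptives, a border
    correlation of 0.6 (the borders are reported as mutually correlated
    but no numeric value is printed), residual noise σ = 2.9 mm around the
    published equation, and the published coefficients themselves.
    """

    n: int
    seed: int
    means: Mapping[str, float] = field(default_factory=lambda: TRAINING_MEANS)
    sds: Mapping[str, float] = field(default_factory=lambda: TRAINING_SDS)
    border_rho: float = 0.6
    resid_sd: float = 2.9
    equation: GapEquation = DEFAULT_EQUATION

    def __post_init__(self):
        if self.n < 0:
            raise ParameterError(f"n must be >= 0, got {self.n}")
        if not -1.0 < self.border_rho < 1.0:
            raise ParameterError(f"|border_rho| must be < 1, got {self.border_rho}")
        if not self.resid_sd >= 0:
            raise ParameterError(f"resid_sd must be >= 0, got {self.resid_sd}")
        for name in (*_BORDERS, *_CUTS):
            if name not in self.means or name not in self.sds:
                raise ParameterError(f"means/sds must include {name!r}")
            if not self.sds[name] > 0:
                raise ParameterError(f"SD of {name!r} must be positive")


@lru_cache(maxsize=256)
def _matched_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose zero-truncated normal has the given
    mean and SD."""

    def eqs(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a = -mu / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = fsolve(eqs, [mean, math.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(math.exp(sol[1]))
    return mu, sigma


def _truncnorm_from_uniform(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    mu, sigma = _matched_truncnorm_params(mean, sd)
    a = -mu / sigma
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)


def simulate_measurements(cfg: TabularSimConfig) -> pd.DataFrame:
    """Draw ``cfg.n`` per-knee measurement records.

    Border lengths x, y, z, w share a latent equicorrelation
    ``cfg.border_rho``; the three cut predictors are independent.  The
    joint gap is the configured equation evaluated on the realised
    predictors plus N(0, resid_sd) noise.  Fully reproducible for a fixed
    seed.
    """
    columns = [*_BORDERS, *_CUTS, "joint_gap"]
    if cfg.n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns})
    rng = np.random.default_rng(cfg.seed)

    # latent correlated normals for the borders, via Cholesky
    R = np.full((4, 4), cfg.border_rho) + (1.0 - cfg.border_rho) * np.eye(4)
    L = np.linalg.cholesky(R)
    zb = rng.standard_normal((cfg.n, 4)) @ L.T
    zc = rng.standard_normal((cfg.n, 3))
    noise = rng.normal(0.0, cfg.resid_sd, cfg.n)

    data = {}
    for j, name in enumerate(_BORDERS):
        data[name] = _truncnorm_from_uniform(ndtr(zb[:, j]), cfg.means[name], cfg.sds[name])
    for j, name in enumerate(_CUTS):
        data[name] = _truncnorm_from_uniform(ndtr(zc[:, j]), cfg.means[name], cfg.sds[name])
    data["joint_gap"] = (
        np.asarray(
            cfg.equation.predict(
                data["y"], data["tibial_cut"], data["femoral_cut"], data["post_condyle"]
            )
        )
        + noise
    )
    return pd.DataFrame(data, columns=columns)


def split_train_test(records, seed: int, test_fraction: float = 0.1):
    """Random 9:1 train/test split (seeded, disjoint and exhaustive).

    The test size is round(n * test_fraction) with halves rounded up, so
    110 records split into 99 training and 11 test records.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    n = len(df)
    if n < 2:
        raise ParameterError(f"need at least 2 records to split, got {n}")
    n_test = int(math.floor(n * test_fraction + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])
    return df.iloc[train_idx].reset_index(drop=True), df.iloc[test_idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# parametric knee annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KneeSimConfig:
    """Parameters of the synthetic right-knee AP annotation (mm).

    The femoral axis is vertical before ``varus_tilt_deg`` rotates the
    femur about the joint centre; the tibia stays vertical.  A positive
    ``magnification`` scales every coordinate and sets the marker block
    accordingly, so calibration can be exercised end to end.
    """

    seed: int = 0
    femoral_shaft_width: float = 32.0
    femoral_length: float = 175.0
    condyle_radius: float = 19.0
    condyle_half_spacing: float = 19.0
    medial_condyle_drop: float = 1.5
    tibial_plateau_width: float = 78.0
    tibial_shaft_width: float = 32.0
    tibial_length: float = 160.0
    plateau_y: float = -10.0
    medial_dip_depth: float = 2.0
    varus_tilt_deg: float = 0.0
    osteophyte_protrusion: float = 5.0
    magnification: float = 1.0
    laterality: str = "right"
    with_marker: bool = True
    marker_true_mm: float = 25.0
    jitter: float = 0.0

    def __post_init__(self):
        for name in (
            "femoral_shaft_width",
            "femoral_length",
            "condyle_radius",
            "tibial_plateau_width",
            "tibial_shaft_width",
            "tibial_length",
            "osteophyte_protrusion",
            "magnification",
            "marker_true_mm",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if self.laterality not in ("left", "right"):
            raise ParameterError(f"laterality must be left or right, got {self.laterality}")


def _arc(cx, cy, r, deg0, deg1, n=13):
    degs = np.linspace(deg0, deg1, n)
    return [(cx + r * math.cos(math.radians(d)), cy + r * math.sin(math.radians(d))) for d in degs]


def _femur_vertices(cfg: KneeSimConfig) -> list[tuple[float, float]]:
    hw = cfg.femoral_shaft_width / 2.0
    r = cfg.condyle_radius
    cxm, cxl = cfg.condyle_half_spacing, -cfg.condyle_half_spacing
    # condyle circle centres: lateral bottom at y=0, medial lower by drop
    cym = r - cfg.medial_condyle_drop
    cyl = r
    flare_y, wall_top = 45.0, 32.0
    pts: list[tuple[float, float]] = []
    pts += [(-hw, cfg.femoral_length), (hw, cfg.femoral_length)]          # shaft top
    pts += [(hw, flare_y)]                                                 # medial shaft
    pts += [(cxm + r - 4.0, wall_top)]                                     # medial flare
    pts += [(cxm + r, cym + 6.0)]                                          # medial wall
    pts += _arc(cxm, cym, r, 0.0, -180.0, 25)                              # medial condyle
    pts += _arc(cxl, cyl, r, 0.0, -180.0, 25)                              # lateral condyle
    pts += [(cxl - r, cyl + 6.0)]                                          # lateral wall
    pts += [(cxl - r + 4.0, wall_top)]                                     # lateral flare
    pts += [(-hw, flare_y)]                                                # lateral shaft
    return pts


def _tibia_vertices(cfg: KneeSimConfig) -> list[tuple[float, float]]:
    hp = cfg.tibial_plateau_width / 2.0
    hs = cfg.tibial_shaft_width / 2.0
    top = cfg.plateau_y
    bottom = top - cfg.tibial_length
    dip_x, dip_y = 20.0, top - cfg.medial_dip_depth
    pts = [
        (-hp, top),              # lateral plateau edge
        (10.0, top),             # flat plateau surface
        (dip_x, dip_y),          # medial plateau low point (T_M truth)
        (28.0, top - 0.5),
        (hp, top - 0.5),         # medial plateau edge
        (hp, top - 14.0),        # medial metaphysis wall
        (hs, top - 26.0),        # taper to shaft
        (hs, bottom),
        (-hs, bottom),
        (-hs, top - 26.0),
        (-hp, top - 14.0),
    ]
    return pts


def simulate_knee(cfg: KneeSimConfig) -> tuple[AnnotatedView, dict]:
    """Build a pre-op AP annotation with analytically known ground truth.

    Returns the (possibly magnified, possibly left-mirrored) annotation
    together with a ground-truth dictionary in true canonical millimetres:
    axis directions, plateau checkpoints, trapezoid border lengths and the
    first-contact condyle side.
    """
    rng = np.random.default_rng(cfg.seed)

    for attempt in range(5):
        jit = cfg.jitter if attempt == 0 else cfg.jitter + 0.05 * attempt
        try:
            fem_pts = _femur_vertices(cfg)
            tib_pts = _tibia_vertices(cfg)
            if jit > 0:
                fem_pts = [
                    (px + rng.uniform(-jit, jit), py + rng.uniform(-jit, jit))
                    for px, py in fem_pts
                ]
                tib_pts = [
                    (px + rng.uniform(-jit, jit), py + rng.uniform(-jit, jit))
                    for px, py in tib_pts
                ]
            femur = PolyContour([Point2D(*p) for p in fem_pts])
            tibia = PolyContour([Point2D(*p) for p in tib_pts])
            break
        except Exception:
            if attempt == 4:
                raise GenerationError("could not generate a simple knee contour")
    # osteophyte checkpoints (medial marginal osteophytes); F-points move
    # with the femur under the varus tilt, T-points with the tibia
    hp = cfg.tibial_plateau_width / 2.0
    fx = cfg.condyle_half_spacing + cfg.condyle_radius  # medial femoral cortex
    p = cfg.osteophyte_protrusion
    F1 = Point2D(fx, 4.0)
    F2 = Point2D(fx + p, 0.0)
    T2 = Point2D(hp + 1.0 + p, cfg.plateau_y - 0.5)
    T1 = Point2D(hp + 1.0, cfg.plateau_y - 2.0)

    view = AnnotatedView(
        view="AP",
        phase="preop",
        laterality="right",
        femur_contour=femur,
        tibia_contour=tibia,
        osteophyte_points={"F1": F1, "F2": F2, "T2": T2, "T1": T1},
        marker=None,
        calibrated=True,
    )

    tilt = cfg.varus_tilt_deg
    if tilt != 0.0:
        # rotate only the femoral side about the joint centre
        tilted = rigid_transform_view(view, rotation_deg=tilt)
        view = replace(
            view,
            femur_contour=tilted.femur_contour,
            osteophyte_points={
                "F1": tilted.osteophyte_points["F1"],
                "F2": tilted.osteophyte_points["F2"],
                "T2": view.osteophyte_points["T2"],
                "T1": view.osteophyte_points["T1"],
            },
        )

    pts = view.osteophyte_points
    # the femoral axis is the vertical rotated by the varus tilt; the
    # first-contact condyle flips to medial only once the medial condyle
    # sits lower than the reference-line obliquity can compensate
    c, s = math.cos(math.radians(tilt)), math.sin(math.radians(tilt))
    drop_threshold = 2.0 * cfg.condyle_half_spacing * math.tan(math.radians(5.0))
    truth = {
        "f_axis_direction": (-s, c),
        "t_axis_direction": (0.0, 1.0),
        "t_axis_x": 0.0,
        "T_M": Point2D(20.0, cfg.plateau_y - cfg.medial_dip_depth),
        "T_L": Point2D(-hp + (3.0 / 8.0) * cfg.tibial_plateau_width, cfg.plateau_y),
        "plateau_width": cfg.tibial_plateau_width,
        "trapezoid": {
            "x_len": pts["F1"].distance_to(pts["F2"]),
            "y_len": pts["F2"].distance_to(pts["T2"]),
            "z_len": pts["T1"].distance_to(pts["T2"]),
            "w_len": pts["F1"].distance_to(pts["T1"]),
        },
        "f_contact_side": (
            "medial" if cfg.medial_condyle_drop > drop_threshold else "lateral"
        ),
        "magnification": cfg.magnification,
        "laterality": cfg.laterality,
    }

    if cfg.magnification != 1.0 or cfg.with_marker:
        mag = cfg.magnification

        def scale_pt(q: Point2D) -> Point2D:
            return Point2D(q.x * mag, q.y * mag)

        view = _transformed_view(view, scale_pt, calibrated=False)
        if cfg.with_marker:
            view = replace(
                view,
                marker=Marker(
                    measured_units=cfg.marker_true_mm * mag, true_mm=cfg.marker_true_mm
                ),
            )

    if cfg.laterality == "left":
        view = mirror_view(view)
        view = replace(view, laterality="left", mirrored=False)

    return view, truth
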