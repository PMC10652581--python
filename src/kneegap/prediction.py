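"""The joint-gap prediction equation and plan-report assembly.

The balanced post-operative joint gap S (mm) is modelled as a linear
function of four pre-operative quantities:

    S = 1.82 + 0.15*y + 0.552*tibial_cut + 0.953*femoral_cut
             + 0.197*post_condyle

where ``y`` is the tip-to-tip (outer rim) border of the osteophyte
trapezoid, ``tibial_cut`` and ``femoral_cut`` are the planned resection
thicknesses and ``post_condyle`` is the posterior condylar thickness of
the femoral implant.  These default coefficients are the published values
and can be overridden, e.g. after refitting on new data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import AnnotationError, ParameterError
from .geometry import (
    AnnotatedView,
    CutPlan,
    OsteophyteTrapezoid,
    build_cut_plan,
    osteophyte_trapezoid,
    release_gap,
)

__all__ = ["GapEquation", "DEFAULT_EQUATION", "evaluate_gap_equation", "PlanResult", "plan_report"]


@dataclass(frozen=True)
class GapEquation:
    """Linear predictor of the balanced joint gap (all terms in mm)."""

    intercept: float = 1.82
    coef_y: float = 0.15
    coef_tibial: float = 0.552
    coef_femoral: float = 0.953
    coef_post: float = 0.197

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise ParameterError(f"equation term {name} is not finite")

    def predict(self, y, tibial_cut, femoral_cut, post_condyle):
        """Vectorised evaluation (no input validation; see
        :func:`evaluate_gap_equation` for the checked scalar form)."""
        return (
            self.intercept
            + self.coef_y * np.asarray(y)
            + self.coef_tibial * np.asarray(tibial_cut)
            + self.coef_femoral * np.asarray(femoral_cut)
            + self.coef_post * np.asarray(post_condyle)
        )


DEFAULT_EQUATION = GapEquation()


def evaluate_gap_equation(
    y: float,
    tibial_cut: float,
    femoral_cut: float,
    post_condyle: float,
    equation: GapEquation = DEFAULT_EQUATION,
) -> float:
    """Predicted joint gap S in mm for one knee.

    Negative predictors are rejected rather than extrapolated: the model
    was fitted on physical (non-negative) measurements.
    """
    values = {
        "y": y,
        "tibial_cut": tibial_cut,
        "femoral_cut": femoral_cut,
        "post_condyle": post_condyle,
    }
    for name, v in values.items():
        if not math.isfinite(v):
            raise ParameterError(f"predictor {name} is not finite")
        if v < 0:
            raise ParameterError(f"predictor {name} must be non-negative, got {v}")
    return float(equation.predict(y, tibial_cut, femoral_cut, post_condyle))


@dataclass
class PlanResult:
    """Full pre-operative plan: cuts, osteophyte borders and predicted gap.

    Inputs are echoed (settings, trapezoid borders) so a report can be
    audited without re-running the geometry.
    """

    femoral_cut: float
    tibial_cut: float
    w_len: float
    x_len: float
    y_len: float
    z_len: float
    release_gap: float
    post_condyle: float
    predicted_gap: float
    cut_plan: CutPlan
    trapezoid: OsteophyteTrapezoid
    equation: GapEquation

    def as_dict(self) -> dict:
        """Flat numeric summary (mm), suitable for JSON reports."""
        return {
            "femoral_cut": self.femoral_cut,
            "tibial_cut": self.tibial_cut,
            "w": self.w_len,
            "x": self.x_len,
            "y": self.y_len,
            "z": self.z_len,
            "release_gap": self.release_gap,
            "post_condyle": self.post_condyle,
            "predicted_gap": self.predicted_gap,
        }

    def report_text(self) -> str:
        lines = ["Joint-gap plan report", "---------------------"]
        for key, val in self.as_dict().items():
            lines.append(f"{key:>14s}: {val:10.4f} mm")
        return "\n".join(lines)


def plan_report(
    preop: AnnotatedView,
    post_condyle_mm: float,
    aldfa_deg: float = 85.0,
    femoral_offset_mm: float = 9.0,
    tibial_offset_mm: float = 10.0,
    tibial_lateral_fraction: float = 3.0 / 8.0,
    equation: GapEquation = DEFAULT_EQUATION,
) -> PlanResult:
    """Run the full planning pipeline on a calibrated pre-op AP annotation.

    Axis fitting, reference/cut construction and cut thicknesses come from
    :func:`kneegap.geometry.build_cut_plan`; the osteophyte trapezoid from
    the annotated checkpoints; and the predicted gap from the (default or
    overridden) linear equation.  ``post_condyle_mm`` is the implant
    posterior-condylar thickness, a surgeon preset at planning time since
    it can only be measured post-operatively.

    Deterministic: the same annotation and settings always give the same
    report.
    """
    if preop.marker is not None and not preop.calibrated:
        raise AnnotationError(
            "annotation carries a calibration marker but has not been "
            "calibrated; apply the marker scale first"
        )
    if not preop.osteophyte_points:
        raise AnnotationError(
            "osteophyte checkpoints F1/F2/T2/T1 are not annotated; the "
            "outer-rim border y is unavailable"
        )
    plan = build_cut_plan(
        preop,
        aldfa_deg=aldfa_deg,
        femoral_offset_mm=femoral_offset_mm,
        tibial_offset_mm=tibial_offset_mm,
        tibial_lateral_fraction=tibial_lateral_fraction,
    )
    pts = preop.osteophyte_points
    trap = osteophyte_trapezoid(pts["F1"], pts["F2"], pts["T2"], pts["T1"])
    gap = evaluate_gap_equation(
        trap.y_len, plan.tibial_cut, plan.femoral_cut, post_condyle_mm, equation
    )
    return PlanResult(
        femoral_cut=plan.femoral_cut,
        tibial_cut=plan.tibial_cut,
        w_len=trap.w_len,
        x_len=trap.x_len,
        y_len=trap.y_len,
        z_len=trap.z_len,
        release_gap=release_gap(trap),
        post_condyle=post_condyle_mm,
        predicted_gap=gap,
        cut_plan=plan,
        trapezoid=trap,
        equation=equation,
    )
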