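"""Magnification calibration and pre/post-operative cut-line overlay.

Plain films magnify the bone by an unknown factor; a marker of known
physical size placed at bone level during the exposure lets every
annotation be rescaled to true millimetres, so measurements from different
films share a unified magnification.  Once both films are calibrated, the
post-operative cut lines can be overlaid on the pre-operative plan and the
resection thicknesses recomputed from the original checkpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np

from .errors import CalibrationError, ParameterError, RegistrationError
from .geometry import (
    AnnotatedView,
    CutPlan,
    Point2D,
    PostopMeasures,
    _transformed_view,
    cut_thickness,
)

__all__ = [
    "CalibrationScale",
    "scale_from_marker",
    "apply_scale",
    "overlay_adjust_cut",
]


@dataclass(frozen=True)
class CalibrationScale:
    """Millimetres of true anatomy per annotation unit."""

    mm_per_unit: float
    source: Literal["marker", "unity"] = "marker"

    def __post_init__(self):
        if not (self.mm_per_unit > 0 and math.isfinite(self.mm_per_unit)):
            raise ParameterError(
                f"mm_per_unit must be positive and finite, got {self.mm_per_unit}"
            )


def scale_from_marker(measured_extent: float, true_extent_mm: float) -> CalibrationScale:
    """Scale factor from a calibration marker of known physical size."""
    if not (measured_extent > 0 and math.isfinite(measured_extent)):
        raise ParameterError(f"measured extent must be positive, got {measured_extent}")
    if not (true_extent_mm > 0 and math.isfinite(true_extent_mm)):
        raise ParameterError(f"true extent must be positive, got {true_extent_mm}")
    return CalibrationScale(true_extent_mm / measured_extent, source="marker")


def apply_scale(view_or_lengths, scale: CalibrationScale):
    """Rescale an annotation (or bare lengths) to true millimetres.

    Applied to an :class:`AnnotatedView`, every coordinate is multiplied by
    ``scale.mm_per_unit`` and the view is marked calibrated; calibrating a
    view twice is an error, because the operation would silently compound.
    Applied to a scalar or sequence of lengths, the values are simply
    multiplied.
    """
    s = scale.mm_per_unit
    if isinstance(view_or_lengths, AnnotatedView):
        view = view_or_lengths
        if view.calibrated:
            raise CalibrationError("view is already calibrated")
        out = _transformed_view(
            view, lambda p: Point2D(p.x * s, p.y * s), calibrated=True
        )
        return out
    if isinstance(view_or_lengths, (int, float)):
        return view_or_lengths * s
    if isinstance(view_or_lengths, np.ndarray):
        return view_or_lengths * s
    if isinstance(view_or_lengths, Iterable):
        return type(view_or_lengths)(x * s for x in view_or_lengths)
    raise ParameterError(
        f"cannot apply a calibration scale to {type(view_or_lengths).__name__}"
    )


def overlay_adjust_cut(
    preop_plan: CutPlan,
    postop: PostopMeasures,
    max_angle_deg: float = 15.0,
) -> CutPlan:
    """Replace planned cut lines by the actual post-operative ones.

    Both films must already be calibrated to the unified magnification, so
    the overlaid post-operative line can be adopted directly (orientation
    and along-axis position); the femoral and tibial resection thicknesses
    are then recomputed from the original contact checkpoints.  Lines more
    than ``max_angle_deg`` from parallel indicate an annotation blunder and
    raise instead of silently registering.

    The operation is idempotent: adjusting again with the same post-op
    lines changes nothing.
    """
    plan = preop_plan
    changes = {}
    if postop.femoral_cut_line is not None:
        angle = plan.f_cut.angle_to(postop.femoral_cut_line)
        if angle > max_angle_deg:
            raise RegistrationError(
                f"femoral cut lines {angle:.1f}° apart exceed the "
                f"{max_angle_deg}° registration gate"
            )
        changes["f_cut"] = postop.femoral_cut_line
        changes["femoral_cut"] = cut_thickness(plan.f_contact, postop.femoral_cut_line)
    if postop.tibial_cut_line is not None:
        angle = plan.t_cut.angle_to(postop.tibial_cut_line)
        if angle > max_angle_deg:
            raise RegistrationError(
                f"tibial cut lines {angle:.1f}° apart exceed the "
                f"{max_angle_deg}° registration gate"
            )
        changes["t_cut"] = postop.tibial_cut_line
        changes["tibial_cut"] = cut_thickness(plan.t_l, postop.tibial_cut_line)
    if not changes:
        return plan
    return replace(plan, **changes)
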