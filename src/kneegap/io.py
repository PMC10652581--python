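"""Readers and writers: landmark JSON (versioned schema) and measurement CSV.

Landmark schema (version 1)::

    {
      "schema_version": 1,
      "view": "AP" | "lateral",
      "phase": "preop" | "postop",
      "laterality": "left" | "right",
      "femur_contour": [[x, y], ...],          # optional per phase/view
      "tibia_contour": [[x, y], ...],
      "osteophyte_points": {"F1": [x, y], "F2": ..., "T2": ..., "T1": ...},
      "implant_rectangles": {"joint_space": [[x, y] * 4], ...},
      "marker": {"measured_units": float, "true_mm": float},
      "calibrated": bool
    }

Coordinates are serialised at full float precision so a write-then-read
round trip is exact; 4-decimal formatting is reserved for human-facing
report text.  Left-knee files are mirrored into the canonical right-knee
frame on load (with a log entry), so all downstream geometry can assume
canonical laterality.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParameterError, ValidationError
from .geometry import (
    OSTEOPHYTE_POINT_NAMES,
    AnnotatedView,
    Marker,
    Point2D,
    PolyContour,
    mirror_view,
)
from .prediction import GapEquation

logger = logging.getLogger("kneegap")

__all__ = [
    "RunConfig",
    "read_landmarks",
    "write_landmarks",
    "read_measurements",
    "write_measurements",
    "MEASUREMENT_COLUMNS",
]

SCHEMA_VERSION = 1

#: Canonical measurement CSV header.
MEASUREMENT_COLUMNS = (
    "x",
    "y",
    "z",
    "w",
    "tibial_cut",
    "femoral_cut",
    "post_condyle",
    "joint_gap",
)


@dataclass
class RunConfig:
    """Planning constants and equation coefficients, overridable from a
    JSON config file via the CLI ``--config`` option."""

    aldfa_deg: float = 85.0
    femoral_offset_mm: float = 9.0
    tibial_offset_mm: float = 10.0
    tibial_lateral_fraction: float = 3.0 / 8.0
    equation: GapEquation = field(default_factory=GapEquation)
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.femoral_offset_mm > 0 or not self.tibial_offset_mm > 0:
            raise ParameterError("resection offsets must be positive")
        if not 0.0 < self.tibial_lateral_fraction < 1.0:
            raise ParameterError("tibial_lateral_fraction must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        eq_kwargs = raw.pop("equation", {})
        cfg = cls(**{k: v for k, v in raw.items()})
        if eq_kwargs:
            cfg.equation = GapEquation(**eq_kwargs)
        return cfg


# ---------------------------------------------------------------------------
# landmark JSON
# ---------------------------------------------------------------------------


def _point_from_json(obj, path: str, problems: list[str]) -> Point2D | None:
    if (
        not isinstance(obj, (list, tuple))
        or len(obj) != 2
        or not all(isinstance(v, (int, float)) for v in obj)
    ):
        problems.append(f"{path}: expected [x, y] numbers, got {obj!r}")
        return None
    try:
        return Point2D(float(obj[0]), float(obj[1]))
    except Exception as exc:
        problems.append(f"{path}: {exc}")
        return None


def _contour_from_json(obj, path: str, problems: list[str]) -> PolyContour | None:
    if not isinstance(obj, list) or len(obj) < 3:
        problems.append(f"{path}: expected a list of at least 3 [x, y] vertices")
        return None
    pts = [_point_from_json(v, f"{path}[{i}]", problems) for i, v in enumerate(obj)]
    if any(p is None for p in pts):
        return None
    try:
        return PolyContour(pts, closed=True)
    except Exception as exc:
        problems.append(f"{path}: {exc}")
        return None


def view_from_dict(raw: dict) -> AnnotatedView:
    """Validate a landmark dictionary and build the annotation.

    Raises :class:`ValidationError` with every problem itemised.
    """
    problems: list[str] = []
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            [f"schema_version: expected {SCHEMA_VERSION}, got {version!r}"]
        )

    view = raw.get("view")
    phase = raw.get("phase")
    laterality = raw.get("laterality")
    if view not in ("AP", "lateral"):
        problems.append(f"view: must be 'AP' or 'lateral', got {view!r}")
    if phase not in ("preop", "postop"):
        problems.append(f"phase: must be 'preop' or 'postop', got {phase!r}")
    if laterality not in ("left", "right"):
        problems.append(f"laterality: must be 'left' or 'right', got {laterality!r}")

    femur = tibia = None
    if raw.get("femur_contour") is not None:
        femur = _contour_from_json(raw["femur_contour"], "femur_contour", problems)
    if raw.get("tibia_contour") is not None:
        tibia = _contour_from_json(raw["tibia_contour"], "tibia_contour", problems)
    if phase == "preop" and view == "AP":
        if raw.get("femur_contour") is None:
            problems.append("femur_contour: required on a preop AP view")
        if raw.get("tibia_contour") is None:
            problems.append("tibia_contour: required on a preop AP view")

    osteo = None
    if raw.get("osteophyte_points") is not None:
        obj = raw["osteophyte_points"]
        if not isinstance(obj, dict):
            problems.append("osteophyte_points: expected a name -> [x, y] mapping")
        else:
            osteo = {}
            for name in OSTEOPHYTE_POINT_NAMES:
                if name not in obj:
                    problems.append(f"osteophyte_points.{name}: missing")
                    continue
                p = _point_from_json(obj[name], f"osteophyte_points.{name}", problems)
                if p is not None:
                    osteo[name] = p

    rects = None
    if raw.get("implant_rectangles") is not None:
        obj = raw["implant_rectangles"]
        if not isinstance(obj, dict):
            problems.append("implant_rectangles: expected a name -> corner-list mapping")
        else:
            rects = {}
            for name, corners in obj.items():
                if not isinstance(corners, list) or len(corners) != 4:
                    problems.append(f"implant_rectangles.{name}: expected 4 corners")
                    continue
                pts = [
                    _point_from_json(c, f"implant_rectangles.{name}[{i}]", problems)
                    for i, c in enumerate(corners)
                ]
                if all(p is not None for p in pts):
                    rects[name] = tuple(pts)
    if phase == "postop" and not rects:
        problems.append("implant_rectangles: required on a postop view")

    marker = None
    if raw.get("marker") is not None:
        m = raw["marker"]
        if (
            not isinstance(m, dict)
            or not isinstance(m.get("measured_units"), (int, float))
            or not isinstance(m.get("true_mm"), (int, float))
        ):
            problems.append("marker: expected {'measured_units': float, 'true_mm': float}")
        elif m["measured_units"] <= 0 or m["true_mm"] <= 0:
            problems.append("marker: extents must be positive")
        else:
            marker = Marker(float(m["measured_units"]), float(m["true_mm"]))

    if problems:
        raise ValidationError(problems)

    return AnnotatedView(
        view=view,
        phase=phase,
        laterality=laterality,
        femur_contour=femur,
        tibia_contour=tibia,
        osteophyte_points=osteo,
        implant_rectangles=rects,
        marker=marker,
        calibrated=bool(raw.get("calibrated", False)),
    )


def view_to_dict(view: AnnotatedView) -> dict:
    def pt(p: Point2D):
        return [p.x, p.y]

    raw: dict = {
        "schema_version": SCHEMA_VERSION,
        "view": view.view,
        "phase": view.phase,
        "laterality": view.laterality,
        "calibrated": view.calibrated,
    }
    if view.femur_contour is not None:
        raw["femur_contour"] = [pt(v) for v in view.femur_contour.vertices]
    if view.tibia_contour is not None:
        raw["tibia_contour"] = [pt(v) for v in view.tibia_contour.vertices]
    if view.osteophyte_points is not None:
        raw["osteophyte_points"] = {k: pt(v) for k, v in view.osteophyte_points.items()}
    if view.implant_rectangles is not None:
        raw["implant_rectangles"] = {
            k: [pt(c) for c in corners] for k, corners in view.implant_rectangles.items()
        }
    if view.marker is not None:
        raw["marker"] = {
            "measured_units": view.marker.measured_units,
            "true_mm": view.marker.true_mm,
        }
    return raw


def read_landmarks(path) -> AnnotatedView:
    """Load, validate and canonicalise a landmark JSON file.

    Left knees are mirrored about the y axis into the canonical right-knee
    frame (logged); the returned view keeps its ``laterality`` field but
    ``mirrored`` is set.
    """
    raw = json.loads(Path(path).read_text())
    view = view_from_dict(raw)
    if view.laterality == "left" and not view.mirrored:
        logger.info("mirroring left-knee annotation %s into the canonical frame", path)
        view = mirror_view(view)
    return view


def write_landmarks(view: AnnotatedView, path) -> None:
    Path(path).write_text(json.dumps(view_to_dict(view), indent=1))


# ---------------------------------------------------------------------------
# measurement CSV
# ---------------------------------------------------------------------------


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV with the eight canonical columns.

    Extra columns are preserved.  Missing canonical columns are reported
    by name; non-numeric cells by (1-based data) row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            [
                f"missing column(s) {missing}; expected header to contain "
                f"{list(MEASUREMENT_COLUMNS)}"
            ]
        )
    problems = []
    for col in MEASUREMENT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for idx in df.index[bad]:
            problems.append(
                f"column {col!r}, row {idx + 1}: non-numeric value {df.at[idx, col]!r}"
            )
        df[col] = coerced.astype(float)
    if problems:
        raise ValidationError(problems)
    return df


def write_measurements(records, path) -> None:
    """Write measurements at full float precision (lossless round trip)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, index=False)
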