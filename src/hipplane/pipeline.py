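"""Bi-planar landmark workflow: from two radiographs to the hip-plane factor.

The method needs one antero-posterior (a.p.) and one lateral radiograph
of the pelvis with a single spherical marker fixed to the patient
("belt-buckle" position, anterior midline).  From the a.p. view the
marker height above the detector (``H_ECM``) is solved; from the
lateral view the horizontal marker-to-hip-plane distance ``d`` is
measured.  Two use errors are corrected:

* *lateral offset* ``i`` — the marker sits off the central beam in the
  a.p. view, which displaces it along the beam axis of the lateral view;
* *patient rotation* ``alpha`` — imperfect lateral positioning, detected
  by the imperfect overlay of the two hip centers in the lateral image
  and quantified as ``alpha = asin(c_cal / m_cal)``.

The corrected distance is

    y_correction = (d_cal +/- sin(alpha) * i_cal) / cos(alpha)

with the sign given by the product of the offset direction and the
rotation direction (toward the source = +1, away = -1).  The hip-plane
height is then ``H_Hip = H_ECM - y_correction`` and the templating
factor ``F_Hip = 100*S/(S - H_Hip)``.

Coordinate conventions (enforced on input, documented in the JSON
schema): detector-plane millimetres, origin at the central beam, x
horizontal, y vertical, images viewed from the source.  In the a.p.
image the x axis is the patient's left-right axis with patient-right at
negative x (configurable).  In the lateral image ``facing`` records the
image direction the patient faces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

from .errors import ConvergenceError, GeometryError, PipelineError, ValidationError
from .projection import (
    DeviceSetup,
    HeightSolution,
    MarkerProjection,
    factor_from_height,
    marker_height_iterative,
)

__all__ = [
    "Point",
    "LateralLandmarks",
    "APLandmarks",
    "LateralMeasurements",
    "APMeasurements",
    "RotationEstimate",
    "HipPlaneResult",
    "PipelineConfig",
    "derive_lateral",
    "derive_ap",
    "estimate_rotation",
    "offset_direction_lateral",
    "correct_rotation",
    "run_pipeline",
]

Point = Tuple[float, float]
Facing = Literal["left", "right"]
Side = Literal["left", "right"]
Direction = Literal["toward_source", "away_from_source"]


def _check_point(name: str, p: Point) -> Point:
    try:
        x, y = float(p[0]), float(p[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ValidationError(f"{name} is not a 2-point: {p!r}") from exc
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValidationError(f"{name} has non-finite coordinates: {p!r}")
    return (x, y)


@dataclass(frozen=True)
class LateralLandmarks:
    """Landmarks of the lateral radiograph (detector mm, origin at beam).

    ``facing`` is the image direction the patient faces ("left" means
    the patient's anterior points toward negative image x).
    """

    image_center: Point
    marker_center: Point
    right_hip: Point
    left_hip: Point
    marker_long_axis_mm: float
    facing: Facing

    def __post_init__(self):
        for name in ("image_center", "marker_center", "right_hip", "left_hip"):
            object.__setattr__(self, name, _check_point(name, getattr(self, name)))
        if self.facing not in ("left", "right"):
            raise ValidationError(f"facing must be 'left' or 'right', got {self.facing!r}")
        if not math.isfinite(self.marker_long_axis_mm) or self.marker_long_axis_mm <= 0:
            raise ValidationError(
                f"marker_long_axis_mm must be positive, got {self.marker_long_axis_mm!r}")


@dataclass(frozen=True)
class APLandmarks:
    """Landmarks of the antero-posterior radiograph (detector mm)."""

    image_center: Point
    marker_center: Point
    right_hip: Point
    left_hip: Point
    marker_long_axis_mm: float

    def __post_init__(self):
        for name in ("image_center", "marker_center", "right_hip", "left_hip"):
            object.__setattr__(self, name, _check_point(name, getattr(self, name)))
        if not math.isfinite(self.marker_long_axis_mm) or self.marker_long_axis_mm <= 0:
            raise ValidationError(
                f"marker_long_axis_mm must be positive, got {self.marker_long_axis_mm!r}")


@dataclass(frozen=True)
class LateralMeasurements:
    """Scalar measurements derived from the lateral landmarks.

    ``a``: direct image-center-to-marker distance; ``c_signed``: signed
    horizontal right-minus-left hip-center distance (the sign carries
    the rotation direction); ``d``: horizontal distance from the
    hip-center construct to the marker center.
    """

    a: float
    c_signed: float
    d: float

    @property
    def c(self) -> float:
        return abs(self.c_signed)


@dataclass(frozen=True)
class APMeasurements:
    """Scalar measurements derived from the a.p. landmarks.

    ``h``: direct image-center-to-marker distance; ``i``: its horizontal
    component (the lateral offset), with ``offset_side`` the patient
    side it points to; ``m``: horizontal inter-hip-center distance.
    """

    h: float
    i: float
    offset_side: Side
    m: float


@dataclass(frozen=True)
class RotationEstimate:
    alpha_deg: float
    direction: Direction


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of :func:`run_pipeline`.

    ``factor_tol`` is the stopping tolerance of the per-view marker
    height iteration; ``outer_tol`` that of the outer fixed point which
    calibrates the inter-hip distance ``m`` at the (initially unknown)
    hip plane.  ``apply_correction=False`` reproduces the naive
    uncorrected pipeline (``y_correction = d_cal``) for error studies.
    """

    factor_tol: float = 1e-4
    max_iter: int = 100
    outer_tol: float = 1e-4
    outer_max_iter: int = 50
    apply_correction: bool = True
    rotation_direction_override: Optional[Direction] = None
    offset_direction_override: Optional[Direction] = None
    ap_patient_right_negative_x: bool = True


@dataclass(frozen=True)
class HipPlaneResult:
    """Full output of the bi-planar calibration with intermediates."""

    H_ECM: float
    d_cal: float
    i_cal: float
    alpha_deg: float
    x: float                   # signed offset correction sin(a)*i*signs
    y_correction: float
    H_Hip: float
    F_Hip: float
    offset_direction: Direction
    rotation_direction: Direction
    lateral: LateralMeasurements
    ap: APMeasurements
    ap_solution: HeightSolution
    lateral_solution: HeightSolution
    m_cal: float
    c_cal: float
    n_outer_iterations: int
    diagnostics: dict = field(default_factory=dict)


def derive_lateral(landmarks: LateralLandmarks) -> LateralMeasurements:
    """Construct the lateral scalar measurements from landmarks.

    Follows the geometric construction on the image: the vertical line
    through the right hip C and the horizontal line through the left
    hip D intersect at E; G is the midpoint of E and D (so x_G is the
    horizontal hip-center midpoint); the marker distance d is measured
    horizontally from G to the marker center B.
    """
    A, B = landmarks.image_center, landmarks.marker_center
    C, D = landmarks.right_hip, landmarks.left_hip
    a = math.hypot(B[0] - A[0], B[1] - A[1])
    E = (C[0], D[1])
    G = ((E[0] + D[0]) / 2.0, (E[1] + D[1]) / 2.0)
    c_signed = C[0] - D[0]
    d = abs(B[0] - G[0])
    return LateralMeasurements(a=a, c_signed=c_signed, d=d)


def derive_ap(landmarks: APLandmarks,
              patient_right_negative_x: bool = True) -> APMeasurements:
    """Construct the a.p. scalar measurements from landmarks.

    Raises
    ------
    GeometryError
        If the two hip centers coincide horizontally (degenerate
        anatomy: the inter-hip distance m would be zero).
    """
    O, P = landmarks.image_center, landmarks.marker_center
    Q, R = landmarks.right_hip, landmarks.left_hip
    h = math.hypot(P[0] - O[0], P[1] - O[1])
    dx = P[0] - O[0]
    i = abs(dx)
    if patient_right_negative_x:
        side: Side = "left" if dx >= 0 else "right"
    else:
        side = "right" if dx >= 0 else "left"
    m = abs(Q[0] - R[0])
    if m == 0:
        raise GeometryError("hip centers coincide horizontally in the a.p. "
                            "image (m = 0): cannot estimate rotation scale")
    return APMeasurements(h=h, i=i, offset_side=side, m=m)


def estimate_rotation(c_cal: float, m_cal: float,
                      landmarks: LateralLandmarks) -> RotationEstimate:
    """Patient rotation in the lateral view from the hip-center overlay.

    ``alpha = asin(|c_cal| / m_cal)`` (degrees).  The rotation direction
    is inferred from the horizontal order of the projected hip centers:
    with images viewed from the source, the right hip projecting at
    greater image-x than the left hip means the patient rotated toward
    the source — a relation that holds for either facing direction.
    A perfect overlay (c = 0) yields alpha = 0 with direction
    ``toward_source``; the choice is inert because the correction
    vanishes.

    Raises
    ------
    GeometryError
        If ``|c_cal| > m_cal`` (grossly inconsistent landmarking) or the
        implied rotation is not below 90 degrees.
    """
    if m_cal <= 0:
        raise GeometryError(f"m_cal must be > 0, got {m_cal}")
    if abs(c_cal) > m_cal:
        raise GeometryError(
            f"|c_cal| = {abs(c_cal):.3f} exceeds m_cal = {m_cal:.3f}: "
            "inconsistent hip-center measurements")
    alpha = math.degrees(math.asin(abs(c_cal) / m_cal))
    if alpha >= 90.0:
        raise GeometryError(
            f"implied rotation {alpha:.1f} deg is out of the admissible "
            "range [0, 90)")
    x_right = landmarks.right_hip[0]
    x_left = landmarks.left_hip[0]
    direction: Direction = ("toward_source" if x_right > x_left
                            else "away_from_source")
    return RotationEstimate(alpha_deg=alpha, direction=direction)


def offset_direction_lateral(offset_side: Side, facing: Facing) -> Direction:
    """Direction of the marker's lateral offset along the beam axis of
    the lateral view.

    A marker offset toward the patient's right moves it toward the
    source when the patient faces left, and away from the source when
    the patient faces right (and mirrored for a left offset).
    """
    if offset_side not in ("left", "right"):
        raise ValidationError(f"offset_side must be 'left'/'right', got {offset_side!r}")
    if facing not in ("left", "right"):
        raise ValidationError(f"facing must be 'left'/'right', got {facing!r}")
    return "toward_source" if offset_side != facing else "away_from_source"


def correct_rotation(
    d_cal: float,
    i_cal: float,
    alpha_deg: float,
    offset_direction: Direction,
    rotation_direction: Direction,
) -> Tuple[float, float, float]:
    """Rotation/offset correction of the marker-to-hip-plane distance.

    Returns ``(x, y, y_correction)`` with ``x = s * sin(alpha) * i_cal``
    (``s`` the product of the two direction signs, +1 toward the
    source), ``y = d_cal + x`` and ``y_correction = y / cos(alpha)``.
    """
    if not 0 <= alpha_deg < 90:
        raise GeometryError(f"alpha must be in [0, 90) deg, got {alpha_deg}")
    if d_cal < 0 or i_cal < 0:
        raise GeometryError("d_cal and i_cal must be non-negative")
    s_off = 1.0 if offset_direction == "toward_source" else -1.0
    s_rot = 1.0 if rotation_direction == "toward_source" else -1.0
    al = math.radians(alpha_deg)
    x = s_off * s_rot * math.sin(al) * i_cal
    y = d_cal + x
    y_correction = y / math.cos(al)
    return x, y, y_correction


def run_pipeline(
    setup: DeviceSetup,
    ap: APLandmarks,
    lateral: LateralLandmarks,
    config: PipelineConfig = PipelineConfig(),
) -> HipPlaneResult:
    """Execute the full bi-planar calibration.

    Stages: (1) scalar measurements from both landmark sets; (2) the
    iterative marker-height solve per view (a.p. gives ``H_ECM``,
    lateral gives the marker height used only to calibrate lateral
    distances); (3) distance calibration — ``d`` and ``c`` at the
    lateral marker plane, ``i`` at the a.p. marker plane, ``m`` at the
    hip plane through an outer fixed point on ``F_Hip``; (4) rotation
    estimation; (5) direction resolution; (6) the correction formula;
    (7) ``H_Hip = H_ECM - y_correction`` and ``F_Hip``.
    """
    S = setup.S

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    lat_meas = stage("derive_lateral", derive_lateral, lateral)
    ap_meas = stage("derive_ap", derive_ap, ap,
                    config.ap_patient_right_negative_x)

    sol_ap = stage(
        "marker_height_ap", marker_height_iterative, setup,
        MarkerProjection(ap.marker_long_axis_mm, ap_meas.h, "antero-posterior"),
        tol=config.factor_tol, max_iter=config.max_iter)
    sol_lat = stage(
        "marker_height_lateral", marker_height_iterative, setup,
        MarkerProjection(lateral.marker_long_axis_mm, lat_meas.a, "lateral"),
        tol=config.factor_tol, max_iter=config.max_iter)

    H_ECM = sol_ap.height_mm
    f_lat = sol_lat.factor_percent / 100.0
    f_ap = sol_ap.factor_percent / 100.0

    d_cal = lat_meas.d / f_lat
    c_cal = lat_meas.c / f_lat
    i_cal = ap_meas.i / f_ap

    offset_dir = config.offset_direction_override or offset_direction_lateral(
        ap_meas.offset_side, lateral.facing)

    # Outer fixed point: m lies in the (unknown) hip plane, so its
    # calibration factor is the quantity being solved for.  Initialise
    # with the a.p. marker factor and iterate F_Hip to stability.
    F_hip = sol_ap.factor_percent
    rot = RotationEstimate(0.0, "toward_source")
    x = 0.0
    y_correction = d_cal
    n_outer = 0
    m_cal = ap_meas.m / (F_hip / 100.0)
    while True:
        n_outer += 1
        m_cal = ap_meas.m / (F_hip / 100.0)
        rot = stage("estimate_rotation", estimate_rotation,
                    c_cal, m_cal, lateral)
        rotation_dir = config.rotation_direction_override or rot.direction
        if config.apply_correction:
            x, _y, y_correction = stage(
                "correct_rotation", correct_rotation,
                d_cal, i_cal, rot.alpha_deg, offset_dir, rotation_dir)
        else:
            x, y_correction = 0.0, d_cal
        H_Hip = H_ECM - y_correction
        if not 0 <= H_Hip < S:
            raise PipelineError(
                "hip_plane", GeometryError(
                    f"H_Hip = {H_Hip:.3f} mm outside [0, S={S}): "
                    "inconsistent geometry"))
        F_new = factor_from_height(S, H_Hip)
        if abs(F_new - F_hip) < config.outer_tol:
            F_hip = F_new
            break
        F_hip = F_new
        if n_outer >= config.outer_max_iter:
            raise PipelineError("hip_plane", ConvergenceError(
                f"outer hip-plane fixed point did not reach "
                f"|dF| < {config.outer_tol} in {config.outer_max_iter} passes",
                last=F_hip))

    rotation_dir = config.rotation_direction_override or rot.direction
    return HipPlaneResult(
        H_ECM=H_ECM,
        d_cal=d_cal,
        i_cal=i_cal,
        alpha_deg=rot.alpha_deg,
        x=x,
        y_correction=y_correction,
        H_Hip=H_ECM - y_correction,
        F_Hip=F_hip,
        offset_direction=offset_dir,
        rotation_direction=rotation_dir,
        lateral=lat_meas,
        ap=ap_meas,
        ap_solution=sol_ap,
        lateral_solution=sol_lat,
        m_cal=m_cal,
        c_cal=c_cal,
        n_outer_iterations=n_outer,
        diagnostics={
            "F_ap": sol_ap.factor_percent,
            "F_lat": sol_lat.factor_percent,
            "n_iter_ap": sol_ap.n_iterations,
            "n_iter_lat": sol_lat.n_iterations,
        },
    )
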