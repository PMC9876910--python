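"""Synthetic scene generator and forward projector.

Builds 3D pelvis-plus-marker scenes with known ground truth and
projects them into paired a.p./lateral landmark sets, so the recovery
accuracy of the calibration pipeline can be measured against truth.

Patient frame: origin at the inter-hip midpoint, x toward the patient's
left, y anterior, z superior.  The right/left hip centers sit at
(-m/2, 0, 0) and (+m/2, 0, 0); the marker at (lambda, d, v) with
``lambda`` the signed lateral offset (positive = patient-left), ``d``
the anterior marker-to-hip-plane distance and ``v`` a vertical offset.

Two projection fidelities are provided:

``paper_model``
    The measurement model the correction formulas assume exactly: the
    a.p. view projects points through the pinhole at their own plane
    and synthesises the marker ellipse by numerically inverting the
    height formula at the true radial displacement; the lateral view is
    a weak-perspective projection at the marker plane, so the in-plane
    trigonometry of rotation and offset (d*cos(a) -/+ i*sin(a),
    c = m*sin(a)) is undistorted by depth.  Under this fidelity the
    corrected pipeline recovers truth up to iteration tolerance.

``full_pinhole``
    Exact per-point pinhole projection plus tangent-cone sphere
    shadows in both views.  This includes the depth-magnification
    coupling that the trigonometric correction ignores, so residual
    recovery errors are expected and are reported rather than asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GeometryError
from .pipeline import (
    APLandmarks,
    Direction,
    Facing,
    HipPlaneResult,
    LateralLandmarks,
    PipelineConfig,
    run_pipeline,
)
from .projection import DeviceSetup, factor_from_height

__all__ = [
    "Scene3D",
    "SyntheticCase",
    "project_sphere",
    "project_point",
    "axis_for_height",
    "scene_to_landmarks",
    "generate_case",
    "standard_model_scene",
    "recovery_report",
]

PAPER_MODEL = "paper_model"
FULL_PINHOLE = "full_pinhole"


@dataclass(frozen=True)
class Scene3D:
    """Ground-truth scene: pelvis geometry, marker placement and pose."""

    hip_separation_mm: float          # m_true
    marker_anterior_mm: float         # d_true > 0
    marker_left_mm: float             # signed lateral offset (+ = patient left)
    marker_sup_mm: float              # marker vertical offset in patient frame
    rotation_deg: float               # alpha_true >= 0 (lateral view only)
    rotation_direction: Direction
    facing: Facing
    hip_plane_height_mm: float        # height of hip plane above detector, a.p.
    lateral_pivot_height_mm: float    # height of hip midpoint above detector, lat.
    ap_vertical_offset_mm: float = 0.0     # pelvis origin vs beam, a.p. vertical
    lat_horizontal_offset_mm: float = 0.0  # pelvis origin vs beam, lat. horizontal
    lat_vertical_offset_mm: float = 0.0    # pelvis origin vs beam, lat. vertical
    rotation_pivot: Tuple[float, float] = (0.0, 0.0)  # (left, anterior), patient frame

    def __post_init__(self):
        if self.hip_separation_mm <= 0:
            raise GeometryError("hip separation must be > 0")
        if self.marker_anterior_mm <= 0:
            raise GeometryError("marker must be anterior of the hip plane")
        if not 0 <= self.rotation_deg < 90:
            raise GeometryError("rotation must be in [0, 90) deg")

    # -- convenience accessors -------------------------------------------
    @property
    def hip_center_right(self) -> Tuple[float, float, float]:
        return (-self.hip_separation_mm / 2.0, 0.0, 0.0)

    @property
    def hip_center_left(self) -> Tuple[float, float, float]:
        return (self.hip_separation_mm / 2.0, 0.0, 0.0)

    @property
    def marker_center(self) -> Tuple[float, float, float]:
        return (self.marker_left_mm, self.marker_anterior_mm, self.marker_sup_mm)

    @property
    def offset_side(self) -> str:
        return "left" if self.marker_left_mm >= 0 else "right"

    @property
    def marker_height_ap_mm(self) -> float:
        """Marker-center height above the detector in the a.p. view."""
        return self.hip_plane_height_mm + self.marker_anterior_mm


@dataclass(frozen=True)
class SyntheticCase:
    """A projected scene: landmark sets plus ground truth."""

    device: DeviceSetup
    scene: Optional[Scene3D]   # absent when reloaded from disk
    ap_landmarks: APLandmarks
    lateral_landmarks: LateralLandmarks
    truth: dict
    fidelity: str
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# exact pinhole primitives
# ---------------------------------------------------------------------------

def project_point(setup: DeviceSetup, inplane_mm: float, height_mm: float) -> float:
    """Pinhole projection of one in-plane coordinate of a point at
    ``height_mm`` above the detector onto the detector plane."""
    if height_mm >= setup.S:
        raise GeometryError("point at or above the source plane")
    return inplane_mm * setup.S / (setup.S - height_mm)


def project_sphere(setup: DeviceSetup, radial_offset_mm: float,
                   height_mm: float) -> Tuple[float, float]:
    """Exact tangent-cone shadow of a sphere.

    The sphere center sits ``radial_offset_mm`` from the central beam
    at ``height_mm`` above the detector.  Working in the plane spanned
    by the source, the sphere center and the central beam, the two
    tangent rays from the source meet the detector at
    ``S*tan(theta -/+ beta)`` with ``theta`` the ray angle to the
    center and ``sin(beta) = r/D``.  Returns the long axis of the
    projected conic and the radial displacement of its midpoint (the
    measurable ellipse center).
    """
    S, r = setup.S, setup.r
    rho = abs(radial_offset_mm)
    D = math.hypot(rho, S - height_mm)
    if D <= r:
        raise GeometryError("sphere intersects the X-ray source")
    if height_mm + r >= S:
        raise GeometryError("sphere intersects the source plane")
    beta = math.asin(r / D)
    theta = math.atan2(rho, S - height_mm)
    if theta + beta >= math.pi / 2:
        raise GeometryError("tangent ray parallel to the detector: sphere "
                            "too far off-axis for a bounded shadow")
    x1 = S * math.tan(theta - beta)
    x2 = S * math.tan(theta + beta)
    return x2 - x1, (x1 + x2) / 2.0


def axis_for_height(setup: DeviceSetup, height_mm: float,
                    radial_offset_mm: float) -> float:
    """Invert the closed-form height formula: the ellipse long axis that
    yields ``height_mm`` at the given (true) radial displacement.

    Used by the ``paper_model`` generator so that the synthetic ellipse
    measurement is exactly consistent with the inverse formula.
    """
    S, r = setup.S, setup.r
    if not 0 <= height_mm < S - r:
        raise GeometryError("height must lie in [0, S - r)")
    disp = abs(radial_offset_mm)

    def f(axis):
        # raw closed form; may be negative below the physical range,
        # which keeps the bracket valid (height is increasing in axis)
        inner = math.sqrt((r * S / axis) ** 2 + disp * disp)
        H = S - math.sqrt(r * r * (1 + 2 * S * S / (axis * axis))
                          + (2 * r * S / axis) * inner)
        return H - height_mm

    lo = 2 * r * (1 + 1e-12)       # f(lo) < 0: shadow barely magnified
    hi = 4 * r
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise GeometryError("no physical ellipse axis for requested height")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# scene -> landmarks
# ---------------------------------------------------------------------------

def _lateral_frame(scene: Scene3D):
    """Axes of the lateral view in detector coordinates (u horizontal,
    w toward the source), and the rotation angle of the patient frame."""
    sf = 1.0 if scene.facing == "right" else -1.0
    sr = 1.0 if scene.rotation_direction == "toward_source" else -1.0
    phi = sr * sf * math.radians(scene.rotation_deg)
    A = (sf, 0.0)   # anterior axis
    L = (0.0, sf)   # patient-left axis
    return A, L, phi


def _lateral_world(scene: Scene3D, point_pat: Tuple[float, float, float]):
    """Patient-frame point -> (u, height, v) in the lateral view."""
    A, L, phi = _lateral_frame(scene)
    px, py, pz = point_pat
    pvx, pvy = scene.rotation_pivot
    # horizontal plane vector relative to the rotation pivot
    rel_u = (py - pvy) * A[0] + (px - pvx) * L[0]
    rel_w = (py - pvy) * A[1] + (px - pvx) * L[1]
    ru = rel_u * math.cos(phi) - rel_w * math.sin(phi)
    rw = rel_u * math.sin(phi) + rel_w * math.cos(phi)
    piv_u = pvy * A[0] + pvx * L[0]
    piv_w = pvy * A[1] + pvx * L[1]
    u = scene.lat_horizontal_offset_mm + piv_u + ru
    w = piv_w + rw
    v = pz + scene.lat_vertical_offset_mm
    height = scene.lateral_pivot_height_mm + w
    return u, height, v


def _ap_world(scene: Scene3D, point_pat: Tuple[float, float, float]):
    """Patient-frame point -> (x, height, y_vertical) in the a.p. view.

    The a.p. radiograph is taken unrotated with the patient facing the
    source and the pelvis midline on the central beam; image x is the
    patient's left-right axis (patient-right negative)."""
    px, py, pz = point_pat
    return px, scene.hip_plane_height_mm + py, pz + scene.ap_vertical_offset_mm


def _project_marker(setup: DeviceSetup, u: float, v: float, height: float,
                    fidelity: str):
    """Image center point and ellipse axis of the marker in one view."""
    rho = math.hypot(u, v)
    if fidelity == FULL_PINHOLE:
        axis, disp = project_sphere(setup, rho, height)
    elif fidelity == PAPER_MODEL:
        axis = axis_for_height(setup, height, rho)
        disp = rho * setup.S / (setup.S - height)
    else:
        raise ValueError(f"unknown fidelity {fidelity!r}")
    if rho == 0:
        center = (0.0, 0.0)
    else:
        center = (disp * u / rho, disp * v / rho)
    return center, axis


def scene_to_landmarks(setup: DeviceSetup, scene: Scene3D,
                       fidelity: str = PAPER_MODEL
                       ) -> Tuple[APLandmarks, LateralLandmarks]:
    """Project a scene into the two landmark sets at the given fidelity."""
    # ---- antero-posterior view (per-point pinhole in both fidelities)
    ap_pts = {}
    for name, p in (("right_hip", scene.hip_center_right),
                    ("left_hip", scene.hip_center_left)):
        x, height, yv = _ap_world(scene, p)
        ap_pts[name] = (project_point(setup, x, height),
                        project_point(setup, yv, height))
    mx, mheight, mv = _ap_world(scene, scene.marker_center)
    m_center, m_axis = _project_marker(setup, mx, mv, mheight, fidelity)
    ap = APLandmarks(
        image_center=(0.0, 0.0),
        marker_center=m_center,
        right_hip=ap_pts["right_hip"],
        left_hip=ap_pts["left_hip"],
        marker_long_axis_mm=m_axis,
    )

    # ---- lateral view
    mu, mheight_lat, mvv = _lateral_world(scene, scene.marker_center)
    lat_pts = {}
    if fidelity == PAPER_MODEL:
        # weak perspective at the marker plane: uniform magnification
        mag = setup.S / (setup.S - mheight_lat)
        for name, p in (("right_hip", scene.hip_center_right),
                        ("left_hip", scene.hip_center_left)):
            u, _height, v = _lateral_world(scene, p)
            lat_pts[name] = (u * mag, v * mag)
        lm_center, lm_axis = _project_marker(
            setup, mu, mvv, mheight_lat, PAPER_MODEL)
    else:
        for name, p in (("right_hip", scene.hip_center_right),
                        ("left_hip", scene.hip_center_left)):
            u, height, v = _lateral_world(scene, p)
            lat_pts[name] = (project_point(setup, u, height),
                             project_point(setup, v, height))
        lm_center, lm_axis = _project_marker(
            setup, mu, mvv, mheight_lat, FULL_PINHOLE)
    lat = LateralLandmarks(
        image_center=(0.0, 0.0),
        marker_center=lm_center,
        right_hip=lat_pts["right_hip"],
        left_hip=lat_pts["left_hip"],
        marker_long_axis_mm=lm_axis,
        facing=scene.facing,
    )
    return ap, lat


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------

#: Default sampling ranges for :func:`generate_case` (uniform draws).
#: Centered on the standard-model geometry of an adult pelvis.
DEFAULT_RANGES = {
    "m_true": (140.0, 160.0),           # inter-hip distance
    "d_true": (90.0, 130.0),            # anterior marker distance
    "i_true": (0.0, 60.0),              # lateral offset magnitude
    "alpha_true": (0.0, 30.0),          # rotation in the lateral view
    "hip_plane_height": (190.0, 250.0),  # a.p. hip-plane height
    "lateral_pivot_height": (280.0, 350.0),
    "marker_sup": (-20.0, 20.0),
    "ap_vertical_offset": (-15.0, 15.0),
    "lat_horizontal_offset": (-30.0, 30.0),
    "lat_vertical_offset": (150.0, 220.0),
}


def standard_model_scene(
    alpha_deg: float = 0.0,
    offset_mm: float = 0.0,
    *,
    marker_height_ap_mm: float,
    d_true: float = 110.0,
    m_true: float = 150.0,
    facing: Facing = "left",
    rotation_direction: Direction = "toward_source",
    lateral_pivot_height_mm: float = 316.0,
) -> Scene3D:
    """Scene matching the standard simulation model.

    The marker height in the a.p. view is supplied explicitly (it is
    the quantity the a.p. measurements encode); the hip-plane height
    follows as ``marker_height - d_true``.  The lateral offset is
    placed toward the patient's right so that, with the default
    ``facing="left"``, the offset points toward the source — the
    branch used by the error simulation.
    """
    return Scene3D(
        hip_separation_mm=m_true,
        marker_anterior_mm=d_true,
        marker_left_mm=-abs(offset_mm),
        marker_sup_mm=0.0,
        rotation_deg=alpha_deg,
        rotation_direction=rotation_direction,
        facing=facing,
        hip_plane_height_mm=marker_height_ap_mm - d_true,
        lateral_pivot_height_mm=lateral_pivot_height_mm,
        lat_vertical_offset_mm=180.0,
    )


def generate_case(
    seed: int,
    setup: DeviceSetup = DeviceSetup(1150.0, 12.5),
    fidelity: str = PAPER_MODEL,
    ranges: Optional[dict] = None,
) -> SyntheticCase:
    """Draw a random scene and project it into a synthetic case.

    Deterministic for a fixed seed: identical seeds yield bit-identical
    cases.  All scalar scene parameters are drawn uniformly from
    ``ranges`` (defaults in :data:`DEFAULT_RANGES`); facing, offset
    side and rotation direction are drawn uniformly from their two
    values.
    """
    rng = np.random.default_rng(seed)
    rr = dict(DEFAULT_RANGES)
    if ranges:
        rr.update(ranges)

    def u(key):
        lo, hi = rr[key]
        return float(rng.uniform(lo, hi))

    m_true = u("m_true")
    d_true = u("d_true")
    i_true = u("i_true")
    alpha = u("alpha_true")
    hip_h = u("hip_plane_height")
    side_sign = -1.0 if rng.integers(2) else 1.0   # -1 = patient right
    facing: Facing = "left" if rng.integers(2) else "right"
    rot_dir: Direction = ("toward_source" if rng.integers(2)
                          else "away_from_source")
    scene = Scene3D(
        hip_separation_mm=m_true,
        marker_anterior_mm=d_true,
        marker_left_mm=side_sign * i_true,
        marker_sup_mm=u("marker_sup"),
        rotation_deg=alpha,
        rotation_direction=rot_dir,
        facing=facing,
        hip_plane_height_mm=hip_h,
        lateral_pivot_height_mm=u("lateral_pivot_height"),
        ap_vertical_offset_mm=u("ap_vertical_offset"),
        lat_horizontal_offset_mm=u("lat_horizontal_offset"),
        lat_vertical_offset_mm=u("lat_vertical_offset"),
    )
    if scene.marker_height_ap_mm + setup.r >= setup.S:
        raise GeometryError("marker too close to the source plane; narrow "
                            "the height ranges")
    ap, lat = scene_to_landmarks(setup, scene, fidelity)
    truth = {
        "H_Hip_true": scene.hip_plane_height_mm,
        "F_Hip_true": factor_from_height(setup.S, scene.hip_plane_height_mm),
        "alpha_true": alpha,
        "i_true": i_true,
        "d_true": d_true,
        "m_true": m_true,
        "H_ECM_true": scene.marker_height_ap_mm,
    }
    return SyntheticCase(setup, scene, ap, lat, truth, fidelity, seed)


def case_from_scene(setup: DeviceSetup, scene: Scene3D,
                    fidelity: str = PAPER_MODEL,
                    seed: Optional[int] = None) -> SyntheticCase:
    """Project an explicitly constructed scene into a case."""
    ap, lat = scene_to_landmarks(setup, scene, fidelity)
    truth = {
        "H_Hip_true": scene.hip_plane_height_mm,
        "F_Hip_true": factor_from_height(setup.S, scene.hip_plane_height_mm),
        "alpha_true": scene.rotation_deg,
        "i_true": abs(scene.marker_left_mm),
        "d_true": scene.marker_anterior_mm,
        "m_true": scene.hip_separation_mm,
        "H_ECM_true": scene.marker_height_ap_mm,
    }
    return SyntheticCase(setup, scene, ap, lat, truth, fidelity, seed)


# ---------------------------------------------------------------------------
# recovery reporting
# ---------------------------------------------------------------------------

def recovery_report(
    cases: Sequence[SyntheticCase],
    config: PipelineConfig = PipelineConfig(),
    csv_path=None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pipeline over cases and compare with ground truth.

    Returns ``(per_case, summary)``: one row per case with recovered
    vs. true values and the signed relative factor error in percent,
    and a per-fidelity summary (bias, mean |error|, max |error|).
    """
    if len(cases) == 0:
        raise ValueError("at least one case is required")
    rows = []
    for case in cases:
        res: HipPlaneResult = run_pipeline(
            case.device, case.ap_landmarks, case.lateral_landmarks, config)
        F_true = case.truth["F_Hip_true"]
        rows.append({
            "seed": case.seed,
            "fidelity": case.fidelity,
            "alpha_true": case.truth["alpha_true"],
            "i_true": case.truth["i_true"],
            "F_Hip_true": F_true,
            "F_Hip": res.F_Hip,
            "H_Hip_true": case.truth["H_Hip_true"],
            "H_Hip": res.H_Hip,
            "alpha_est": res.alpha_deg,
            "rel_err_pct": 100.0 * (res.F_Hip - F_true) / F_true,
        })
    per_case = pd.DataFrame(rows)
    summary = per_case.groupby("fidelity")["rel_err_pct"].agg(
        bias_pct="mean",
        mean_abs_pct=lambda s: s.abs().mean(),
        max_abs_pct=lambda s: s.abs().max(),
        n="size",
    ).reset_index()
    if csv_path is not None:
        per_case.to_csv(csv_path, index=False)
    return per_case, summary
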