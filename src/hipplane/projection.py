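"""Sphere-projection geometry for radiograph magnification calibration.

A radiopaque sphere (external calibration marker, ECM) of known radius
``r`` is imaged by a point X-ray source at source--detector distance
``S``.  Its shadow on the detector is an ellipse whose long axis grows
with the marker's height above the detector and with its distance from
the central beam.  Inverting that relationship gives the marker-center
height ``H`` and hence the magnification ("calibration factor")

    F = 100 * S / (S - H)        [percent; 100 = life size]

of any object lying in the plane through the marker parallel to the
detector.

The closed form used here takes the *measured* long axis of the ellipse
and the *measured* (projected) displacement of its center from the
central beam.  Because the projected displacement is itself magnified,
the height is refined by a fixed-point iteration that repeatedly
de-magnifies the displacement with the latest factor until the factor
is stable; at least one refinement pass is always performed.

All lengths are millimetres; factors are percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConvergenceError, GeometryError

__all__ = [
    "DeviceSetup",
    "MarkerProjection",
    "HeightSolution",
    "marker_height",
    "marker_height_iterative",
    "factor_from_height",
    "height_from_factor",
]

#: Default stopping tolerance on the factor difference between passes.
DEFAULT_FACTOR_TOL = 1e-4


def _require_finite(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise GeometryError(f"{name} must be finite, got {value!r}")
    return v


@dataclass(frozen=True)
class DeviceSetup:
    """X-ray device constants shared by every computation.

    Parameters
    ----------
    source_detector_distance_mm :
        Distance S from the focal spot to the detector plane.
    marker_radius_mm :
        True radius r of the spherical calibration marker.
    """

    source_detector_distance_mm: float
    marker_radius_mm: float

    def __post_init__(self):
        S = _require_finite("source_detector_distance_mm",
                            self.source_detector_distance_mm)
        r = _require_finite("marker_radius_mm", self.marker_radius_mm)
        if S <= 0:
            raise GeometryError(f"source-detector distance must be > 0, got {S}")
        if not 0 < r < S / 2:
            raise GeometryError(
                f"marker radius must satisfy 0 < r < S/2, got r={r}, S={S}")

    @property
    def S(self) -> float:
        return self.source_detector_distance_mm

    @property
    def r(self) -> float:
        return self.marker_radius_mm


@dataclass(frozen=True)
class MarkerProjection:
    """Scalar measurements of the projected marker ellipse in one view.

    ``long_axis_mm`` is the measured long axis of the ellipse;
    ``displacement_mm`` the measured direct (radial) distance of the
    ellipse center from the central beam / image center.
    """

    long_axis_mm: float
    displacement_mm: float
    view: str = "antero-posterior"  # or "lateral"; metadata only

    def __post_init__(self):
        _require_finite("long_axis_mm", self.long_axis_mm)
        d = _require_finite("displacement_mm", self.displacement_mm)
        if d < 0:
            raise GeometryError(f"displacement must be >= 0, got {d}")


@dataclass(frozen=True)
class HeightSolution:
    """Result of the iterative height solver for one view."""

    height_mm: float           # marker-center height above the detector
    factor_percent: float      # 100*S/(S - height)
    n_iterations: int          # recalibration passes performed (>= 1)
    converged: bool


def marker_height(setup: DeviceSetup, proj: MarkerProjection) -> float:
    """Marker-center height above the detector from one ellipse measurement.

    Closed-form inversion of the tangent-cone projection of a sphere:

        H = S - sqrt( r^2 (1 + 2 S^2 / axis^2)
                      + (2 r S / axis) * sqrt(r^2 S^2 / axis^2 + disp^2) )

    The displacement is used as measured (projected); see
    :func:`marker_height_iterative` for the de-magnified refinement.

    Raises
    ------
    GeometryError
        If the axis is not larger than the marker diameter (no
        magnification) or the resulting height is negative.
    """
    S, r = setup.S, setup.r
    axis = proj.long_axis_mm
    disp = proj.displacement_mm
    if axis <= 2 * r:
        raise GeometryError(
            f"projected long axis ({axis} mm, {proj.view}) must exceed the "
            f"marker diameter {2 * r} mm")
    inner = math.sqrt((r * S / axis) ** 2 + disp * disp)
    H = S - math.sqrt(r * r * (1 + 2 * S * S / (axis * axis))
                      + (2 * r * S / axis) * inner)
    if H < 0:
        if H > -1e-9 * S:
            return 0.0
        raise GeometryError(
            f"non-physical measurement (axis={axis} mm, displacement={disp} mm,"
            f" {proj.view}): implied marker height {H:.3f} mm is below the "
            "detector")
    return H


def marker_height_iterative(
    setup: DeviceSetup,
    proj: MarkerProjection,
    tol: float = DEFAULT_FACTOR_TOL,
    max_iter: int = 100,
) -> HeightSolution:
    """Height solver with displacement de-magnification.

    The measured displacement is a projected distance and therefore
    magnified by the (initially unknown) marker-plane factor.  Each pass
    recomputes the height with the original displacement divided by the
    latest factor, ``disp_n = disp_0 * (S - H_n) / S``, and stops once
    the factor changes by less than ``tol`` between passes.  At least
    one recalibration pass is always performed, so ``n_iterations >= 1``.

    Raises
    ------
    ConvergenceError
        If ``max_iter`` passes do not reach ``tol``; carries the last
        :class:`HeightSolution` in ``.last``.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    S = setup.S
    disp0 = proj.displacement_mm

    H = marker_height(setup, proj)
    F = factor_from_height(S, H)
    n = 0
    while n < max_iter:
        n += 1
        disp = disp0 * (S - H) / S
        H = marker_height(
            setup, MarkerProjection(proj.long_axis_mm, disp, proj.view))
        F_new = factor_from_height(S, H)
        delta, F = abs(F_new - F), F_new
        if delta < tol:
            return HeightSolution(H, F, n, True)
    raise ConvergenceError(
        f"height iteration did not reach |dF| < {tol} in {max_iter} passes "
        f"({proj.view})",
        last=HeightSolution(H, F, n, False))


def factor_from_height(S: float, height_mm: float) -> float:
    """Intercept-theorem calibration factor (percent) of a plane at
    ``height_mm`` above the detector: ``100*S/(S - height)``."""
    if not 0 <= height_mm < S:
        raise GeometryError(
            f"object height must lie in [0, S), got {height_mm} with S={S}")
    return 100.0 * S / (S - height_mm)


def height_from_factor(S: float, factor_percent: float) -> float:
    """Inverse of :func:`factor_from_height`: ``S * (1 - 100/F)``."""
    if factor_percent < 100.0:
        raise GeometryError(
            f"calibration factor must be >= 100, got {factor_percent}")
    return S * (1.0 - 100.0 / factor_percent)
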