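"""Standard-model simulation of uncorrected rotation/offset error.

If the patient is rotated by ``alpha`` in the lateral radiograph and
the marker carries a lateral offset ``i``, but no correction is
applied, the naive pipeline still reports the factor computed from the
measured distance ``d``.  The *true* marker-to-hip-plane distance in
that rotated geometry is

    y_rot = (d + i * sin(alpha)) / cos(alpha)

(the "+"/toward-source branch of the correction formula), so the true
hip-plane factor is lower than the reported one.  The error is the
difference between the reported (non-rotated) factor ``F_ref`` and the
true rotated-geometry factor ``F_rot``, as absolute factor points and
as a percentage of ``F_ref``.

The standard model carries empirical mean measurement values for an
adult pelvis; ``d`` is the already-calibrated true marker-to-hip-plane
distance.  The lateral-view entries (``a``, ``b``) and the inter-hip
distance ``m`` are part of the model description but do not enter this
error computation (``c`` is simulated as ``m*sin(alpha)`` when needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import GeometryError
from .projection import (
    DeviceSetup,
    MarkerProjection,
    factor_from_height,
    marker_height_iterative,
)

__all__ = [
    "StandardModel",
    "ErrorCell",
    "reference_factor",
    "rotation_error",
    "error_table",
    "threshold_scan",
    "DEFAULT_OFFSETS",
]

DEFAULT_OFFSETS = (0.0, 20.0, 60.0)
DEFAULT_ROTATIONS = tuple(range(0, 31))


@dataclass(frozen=True)
class StandardModel:
    """Empirical mean measurement values of the standard pelvis model (mm)."""

    S: float = 1150.0     # source-detector distance
    r: float = 12.5       # marker radius
    k: float = 35.0       # a.p. marker ellipse long axis
    h: float = 10.0       # a.p. image-center-to-marker distance
    d: float = 110.0      # true marker-to-hip-plane distance (calibrated)
    a: float = 200.0      # lateral image-center-to-marker distance
    b: float = 35.0       # lateral marker ellipse long axis
    m: float = 150.0      # inter-hip-center distance

    def __post_init__(self):
        for name in ("S", "r", "k", "h", "d", "a", "b", "m"):
            if getattr(self, name) <= 0 and name != "h" and name != "d":
                raise GeometryError(f"standard-model value {name} must be > 0")
        if self.h < 0 or self.d < 0:
            raise GeometryError("h and d must be >= 0")

    @property
    def device(self) -> DeviceSetup:
        return DeviceSetup(self.S, self.r)


@dataclass(frozen=True)
class ErrorCell:
    """One simulated scenario: uncorrected error at (rotation, offset)."""

    rotation_deg: float
    offset_mm: float
    absolute_error: float   # F_ref - F_rot, factor points (unrounded)
    relative_error: float   # 100 * absolute_error / F_ref, percent (unrounded)


def marker_height_standard(model: StandardModel, tol: float = 1e-4) -> float:
    """H_ECM of the standard model from the a.p. measurements (k, h)."""
    sol = marker_height_iterative(
        model.device, MarkerProjection(model.k, model.h, "antero-posterior"),
        tol=tol)
    return sol.height_mm


def reference_factor(model: StandardModel = StandardModel(),
                     tol: float = 1e-4) -> float:
    """Hip-plane factor of the standard model at zero rotation/offset."""
    H_ECM = marker_height_standard(model, tol)
    return factor_from_height(model.S, H_ECM - model.d)


def rotation_error(model: StandardModel, rotation_deg: float,
                   offset_mm: float, tol: float = 1e-4) -> ErrorCell:
    """Uncorrected-pipeline error for one (rotation, offset) scenario."""
    if not 0 <= rotation_deg < 90:
        raise GeometryError(
            f"rotation must be in [0, 90) deg, got {rotation_deg}")
    if offset_mm < 0:
        raise GeometryError(f"offset must be >= 0, got {offset_mm}")
    H_ECM = marker_height_standard(model, tol)
    F_ref = factor_from_height(model.S, H_ECM - model.d)
    al = math.radians(rotation_deg)
    y_rot = (model.d + offset_mm * math.sin(al)) / math.cos(al)
    F_rot = factor_from_height(model.S, H_ECM - y_rot)
    abs_err = F_ref - F_rot
    return ErrorCell(rotation_deg, offset_mm, abs_err, 100.0 * abs_err / F_ref)


def error_table(
    model: StandardModel = StandardModel(),
    rotations: Sequence[float] = DEFAULT_ROTATIONS,
    offsets: Sequence[float] = DEFAULT_OFFSETS,
    rounded: bool = False,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Error grid over rotations x offsets.

    Columns: ``rotation_deg`` plus ``abs_err_i{o}`` and ``rel_err_i{o}``
    per offset ``o``.  With ``rounded=True`` absolute errors are
    reported to 3 decimals and relative errors to 1 decimal, the
    precision used in the printed report.
    """
    H_ECM = marker_height_standard(model, tol)
    F_ref = factor_from_height(model.S, H_ECM - model.d)
    cols: dict = {"rotation_deg": list(rotations)}
    for o in offsets:
        key = f"{o:g}"
        abs_col, rel_col = [], []
        for rot in rotations:
            al = math.radians(rot)
            y_rot = (model.d + o * math.sin(al)) / math.cos(al)
            e = F_ref - factor_from_height(model.S, H_ECM - y_rot)
            abs_col.append(round(e, 3) if rounded else e)
            rel_col.append(round(100 * e / F_ref, 1) if rounded
                           else 100 * e / F_ref)
        cols[f"abs_err_i{key}"] = abs_col
        cols[f"rel_err_i{key}"] = rel_col
    order = (["rotation_deg"]
             + [f"abs_err_i{o:g}" for o in offsets]
             + [f"rel_err_i{o:g}" for o in offsets])
    return pd.DataFrame(cols)[order]


def threshold_scan(
    model: StandardModel = StandardModel(),
    threshold: float = 1.5,
    offsets: Sequence[float] = DEFAULT_OFFSETS,
    rotations: Sequence[float] = DEFAULT_ROTATIONS,
    tol: float = 1e-4,
) -> "dict[float, Optional[int]]":
    """First rotation (on the scanned grid) whose absolute error reaches
    ``threshold`` factor points, per offset; ``None`` if never reached."""
    if threshold <= 0:
        raise GeometryError(f"threshold must be > 0, got {threshold}")
    tab = error_table(model, rotations, offsets, rounded=False, tol=tol)
    out: dict = {}
    for o in offsets:
        col = tab[f"abs_err_i{o:g}"]
        hit = tab.loc[col >= threshold, "rotation_deg"]
        out[o] = None if hit.empty else int(hit.iloc[0])
    return out
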