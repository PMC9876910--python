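"""Measurement schema (JSON/CSV) and report serialisation.

The measurement schema carries everything the pipeline needs::

    {
      "device":  {"sdd_mm": 1150.0, "marker_radius_mm": 12.5},
      "ap":      {"image_center": [x, y], "marker_center": [x, y],
                  "right_hip": [x, y], "left_hip": [x, y],
                  "marker_long_axis_mm": ...},
      "lateral": {"image_center": [x, y], "marker_center": [x, y],
                  "right_hip": [x, y], "left_hip": [x, y],
                  "marker_long_axis_mm": ..., "facing": "left"|"right"}
    }

Coordinates are detector-plane millimetres with the origin at the
central beam, images viewed from the source; in the a.p. image the
patient's right is at negative x.  The CSV variant flattens the same
fields into one row per case (``ap_marker_center_x`` etc.).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Tuple, Union

import pandas as pd

from .errors import ValidationError
from .pipeline import APLandmarks, HipPlaneResult, LateralLandmarks
from .projection import DeviceSetup

__all__ = [
    "measurements_to_dict",
    "measurements_from_dict",
    "load_measurements",
    "save_measurements",
    "load_measurements_csv",
    "result_to_dict",
]

_POINTS = ("image_center", "marker_center", "right_hip", "left_hip")


def measurements_to_dict(setup: DeviceSetup, ap: APLandmarks,
                         lateral: LateralLandmarks) -> dict:
    return {
        "device": {
            "sdd_mm": setup.source_detector_distance_mm,
            "marker_radius_mm": setup.marker_radius_mm,
        },
        "ap": {
            **{p: list(getattr(ap, p)) for p in _POINTS},
            "marker_long_axis_mm": ap.marker_long_axis_mm,
        },
        "lateral": {
            **{p: list(getattr(lateral, p)) for p in _POINTS},
            "marker_long_axis_mm": lateral.marker_long_axis_mm,
            "facing": lateral.facing,
        },
    }


def measurements_from_dict(data: dict
                           ) -> Tuple[DeviceSetup, APLandmarks, LateralLandmarks]:
    try:
        dev = data["device"]
        setup = DeviceSetup(float(dev["sdd_mm"]),
                            float(dev["marker_radius_mm"]))
        ap_d = data["ap"]
        ap = APLandmarks(
            **{p: tuple(ap_d[p]) for p in _POINTS},
            marker_long_axis_mm=float(ap_d["marker_long_axis_mm"]))
        lat_d = data["lateral"]
        lat = LateralLandmarks(
            **{p: tuple(lat_d[p]) for p in _POINTS},
            marker_long_axis_mm=float(lat_d["marker_long_axis_mm"]),
            facing=lat_d["facing"])
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed measurement record: {exc}") from exc
    return setup, ap, lat


def load_measurements(path: Union[str, Path]
                      ) -> Tuple[DeviceSetup, APLandmarks, LateralLandmarks]:
    with open(path) as fh:
        return measurements_from_dict(json.load(fh))


def save_measurements(path: Union[str, Path], setup: DeviceSetup,
                      ap: APLandmarks, lateral: LateralLandmarks) -> None:
    with open(path, "w") as fh:
        json.dump(measurements_to_dict(setup, ap, lateral), fh, indent=2)


def _flatten(prefix: str, d: dict, row: dict) -> None:
    for key, val in d.items():
        if isinstance(val, list) and len(val) == 2:
            row[f"{prefix}_{key}_x"], row[f"{prefix}_{key}_y"] = val
        else:
            row[f"{prefix}_{key}"] = val


def measurements_to_row(setup: DeviceSetup, ap: APLandmarks,
                        lateral: LateralLandmarks) -> dict:
    d = measurements_to_dict(setup, ap, lateral)
    row: dict = {"sdd_mm": d["device"]["sdd_mm"],
                 "marker_radius_mm": d["device"]["marker_radius_mm"]}
    _flatten("ap", d["ap"], row)
    _flatten("lateral", d["lateral"], row)
    return row


def load_measurements_csv(path: Union[str, Path]):
    """Yield ``(setup, ap, lateral)`` per row of a flattened CSV."""
    df = pd.read_csv(path)
    for _, row in df.iterrows():
        data = {
            "device": {"sdd_mm": row["sdd_mm"],
                       "marker_radius_mm": row["marker_radius_mm"]},
            "ap": {
                **{p: [row[f"ap_{p}_x"], row[f"ap_{p}_y"]] for p in _POINTS},
                "marker_long_axis_mm": row["ap_marker_long_axis_mm"],
            },
            "lateral": {
                **{p: [row[f"lateral_{p}_x"], row[f"lateral_{p}_y"]]
                   for p in _POINTS},
                "marker_long_axis_mm": row["lateral_marker_long_axis_mm"],
                "facing": row["lateral_facing"],
            },
        }
        yield measurements_from_dict(data)


def result_to_dict(result: HipPlaneResult) -> dict:
    """JSON-serialisable report with all intermediate quantities."""
    return {
        "F_Hip": result.F_Hip,
        "H_Hip_mm": result.H_Hip,
        "H_ECM_mm": result.H_ECM,
        "alpha_deg": result.alpha_deg,
        "x_mm": result.x,
        "y_correction_mm": result.y_correction,
        "d_cal_mm": result.d_cal,
        "i_cal_mm": result.i_cal,
        "c_cal_mm": result.c_cal,
        "m_cal_mm": result.m_cal,
        "offset_direction": result.offset_direction,
        "rotation_direction": result.rotation_direction,
        "measurements": {
            "lateral": asdict(result.lateral),
            "ap": asdict(result.ap),
        },
        "marker_solutions": {
            "ap": asdict(result.ap_solution),
            "lateral": asdict(result.lateral_solution),
        },
        "n_outer_iterations": result.n_outer_iterations,
        "diagnostics": result.diagnostics,
    }
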