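"""CSV/JSON serialization of traces, curves and configs.

Dialects:
  * force trace CSV — ``time_s,f_n`` (one channel) or
    ``time_s,f1_n,f2_n,f3_n`` (three channels);
  * decoupled trace CSV — ``time_s,f_total_n,ex_m,ey_m``;
  * distraction curve CSV — ``distraction_mm,force_n``;
  * comparison CSV — ``step_mm,measured_n,predicted_n``;
  * Ogden parameters JSON — ``{"mu": ..., "alpha": ..., "d1": ...,
    "units": "Pa"|"MPa"}`` (mu in the tagged unit, d1 in its inverse).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, TraceError
from .metrology import ForceTrace
from .ogden import OgdenParams
from .predictor import DistractionCurve, SegmentGeometry
from .report import ComparisonTable
from .sensor_array import SensorArrayGeometry

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_curve_csv",
    "write_curve_csv",
    "read_comparison_csv",
    "load_ogden_params",
    "load_segment_geometry",
    "load_sensor_geometry",
]


def read_trace_csv(path) -> ForceTrace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise TraceError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if {"f1_n", "f2_n", "f3_n"} <= set(df.columns):
        values = df[["f1_n", "f2_n", "f3_n"]].to_numpy(dtype=float)
    elif "f_n" in df.columns:
        values = df["f_n"].to_numpy(dtype=float)
    else:
        raise TraceError(f"{path}: expected f_n or f1_n,f2_n,f3_n columns")
    rate = 1.0 / float(np.median(np.diff(t)))
    return ForceTrace(t, values, rate)


def write_trace_csv(trace: ForceTrace, path) -> None:
    if trace.n_channels == 1:
        df = pd.DataFrame({"time_s": trace.time, "f_n": trace.values})
    else:
        df = pd.DataFrame(
            {
                "time_s": trace.time,
                "f1_n": trace.values[:, 0],
                "f2_n": trace.values[:, 1],
                "f3_n": trace.values[:, 2],
            }
        )
    df.to_csv(path, index=False)


def read_curve_csv(path, provenance: str = "measured") -> DistractionCurve:
    df = pd.read_csv(path)
    missing = {"distraction_mm", "force_n"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    return DistractionCurve(
        df["distraction_mm"].to_numpy(dtype=float),
        df["force_n"].to_numpy(dtype=float),
        provenance,
    )


def write_curve_csv(curve: DistractionCurve, path) -> None:
    pd.DataFrame({"distraction_mm": curve.lengths_mm, "force_n": curve.forces_n}).to_csv(
        path, index=False
    )


def read_comparison_csv(path) -> ComparisonTable:
    df = pd.read_csv(path)
    return ComparisonTable(df)


def load_ogden_params(path) -> OgdenParams:
    cfg = json.loads(Path(path).read_text())
    units = cfg.get("units", "Pa")
    if units == "Pa":
        scale = 1.0
    elif units == "MPa":
        scale = 1e6
    else:
        raise ConfigError(f"unknown units tag {units!r} (use Pa or MPa)")
    return OgdenParams(
        mu=float(cfg["mu"]) * scale,
        alpha=float(cfg["alpha"]),
        d1=float(cfg.get("d1", 0.0)) / scale,
    )


def load_segment_geometry(path) -> SegmentGeometry:
    cfg = json.loads(Path(path).read_text())
    return SegmentGeometry(
        gauge_length=float(cfg["gauge_length_m"]),
        reference_area=float(cfg["reference_area_m2"]) if "reference_area_m2" in cfg else None,
        muscle_volume=float(cfg["muscle_volume_m3"]) if "muscle_volume_m3" in cfg else None,
    )


def load_sensor_geometry(path) -> SensorArrayGeometry:
    cfg = json.loads(Path(path).read_text())
    kwargs = {}
    if "ring_radius_m" in cfg:
        kwargs["ring_radius"] = float(cfg["ring_radius_m"])
    if "sensor_angles_rad" in cfg:
        kwargs["sensor_angles"] = tuple(float(a) for a in cfg["sensor_angles_rad"])
    return SensorArrayGeometry(**kwargs)
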