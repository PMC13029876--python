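"""Seeded fixture generators: every experiment in the study, on the desk.

Three scenario generators emulate the data streams of the in vivo pilot —
the 0–200 N dead-weight calibration ladder, the three-channel acute
distraction trace with exponential relaxation holds, and noisy uniaxial
stress–stretch data for constitutive identification — plus the packaged
single-subject measured-vs-predicted force table.  All generators are pure
functions of (spec, seed): the same spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .metrology import (
    DEFAULT_CUTOFF_HZ,
    DEFAULT_FILTER_ORDER,
    DEFAULT_RATE_HZ,
    CalibrationRun,
    ForceTrace,
    SensorErrorModel,
    lowpass_filter,
)
from .ogden import OgdenParams, uniaxial_true_stress
from .predictor import (
    DistractionCurve,
    DistractionProtocol,
    SegmentGeometry,
    predict_force_curve,
)
from .report import ComparisonTable
from .sensor_array import SensorArrayGeometry
from .relaxation import PronySeries

__all__ = [
    "FixtureSpec",
    "gen_calibration_dataset",
    "gen_drift_hold",
    "gen_invivo_trace",
    "gen_uniaxial_dataset",
    "table1_fixture",
]

_SCENARIOS = ("calibration", "invivo_trace", "uniaxial", "table1")


@dataclass(frozen=True)
class FixtureSpec:
    """Scenario tag, parameter overrides and the seed that fixes the bytes."""

    scenario: str = "calibration"
    seed: int = 42
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; pick from {_SCENARIOS}")

    def get(self, key, default):
        return self.overrides.get(key, default)


def _hysteresis_gap(load: float, model: SensorErrorModel) -> float:
    f = np.clip(load / model.full_scale, 0.0, 1.0)
    return 4.0 * model.hysteresis_fraction * model.full_scale * f * (1.0 - f)


def gen_calibration_dataset(spec: FixtureSpec) -> CalibrationRun:
    """Simulate a dead-weight ladder 0→200→0 N through the full sensor chain.

    Each load level is held for a few seconds; the raw noisy hold trace is
    low-pass filtered and its mean becomes the recorded reading, exactly as
    the benchtop campaign produces readings.  Drift accumulates over the
    campaign clock, the hysteresis offset follows the branch direction, and
    a per-repeat mounting offset emulates trial-to-trial variability.
    """
    model: SensorErrorModel = spec.get("error_model", SensorErrorModel(seed=spec.seed))
    levels = np.asarray(spec.get("levels_n", np.arange(0.0, 200.0 + 1e-9, 20.0)))
    n_repeats = int(spec.get("n_repeats", 3))
    hold_s = float(spec.get("hold_s", 5.0))
    rate = float(spec.get("rate_hz", DEFAULT_RATE_HZ))
    repeat_offset_sd = float(spec.get("repeat_offset_sd_n", 0.15))
    rng = np.random.default_rng(spec.seed)

    n_hold = int(round(hold_s * rate))
    t_clock = 0.0
    loading = np.empty((n_repeats, levels.size))
    unloading = np.empty((n_repeats, levels.size))
    for r in range(n_repeats):
        offset_r = rng.normal(0.0, repeat_offset_sd) if repeat_offset_sd > 0 else 0.0
        for branch, sign, store in (("up", -0.5, loading), ("down", +0.5, unloading)):
            branch_levels = levels if branch == "up" else levels[::-1]
            for load in branch_levels:
                raw = load + (
                    rng.normal(0.0, model.noise_sd, n_hold) if model.noise_sd > 0 else 0.0
                )
                trace = ForceTrace(np.arange(n_hold) / rate, np.broadcast_to(raw, (n_hold,)).astype(float), rate)
                reading = float(lowpass_filter(trace).values.mean())
                t_mid = t_clock + 0.5 * hold_s
                reading += model.drift_rate * t_mid / 3600.0
                reading += sign * _hysteresis_gap(load, model)
                reading += offset_r
                j = int(np.argmin(np.abs(levels - load)))
                store[r, j] = reading
                t_clock += hold_s
    return CalibrationRun(levels, loading, levels[::-1], unloading[:, ::-1])


def gen_drift_hold(spec: FixtureSpec, load_n: float = 100.0, duration_s: float = 3600.0) -> ForceTrace:
    """One-hour constant-load hold for the zero-point-drift check (filtered)."""
    from .metrology import simulate_sensor_trace

    model: SensorErrorModel = spec.get("error_model", SensorErrorModel(seed=spec.seed))
    rate = float(spec.get("rate_hz", DEFAULT_RATE_HZ))
    trace = simulate_sensor_trace(
        lambda t: load_n, model, duration_s, rate, rng=np.random.default_rng(spec.seed)
    )
    return lowpass_filter(trace)


def gen_invivo_trace(spec: FixtureSpec) -> ForceTrace:
    """Three-channel acute distraction trace: ramps, peaks and relaxations.

    Step peaks follow the equivalent-cylinder force curve for the spec's
    geometry and material; each 2-min hold decays along a Prony series; the
    axial force is split onto the three cells through the static
    distribution law at the spec's (possibly time-varying) eccentricity, and
    per-channel white noise is added on top.
    """
    params: OgdenParams = spec.get("ogden_params", OgdenParams())
    geom: SegmentGeometry = spec.get("segment_geometry", SegmentGeometry())
    array_geom: SensorArrayGeometry = spec.get("array_geometry", SensorArrayGeometry())
    protocol: DistractionProtocol = spec.get("protocol", DistractionProtocol())
    rate = float(spec.get("rate_hz", DEFAULT_RATE_HZ))
    ramp_s = float(spec.get("ramp_s", 1.0))
    hold_s = float(spec.get("hold_s", 120.0))
    tau_s = float(spec.get("tau_s", 30.0))
    equilibrium_ratio = float(spec.get("equilibrium_ratio", 0.824))
    noise_sd = float(spec.get("channel_noise_sd_n", 0.1))
    eccentricity = spec.get("eccentricity_m", (0.01, 0.005))
    rng = np.random.default_rng(spec.seed)

    peaks = predict_force_curve(protocol, geom, params).forces_n
    n_ramp, n_hold = int(round(ramp_s * rate)), int(round(hold_s * rate))
    segments = []
    f_prev = 0.0
    for peak in peaks:
        ramp = np.linspace(f_prev, peak, n_ramp, endpoint=False)
        t_hold = np.arange(n_hold) / rate
        f_inf = equilibrium_ratio * peak
        hold = PronySeries(f_inf, peak, ((1.0, tau_s),))(t_hold)
        segments.extend([ramp, hold])
        f_prev = hold[-1]
    axial = np.concatenate(segments)
    n = axial.size
    t = np.arange(n) / rate

    p = array_geom.positions
    r2 = array_geom.ring_radius**2
    if callable(eccentricity):
        e = np.asarray([eccentricity(ti) for ti in t], dtype=float)  # (n, 2)
        weights = 1.0 / 3.0 + 2.0 * (e @ p.T) / (3.0 * r2)
    else:
        e = np.asarray(eccentricity, dtype=float)
        weights = np.broadcast_to(1.0 / 3.0 + 2.0 * (p @ e) / (3.0 * r2), (n, 3))
    channels = axial[:, None] * weights
    if noise_sd > 0:
        channels = channels + rng.normal(0.0, noise_sd, size=channels.shape)
    return ForceTrace(t, channels, rate)


def gen_uniaxial_dataset(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noisy uniaxial (λ, σ) pairs from the Ogden model.

    Multiplicative noise (default 2% SD) on a λ ∈ [1, 1.1] grid — the
    stretch range the 40 mm protocol actually explores on the effective
    gauge length.
    """
    params: OgdenParams = spec.get("ogden_params", OgdenParams())
    n = int(spec.get("n_points", 20))
    lam = np.asarray(spec.get("stretch_grid", np.linspace(1.0, 1.1, n)))
    noise = float(spec.get("relative_noise_sd", 0.02))
    rng = np.random.default_rng(spec.seed)
    sigma = uniaxial_true_stress(lam, params)
    if noise > 0:
        sigma = sigma * (1.0 + rng.normal(0.0, noise, size=lam.size))
    return lam, sigma


def table1_fixture() -> ComparisonTable:
    """The packaged single-subject measured-vs-predicted force table.

    Six distraction steps (5–40 mm) with measured and model-predicted
    forces; the absolute-error column is recomputed on load and checked
    against the shipped one to printed rounding.
    """
    with resources.files("drfkit.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return ComparisonTable(df)


def table1_curves() -> tuple[DistractionCurve, DistractionCurve]:
    """The fixture split into (measured, predicted) distraction curves."""
    t = table1_fixture().data
    measured = DistractionCurve(t["step_mm"].to_numpy(), t["measured_n"].to_numpy(), "measured")
    predicted = DistractionCurve(t["step_mm"].to_numpy(), t["predicted_n"].to_numpy(), "predicted")
    return measured, predicted
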