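"""Sensor-signal simulation, filtering and benchtop calibration metrology.

The acquisition chain is characterised on the bench before any in vivo use:
dead weights step the load from 0 to 200 N and back, repeated several times,
and the ladder yields linearity (OLS R²), hysteresis (max loading/unloading
gap as % of full scale), repeatability (half-range across repeats) and, from
a one-hour 100 N hold, zero-point drift.  The combined standard uncertainty
is propagated per GUM: each budget component contributes
``u_i = magnitude / divisor`` (divisor √3 for rectangular limits, the stated
coverage factor for normally distributed ones) and the expanded uncertainty
is ``U = k·sqrt(Σ u_i²)``.

The simulator in this module produces traces with white noise, linear drift
and a direction-dependent hysteresis offset so the whole simulate → filter →
fit chain can be exercised without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

from .errors import ConfigError, FitError, TraceError

__all__ = [
    "ForceTrace",
    "SensorErrorModel",
    "CalibrationRun",
    "CalibrationReport",
    "UncertaintyComponent",
    "UncertaintyBudget",
    "simulate_sensor_trace",
    "lowpass_filter",
    "fit_linearity",
    "hysteresis_error",
    "zero_drift",
    "repeatability",
    "gum_expanded_uncertainty",
    "analyze_calibration",
    "default_uncertainty_budget",
]

#: Default Butterworth settings: 4th order, 5 Hz cutoff at 100 Hz sampling.
DEFAULT_FILTER_ORDER = 4
DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_RATE_HZ = 100.0


@dataclass(frozen=True)
class ForceTrace:
    """A uniformly sampled force-time signal, one or three channels.

    ``values`` has shape (n,) for a single channel or (n, 3) for the
    three-cell array.
    """

    time: np.ndarray
    values: np.ndarray
    sampling_rate: float
    filtered: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size < 2:
            raise TraceError("time must be a 1-d array with >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TraceError("time must be strictly increasing")
        if np.ptp(dt) > 1e-9:
            raise TraceError("sampling interval must be constant to within 1e-9 s")
        if v.shape[0] != t.size:
            raise TraceError("values and time length mismatch")
        if v.ndim == 2 and v.shape[1] != 3:
            raise TraceError("multi-channel traces must have exactly 3 channels")
        if v.ndim > 2:
            raise TraceError("values must be 1- or 2-dimensional")

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel_sum(self) -> np.ndarray:
        """Total axial force per sample (the Eq.-style sum for 3 channels)."""
        return self.values if self.values.ndim == 1 else self.values.sum(axis=1)


@dataclass(frozen=True)
class SensorErrorModel:
    """Additive error model of one load cell.

    noise_sd in N, drift_rate in N/h, hysteresis_fraction as a fraction of
    ``full_scale`` (default 500 N rated capacity).
    """

    noise_sd: float = 0.25
    drift_rate: float = 0.2
    hysteresis_fraction: float = 0.001
    full_scale: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.noise_sd, self.drift_rate, self.hysteresis_fraction) < 0:
            raise ConfigError("error magnitudes must be >= 0")
        if not self.full_scale > 0:
            raise ConfigError("full_scale must be > 0")


IDEAL_SENSOR = SensorErrorModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CalibrationRun:
    """A loading/unloading dead-weight ladder with repeats.

    ``measured_loading``/``measured_unloading`` have shape
    (n_repeats, n_levels) matching the applied-load vectors.
    """

    applied_loading: np.ndarray
    measured_loading: np.ndarray
    applied_unloading: np.ndarray | None = None
    measured_unloading: np.ndarray | None = None

    def __post_init__(self) -> None:
        al = np.atleast_1d(np.asarray(self.applied_loading, dtype=float))
        ml = np.atleast_2d(np.asarray(self.measured_loading, dtype=float))
        object.__setattr__(self, "applied_loading", al)
        object.__setattr__(self, "measured_loading", ml)
        if np.any(np.diff(al) < 0):
            raise ValueError("loading branch must be monotone non-decreasing")
        if ml.shape[1] != al.size:
            raise ValueError("measured_loading shape does not match applied_loading")
        if self.applied_unloading is not None:
            au = np.atleast_1d(np.asarray(self.applied_unloading, dtype=float))
            mu = np.atleast_2d(np.asarray(self.measured_unloading, dtype=float))
            object.__setattr__(self, "applied_unloading", au)
            object.__setattr__(self, "measured_unloading", mu)
            if np.any(np.diff(au) > 0):
                raise ValueError("unloading branch must be monotone non-increasing")
            if mu.shape[1] != au.size:
                raise ValueError("measured_unloading shape does not match applied_unloading")

    @property
    def n_repeats(self) -> int:
        return self.measured_loading.shape[0]


@dataclass(frozen=True)
class CalibrationReport:
    """Summary metrology of one benchtop calibration campaign."""

    r_squared: float
    slope: float
    intercept: float
    max_hysteresis_error_pct_fs: float
    zero_drift_n: float
    repeatability_halfwidth_n: float
    expanded_uncertainty_n: float
    coverage_factor: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        for name in (
            "max_hysteresis_error_pct_fs",
            "zero_drift_n",
            "repeatability_halfwidth_n",
            "expanded_uncertainty_n",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "max_hysteresis_error_pct_fs": self.max_hysteresis_error_pct_fs,
            "zero_drift_n": self.zero_drift_n,
            "repeatability_halfwidth_n": self.repeatability_halfwidth_n,
            "expanded_uncertainty_n": self.expanded_uncertainty_n,
            "coverage_factor": self.coverage_factor,
        }


@dataclass(frozen=True)
class UncertaintyComponent:
    """One GUM budget line: u = magnitude / divisor."""

    name: str
    magnitude: float
    distribution: str = "rectangular"
    divisor: float | None = None

    def standard_uncertainty(self) -> float:
        if self.magnitude < 0:
            raise ConfigError("component magnitude must be >= 0")
        if self.divisor is not None:
            return self.magnitude / self.divisor
        if self.distribution == "rectangular":
            return self.magnitude / np.sqrt(3.0)
        if self.distribution == "normal":
            return self.magnitude  # magnitude already a standard uncertainty
        raise ConfigError(f"unknown distribution tag {self.distribution!r}")


@dataclass(frozen=True)
class UncertaintyBudget:
    components: tuple[UncertaintyComponent, ...]

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ConfigError("uncertainty budget needs at least one component")


def default_uncertainty_budget() -> UncertaintyBudget:
    """Default budget from the printed calibration bounds.

    Noise 0.15 N, drift 0.2 N and hysteresis 0.2 N (0.1% of full scale at a
    200 N working load), all treated as rectangular limits.  This is one
    plausible composition of the budget, fully overridable.
    """
    return UncertaintyBudget(
        (
            UncertaintyComponent("noise_floor", 0.15),
            UncertaintyComponent("zero_drift", 0.2),
            UncertaintyComponent("hysteresis", 0.2),
        )
    )


def simulate_sensor_trace(
    true_force_fn,
    model: SensorErrorModel,
    duration: float,
    rate: float = DEFAULT_RATE_HZ,
    *,
    rng: np.random.Generator | None = None,
) -> ForceTrace:
    """Sample a true force history through the sensor error model.

    reading(t) = F(t) + white noise + drift_rate·t + hysteresis offset.

    The hysteresis offset follows the loop direction (sign of dF/dt, held
    through flat segments) with a closed-loop gap 4·h·FS·f(1−f), f = F/FS:
    zero at the loop endpoints, maximal mid-loop.  Reproducible for a fixed
    ``model.seed``.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be > 0")
    rng = rng or np.random.default_rng(model.seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    f_true = np.asarray(true_force_fn(t), dtype=float) * np.ones_like(t)
    values = f_true.copy()
    if model.noise_sd > 0:
        values += rng.normal(0.0, model.noise_sd, size=n)
    values += model.drift_rate * t / 3600.0
    if model.hysteresis_fraction > 0:
        d = np.sign(np.diff(f_true, prepend=f_true[0]))
        # hold the last movement direction through flat segments
        last = 1.0
        direction = np.empty(n)
        for i, s in enumerate(d):
            if s != 0:
                last = s
            direction[i] = last
        frac = np.clip(f_true / model.full_scale, 0.0, 1.0)
        gap = 4.0 * model.hysteresis_fraction * model.full_scale * frac * (1.0 - frac)
        values += -0.5 * direction * gap  # loading reads low, unloading high
    return ForceTrace(t, values, rate, filtered=False)


def lowpass_filter(
    trace: ForceTrace,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> ForceTrace:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    Zero-phase filtering preserves the timing of distraction steps, which
    matters when pairing peaks with actuator events; the analysis is offline
    so the non-causal pass is acceptable.  DC gain is exactly 1.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ConfigError(f"cutoff must lie in (0, {nyquist:g}) Hz, got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.values, axis=0)
    return replace(trace, values=filtered, filtered=True)


def fit_linearity(run: CalibrationRun) -> tuple[float, float, float]:
    """OLS fit of measured vs applied on the pooled loading branch.

    Returns (slope, intercept, R²) with R² = 1 − SS_res/SS_tot.
    """
    if np.unique(run.applied_loading).size < 3:
        raise FitError("need >= 3 distinct load levels for a linearity fit")
    x = np.tile(run.applied_loading, run.n_repeats)
    y = run.measured_loading.ravel()
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def hysteresis_error(run: CalibrationRun, full_scale: float) -> float:
    """Max loading/unloading branch gap at matched levels, % of full scale."""
    if run.applied_unloading is None:
        raise ValueError("calibration run has no unloading branch")
    up_mean = run.measured_loading.mean(axis=0)
    down_mean = run.measured_unloading.mean(axis=0)
    worst = 0.0
    for j, load in enumerate(run.applied_loading):
        match = np.isclose(run.applied_unloading, load)
        if match.any():
            gap = abs(up_mean[j] - down_mean[match].mean())
            worst = max(worst, gap)
    return 100.0 * worst / full_scale


def zero_drift(trace: ForceTrace, window_s: float = 60.0) -> float:
    """|mean of the final window − mean of the first window| of a hold (N)."""
    if trace.duration < 120.0:
        raise TraceError("zero-drift hold must be at least 2 min long")
    n_win = int(round(window_s * trace.sampling_rate))
    v = trace.channel_sum() if trace.n_channels == 3 else trace.values
    return float(abs(v[-n_win:].mean() - v[:n_win].mean()))


def repeatability(run: CalibrationRun) -> float:
    """Max over load levels of half the range across repeats (N)."""
    if run.n_repeats < 2:
        raise ValueError("repeatability needs >= 2 repeats")
    branches = [run.measured_loading]
    if run.measured_unloading is not None:
        branches.append(run.measured_unloading)
    half_ranges = [0.5 * np.ptp(m, axis=0).max() for m in branches]
    return float(max(half_ranges))


def gum_expanded_uncertainty(budget: UncertaintyBudget, k: float = 2.0) -> float:
    """Expanded uncertainty U = k·sqrt(Σ u_i²) (N)."""
    u = np.array([c.standard_uncertainty() for c in budget.components])
    return float(k * np.sqrt(np.sum(u**2)))


def analyze_calibration(
    run: CalibrationRun,
    full_scale: float,
    *,
    drift_trace: ForceTrace | None = None,
    budget: UncertaintyBudget | None = None,
    k: float = 2.0,
) -> CalibrationReport:
    """Bundle the ladder metrics (and optional drift hold) into one report."""
    slope, intercept, r2 = fit_linearity(run)
    hyst = hysteresis_error(run, full_scale) if run.applied_unloading is not None else 0.0
    drift = zero_drift(drift_trace) if drift_trace is not None else 0.0
    rep = repeatability(run) if run.n_repeats >= 2 else 0.0
    budget = budget or default_uncertainty_budget()
    return CalibrationReport(
        r_squared=r2,
        slope=slope,
        intercept=intercept,
        max_hysteresis_error_pct_fs=hyst,
        zero_drift_n=drift,
        repeatability_halfwidth_n=rep,
        expanded_uncertainty_n=gum_expanded_uncertainty(budget, k),
        coverage_factor=k,
    )
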