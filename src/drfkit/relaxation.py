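"""Post-step viscoelastic stress relaxation of the soft-tissue envelope.

Living muscle and fascia are viscoelastic: after each acute distraction step
the force peaks and then decays toward a static equilibrium during the hold
(two minutes in the acute protocol).  The decay is represented by a
normalized Prony (exponential) series

    F(t) = F_inf + (F_peak − F_inf) · Σ g_i · exp(−t/τ_i),   Σ g_i = 1,

with dimensionless amplitudes g_i and time constants τ_i.  One term is the
default and two the maximum — more terms invite the non-unique
identification that single-subject data cannot support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitError, TraceError
from .metrology import ForceTrace

__all__ = [
    "PronySeries",
    "StepHoldTrace",
    "simulate_step_hold",
    "fit_prony",
    "extract_peak_equilibrium",
]


@dataclass(frozen=True)
class PronySeries:
    """Normalized exponential relaxation from F_peak to F_inf.

    ``terms`` is a tuple of (g_i, tau_i) with g_i > 0, tau_i > 0 (s) and
    Σ g_i = 1.
    """

    f_inf: float
    f_peak: float
    terms: tuple[tuple[float, float], ...] = ((1.0, 30.0),)

    def __post_init__(self) -> None:
        g = np.array([t[0] for t in self.terms])
        tau = np.array([t[1] for t in self.terms])
        if np.any(g <= 0) or np.any(tau <= 0):
            raise ValueError("Prony amplitudes and time constants must be > 0")
        if not np.isclose(g.sum(), 1.0, atol=1e-9):
            raise ValueError(f"Prony amplitudes must sum to 1, got {g.sum()}")
        if self.f_inf > self.f_peak:
            raise ValueError("equilibrium force cannot exceed the peak force")

    def __call__(self, t) -> np.ndarray:
        """Evaluate F(t) with t measured from the peak (s)."""
        t = np.asarray(t, dtype=float)
        decay = sum(g * np.exp(-t / tau) for g, tau in self.terms)
        return self.f_inf + (self.f_peak - self.f_inf) * decay


@dataclass(frozen=True)
class StepHoldTrace:
    """A single-channel force trace covering one step and its hold.

    ``step_time`` (s, on the trace clock) marks the actuation instant; the
    hold runs from the post-step peak to the end of the trace.
    """

    trace: ForceTrace
    step_time: float = 0.0
    hold_duration: float = 120.0

    def __post_init__(self) -> None:
        if self.trace.n_channels != 1:
            raise TraceError("step-hold analysis expects a single-channel trace")
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be > 0")

    def hold_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, f) of the hold, with t re-zeroed at the step."""
        mask = self.trace.time >= self.step_time
        return self.trace.time[mask] - self.step_time, self.trace.values[mask]


def simulate_step_hold(
    prony: PronySeries,
    duration: float = 120.0,
    rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StepHoldTrace:
    """Synthesize one relaxation hold: F(t) = Prony decay + white noise."""
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    f = prony(t)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=n)
    return StepHoldTrace(ForceTrace(t, f, rate), step_time=0.0, hold_duration=duration)


def fit_prony(trace: StepHoldTrace, n_terms: int = 1) -> tuple[PronySeries, dict]:
    """Nonlinear least squares for (F_inf, g_i, τ_i) on one hold.

    Starts from a log-spaced τ grid (multi-start) and keeps the best
    converged solution.  A fitted τ exceeding the hold duration is flagged
    in the diagnostics rather than silently trusted — the data then do not
    constrain the equilibrium.
    """
    if n_terms not in (1, 2):
        raise ValueError("n_terms must be 1 or 2")
    t, f = trace.hold_segment()
    if t.size < 10:
        raise FitError("need at least 10 samples in the hold")
    hold = float(t[-1] - t[0])
    f_peak0 = float(f[: max(1, t.size // 100)].mean())
    f_inf0 = float(f[-max(1, t.size // 10):].mean())
    amp0 = f_peak0 - f_inf0

    def model(x):
        f_inf = x[0]
        amps = x[1 : 1 + n_terms]
        taus = np.exp(x[1 + n_terms :])
        return f_inf + sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))

    def residuals(x):
        return model(x) - f

    best = None
    tau_grid = np.geomspace(hold / 40.0, hold, 4)
    starts = (
        [[tau] for tau in tau_grid]
        if n_terms == 1
        else [[a, b] for a in tau_grid for b in tau_grid if a < b]
    )
    for taus0 in starts:
        x0 = np.concatenate([[f_inf0], np.full(n_terms, max(amp0, 1e-6) / n_terms), np.log(taus0)])
        lb = np.concatenate([[-np.inf], np.zeros(n_terms), np.full(n_terms, np.log(1e-3))])
        ub = np.concatenate([[np.inf], np.full(n_terms, np.inf), np.full(n_terms, np.log(1e5))])
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("Prony fit failed to converge from all starts")
    f_inf = float(best.x[0])
    amps = np.maximum(best.x[1 : 1 + n_terms], 1e-300)
    taus = np.exp(best.x[1 + n_terms :])
    total = float(amps.sum())
    if total <= 1e-12:
        warnings.warn("no measurable relaxation; returning a degenerate single term")
        series = PronySeries(f_inf, f_inf, ((1.0, max(hold, 1.0)),))
        amps = np.array([0.0])
    else:
        order = np.argsort(taus)
        terms = tuple((float(amps[i] / total), float(taus[i])) for i in order)
        series = PronySeries(f_inf, f_inf + total, terms)
    diagnostics = {
        "rmse_n": float(np.sqrt(2.0 * best.cost / t.size)),
        "tau_exceeds_hold": bool(np.any(taus > hold)),
        "hold_duration_s": hold,
        "nfev": best.nfev,
    }
    if diagnostics["tau_exceeds_hold"]:
        warnings.warn(
            "fitted time constant exceeds the hold duration; equilibrium is extrapolated"
        )
    return series, diagnostics


def extract_peak_equilibrium(
    trace: StepHoldTrace, *, peak_window_s: float = 1.0, tail_window_s: float = 10.0
) -> tuple[float, float]:
    """(F_peak, F_equilibrium) of one hold.

    Peak = max over the first ``peak_window_s`` after the step; equilibrium
    = mean over the final ``tail_window_s``.  Both windows are conventions
    (configurable), the protocol itself only fixes the 2-min hold.
    """
    t, f = trace.hold_segment()
    if t[-1] - t[0] < 20.0:
        raise TraceError("hold must be at least 20 s for peak/equilibrium extraction")
    peak = float(f[t <= t[0] + peak_window_s].max())
    tail = f[t >= t[-1] - tail_window_s]
    equilibrium = float(tail.mean())
    noise = float(tail.std())
    if peak - equilibrium < 3.0 * noise:
        warnings.warn("low signal-to-noise: peak barely exceeds the tail scatter")
    return peak, equilibrium
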