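"""Reduced-order prediction of distraction resisting force (DRF).

The soft-tissue envelope bridging the osteotomy is reduced to an equivalent
incompressible Ogden cylinder: an effective gauge length L0 and reference
cross-section A0 (optionally derived from a segmented muscle volume,
A0 = V/L0).  Pulling the distal end by δ imposes the uniaxial stretch
λ = 1 + δ/L0 and the reaction force is

    F(δ) = A0 · P(λ),

with P the uniaxial engineering stress of the first-order Ogden model
(force is conventionally reported per reference area; the true-stress-on-
current-area alternative, which differs by a factor λ, is exposed via a
flag).  A displacement-driven total-Lagrangian chain of nonlinear bar
elements provides an independent finite-element oracle for the closed form
and supports heterogeneous areas; its volumetric behaviour follows the
penalty parameter D1 when one is set.

The interface accepts a muscle volume so that a full 3-D patient-specific
backend can replace the cylinder without changing callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import optimize

from .errors import FitError, GeometryError
from .ogden import (
    OgdenParams,
    uniaxial_engineering_stress,
    uniaxial_tangent_stiffness,
    uniaxial_true_stress,
)

__all__ = [
    "SegmentGeometry",
    "DistractionProtocol",
    "DistractionCurve",
    "predict_force_curve",
    "bar_fe_solve",
    "calibrate_geometry",
]

#: Effective cylinder defaults calibrated against the packaged
#: measured-vs-predicted force table; effective values, not anatomy.
DEFAULT_GAUGE_LENGTH = 0.99
DEFAULT_REFERENCE_AREA = 4.7e-4

#: Protocol steps (mm) of the acute 40 mm distraction experiment.
DEFAULT_STEPS_MM = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0)


@dataclass(frozen=True)
class SegmentGeometry:
    """Equivalent-cylinder geometry of the soft-tissue segment.

    Either give (gauge_length, reference_area) directly or a muscle volume,
    in which case A0 = V/L0.
    """

    gauge_length: float = DEFAULT_GAUGE_LENGTH
    reference_area: float | None = DEFAULT_REFERENCE_AREA
    muscle_volume: float | None = None

    def __post_init__(self) -> None:
        if not self.gauge_length > 0:
            raise GeometryError(f"gauge_length must be > 0, got {self.gauge_length}")
        if self.muscle_volume is not None:
            derived = self.muscle_volume / self.gauge_length
            if self.reference_area is not None and not np.isclose(
                self.reference_area, derived, rtol=1e-9
            ):
                raise GeometryError("reference_area inconsistent with muscle_volume / gauge_length")
            object.__setattr__(self, "reference_area", derived)
        if self.reference_area is None or not self.reference_area > 0:
            raise GeometryError("reference_area must be > 0 (or derivable from muscle_volume)")


@dataclass(frozen=True)
class DistractionProtocol:
    """Ordered cumulative distraction magnitudes (m)."""

    step_lengths: tuple[float, ...] = tuple(s * 1e-3 for s in DEFAULT_STEPS_MM)

    def __post_init__(self) -> None:
        s = np.asarray(self.step_lengths, dtype=float)
        if s.size == 0 or np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("step lengths must be positive and strictly increasing")

    @property
    def total_length(self) -> float:
        return float(self.step_lengths[-1])

    @property
    def steps_mm(self) -> np.ndarray:
        return np.asarray(self.step_lengths, dtype=float) * 1e3


@dataclass(frozen=True)
class DistractionCurve:
    """Force vs distraction length, measured or predicted."""

    lengths_mm: np.ndarray
    forces_n: np.ndarray
    provenance: str = "predicted"

    def __post_init__(self) -> None:
        l = np.atleast_1d(np.asarray(self.lengths_mm, dtype=float))
        f = np.atleast_1d(np.asarray(self.forces_n, dtype=float))
        object.__setattr__(self, "lengths_mm", l)
        object.__setattr__(self, "forces_n", f)
        if l.shape != f.shape:
            raise ValueError("lengths and forces must have the same shape")
        if np.any(np.diff(l) <= 0):
            raise ValueError("distraction lengths must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("forces must be non-negative")

    def __len__(self) -> int:
        return self.lengths_mm.size


def predict_force_curve(
    protocol: DistractionProtocol,
    geom: SegmentGeometry,
    params: OgdenParams,
    *,
    use_true_stress: bool = False,
    provenance: str = "predicted",
) -> DistractionCurve:
    """Closed-form DRF curve of the equivalent cylinder.

    F(δ) = A0·P(1 + δ/L0); with ``use_true_stress`` the Cauchy stress acts
    on the current (necked) area A0/λ, which gives the identical force — the
    flag instead switches to σ·A0, i.e. true stress on the reference area,
    for comparison with solvers that report reactions that way.
    """
    delta = np.asarray(protocol.step_lengths, dtype=float)
    lam = 1.0 + delta / geom.gauge_length
    stress = (
        uniaxial_true_stress(lam, params)
        if use_true_stress
        else uniaxial_engineering_stress(lam, params)
    )
    return DistractionCurve(delta * 1e3, geom.reference_area * stress, provenance)


def _penalty_transverse_stretch(lam: float, params: OgdenParams) -> float:
    """Transverse stretch of a nearly incompressible bar at axial stretch lam.

    The element energy uses the isochoric split so the reference state is
    stress free, matching how displacement-based solvers consume
    (mu, alpha, D1):

        Psi = (mu/a)((J^(-1/3)lam)^a + 2(J^(-1/3)q)^a - 3) + (1/d1)(J-1)^2

    with J = lam q^2.  The transverse equilibrium dPsi/dq = 0 reduces to

        (2mu/(3q)) J^(-a/3) (q^a - lam^a) + (4 lam q / d1)(J - 1) = 0,

    solved by bracketed root finding around the incompressible limit.
    """
    mu, a, d1 = params.mu, params.alpha, params.d1

    def g(q):
        j = lam * q * q
        return (2.0 * mu / (3.0 * q)) * j ** (-a / 3.0) * (q**a - lam**a) + (
            4.0 * lam * q / d1
        ) * (j - 1.0)

    if lam == 1.0:
        return 1.0
    q0 = lam**-0.5  # incompressible limit
    lo, hi = 0.9 * q0, 1.2 * q0
    tries = 0
    while g(lo) * g(hi) > 0:
        lo *= 0.95
        hi *= 1.05
        tries += 1
        if tries > 60:
            raise FitError("penalty transverse equilibrium not bracketed")
    return float(optimize.brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16))


def _element_engineering_stress(
    lam: float, params: OgdenParams, volumetric: str = "incompressible"
) -> float:
    """Axial engineering stress of one bar element, P = dPsi/dlam."""
    if volumetric == "incompressible":
        return uniaxial_engineering_stress(lam, params)
    if params.d1 <= 0:
        raise ValueError("penalty volumetric behaviour needs d1 > 0")
    mu, a, d1 = params.mu, params.alpha, params.d1
    q = _penalty_transverse_stretch(lam, params)
    j = lam * q * q
    return float(
        (2.0 * mu / (3.0 * lam)) * j ** (-a / 3.0) * (lam**a - q**a)
        + (2.0 * q * q / d1) * (j - 1.0)
    )


def _element_tangent(lam: float, params: OgdenParams, volumetric: str = "incompressible") -> float:
    if volumetric == "incompressible":
        return uniaxial_tangent_stiffness(lam, params, engineering=True)
    h = 1e-5 * max(lam, 1.0)
    return (
        _element_engineering_stress(lam + h, params, volumetric)
        - _element_engineering_stress(lam - h, params, volumetric)
    ) / (2.0 * h)


def bar_fe_solve(
    protocol: DistractionProtocol,
    geom: SegmentGeometry,
    params: OgdenParams,
    n_elements: int = 64,
    *,
    areas: np.ndarray | None = None,
    volumetric: str = "incompressible",
    newton_tol: float = 1e-10,
    max_iter: int = 50,
) -> DistractionCurve:
    """Displacement-driven Newton solve of a chain of Ogden bar elements.

    Total-Lagrangian uniaxial bars of equal reference length L0/n with a
    consistent tangent; ``areas`` may vary per element.  The proximal node
    is fixed, the distal node displaced through the protocol steps (with
    step halving on Newton divergence), and the reaction at the distal node
    is reported.  For homogeneous properties the solution is the uniform
    stretch, identical to the closed form.

    ``volumetric`` selects the element response: ``"incompressible"``
    (exact, the default — the analytic pipeline's convention) or
    ``"penalty"``, the nearly incompressible form with bulk modulus 2/d1
    that mimics how displacement-based 3-D solvers regularise the
    constraint.  The penalty element is softer by O(mu/K), a percent-level
    systematic, so it is a consistency check rather than an equal-digits
    oracle.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    a = (
        np.full(n_elements, geom.reference_area, dtype=float)
        if areas is None
        else np.asarray(areas, dtype=float)
    )
    if a.size != n_elements or np.any(a <= 0):
        raise ValueError("areas must be positive, one per element")
    l0 = geom.gauge_length / n_elements
    # internal node displacements; end node prescribed
    u_int = np.zeros(n_elements - 1)
    forces = []
    u_prev_end = 0.0
    for delta in protocol.step_lengths:
        u_int, reaction = _advance_step(
            u_int, u_prev_end, delta, a, l0, params, volumetric, newton_tol, max_iter
        )
        u_prev_end = delta
        forces.append(reaction)
    return DistractionCurve(
        np.asarray(protocol.step_lengths) * 1e3, np.asarray(forces), "surrogate"
    )


def _advance_step(u_int, u_start, u_end, areas, l0, params, volumetric, tol, max_iter):
    """March the end displacement from u_start to u_end with halving."""
    n_el = areas.size
    target = u_end
    current = u_start
    step = target - current
    u = u_int.copy()
    while current < target - 1e-15:
        trial_end = min(current + step, target)
        scale = trial_end / max(current, 1e-30) if current > 0 else None
        u_trial = u * scale if scale is not None else np.linspace(
            trial_end / n_el, trial_end * (n_el - 1) / n_el, n_el - 1
        )
        ok, u_new = _newton(u_trial, trial_end, areas, l0, params, volumetric, tol, max_iter)
        if ok:
            u = u_new
            current = trial_end
        else:
            step *= 0.5
            if step < 1e-12:
                raise FitError("bar FE Newton failed to converge even with load halving")
    lam_last = 1.0 + (target - (u[-1] if n_el > 1 else 0.0)) / l0
    reaction = areas[-1] * _element_engineering_stress(lam_last, params, volumetric)
    return u, reaction


def _newton(u_int, u_end, areas, l0, params, volumetric, tol, max_iter):
    n_el = areas.size
    if n_el == 1:
        return True, u_int
    for _ in range(max_iter):
        disp = np.concatenate([[0.0], u_int, [u_end]])
        lam = 1.0 + np.diff(disp) / l0
        if np.any(lam <= 0):
            return False, u_int
        n_force = areas * np.array(
            [_element_engineering_stress(x, params, volumetric) for x in lam]
        )
        resid = n_force[1:] - n_force[:-1]
        ref = max(np.abs(n_force).max(), 1.0)
        if np.linalg.norm(resid) <= tol * ref:
            return True, u_int
        k = areas * np.array([_element_tangent(x, params, volumetric) for x in lam]) / l0
        # assembled tridiagonal stiffness wrt internal dofs; the residual
        # jacobian is -K, so the Newton update solves K du = resid
        stiff = np.diag(k[:-1] + k[1:])
        off = -k[1:-1]
        if off.size:
            stiff += np.diag(off, 1) + np.diag(off, -1)
        try:
            du = np.linalg.solve(stiff, resid)
        except np.linalg.LinAlgError:
            return False, u_int
        u_int = u_int + du
    return False, u_int


def calibrate_geometry(
    target: DistractionCurve,
    params: OgdenParams,
    *,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-5, 1e-2), (0.05, 2.0)),
    x0: tuple[float, float] | None = None,
) -> tuple[SegmentGeometry, dict]:
    """Fit the effective (A0, L0) of the cylinder to a target force curve.

    Log-parameterised bounded least squares on the force residuals; the
    gauge length is an *effective* quantity (the cylinder aggregates muscle,
    fascia and skin in parallel), so the default bounds are deliberately
    wide rather than anatomical.

    Returns the fitted geometry and a report with RMSE (N) and per-step
    residuals.  A single-point target is under-determined: L0 is pinned to
    its lower bound with a warning.
    """
    (a_lo, a_hi), (l_lo, l_hi) = bounds
    if a_lo >= a_hi or l_lo >= l_hi:
        raise ValueError("infeasible bounds")
    delta = target.lengths_mm * 1e-3
    meas = target.forces_n

    if len(target) < 2:
        warnings.warn("single-point target is under-determined; fixing L0 to its lower bound")
        l0 = l_lo
        lam = 1.0 + delta / l0
        a0 = float(meas[0] / uniaxial_engineering_stress(lam[0], params))
        geom = SegmentGeometry(l0, np.clip(a0, a_lo, a_hi))
        resid = _curve_residual(geom, delta, meas, params)
        return geom, {"rmse_n": float(np.sqrt(np.mean(resid**2))), "residuals_n": resid}

    def residuals(x):
        geom = SegmentGeometry(np.exp(x[1]), np.exp(x[0]))
        return _curve_residual(geom, delta, meas, params)

    x0 = x0 or (DEFAULT_REFERENCE_AREA, 1.0)
    sol = optimize.least_squares(
        residuals,
        np.log(x0),
        bounds=(np.log([a_lo, l_lo]), np.log([a_hi, l_hi])),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        # multi-start fallback on a coarse log grid (deterministic)
        best = sol
        for la in np.log(np.geomspace(a_lo * 2, a_hi / 2, 5)):
            for ll in np.log(np.geomspace(l_lo * 2, l_hi / 2, 5)):
                trial = optimize.least_squares(
                    residuals, [la, ll], bounds=(np.log([a_lo, l_lo]), np.log([a_hi, l_hi]))
                )
                if trial.cost < best.cost:
                    best = trial
        sol = best
        if not sol.success:
            raise FitError(f"geometry calibration failed: {sol.message}")
    geom = SegmentGeometry(float(np.exp(sol.x[1])), float(np.exp(sol.x[0])))
    resid = residuals(sol.x)
    report = {
        "rmse_n": float(np.sqrt(np.mean(resid**2))),
        "residuals_n": resid,
        "nfev": sol.nfev,
    }
    return geom, report


def _curve_residual(geom, delta, meas, params):
    lam = 1.0 + delta / geom.gauge_length
    return geom.reference_area * uniaxial_engineering_stress(lam, params) - meas
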