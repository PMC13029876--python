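"""First-order Ogden hyperelasticity for the soft-tissue envelope.

Skeletal muscle, fascia and skin stretched across a lengthening gap show the
classic J-shaped, strain-stiffening response that linear elasticity cannot
capture.  The first-order Ogden strain-energy density

    Ψ(λ1, λ2, λ3) = (μ/α)(λ1^α + λ2^α + λ3^α − 3) + (1/D1)(J − 1)²

with shear-modulus-like coefficient μ, strain-hardening exponent α and
incompressibility parameter D1 is the minimal phenomenological model that
does, while keeping parameter identification well-posed for single-subject
data.  Under exact incompressibility (J = 1, enforced by a hydrostatic
pressure p) the principal Cauchy stresses are

    σi = λi ∂Ψ/∂λi − p = μ λi^α − p.

The dominant loading mode in limb lengthening is uniaxial distraction, for
which the transverse-stress-free closed form is

    σ(λ) = μ (λ^α − λ^(−α/2)),        P(λ) = σ(λ)/λ,

with P the engineering (first Piola-Kirchhoff) stress on the reference area.
Powers are evaluated in log space (exp(α·ln λ)) so large hardening exponents
do not overflow prematurely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitError

__all__ = [
    "OgdenParams",
    "Kinematics",
    "StressState",
    "kinematics_from_uniaxial",
    "strain_energy",
    "principal_cauchy_stress",
    "uniaxial_true_stress",
    "uniaxial_engineering_stress",
    "uniaxial_tangent_stiffness",
    "fit_ogden_params",
]

# exp() overflows just above 709; leave headroom for downstream products.
_LOG_OVERFLOW = 700.0


@dataclass(frozen=True)
class OgdenParams:
    """Material parameters of the first-order Ogden model.

    Parameters
    ----------
    mu : float
        Shear-modulus-like coefficient (Pa), > 0.
    alpha : float
        Strain-hardening exponent (dimensionless), != 0.
    d1 : float
        Incompressibility parameter (Pa⁻¹), >= 0.  ``d1 = 0`` means exact
        incompressibility; a small positive value gives the nearly
        incompressible penalty form with bulk modulus 2/d1.

    Notes
    -----
    The ovine soft-tissue envelope defaults are μ = 700 kPa, α = 20.  The
    default d1 corresponds to 0.049 MPa⁻¹ (bulk ≈ 40.8 MPa); the analytic
    uniaxial pipeline enforces J = 1 exactly and only the penalty-based bar
    finite-element solver consumes d1.
    """

    mu: float = 700e3
    alpha: float = 20.0
    d1: float = 0.049e-6

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.alpha == 0:
            raise ValueError("alpha must be non-zero")
        if self.d1 < 0:
            raise ValueError(f"d1 must be >= 0, got {self.d1}")

    @property
    def small_strain_shear_modulus(self) -> float:
        """Consistent small-strain shear modulus G = μα/2 (Pa)."""
        return 0.5 * self.mu * self.alpha


@dataclass(frozen=True)
class Kinematics:
    """Principal-stretch representation of a homogeneous deformation."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.stretches):
            raise ValueError(f"principal stretches must be > 0, got {self.stretches}")

    @property
    def stretches(self) -> tuple[float, float, float]:
        return (self.l1, self.l2, self.l3)

    @property
    def deformation_gradient(self) -> np.ndarray:
        """Diagonal deformation gradient F = diag(λ1, λ2, λ3)."""
        return np.diag(self.stretches)

    @property
    def jacobian(self) -> float:
        """Volume ratio J = det F = λ1 λ2 λ3."""
        return self.l1 * self.l2 * self.l3

    @property
    def left_cauchy_green(self) -> np.ndarray:
        """B = F Fᵀ (symmetric positive definite)."""
        f = self.deformation_gradient
        return f @ f.T

    @property
    def first_invariant(self) -> float:
        """I1 = tr B = λ1² + λ2² + λ3²."""
        return self.l1**2 + self.l2**2 + self.l3**2


@dataclass(frozen=True)
class StressState:
    """Principal Cauchy stresses with the pressure that produced them."""

    s1: float
    s2: float
    s3: float
    pressure: float
    strain_energy: float

    @property
    def principal(self) -> tuple[float, float, float]:
        return (self.s1, self.s2, self.s3)


def _pow(base, exponent: float):
    """base**exponent via exp(exponent·ln base) with an overflow guard."""
    log = exponent * np.log(base)
    if np.any(np.abs(log) > _LOG_OVERFLOW):
        raise OverflowError(
            f"lambda^alpha overflows (|alpha·ln lambda| > {_LOG_OVERFLOW:g}); "
            "reduce the stretch or the hardening exponent"
        )
    return np.exp(log)


def kinematics_from_uniaxial(stretch: float, incompressible: bool = True) -> Kinematics:
    """Kinematics of uniaxial extension at axial stretch λ.

    With exact incompressibility the transverse stretches are λ^(−1/2), so
    J = 1 and I1 = λ² + 2/λ.
    """
    if not stretch > 0:
        raise ValueError(f"stretch must be > 0, got {stretch}")
    if not incompressible:
        raise NotImplementedError("only the incompressible uniaxial path is modelled")
    transverse = stretch**-0.5
    return Kinematics(stretch, transverse, transverse)


def strain_energy(kin: Kinematics, params: OgdenParams) -> float:
    """Strain energy density Ψ (J/m³).

    The volumetric penalty (1/D1)(J−1)² is skipped for the exactly
    incompressible material (d1 = 0), which requires J = 1.
    """
    l1, l2, l3 = kin.stretches
    dev = (params.mu / params.alpha) * (
        _pow(l1, params.alpha) + _pow(l2, params.alpha) + _pow(l3, params.alpha) - 3.0
    )
    j = kin.jacobian
    if params.d1 == 0:
        if abs(j - 1.0) > 1e-8:
            raise ValueError(
                f"J = {j:.6g} violates exact incompressibility (d1 = 0 requires J = 1)"
            )
        return float(dev)
    return float(dev + (j - 1.0) ** 2 / params.d1)


def principal_cauchy_stress(
    kin: Kinematics, params: OgdenParams, pressure: float
) -> StressState:
    """Principal Cauchy stresses σi = μλi^α − p of the incompressible branch."""
    if abs(kin.jacobian - 1.0) > 1e-8:
        raise ValueError("principal_cauchy_stress requires incompressible kinematics (J = 1)")
    s = tuple(params.mu * _pow(l, params.alpha) - pressure for l in kin.stretches)
    psi = strain_energy(kin, OgdenParams(params.mu, params.alpha, 0.0))
    return StressState(*s, pressure=pressure, strain_energy=psi)


def uniaxial_true_stress(stretch, params: OgdenParams):
    """Axial Cauchy stress σ = μ(λ^α − λ^(−α/2)) under uniaxial extension.

    The transverse directions are stress free; eliminating the pressure
    between σ_axial and σ_transverse = 0 gives the closed form.  Accepts
    scalars or arrays.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be > 0")
    out = params.mu * (_pow(lam, params.alpha) - _pow(lam, -params.alpha / 2.0))
    return float(out) if np.isscalar(stretch) else out


def uniaxial_engineering_stress(stretch, params: OgdenParams):
    """Engineering stress P = σ/λ (force per reference area, A = A0/λ)."""
    lam = np.asarray(stretch, dtype=float)
    out = uniaxial_true_stress(lam, params) / lam
    return float(out) if np.isscalar(stretch) else out


def uniaxial_tangent_stiffness(stretch, params: OgdenParams, *, engineering: bool = False):
    """Analytic dσ/dλ (or dP/dλ) along the uniaxial path.

    At λ = 1 the true-stress tangent is 3μα/2, the small-strain Young's
    modulus of the incompressible material.
    """
    lam = np.asarray(stretch, dtype=float)
    a = params.alpha
    if engineering:
        out = params.mu * (
            (a - 1.0) * _pow(lam, a - 2.0) + (a / 2.0 + 1.0) * _pow(lam, -a / 2.0 - 2.0)
        )
    else:
        out = params.mu * (a * _pow(lam, a - 1.0) + (a / 2.0) * _pow(lam, -a / 2.0 - 1.0))
    return float(out) if np.isscalar(stretch) else out


def fit_ogden_params(
    stretches,
    stresses,
    init: OgdenParams | None = None,
    *,
    stress_kind: str = "true",
) -> tuple[OgdenParams, dict]:
    """Least-squares identification of (μ, α) from uniaxial stress data.

    Parameters
    ----------
    stretches, stresses : array-like
        Paired (λ, σ) observations; at least 3 points with some λ > 1.
    init : OgdenParams, optional
        Starting point; defaults to the package's soft-tissue defaults.
    stress_kind : {"true", "engineering"}
        Which stress measure the data report.

    Returns
    -------
    (OgdenParams, dict)
        Fitted parameters (d1 carried over from ``init``) and diagnostics:
        residual norm, RMSE, a covariance proxy from the Gauss-Newton
        approximation, and the optimizer status.

    Notes
    -----
    μ is fitted in log space to stay positive; a single-term model keeps the
    identification well-posed, but the (μ, α) pair is still correlated along
    a stiffness ridge, so the covariance proxy should be inspected when data
    span only small stretches.
    """
    lam = np.asarray(stretches, dtype=float)
    sig = np.asarray(stresses, dtype=float)
    if lam.size < 3:
        raise FitError("need at least 3 (stretch, stress) points")
    if not np.any(lam > 1.0):
        raise FitError("data must include stretches > 1")
    init = init or OgdenParams()
    model = uniaxial_true_stress if stress_kind == "true" else uniaxial_engineering_stress

    def residuals(x):
        p = OgdenParams(np.exp(x[0]), x[1], 0.0)
        return model(lam, p) - sig

    x0 = np.array([np.log(init.mu), init.alpha])
    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitError(f"Ogden fit failed: {sol.message}")
    fitted = OgdenParams(float(np.exp(sol.x[0])), float(sol.x[1]), init.d1)
    jtj = sol.jac.T @ sol.jac
    dof = max(lam.size - 2, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    diagnostics = {
        "residual_norm": float(np.sqrt(2.0 * sol.cost)),
        "rmse": float(np.sqrt(2.0 * sol.cost / lam.size)),
        "covariance_logmu_alpha": cov,
        "status": sol.status,
        "nfev": sol.nfev,
    }
    return fitted, diagnostics
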