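"""First-order Ogden model: kinematics, energy, stress, parameter identification."""

import numpy as np
import pytest
from scipy import integrate, optimize

from drfkit.errors import FitError
from drfkit.ogden import (
    OgdenParams,
    fit_ogden_params,
    kinematics_from_uniaxial,
    principal_cauchy_stress,
    strain_energy,
    uniaxial_engineering_stress,
    uniaxial_tangent_stiffness,
    uniaxial_true_stress,
)


class TestKinematics:
    def test_identity(self):
        k = kinematics_from_uniaxial(1.0)
        assert k.stretches == (1.0, 1.0, 1.0)
        assert k.jacobian == pytest.approx(1.0)
        assert k.first_invariant == pytest.approx(3.0)

    def test_uniaxial_transverse_contraction(self):
        k = kinematics_from_uniaxial(1.1)
        assert k.l2 == pytest.approx(1.1**-0.5)
        assert k.first_invariant == pytest.approx(1.21 + 2 / 1.1)
        assert k.jacobian == pytest.approx(1.0, abs=1e-15)

    def test_large_stretch_preserves_volume(self):
        assert kinematics_from_uniaxial(4.0).jacobian == pytest.approx(1.0)

    def test_invalid_stretch(self):
        with pytest.raises(ValueError):
            kinematics_from_uniaxial(0.0)

    def test_left_cauchy_green_spd(self):
        b = kinematics_from_uniaxial(1.3).left_cauchy_green
        assert np.allclose(b, b.T)
        assert np.all(np.linalg.eigvalsh(b) > 0)


class TestStrainEnergy:
    def test_zero_at_reference(self, soft_tissue):
        assert strain_energy(kinematics_from_uniaxial(1.0), soft_tissue) == 0.0

    def test_uniaxial_value_matches_work_integral(self, soft_tissue):
        # independent oracle: Psi(lam) = integral of P dlam along the path
        lam = 1.1
        work, _ = integrate.quad(
            lambda x: uniaxial_engineering_stress(x, soft_tissue), 1.0, lam, epsrel=1e-12
        )
        psi = strain_energy(kinematics_from_uniaxial(lam), soft_tissue)
        assert psi == pytest.approx(work, rel=1e-9)
        # direct arithmetic of the energy function itself
        assert psi == pytest.approx((700e3 / 20) * (1.1**20 + 2 * 1.1**-10 - 3), rel=1e-12)

    def test_isotropy_under_stretch_permutation(self, soft_tissue):
        from drfkit.ogden import Kinematics

        a = strain_energy(Kinematics(1.2, 0.95, 1 / (1.2 * 0.95)), soft_tissue)
        b = strain_energy(Kinematics(0.95, 1 / (1.2 * 0.95), 1.2), soft_tissue)
        assert a == pytest.approx(b, rel=1e-12)

    def test_incompressibility_violation_rejected(self, soft_tissue):
        from drfkit.ogden import Kinematics

        with pytest.raises(ValueError, match="incompressibility"):
            strain_energy(Kinematics(1.2, 1.0, 1.0), soft_tissue)


class TestStress:
    def test_stress_free_reference_at_p_equals_mu(self, soft_tissue):
        s = principal_cauchy_stress(
            kinematics_from_uniaxial(1.0), soft_tissue, pressure=soft_tissue.mu
        )
        assert s.principal == pytest.approx((0.0, 0.0, 0.0))
        assert s.strain_energy == 0.0

    def test_uniaxial_closed_form_eliminates_pressure(self, soft_tissue):
        lam = 1.1
        k = kinematics_from_uniaxial(lam)
        p = soft_tissue.mu * k.l2**soft_tissue.alpha  # sets sigma_2 = 0
        s = principal_cauchy_stress(k, soft_tissue, p)
        assert s.s2 == pytest.approx(0.0, abs=1e-6)
        assert s.s1 == pytest.approx(uniaxial_true_stress(lam, soft_tissue), rel=1e-12)

    def test_deviatoric_stress_linear_in_mu(self, soft_tissue):
        lam = 1.05
        doubled = OgdenParams(2 * soft_tissue.mu, soft_tissue.alpha, 0.0)
        assert uniaxial_true_stress(lam, doubled) == pytest.approx(
            2 * uniaxial_true_stress(lam, soft_tissue), rel=1e-12
        )

    def test_true_stress_value_at_reference_params(self, soft_tissue):
        assert uniaxial_true_stress(1.0, soft_tissue) == 0.0
        # 700 kPa * (1.1^20 - 1.1^-10) = 4.4394e6 Pa
        assert uniaxial_true_stress(1.1, soft_tissue) == pytest.approx(4.439370e6, rel=1e-6)

    def test_engineering_below_true_in_tension(self, soft_tissue):
        lam = np.linspace(1.01, 1.5, 20)
        assert np.all(
            uniaxial_engineering_stress(lam, soft_tissue)
            < uniaxial_true_stress(lam, soft_tissue)
        )
        assert uniaxial_engineering_stress(1.1, soft_tissue) == pytest.approx(
            4.439370e6 / 1.1, rel=1e-6
        )

    def test_small_strain_tangent(self, soft_tissue):
        # analytic dsigma/dlam at identity is 3*mu*alpha/2 = 21 MPa
        assert uniaxial_tangent_stiffness(1.0, soft_tissue) == pytest.approx(21e6)
        h = 1e-7
        fd = (
            uniaxial_true_stress(1 + h, soft_tissue)
            - uniaxial_true_stress(1 - h, soft_tissue)
        ) / (2 * h)
        assert fd == pytest.approx(21e6, rel=1e-6)

    def test_strictly_increasing_strain_stiffening(self, soft_tissue):
        lam = np.linspace(1.0, 1.4, 200)
        sig = uniaxial_true_stress(lam, soft_tissue)
        assert np.all(np.diff(sig) > 0)

    def test_overflow_guard(self, soft_tissue):
        with pytest.raises(OverflowError, match="overflow"):
            uniaxial_true_stress(1e20, soft_tissue)


class TestParameterRecovery:
    def test_noiseless_recovery(self, soft_tissue):
        lam = np.linspace(1.0, 1.1, 20)
        sig = uniaxial_true_stress(lam, soft_tissue)
        fit, diag = fit_ogden_params(lam, sig, OgdenParams(500e3, 15.0, 0.0))
        assert fit.mu == pytest.approx(soft_tissue.mu, rel=1e-3)
        assert fit.alpha == pytest.approx(soft_tissue.alpha, rel=1e-3)
        assert diag["rmse"] < 1.0

    def test_recovery_under_multiplicative_noise(self, soft_tissue, rng):
        lam = np.linspace(1.0, 1.1, 20)
        sig = uniaxial_true_stress(lam, soft_tissue) * (1 + rng.normal(0, 0.02, 20))
        fit, _ = fit_ogden_params(lam, sig)
        assert fit.mu == pytest.approx(soft_tissue.mu, rel=0.05)
        assert fit.alpha == pytest.approx(soft_tissue.alpha, rel=0.05)

    def test_neo_hookean_like_limit(self):
        gen = OgdenParams(200e3, 2.0, 0.0)
        lam = np.linspace(1.0, 1.5, 30)
        fit, _ = fit_ogden_params(lam, uniaxial_true_stress(lam, gen), OgdenParams(100e3, 3.0, 0.0))
        assert fit.alpha == pytest.approx(2.0, rel=1e-4)

    def test_too_few_points_rejected(self, soft_tissue):
        with pytest.raises(FitError):
            fit_ogden_params([1.0, 1.1], [0.0, 1e5])
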