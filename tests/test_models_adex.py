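"""Mean-field AdEx: transfer function, first- and second-order dynamics."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from wbsim import (AdExParams, IntegratorSpec, TransferCoeffs, simulate,
                   transfer_function)
from wbsim.errors import ValidationError
from wbsim.models import (AdExFirstOrderModel, AdExSecondOrderModel,
                          ModelState, adex_second_order_derivatives)


class TestTransferFunction:
    def test_nonnegative_on_random_grid(self, rng):
        coeffs = TransferCoeffs()
        nu_e = rng.uniform(0, 100, 300)
        nu_i = rng.uniform(0, 100, 300)
        W = rng.uniform(0, 200, 300)
        F = transfer_function(nu_e, nu_i, W, coeffs)
        assert np.all(F >= 0.0)
        assert np.all(np.isfinite(F))

    def test_monotone_in_excitatory_rate(self):
        """Grid scan: F nondecreasing in nu_e at fixed nu_i, W (defaults)."""
        coeffs = TransferCoeffs()
        nu_e = np.linspace(0.0, 60.0, 601)
        for nu_i in (0.0, 5.0, 20.0, 50.0):
            for W in (0.0, 50.0, 120.0):
                F = transfer_function(nu_e, np.full_like(nu_e, nu_i),
                                      np.full_like(nu_e, W), coeffs)
                assert np.all(np.diff(F) >= -1e-9)

    def test_output_scale_linearity(self, rng):
        base = TransferCoeffs()
        scaled = TransferCoeffs(scale=2.5)
        nu_e, nu_i, W = rng.uniform(1, 40, 50), rng.uniform(1, 40, 50), \
            rng.uniform(0, 100, 50)
        np.testing.assert_allclose(
            transfer_function(nu_e, nu_i, W, scaled),
            2.5 * transfer_function(nu_e, nu_i, W, base), rtol=1e-14)

    def test_missing_coefficients_rejected(self):
        with pytest.raises(ValidationError):
            transfer_function(1.0, 1.0, 0.0, None)
        with pytest.raises(ValidationError):
            TransferCoeffs(P=(0.0, 1.0))

    def test_silent_at_rest_without_drive(self):
        """No synaptic input leaves the membrane far below threshold."""
        assert transfer_function(0.0, 0.0, 0.0, TransferCoeffs()) \
            == pytest.approx(0.0, abs=1e-12)


def independent_first_order(values, coupling, p):
    """Second transcription of the first-order mean-field equations."""
    nu_e, nu_i, W = values
    n = values.shape[1]
    out = np.empty_like(values)
    for k in range(n):
        drive = nu_e[k] + p.nu_ext + (coupling[k] if coupling is not None
                                      else 0.0)
        F_e = transfer_function(drive, nu_i[k], W[k], p.coeffs_e)
        F_i = transfer_function(drive, nu_i[k], W[k], p.coeffs_i)
        out[0, k] = (F_e - nu_e[k]) / p.T
        out[1, k] = (F_i - nu_i[k]) / p.T
        out[2, k] = -W[k] / p.tau_w + p.b * nu_e[k] * 1e-3
    return out


class TestFirstOrder:
    def test_fixed_point_has_zero_rate_derivatives(self):
        """At nu = F(nu) (with b = 0, W = 0) the rate equations rest."""
        p = AdExParams(b=0.0)
        model = AdExFirstOrderModel(1, p)

        def residual(nu):
            F_e = transfer_function(nu[0], nu[1], 0.0, p.coeffs_e)
            F_i = transfer_function(nu[0], nu[1], 0.0, p.coeffs_i)
            return [F_e - nu[0], F_i - nu[1]]

        nu = fsolve(residual, [10.0, 10.0], xtol=1e-13)
        assert np.allclose(residual(nu), 0.0, atol=1e-9)
        deriv, _ = model.dfun(np.array([[nu[0]], [nu[1]], [0.0]]), None)
        np.testing.assert_allclose(deriv, 0.0, atol=1e-9)

    def test_adaptation_off_stays_zero(self):
        p = AdExParams(b=0.0)
        model = AdExFirstOrderModel(1, p)
        track = []

        class W:
            def record(self, step, values, obs):
                track.append(values[2, 0])

        initial = np.array([[5.0], [5.0], [0.0]])
        simulate(model, IntegratorSpec(scheme="euler", dt=0.1), 50.0,
                 monitors=[W()], initial=initial)
        assert np.all(np.asarray(track) == 0.0)

    def test_matches_independent_transcription(self, rng):
        p = AdExParams(b=30.0, nu_ext=2.0)
        model = AdExFirstOrderModel(3, p)
        for _ in range(200):
            values = np.abs(rng.standard_normal((3, 3))) * [[20], [20], [80]]
            coupling = rng.uniform(0, 10, 3)
            deriv, _ = model.dfun(values, coupling)
            np.testing.assert_allclose(
                deriv, independent_first_order(values, coupling, p),
                rtol=1e-12, atol=1e-15)

    def test_strict_signs_flips_derivatives(self, rng):
        values = np.abs(rng.standard_normal((3, 2))) * 10
        d_fixed, _ = AdExFirstOrderModel(2, AdExParams()).dfun(values, None)
        d_print, _ = AdExFirstOrderModel(
            2, AdExParams(strict_signs=True)).dfun(values, None)
        np.testing.assert_allclose(d_print, -d_fixed, rtol=1e-14)


def independent_second_order(values, coupling, p):
    """Independent finite-difference transcription of the covariance model."""
    h = p.fd_step
    nu_e, nu_i, c_ee, c_ei, c_ie, c_ii, W = values
    n = values.shape[1]
    out = np.empty_like(values)
    T_s = p.T * 1e-3
    for k in range(n):
        drive = nu_e[k] + p.nu_ext + (coupling[k] if coupling is not None
                                      else 0.0)
        coeffs = [p.coeffs_e, p.coeffs_i]

        def F(mu, de=0.0, di=0.0):
            return transfer_function(drive + de, nu_i[k] + di, W[k],
                                     coeffs[mu])

        nu = [nu_e[k], nu_i[k]]
        c = np.array([[c_ee[k], c_ei[k]], [c_ie[k], c_ii[k]]])
        N = [p.N_e, p.N_i]
        F0 = [F(0), F(1)]
        dF = np.array([[(F(m, de=h) - F(m, de=-h)) / (2 * h),
                        (F(m, di=h) - F(m, di=-h)) / (2 * h)]
                       for m in range(2)])
        d2F = np.empty((2, 2, 2))
        for m in range(2):
            d2F[m, 0, 0] = (F(m, de=h) - 2 * F0[m] + F(m, de=-h)) / h ** 2
            d2F[m, 1, 1] = (F(m, di=h) - 2 * F0[m] + F(m, di=-h)) / h ** 2
            cross = (F(m, de=h, di=h) - F(m, de=h, di=-h)
                     - F(m, de=-h, di=h) + F(m, de=-h, di=-h)) / (4 * h ** 2)
            d2F[m, 0, 1] = d2F[m, 1, 0] = cross
        dnu = np.empty(2)
        for m in range(2):
            corr = 0.5 * sum(c[l, q] * d2F[m, l, q]
                             for l in range(2) for q in range(2))
            dnu[m] = (F0[m] - nu[m] + corr) / p.T
        dc = np.empty((2, 2))
        for l in range(2):
            for q in range(2):
                A = (F0[l] * (1.0 / T_s - F0[l]) / N[l]) if l == q else 0.0
                relax = sum(c[l, m] * dF[q, m] + c[m, q] * dF[l, m]
                            for m in range(2))
                dc[l, q] = (A + (F0[l] - nu[l]) * (F0[q] - nu[q])
                            + relax - 2 * c[l, q]) / p.T
        out[0, k], out[1, k] = dnu
        out[2, k], out[3, k], out[4, k], out[5, k] = (dc[0, 0], dc[0, 1],
                                                      dc[1, 0], dc[1, 1])
        out[6, k] = -W[k] / p.tau_w + p.b * nu_e[k] * 1e-3
    return out


class TestSecondOrder:
    def _random_state(self, rng, n):
        values = np.zeros((7, n))
        values[0] = rng.uniform(1, 30, n)
        values[1] = rng.uniform(1, 30, n)
        values[2] = rng.uniform(0, 4, n)
        values[3] = rng.uniform(-1, 1, n)
        values[4] = values[3]
        values[5] = rng.uniform(0, 4, n)
        values[6] = rng.uniform(0, 100, n)
        return values

    def test_matches_independent_transcription(self, rng):
        p = AdExParams(order=2, b=30.0)
        model = AdExSecondOrderModel(2, p)
        for _ in range(100):
            values = self._random_state(rng, 2)
            coupling = rng.uniform(0, 5, 2)
            deriv, _ = model.dfun(values, coupling)
            # the 1/h^2 of the finite-difference Hessian amplifies float
            # rounding, so agreement is bounded by ~eps/h^2, not 1e-12
            np.testing.assert_allclose(
                deriv, independent_second_order(values, coupling, p),
                rtol=1e-6, atol=1e-9)

    def test_zero_rate_zero_finite_size_term(self):
        """F = 0 (silent populations) makes the A term vanish: with c = 0
        and nu = 0 the covariance derivatives are zero."""
        p = AdExParams(order=2, b=0.0)
        model = AdExSecondOrderModel(1, p)
        deriv, _ = model.dfun(np.zeros((7, 1)), None)
        np.testing.assert_allclose(deriv[2:6], 0.0, atol=1e-12)

    def test_zero_covariance_means_reduce_to_first_order(self, rng):
        p = AdExParams(order=2, b=20.0, covariance_dynamics=False)
        p1 = AdExParams(b=20.0)
        values = self._random_state(rng, 3)
        values[2:6] = 0.0
        deriv2, _ = AdExSecondOrderModel(3, p).dfun(values, None)
        deriv1, _ = AdExFirstOrderModel(3, p1).dfun(values[[0, 1, 6]], None)
        np.testing.assert_allclose(deriv2[[0, 1, 6]], deriv1, rtol=1e-13)
        np.testing.assert_array_equal(deriv2[2:6], 0.0)

    def test_frozen_covariance_reproduces_first_order_trajectory(self, rng):
        """With the covariance block disabled and started at zero, the
        second-order trajectory equals the first-order one exactly."""
        p2 = AdExParams(order=2, b=20.0, covariance_dynamics=False)
        p1 = AdExParams(b=20.0)
        spec = IntegratorSpec(scheme="euler", dt=0.1)
        traj = {1: [], 2: []}

        class Track:
            def __init__(self, key):
                self.key = key

            def record(self, step, values, obs):
                traj[self.key].append(values[[0, 1]].copy()
                                      if self.key == 1
                                      else values[[0, 1]].copy())

        init1 = np.array([[4.0], [6.0], [0.0]])
        init2 = np.zeros((7, 1))
        init2[0, 0], init2[1, 0] = 4.0, 6.0
        simulate(AdExFirstOrderModel(1, p1), spec, 20.0,
                 monitors=[Track(1)], initial=init1)
        simulate(AdExSecondOrderModel(1, p2), spec, 20.0,
                 monitors=[Track(2)], initial=init2)
        np.testing.assert_array_equal(np.array(traj[1]), np.array(traj[2]))

    def test_asymmetric_covariance_rejected(self, rng):
        values = self._random_state(rng, 1)
        values[3] += 0.5   # break c_ei = c_ie
        model = AdExSecondOrderModel(1, AdExParams(order=2))
        with pytest.raises(ValidationError, match="asymmetric"):
            model.dfun(values, None)

    def test_functional_form(self, rng):
        state = ModelState(values=self._random_state(rng, 2),
                           variable_names=AdExSecondOrderModel.state_names)
        out = adex_second_order_derivatives(state, np.zeros(2),
                                            AdExParams(order=2))
        assert out.values.shape == (7, 2)
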