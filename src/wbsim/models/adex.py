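"""Mean-field model of adaptive exponential integrate-and-fire networks.

Each region holds an excitatory and an inhibitory population whose mean
rates relax toward population transfer functions ``F_e, F_i`` on a slow
timescale ``T``, plus a spike-frequency adaptation variable ``W`` driven
by the excitatory rate:

    T dnu_mu/dt = F_mu(nu_e, nu_i, W) - nu_mu        (mu in {e, i})
    dW/dt       = -W/tau_w + b * nu_e

The second-order variant adds the covariances ``c_{lambda eta}`` of the
population rates (finite-size fluctuations) and their feedback on the
means through the curvature of F:

    T dnu_mu/dt = (F_mu - nu_mu)
                  + 1/2 sum_{l,h} c_lh d2F_mu/dnu_l dnu_h
    T dc_lh/dt  = A_lh + (F_l - nu_l)(F_h - nu_h)
                  + sum_m [ c_lm dF_h/dnu_m + c_mh dF_l/dnu_m ] - 2 c_lh
    A_lh        = delta_lh * F_l (1/T - F_l) / N_l

with population sizes ``N_e, N_i``.  Derivatives of F are taken by
central finite differences.

The printed mean and adaptation equations of the source formulation carry
relaxation signs that make the dynamics unstable (growth away from F and
unbounded W); the stable convention above is the default, and
``strict_signs=True`` restores the printed one.

Transfer function
-----------------
F is the semi-analytic error-function form of the conductance-based
mean-field literature: synaptic shot noise with rates ``K_s nu_s`` gives
the subthreshold membrane statistics (mean ``mu_V``, std ``sigma_V``,
autocorrelation time ``tau_V``), and the output rate is

    F = scale * erfc((V_thr_eff - mu_V) / (sqrt(2) sigma_V)) / (2 tau_V)

where the effective threshold ``V_thr_eff`` is a quadratic polynomial in
the normalized (mu_V, sigma_V, tau_V) with a pluggable 10-coefficient
vector ``P``.  The default ``P`` keeps only the constant term (a fixed
-50 mV effective threshold); vectors fitted to specific single-neuron
models can be supplied instead (the fitting procedure itself is out of
scope).  Units: rates Hz, potentials mV inside the statistics, volts in
the threshold polynomial (the literature's fitting convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.special import erfc

from ..errors import ValidationError
from .base import ModelState, NeuralMassModel

FIRST_ORDER_STATE = ("nu_e", "nu_i", "W")
SECOND_ORDER_STATE = ("nu_e", "nu_i", "c_ee", "c_ei", "c_ie", "c_ii", "W")

#: default threshold polynomial: constant -50 mV effective threshold
DEFAULT_P = (-0.05, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class TransferCoeffs:
    """Coefficients of the semi-analytic transfer function.

    Conductance parameters describe the postsynaptic target population;
    ``P`` parameterizes the effective threshold (volts, quadratic in the
    normalized membrane statistics); ``scale`` is a dimensionless output
    gain.
    """

    g_L: float = 10.0       # leak conductance, nS
    E_L: float = -65.0      # leak reversal, mV
    C: float = 200.0        # capacitance, pF
    E_e: float = 0.0        # excitatory reversal, mV
    E_i: float = -80.0      # inhibitory reversal, mV
    Q_e: float = 1.5        # excitatory quantal conductance, nS
    Q_i: float = 5.0        # inhibitory quantal conductance, nS
    tau_se: float = 5.0     # excitatory synaptic time constant, ms
    tau_si: float = 5.0     # inhibitory synaptic time constant, ms
    K_e: float = 400.0      # excitatory in-degree
    K_i: float = 100.0      # inhibitory in-degree
    P: Tuple[float, ...] = DEFAULT_P
    scale: float = 1.0
    # normalization constants of the threshold polynomial (mV / mV / -)
    mu_V0: float = -60.0
    d_mu_V: float = 10.0
    sigma_V0: float = 4.0
    d_sigma_V: float = 6.0
    tau_V0: float = 0.5
    d_tau_V: float = 1.0

    def __post_init__(self):
        if len(self.P) != 10:
            raise ValidationError("threshold polynomial needs 10 "
                                  f"coefficients, got {len(self.P)}")


def membrane_statistics(nu_e, nu_i, W, c: TransferCoeffs):
    """Mean, std, and autocorrelation time of the membrane potential.

    Shot-noise statistics of conductance-based synaptic bombardment at
    presynaptic rates ``K_e nu_e`` and ``K_i nu_i`` (nu in Hz, W in pA).
    Returns (mu_V [mV], sigma_V [mV], tau_V [s]).
    """
    nu_e = np.maximum(np.asarray(nu_e, dtype=float), 0.0)
    nu_i = np.maximum(np.asarray(nu_i, dtype=float), 0.0)
    tau_se, tau_si = c.tau_se * 1e-3, c.tau_si * 1e-3   # s
    mu_Ge = nu_e * c.K_e * tau_se * c.Q_e               # nS
    mu_Gi = nu_i * c.K_i * tau_si * c.Q_i
    mu_G = c.g_L + mu_Ge + mu_Gi
    tau_m = (c.C * 1e-3) / mu_G                         # s  (nF / nS)
    mu_V = (mu_Ge * c.E_e + mu_Gi * c.E_i + c.g_L * c.E_L - W) / mu_G
    U_e = c.Q_e / mu_G * (c.E_e - mu_V)                 # mV
    U_i = c.Q_i / mu_G * (c.E_i - mu_V)
    num_e = c.K_e * nu_e * (U_e * tau_se) ** 2
    num_i = c.K_i * nu_i * (U_i * tau_si) ** 2
    var_V = (num_e / (2.0 * (tau_se + tau_m))
             + num_i / (2.0 * (tau_si + tau_m)))
    sigma_V = np.sqrt(np.maximum(var_V, 0.0))
    total = num_e + num_i
    damped = num_e / (tau_se + tau_m) + num_i / (tau_si + tau_m)
    tau_V = np.where(total > 0.0, total / np.where(damped > 0, damped, 1.0),
                     tau_m)
    return mu_V, sigma_V, tau_V


def transfer_function(nu_e, nu_i, W, coeffs: TransferCoeffs) -> np.ndarray:
    """Population output rate F(nu_e, nu_i, W) >= 0, in Hz."""
    if coeffs is None:
        raise ValidationError("transfer_function requires a TransferCoeffs")
    mu_V, sigma_V, tau_V = membrane_statistics(nu_e, nu_i, W, coeffs)
    x_m = (mu_V - coeffs.mu_V0) / coeffs.d_mu_V
    x_s = (sigma_V - coeffs.sigma_V0) / coeffs.d_sigma_V
    x_t = (tau_V * coeffs.g_L / (coeffs.C * 1e-3)
           - coeffs.tau_V0) / coeffs.d_tau_V
    P = coeffs.P
    v_thr = (P[0] + P[1] * x_m + P[2] * x_s + P[3] * x_t
             + P[4] * x_m ** 2 + P[5] * x_s ** 2 + P[6] * x_t ** 2
             + P[7] * x_m * x_s + P[8] * x_m * x_t + P[9] * x_s * x_t)
    sigma_V_volt = np.maximum(sigma_V * 1e-3, 1e-9)     # floor: no input
    arg = (v_thr - mu_V * 1e-3) / (np.sqrt(2.0) * sigma_V_volt)
    return coeffs.scale * erfc(arg) / (2.0 * tau_V)


@dataclass
class AdExParams:
    """Parameters shared by the first- and second-order mean fields."""

    T: float = 20.0           # mean-field relaxation timescale, ms
    b: float = 60.0           # adaptation increment, pA per Hz of nu_e
    tau_w: float = 500.0      # adaptation time constant, ms
    N_e: float = 8000.0       # excitatory population size
    N_i: float = 2000.0       # inhibitory population size
    coeffs_e: TransferCoeffs = field(default_factory=TransferCoeffs)
    coeffs_i: TransferCoeffs = field(default_factory=TransferCoeffs)
    order: int = 1
    nu_ext: float = 0.0       # constant external excitatory drive, Hz
    fd_step: float = 1e-4     # finite-difference step for dF/dnu, Hz
    strict_signs: bool = False
    covariance_dynamics: bool = True

    def __post_init__(self):
        if self.T <= 0 or self.tau_w <= 0:
            raise ValidationError("T and tau_w must be positive")
        if self.N_e < 1 or self.N_i < 1:
            raise ValidationError("population sizes must be >= 1")
        if self.order not in (1, 2):
            raise ValidationError("order must be 1 or 2")

    def with_(self, **kwargs) -> "AdExParams":
        return replace(self, **kwargs)


class AdExFirstOrderModel(NeuralMassModel):
    """First-order mean field: (nu_e, nu_i, W) per region."""

    state_names = FIRST_ORDER_STATE
    coupling_var = 0          # nu_e feeds long-range coupling
    applies_G = False         # gain applied by the engine's coupling

    def __init__(self, n_regions: int, params: Optional[AdExParams] = None):
        super().__init__(n_regions)
        self.params = params if params is not None else AdExParams()

    def dfun(self, values: np.ndarray, coupling=None):
        p = self.params
        self._check_shapes(values, coupling)
        nu_e, nu_i, W = values
        drive = nu_e + p.nu_ext + (coupling if coupling is not None else 0.0)
        F_e = transfer_function(drive, nu_i, W, p.coeffs_e)
        F_i = transfer_function(drive, nu_i, W, p.coeffs_i)
        sign = -1.0 if p.strict_signs else 1.0
        dnu_e = sign * (F_e - nu_e) / p.T
        dnu_i = sign * (F_i - nu_i) / p.T
        # W in pA, nu_e in Hz = 1e-3/ms
        dW = sign * (-W / p.tau_w + p.b * nu_e * 1e-3)
        obs = {"F_e": F_e, "F_i": F_i, "r_E": nu_e, "r_I": nu_i}
        return np.stack([dnu_e, dnu_i, dW]), obs


def _tf_pair(drive, nu_i, W, p):
    F_e = transfer_function(drive, nu_i, W, p.coeffs_e)
    F_i = transfer_function(drive, nu_i, W, p.coeffs_i)
    return F_e, F_i


def _tf_derivatives(drive, nu_i, W, p):
    """First and second partials of (F_e, F_i) wrt (nu_e, nu_i).

    Central finite differences with step ``p.fd_step`` Hz; returns
    (F, dF, d2F) with dF[mu][l] and d2F[mu][l][h], mu/l/h in {0: e, 1: i}.
    """
    h = p.fd_step

    def F(de, di):
        return np.stack(_tf_pair(drive + de, nu_i + di, W, p))

    F0 = F(0.0, 0.0)
    Fpe, Fme = F(h, 0.0), F(-h, 0.0)
    Fpi, Fmi = F(0.0, h), F(0.0, -h)
    dF = np.stack([(Fpe - Fme) / (2 * h), (Fpi - Fmi) / (2 * h)], axis=1)
    d2_ee = (Fpe - 2 * F0 + Fme) / h ** 2
    d2_ii = (Fpi - 2 * F0 + Fmi) / h ** 2
    Fpp = F(h, h)
    Fpm = F(h, -h)
    Fmp = F(-h, h)
    Fmm = F(-h, -h)
    d2_ei = (Fpp - Fpm - Fmp + Fmm) / (4 * h ** 2)
    d2 = np.stack([np.stack([d2_ee, d2_ei], axis=1),
                   np.stack([d2_ei, d2_ii], axis=1)], axis=1)
    return F0, dF, d2


class AdExSecondOrderModel(NeuralMassModel):
    """Second-order mean field with rate covariances."""

    state_names = SECOND_ORDER_STATE
    coupling_var = 0
    applies_G = False

    def __init__(self, n_regions: int, params: Optional[AdExParams] = None):
        super().__init__(n_regions)
        self.params = params if params is not None else AdExParams(order=2)

    def dfun(self, values: np.ndarray, coupling=None):
        p = self.params
        self._check_shapes(values, coupling)
        nu_e, nu_i, c_ee, c_ei, c_ie, c_ii, W = values
        if not np.allclose(c_ei, c_ie, rtol=1e-10, atol=1e-12):
            raise ValidationError(
                "covariance block is asymmetric (c_ei != c_ie)")
        drive = nu_e + p.nu_ext + (coupling if coupling is not None else 0.0)
        F0, dF, d2 = _tf_derivatives(drive, nu_i, W, p)
        nu = np.stack([nu_e, nu_i])
        c = np.stack([np.stack([c_ee, c_ei], axis=0),
                      np.stack([c_ie, c_ii], axis=0)], axis=0)
        T_ms = p.T
        T_s = p.T * 1e-3
        N = np.array([p.N_e, p.N_i])

        if p.covariance_dynamics:
            # curvature correction on the means
            corr = 0.5 * np.einsum("lhn,mlhn->mn", c, d2)
            dnu = (F0 - nu + corr) / T_ms
            A = np.zeros_like(c)
            for l in range(2):
                A[l, l] = F0[l] * (1.0 / T_s - F0[l]) / N[l]
            drift = np.einsum("ln,hn->lhn", F0 - nu, F0 - nu)
            relax = (np.einsum("lmn,hmn->lhn", c, dF)
                     + np.einsum("mhn,lmn->lhn", c, dF))
            dc = (A + drift + relax - 2.0 * c) / T_ms
        else:
            dnu = (F0 - nu) / T_ms
            dc = np.zeros_like(c)

        dW = -W / p.tau_w + p.b * nu_e * 1e-3
        if p.strict_signs:
            dnu, dc, dW = -dnu, -dc, -dW
        deriv = np.stack([dnu[0], dnu[1], dc[0, 0], dc[0, 1],
                          dc[1, 0], dc[1, 1], dW])
        obs = {"F_e": F0[0], "F_i": F0[1], "r_E": nu_e, "r_I": nu_i}
        return deriv, obs


def adex_first_order_derivatives(state: ModelState, coupling_input,
                                 params: AdExParams) -> ModelState:
    model = AdExFirstOrderModel(state.n_regions, params)
    deriv, obs = model.dfun(state.values, coupling_input)
    out = ModelState(values=deriv, variable_names=FIRST_ORDER_STATE)
    state.observables.update(obs)
    out.observables.update(obs)
    return out


def adex_second_order_derivatives(state: ModelState, coupling_input,
                                  params: AdExParams) -> ModelState:
    model = AdExSecondOrderModel(state.n_regions, params)
    deriv, obs = model.dfun(state.values, coupling_input)
    out = ModelState(values=deriv, variable_names=SECOND_ORDER_STATE)
    state.observables.update(obs)
    out.observables.update(obs)
    return out
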