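"""Firing-rate equations (FRE) of quadratic integrate-and-fire networks.

Exact mean field of all-to-all QIF networks with Lorentzian input
heterogeneity (half-width ``Delta``, center ``eta``): each population is
described by its firing rate ``r`` and mean membrane potential ``u``.
A single population with chemical weight J and electrical coupling g
obeys::

    tau dr/dt = Delta/(tau*pi) + 2 r u - g r
    tau du/dt = u^2 + eta - (pi tau r)^2 + (J + g ln a) tau r

where ``a`` is the spike-asymmetry parameter: electrical synapses both
equalize potentials (the ``-g r`` term) and act as a "virtual chemical
synapse" of strength ``g ln a``.

The whole-brain configuration couples an excitatory and an inhibitory
population per region (a PING microcircuit) through slow NMDA gating
variables ``S_ee, S_ie`` driven by the excitatory rate, GABA weights
``J_ei_G, J_ii_G``, a long-range AMPA weight ``J_A``, and per-region
feedback-inhibition factors ``J_j``::

    tau_e dr_e/dt = Delta_e/(tau_e pi) + 2 r_e u_e - g_e r_e
    tau_e du_e/dt = u_e^2 + eta_e - (pi tau_e r_e)^2 + I_e
                    + g_e ln(a) tau_e r_e
    tau_i dr_i/dt = Delta_i/(tau_i pi) + 2 r_i u_i - g_i r_i
    tau_i du_i/dt = u_i^2 + eta_i - (pi tau_i r_i)^2 + I_i
                    + g_i ln(a) tau_i r_i
    tau_N dS_ee/dt = -S_ee + J_ee_N r_e
    tau_N dS_ie/dt = -S_ie + J_ie_N r_e
    I_e = I_ext_e + tau_e S_ee - J_j J_ei_G tau_i r_i
          + G J_A tau_e sum_{k!=j} C_jk S_ee_k
    I_i = I_ext_i + tau_e S_ie - J_ii_G tau_i r_i

Setting ``tau_N`` equal to the integration step under Euler-type schemes
slaves the gating variables to their steady state ``S = J_N r_e``, which
recovers the single-population equations when G and the GABA weights are
zero.  Time is in ms; rates are in 1/ms (the natural units of the
equations); the observable ``r_e_Hz`` reports 1000*r_e.

Noise, when enabled, targets only the two gating variables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from ..errors import ValidationError
from .base import ModelState, NeuralMassModel, as_region_vector

STATE_NAMES = ("r_e", "u_e", "r_i", "u_i", "S_ee", "S_ie")


@dataclass
class FREParams:
    """Parameters of the two-population whole-brain FRE model."""

    tau_e: float = 10.0       # excitatory membrane time constant, ms
    tau_i: float = 10.0       # inhibitory membrane time constant, ms
    tau_N: float = 100.0      # NMDA gating time constant, ms
    Delta_e: float = 1.0      # Lorentzian half-width (E)
    Delta_i: float = 1.0
    eta_e: float = -5.0       # Lorentzian center (E)
    eta_i: float = -5.0
    g_e: float = 0.0          # electrical coupling (E)
    g_i: float = 0.0
    J_ee_N: float = 15.0      # NMDA weight E->E
    J_ie_N: float = 15.0      # NMDA weight E->I
    J_A: float = 1.0          # long-range AMPA weight
    J_ei_G: float = 8.0       # GABA weight I->E
    J_ii_G: float = 8.0       # GABA weight I->I
    a: float = 1.0            # spike asymmetry (> 0)
    G: float = 0.0            # global coupling gain
    J: Union[float, np.ndarray] = 1.0  # per-region FIC factor J_j
    I_ext_e: float = 0.0
    I_ext_i: float = 0.0

    def __post_init__(self):
        for name in ("tau_e", "tau_i", "tau_N", "Delta_e", "Delta_i"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.a <= 0:
            raise ValidationError("spike asymmetry a must be positive")

    def with_(self, **kwargs) -> "FREParams":
        return replace(self, **kwargs)


class FREModel(NeuralMassModel):
    state_names = STATE_NAMES
    coupling_var = 4          # S_ee feeds long-range coupling
    applies_G = True

    #: default noise mask: only the gating variables receive noise
    noise_mask = (0.0, 0.0, 0.0, 0.0, 1.0, 1.0)

    def __init__(self, n_regions: int, params: Optional[FREParams] = None):
        super().__init__(n_regions)
        self.params = params if params is not None else FREParams()
        self._J = as_region_vector(self.params.J, n_regions, "J")

    @property
    def J(self) -> np.ndarray:
        return self._J

    @J.setter
    def J(self, value):
        self._J = as_region_vector(value, self.n_regions, "J")

    def dfun(self, values: np.ndarray, coupling=None):
        p = self.params
        self._check_shapes(values, coupling)
        r_e, u_e, r_i, u_i, S_ee, S_ie = values
        net = p.G * coupling if coupling is not None else 0.0
        lna = np.log(p.a)
        I_e = (p.I_ext_e + p.tau_e * S_ee
               - self._J * p.J_ei_G * p.tau_i * r_i
               + p.J_A * p.tau_e * net)
        I_i = p.I_ext_i + p.tau_e * S_ie - p.J_ii_G * p.tau_i * r_i
        dr_e = (p.Delta_e / (p.tau_e * np.pi) + 2.0 * r_e * u_e
                - p.g_e * r_e) / p.tau_e
        du_e = (u_e ** 2 + p.eta_e - (np.pi * p.tau_e * r_e) ** 2 + I_e
                + p.g_e * lna * p.tau_e * r_e) / p.tau_e
        dr_i = (p.Delta_i / (p.tau_i * np.pi) + 2.0 * r_i * u_i
                - p.g_i * r_i) / p.tau_i
        du_i = (u_i ** 2 + p.eta_i - (np.pi * p.tau_i * r_i) ** 2 + I_i
                + p.g_i * lna * p.tau_i * r_i) / p.tau_i
        dS_ee = (-S_ee + p.J_ee_N * r_e) / p.tau_N
        dS_ie = (-S_ie + p.J_ie_N * r_e) / p.tau_N
        obs = {"r_e": r_e, "r_i": r_i, "r_e_Hz": 1e3 * r_e,
               "I_e": I_e, "I_i": I_i}
        return np.stack([dr_e, du_e, dr_i, du_i, dS_ee, dS_ie]), obs


def fre_derivatives(state: ModelState, coupling_input,
                    params: FREParams) -> ModelState:
    """Functional form of the FRE derivative call (raw weighted sum in)."""
    model = FREModel(state.n_regions, params)
    deriv, obs = model.dfun(state.values, coupling_input)
    out = ModelState(values=deriv, variable_names=STATE_NAMES)
    state.observables.update(obs)
    out.observables.update(obs)
    return out


def single_population_fixed_point(params: FREParams,
                                  J: Optional[float] = None,
                                  r_bounds=(1e-6, 10.0)):
    """Stationary states of one isolated population (analysis helper).

    Solves the stationarity conditions of the single-population system
    (using the excitatory parameter set and total chemical weight
    ``J = J_ee_N`` unless given) by scanning r > 0:

        0 = Delta/(tau pi) + 2 r u - g r
        0 = u^2 + eta - (pi tau r)^2 + (J + g ln a) tau r

    Returns an array of (r, u) roots found in ``r_bounds``.
    """
    from scipy.optimize import brentq

    tau, Delta, eta, g, a = (params.tau_e, params.Delta_e, params.eta_e,
                             params.g_e, params.a)
    Jw = params.J_ee_N if J is None else J

    def u_of_r(r):
        return (g * r - Delta / (tau * np.pi)) / (2.0 * r)

    def residual(r):
        u = u_of_r(r)
        return (u ** 2 + eta - (np.pi * tau * r) ** 2
                + (Jw + g * np.log(a)) * tau * r)

    grid = np.linspace(r_bounds[0], r_bounds[1], 20001)
    vals = np.array([residual(r) for r in grid])
    roots = []
    for i in range(len(grid) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) \
                and vals[i] * vals[i + 1] < 0:
            r = brentq(residual, grid[i], grid[i + 1], xtol=1e-14)
            roots.append((r, u_of_r(r)))
    return np.array(roots)
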