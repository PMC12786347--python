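"""Balanced excitation-inhibition (BEI) neural-mass model.

The reduced Wong-Wang dynamic mean-field model with one excitatory and one
inhibitory synaptic gating variable per region.  Per region ``k``::

    I_E_k = W_E*I_o + w_plus*J_N*S_E_k + J_N*G*sum_j C_kj S_E_j
            - J_k*S_I_k + I_ext
    I_I_k = W_I*I_o + J_N*S_E_k - S_I_k + lambda*J_N*G*sum_j C_kj S_E_j
    r_X_k = H_X(I_X_k) = M_X*(a_X*I_X_k - b_X)
            / (1 - exp(-d_X * M_X*(a_X*I_X_k - b_X)))
    dS_E_k/dt = -S_E_k/tau_E + (1 - S_E_k) * gamma * r_E_k
    dS_I_k/dt = -S_I_k/tau_I + r_I_k

Units: time in ms, currents in nA, rates in Hz (the gating equations carry
an implicit 1e-3 Hz->1/ms conversion so tau_E/tau_I can be stated in ms).
``J`` is the per-region feedback-inhibition weight tuned by FIC; ``M_X``
is the regional gain, optionally modulated by a receptor-density map
(e.g., 5-HT2A): ``M_E_k = g_E * (1 + s * density_k)``.

The default parameter values are the standard resting-state set under
which an isolated node fires at ~3 Hz; they ship as the
``bei_deco2014`` preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from ..errors import ValidationError
from .base import ModelState, NeuralMassModel, as_region_vector

STATE_NAMES = ("S_E", "S_I")


@dataclass
class BEIParams:
    """Parameters of the BEI model (defaults: resting-state preset)."""

    W_E: float = 1.0            # excitatory population scaling
    W_I: float = 0.7            # inhibitory population scaling
    I_o: float = 0.382          # overall effective external input, nA
    w_plus: float = 1.4         # local excitatory recurrence
    J_N: float = 0.15           # NMDA synaptic coupling, nA
    lambda_: float = 0.0        # gates long-range drive to the I pool (0/1)
    a_E: float = 310.0          # E gain slope, nC^-1
    b_E: float = 125.0          # E gain threshold term, Hz
    d_E: float = 0.16           # E gain curvature, s
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 100.0        # NMDA gating time constant, ms
    tau_I: float = 10.0         # GABA gating time constant, ms
    gamma_kin: float = 0.641    # kinetic rate factor of the E gating
    I_ext: float = 0.0          # external stimulation, nA
    G: float = 0.0              # global coupling gain
    J: Union[float, np.ndarray] = 1.0   # FIC inhibition weights, nA
    g_E: float = 1.0            # baseline excitatory gain M_E
    g_I: float = 1.0            # baseline inhibitory gain M_I
    gain_scale: float = 0.0     # receptor-map scaling s
    receptor_density: Union[float, np.ndarray] = 0.0  # e.g. 5-HT2A map
    modulate_inhibitory: bool = False

    def __post_init__(self):
        for name in ("tau_E", "tau_I", "d_E", "d_I"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if np.any(np.asarray(self.J) < 0):
            raise ValidationError("J must be nonnegative")

    def with_(self, **kwargs) -> "BEIParams":
        return replace(self, **kwargs)


def gain_function(I: np.ndarray, a: float, b: float, d: float,
                  M: Union[float, np.ndarray] = 1.0) -> np.ndarray:
    """Sigmoidal input-output gain ``H(I) = x / (1 - exp(-d x))``.

    with ``x = M (a I - b)``.  Continuous at x = 0 where the analytic
    limit is 1/d (first-order Taylor 1/d + x/2 used inside |d x| < 1e-10).
    """
    x = np.asarray(M * (a * np.asarray(I, dtype=float) - b), dtype=float)
    dx = d * x
    small = np.abs(dx) < 1e-10
    safe = np.where(small, 1.0, dx)
    out = np.where(small, 1.0 / d + x / 2.0, x / -np.expm1(-safe))
    return out


def regional_gain(g: float, s: float, density) -> np.ndarray:
    """Receptor-density-modulated regional gain ``M_k = g (1 + s rho_k)``."""
    density = np.asarray(density, dtype=float)
    if not np.all(np.isfinite(density)):
        raise ValidationError("receptor density contains non-finite entries")
    return g * (1.0 + s * density)


class BEIModel(NeuralMassModel):
    state_names = STATE_NAMES
    coupling_var = 0        # S_E feeds long-range coupling
    applies_G = True        # G multiplies the raw weighted sum internally

    def __init__(self, n_regions: int, params: Optional[BEIParams] = None):
        super().__init__(n_regions)
        self.params = params if params is not None else BEIParams()
        self._J = as_region_vector(self.params.J, n_regions, "J")
        density = as_region_vector(self.params.receptor_density, n_regions,
                                   "receptor_density")
        self.M_E = regional_gain(self.params.g_E, self.params.gain_scale,
                                 density)
        if self.params.modulate_inhibitory:
            self.M_I = regional_gain(self.params.g_I, self.params.gain_scale,
                                     density)
        else:
            self.M_I = np.full(n_regions, self.params.g_I)

    @property
    def J(self) -> np.ndarray:
        return self._J

    @J.setter
    def J(self, value):
        self._J = as_region_vector(value, self.n_regions, "J")

    def dfun(self, values: np.ndarray, coupling=None):
        p = self.params
        self._check_shapes(values, coupling)
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite state passed to BEI dfun")
        S_E, S_I = values
        net = p.G * coupling if coupling is not None else 0.0
        I_E = (p.W_E * p.I_o + p.w_plus * p.J_N * S_E + p.J_N * net
               - self._J * S_I + p.I_ext)
        I_I = p.W_I * p.I_o + p.J_N * S_E - S_I + p.lambda_ * p.J_N * net
        r_E = gain_function(I_E, p.a_E, p.b_E, p.d_E, self.M_E)
        r_I = gain_function(I_I, p.a_I, p.b_I, p.d_I, self.M_I)
        # rates are in Hz = 1e-3/ms; time constants in ms
        dS_E = -S_E / p.tau_E + (1.0 - S_E) * p.gamma_kin * r_E * 1e-3
        dS_I = -S_I / p.tau_I + r_I * 1e-3
        obs = {"r_E": r_E, "r_I": r_I, "I_E": I_E, "I_I": I_I}
        return np.stack([dS_E, dS_I]), obs


def bei_derivatives(state: ModelState, coupling_input,
                    params: BEIParams) -> ModelState:
    """Functional form of the BEI derivative call.

    ``coupling_input`` is the raw weighted sum ``sum_j C_kj S_E_j``; the
    global gain G and synaptic weight J_N are applied inside.  Returns a
    ModelState holding the derivatives with the observables
    (r_E, r_I, I_E, I_I) filled.
    """
    model = BEIModel(state.n_regions, params)
    deriv, obs = model.dfun(state.values, coupling_input)
    out = ModelState(values=deriv, variable_names=STATE_NAMES)
    state.observables.update(obs)
    out.observables.update(obs)
    return out
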