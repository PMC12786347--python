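"""Hemodynamic forward models: neural rates to BOLD.

Two routes are provided, mirroring the standard fMRI forward-modelling
choices:

* ``balloon_windkessel`` — the Balloon-Windkessel state model: excitatory
  activity drives a vasodilatory signal ``s``, blood inflow ``f``, venous
  volume ``v`` and deoxyhemoglobin content ``q``; the BOLD percent signal
  is a nonlinear readout of (v, q).  A ``log_state`` variant integrates
  the logs of the intrinsically positive states (f, v, q), guaranteeing
  positivity at any step size.
* ``hrf_convolve`` — linear convolution with a first-order Volterra
  kernel (damped sinusoid), the impulse response of the linearized
  hemodynamic cascade.

Plus ``temporal_average``, the plain block-mean downsampler used by the
temporal-average monitor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ValidationError, WbsimError


@dataclass
class BoldSeries:
    """Uniformly sampled BOLD signal: times in s, values (region, sample)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 2:
            raise ValidationError("BoldSeries needs 1-D times and 2-D values")
        if self.values.shape[1] != self.times.size:
            raise ValidationError(
                f"{self.values.shape[1]} samples vs {self.times.size} "
                f"time points")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel constants (Stephan et al. 2007 style defaults).

    Rates in 1/s, times in s.  ``k1, k2, k3`` follow the echo-time
    parameterization k1 = 4.3 * theta0 * rho * TE, k2 = eps * r0 * rho * TE,
    k3 = 1 - eps with theta0 = 40.3 1/s, r0 = 25 1/s, TE = 0.04 s,
    eps = 0.5.
    """

    kappa: float = 0.65       # vasodilatory signal decay, 1/s
    gamma_h: float = 0.41     # flow-dependent feedback rate, 1/s
    tau_h: float = 0.98       # venous transit time, s
    alpha: float = 0.32       # Grubb vessel-stiffness exponent
    rho: float = 0.34         # resting oxygen extraction fraction
    v0: float = 0.04          # resting venous blood volume fraction
    k1: float = 4.3 * 40.3 * 0.34 * 0.04
    k2: float = 0.5 * 25.0 * 0.34 * 0.04
    k3: float = 0.5
    variant: str = "standard"           # or "log_state"
    sampling_period: float = 2.0        # TR, s
    drive_scale: float = 0.5            # neural drive = scale * r + offset
    drive_offset: float = 3.0

    def __post_init__(self):
        if self.variant not in ("standard", "log_state"):
            raise ValidationError(
                f"unknown variant {self.variant!r}; use 'standard' or "
                f"'log_state'")
        for name in ("tau_h", "alpha", "rho", "v0"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.sampling_period <= 0:
            raise ValidationError("sampling_period must be positive")

    def with_(self, **kwargs) -> "HemodynamicParams":
        return replace(self, **kwargs)


@dataclass
class HRFParams:
    """First-order Volterra kernel parameters (damped sinusoid)."""

    tau_s: float = 0.8        # signal decay time, s
    tau_f: float = 0.4        # feedback time, s
    length: float = 20.0      # kernel support, s
    sampling_period: float = 2.0  # TR, s

    def __post_init__(self):
        if self.tau_s <= 0 or self.tau_f <= 0 or self.length <= 0:
            raise ValidationError("HRF parameters must be positive")
        if 1.0 / self.tau_f <= 1.0 / (4.0 * self.tau_s ** 2):
            raise ValidationError(
                "underdamped kernel requires 1/tau_f > 1/(4 tau_s^2)")


def temporal_average(raw: np.ndarray, period: float, dt: float):
    """Non-overlapping block means along the leading (time) axis.

    Timestamps are at block ends (ms); a trailing partial block is
    dropped.  ``period`` must be an integer multiple of ``dt``.
    """
    raw = np.asarray(raw, dtype=float)
    ratio = period / dt
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9:
        raise ValidationError(
            f"period {period} ms is not an integer multiple of dt={dt} ms")
    n_blocks = raw.shape[0] // stride
    trimmed = raw[:n_blocks * stride]
    blocks = trimmed.reshape((n_blocks, stride) + raw.shape[1:])
    times = (np.arange(1, n_blocks + 1)) * period
    return times, blocks.mean(axis=1)


def _balloon_drive(rate: np.ndarray, p: HemodynamicParams) -> np.ndarray:
    return p.drive_scale * rate + p.drive_offset


def balloon_windkessel(rate: np.ndarray, dt: float,
                       params: Optional[HemodynamicParams] = None
                       ) -> BoldSeries:
    """Integrate the Balloon-Windkessel model over a rate time series.

    ``rate`` is (region, time) in Hz sampled at ``dt`` ms.  Per region::

        ds/dt = drive(r) - kappa*s - gamma_h*(f - 1)
        df/dt = s
        dv/dt = (f - v**(1/alpha)) / tau_h
        dq/dt = (f*(1 - (1-rho)**(1/f))/rho - q*v**(1/alpha - 1)) / tau_h
        B     = v0*(k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))

    integrated with deterministic Euler at the input dt, initial state
    s=0, f=v=q=1, and subsampled at the TR.  The ``log_state`` variant
    integrates ln f, ln v, ln q (derivative F(z)/z) and exponentiates, so
    the positive states stay positive by construction; the standard
    variant raises if f, v or q becomes nonpositive rather than clipping.
    """
    p = params if params is not None else HemodynamicParams()
    rate = np.asarray(rate, dtype=float)
    if rate.ndim != 2:
        raise ValidationError("rate must be (regions, time)")
    if not np.all(np.isfinite(rate)):
        raise ValidationError("rate contains non-finite entries")
    n, T = rate.shape
    dt_s = dt * 1e-3
    log_state = p.variant == "log_state"
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    stride = max(int(round(p.sampling_period / dt_s)), 1)
    out_times = []
    out_vals = []
    inv_alpha = 1.0 / p.alpha
    for t in range(T):
        drive = _balloon_drive(rate[:, t], p)
        ds = drive - p.kappa * s - p.gamma_h * (f - 1.0)
        df = s
        dv = (f - v ** inv_alpha) / p.tau_h
        dq = (f * (1.0 - (1.0 - p.rho) ** (1.0 / f)) / p.rho
              - q * v ** (inv_alpha - 1.0)) / p.tau_h
        s = s + dt_s * ds
        if log_state:
            f = f * np.exp(dt_s * df / f)
            v = v * np.exp(dt_s * dv / v)
            q = q * np.exp(dt_s * dq / q)
        else:
            f = f + dt_s * df
            v = v + dt_s * dv
            q = q + dt_s * dq
            for name, z in (("f", f), ("v", v), ("q", q)):
                if np.any(z <= 0.0):
                    k = int(np.argwhere(z <= 0.0)[0][0])
                    raise WbsimError(
                        f"hemodynamic state {name}[{k}] = {z[k]:.3g} "
                        f"nonpositive at step {t}; use the log_state "
                        f"variant")
        if (t + 1) % stride == 0:
            B = p.v0 * (p.k1 * (1.0 - q) + p.k2 * (1.0 - q / v)
                        + p.k3 * (1.0 - v))
            out_times.append((t + 1) * dt_s)
            out_vals.append(B.copy())
    if not out_times:
        return BoldSeries(times=np.empty(0), values=np.empty((n, 0)))
    return BoldSeries(times=np.asarray(out_times),
                      values=np.stack(out_vals, axis=1))


def balloon_steady_state(rate: float, params: HemodynamicParams):
    """Stationary (s, f, v, q, B) under a constant rate (analysis helper).

    Solves the four stationarity equations with a root finder; used to
    cross-check the time integration.
    """
    from scipy.optimize import fsolve
    p = params
    drive = _balloon_drive(np.asarray(rate, dtype=float), p)

    def residual(x):
        s, f, v, q = x
        return [
            drive - p.kappa * s - p.gamma_h * (f - 1.0),
            s,
            (f - v ** (1.0 / p.alpha)) / p.tau_h,
            (f * (1.0 - (1.0 - p.rho) ** (1.0 / f)) / p.rho
             - q * v ** (1.0 / p.alpha - 1.0)) / p.tau_h,
        ]

    sol, info, ier, msg = fsolve(residual, [0.0, 1.0, 1.0, 1.0],
                                 full_output=True)
    if ier != 1:
        raise WbsimError(f"steady-state solve failed: {msg}")
    s, f, v, q = sol
    B = p.v0 * (p.k1 * (1.0 - q) + p.k2 * (1.0 - q / v) + p.k3 * (1.0 - v))
    return s, f, v, q, B


def volterra_kernel(params: HRFParams, dt: float) -> np.ndarray:
    """Sampled first-order Volterra kernel (damped sinusoid), dt in ms.

    h(t) = exp(-t / (2 tau_s)) * sin(omega t) / omega with
    omega = sqrt(1/tau_f - 1/(4 tau_s^2)); the impulse response of the
    linearized flow dynamics.
    """
    dt_s = dt * 1e-3
    t = np.arange(0.0, params.length, dt_s)
    omega = np.sqrt(1.0 / params.tau_f - 1.0 / (4.0 * params.tau_s ** 2))
    return np.exp(-t / (2.0 * params.tau_s)) * np.sin(omega * t) / omega


def hrf_convolve(signal: np.ndarray, dt: float,
                 kernel_params: Optional[HRFParams] = None) -> BoldSeries:
    """Causal convolution of each region's signal with the HRF kernel.

    ``signal`` is (region, time) at ``dt`` ms; output is subsampled at the
    TR.  Linear and time-invariant by construction; the convolution sum is
    scaled by dt (seconds) to approximate the continuous integral.
    """
    p = kernel_params if kernel_params is not None else HRFParams()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValidationError("signal must be (regions, time)")
    kernel = volterra_kernel(p, dt)
    n, T = signal.shape
    if kernel.size >= T:
        raise ValidationError(
            f"kernel ({kernel.size} samples) must be shorter than the "
            f"signal ({T} samples)")
    dt_s = dt * 1e-3
    full = np.stack([np.convolve(signal[k], kernel)[:T] * dt_s
                     for k in range(n)])
    stride = max(int(round(p.sampling_period / dt_s)), 1)
    idx = np.arange(stride - 1, T, stride)
    return BoldSeries(times=(idx + 1) * dt_s, values=full[:, idx])


def save_bold_npz(series: BoldSeries, path) -> None:
    """Write a BoldSeries as NPZ with keys ``times`` (s) and ``data``."""
    np.savez(path, times=series.times, data=series.values)


def load_bold_npz(path) -> BoldSeries:
    with np.load(path) as npz:
        return BoldSeries(times=npz["times"], values=npz["data"])


def save_bold_tsv(series: BoldSeries, path) -> None:
    """Write a BoldSeries as TSV: first column time (s), one per region."""
    table = np.column_stack([series.times, series.values.T])
    header = "time_s\t" + "\t".join(
        f"region_{k}" for k in range(series.n_regions))
    np.savetxt(path, table, delimiter="\t", header=header, comments="")


#: monitor keyword -> implementation, mirroring the reference platform's
#: three BOLD options
_METHODS = ("Stephan2007", "Stephan2007b", "hrf_convolution")


def bold_dispatch(method: str, rate: np.ndarray, dt: float,
                  params=None) -> BoldSeries:
    """Route to a BOLD method by name.

    ``Stephan2007`` is the standard Balloon-Windkessel, ``Stephan2007b``
    its positivity-preserving log-state variant, ``hrf_convolution`` the
    Volterra-kernel convolution.
    """
    if method == "Stephan2007":
        p = params if params is not None else HemodynamicParams()
        return balloon_windkessel(rate, dt, p.with_(variant="standard"))
    if method == "Stephan2007b":
        p = params if params is not None else HemodynamicParams()
        return balloon_windkessel(rate, dt, p.with_(variant="log_state"))
    if method == "hrf_convolution":
        return hrf_convolve(rate, dt, params)
    raise ValidationError(
        f"unknown BOLD method {method!r}; valid methods: {_METHODS}")
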