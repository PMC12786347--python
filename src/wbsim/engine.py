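"""Dynamics engine: delay history, linear coupling, noise, integrators.

The engine advances any neural-mass model through a uniform derivative
contract: ``dfun(values, coupling) -> derivatives`` or
``(derivatives, observables)``, where ``values`` is a
``state_variable x region`` array and ``coupling`` a per-region input
vector built from the (optionally delayed) network activity.

Four fixed-step schemes are provided: deterministic Euler and Heun, and
their stochastic counterparts (Euler-Maruyama and stochastic Heun) with
additive Gaussian noise scaled by ``sigma * sqrt(dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .connectome import DelaySteps
from .errors import DivergenceError, ValidationError

SCHEMES = ("euler", "euler_maruyama", "heun", "heun_stochastic")
STOCHASTIC_SCHEMES = ("euler_maruyama", "heun_stochastic")


def make_rng(seed: int) -> np.random.Generator:
    """Independent, reproducible random stream from an integer seed."""
    return np.random.default_rng(seed)


@dataclass
class NoiseSpec:
    """Additive Gaussian noise description.

    ``sigma`` is a per-state-variable amplitude (scalar or vector); a zero
    entry disables noise on that variable.  Draws are standard normal,
    uncorrelated across variables, regions, and steps.
    """

    sigma: Union[float, Sequence[float]] = 0.0
    seed: int = 0

    def __post_init__(self):
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sig < 0):
            raise ValidationError("noise sigma must be nonnegative")
        self.sigma = sig
        self._column_cache = {}

    def column(self, n_vars: int) -> np.ndarray:
        """Sigma as an (n_vars, 1) column, broadcasting scalars."""
        cached = self._column_cache.get(n_vars)
        if cached is not None:
            return cached
        sig = self.sigma
        if sig.size == 1:
            sig = np.full(n_vars, sig[0])
        elif sig.size != n_vars:
            raise ValidationError(
                f"noise sigma has {sig.size} entries for {n_vars} state "
                f"variables")
        col = sig[:, None]
        self._column_cache[n_vars] = col
        return col


@dataclass
class IntegratorSpec:
    """Integration scheme, step size (ms) and optional noise."""

    scheme: str = "euler"
    dt: float = 0.1
    noise: Optional[NoiseSpec] = None

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}; "
                                  f"choose from {SCHEMES}")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.scheme in STOCHASTIC_SCHEMES and self.noise is None:
            raise ValidationError(
                f"scheme {self.scheme!r} requires a NoiseSpec")


class DelayBuffer:
    """Ring buffer of past coupling-variable vectors.

    Querying at lag 0 returns the most recently pushed vector; lags up to
    ``max_delay`` reach back in integer steps.
    """

    def __init__(self, n_regions: int, max_delay: int,
                 fill: Optional[np.ndarray] = None):
        self.n_regions = n_regions
        self.capacity = max_delay + 1
        self._storage = np.zeros((self.capacity, n_regions))
        if fill is not None:
            fill = np.asarray(fill, dtype=float)
            if fill.shape != (n_regions,):
                raise ValidationError(
                    f"history fill has shape {fill.shape}, expected "
                    f"({n_regions},)")
            self._storage[:] = fill
        self._cursor = self.capacity - 1

    def push(self, current: np.ndarray) -> None:
        current = np.asarray(current, dtype=float)
        if current.shape != (self.n_regions,):
            raise ValidationError(
                f"pushed vector has shape {current.shape}, expected "
                f"({self.n_regions},)")
        self._cursor = (self._cursor + 1) % self.capacity
        self._storage[self._cursor] = current

    def query(self, lag: int) -> np.ndarray:
        if not 0 <= lag < self.capacity:
            raise ValidationError(
                f"lag {lag} exceeds buffer capacity {self.capacity}")
        return self._storage[(self._cursor - lag) % self.capacity]

    def query_lags(self, lags: np.ndarray) -> np.ndarray:
        """Delayed activity matrix ``D[k, j] = S_j(t - lags[k, j] * dt)``."""
        lags = np.asarray(lags)
        if lags.max(initial=0) >= self.capacity:
            raise ValidationError(
                f"lag {lags.max()} exceeds buffer capacity {self.capacity}")
        rows = (self._cursor - lags) % self.capacity
        return self._storage[rows, np.arange(self.n_regions)[None, :]]


def linear_coupling(weights: np.ndarray, buffer: DelayBuffer,
                    delays: Optional[DelaySteps], G: float) -> np.ndarray:
    """Delayed linear network input.

    ``out[k] = G * sum_j weights[k, j] * S_j(t - delays[k, j] * dt)``;
    a ``None`` or delay-free ``delays`` uses the current activity (lag 0).
    """
    if delays is None or delays.delay_free or delays.max_delay == 0:
        return G * (weights @ buffer.query(0))
    delayed = buffer.query_lags(delays.steps)
    return G * np.einsum("kj,kj->k", weights, delayed)


def _split(result):
    """Normalize a dfun return value to (derivatives, observables)."""
    if isinstance(result, tuple):
        return result
    return result, {}


def integrator_step(values: np.ndarray, dfun: Callable,
                    spec: IntegratorSpec, coupling=None,
                    rng: Optional[np.random.Generator] = None,
                    step_index: int = 0):
    """Advance the state one step of ``spec.dt`` milliseconds.

    Returns ``(new_values, observables)`` where the observables are those
    filled by the derivative call at the pre-step state.  Stochastic
    schemes add ``sigma * sqrt(dt) * xi`` with one standard-normal draw per
    variable and region per step; in stochastic Heun the single draw is
    shared by predictor and corrector.
    """
    dt = spec.dt
    stochastic = spec.scheme in STOCHASTIC_SCHEMES
    noise = 0.0
    if stochastic:
        if rng is None:
            rng = make_rng(spec.noise.seed)
        sigma = spec.noise.column(values.shape[0])
        xi = rng.standard_normal(values.shape)
        noise = sigma * np.sqrt(dt) * xi

    k1, obs = _split(dfun(values, coupling))
    if spec.scheme in ("euler", "euler_maruyama"):
        new = values + dt * k1 + noise
    else:  # heun / heun_stochastic
        predictor = values + dt * k1 + noise
        k2, _ = _split(dfun(predictor, coupling))
        new = values + 0.5 * dt * (k1 + k2) + noise

    if not np.all(np.isfinite(new)):
        bad_var = int(np.argwhere(~np.isfinite(new))[0][0])
        raise DivergenceError(step_index, variable=bad_var)
    return new, obs


@dataclass
class MonitorSpec:
    """What to record and at which period.

    ``kind`` is ``raw`` (every step) or ``temporal_average`` (block means
    over ``period`` ms, an integer multiple of dt).  ``variables`` selects
    state-variable rows; ``observables`` selects named per-region outputs
    of the model's derivative call.
    """

    kind: str = "raw"
    period: float = 1.0
    variables: Sequence[int] = (0,)
    observables: Sequence[str] = ()

    def __post_init__(self):
        if self.kind not in ("raw", "temporal_average"):
            raise ValidationError(f"unknown monitor kind {self.kind!r}")


class Monitor:
    """Accumulates selected rows of the running simulation."""

    def __init__(self, spec: MonitorSpec, dt: float):
        self.spec = spec
        self.dt = dt
        if spec.kind == "raw":
            self.stride = 1
        else:
            ratio = spec.period / dt
            self.stride = int(round(ratio))
            if self.stride < 1 or abs(ratio - self.stride) > 1e-9:
                raise ValidationError(
                    f"monitor period {spec.period} ms is not an integer "
                    f"multiple of dt={dt} ms")
        self._block = []
        self._times = []
        self._samples = []

    def _select(self, values, obs):
        rows = [values[i] for i in self.spec.variables]
        for name in self.spec.observables:
            if name not in obs:
                raise ValidationError(
                    f"model does not expose observable {name!r} "
                    f"(available: {sorted(obs)})")
            rows.append(obs[name])
        return np.array(rows)

    def record(self, step_index: int, values, obs) -> None:
        self._block.append(self._select(values, obs))
        if len(self._block) == self.stride:
            self._samples.append(np.mean(self._block, axis=0)
                                 if self.stride > 1 else self._block[0])
            self._times.append((step_index + 1) * self.dt)
            self._block = []

    def finalize(self):
        """Return ``(times_ms, data)``; data is (selected, regions, samples).

        A trailing partial averaging block is dropped.
        """
        if not self._samples:
            n_sel = len(self.spec.variables) + len(self.spec.observables)
            return np.empty(0), np.empty((n_sel, 0, 0))
        data = np.stack(self._samples, axis=-1)
        return np.asarray(self._times), data


def simulate(model, spec: IntegratorSpec, duration: float,
             weights: Optional[np.ndarray] = None,
             delays: Optional[DelaySteps] = None, G: float = 0.0,
             monitors: Sequence[Monitor] = (),
             initial: Optional[np.ndarray] = None,
             rng: Optional[np.random.Generator] = None) -> int:
    """Core simulation loop; feeds monitors each step, returns step count.

    The delay history is pre-filled with the initial coupling-variable
    values (zeros for the default zero initial state).  Models that apply
    the global coupling gain inside their own current equations (flagged by
    ``model.applies_G``) receive the raw weighted sum; the gain is then
    taken from their parameter set.
    """
    if duration < 0:
        raise ValidationError("duration must be nonnegative")
    n = model.n_regions
    values = (model.initial_state() if initial is None
              else np.array(initial, dtype=float))
    if values.shape != (model.n_vars, n):
        raise ValidationError(
            f"initial state shape {values.shape}, expected "
            f"({model.n_vars}, {n})")
    n_steps = int(round(duration / spec.dt))
    max_delay = 0 if delays is None else delays.max_delay
    buffer = DelayBuffer(n, max_delay, fill=values[model.coupling_var])
    if weights is None:
        weights = np.zeros((n, n))
    coupling_gain = 1.0 if getattr(model, "applies_G", False) else G
    if spec.scheme in STOCHASTIC_SCHEMES and rng is None:
        rng = make_rng(spec.noise.seed)

    for i in range(n_steps):
        coupling = linear_coupling(weights, buffer, delays, coupling_gain)
        values, obs = integrator_step(values, model.dfun, spec,
                                      coupling=coupling, rng=rng,
                                      step_index=i)
        buffer.push(values[model.coupling_var])
        for monitor in monitors:
            monitor.record(i, values, obs)
    return n_steps
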