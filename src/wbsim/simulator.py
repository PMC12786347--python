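"""Simulation orchestration: configuration, validation, execution.

A :class:`SimulationConfig` gathers every component of a run —
connectome, model, integrator, coupling, monitors, duration, seed — and
``run_simulation`` validates the assembly, wires the pieces, steps the
engine, and returns one (times, data) pair per monitor plus a metadata
echo sufficient to re-run the simulation exactly.

All randomness flows from the single top-level seed, expanded into
per-component streams.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field, replace
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np

from . import __version__
from .connectome import Connectome, delay_matrix, load_connectome
from .engine import (IntegratorSpec, Monitor, MonitorSpec, NoiseSpec,
                     make_rng, simulate)
from .errors import ConfigError, ValidationError
from .models import MODEL_REGISTRY, build_model


@dataclass
class SimulationConfig:
    """Complete description of a simulation run."""

    connectome: Optional[Union[Connectome, str]] = None
    model: str = "bei"
    model_params: Optional[Any] = None     # params dataclass or dict
    integrator: IntegratorSpec = field(default_factory=IntegratorSpec)
    G: float = 0.0
    conduction_speed: Optional[float] = None   # mm/ms; None = delay-free
    initial_state: Optional[np.ndarray] = None
    monitors: List[MonitorSpec] = field(
        default_factory=lambda: [MonitorSpec(kind="temporal_average",
                                             period=1.0, variables=(0,))])
    duration: float = 1000.0       # ms
    seed: int = 0


@dataclass
class SimulationResult:
    """Per-monitor (times, data) pairs plus a re-runnable config echo."""

    outputs: List[tuple]
    config: SimulationConfig
    metadata: Dict[str, Any] = field(default_factory=dict)


def _resolve_connectome(config: SimulationConfig) -> Connectome:
    conn = config.connectome
    if conn is None:
        raise ConfigError("configuration is missing: connectome")
    if isinstance(conn, Connectome):
        return conn
    return load_connectome(conn)


def validate_config(config: SimulationConfig) -> None:
    missing = []
    if config.connectome is None:
        missing.append("connectome")
    if config.model not in MODEL_REGISTRY:
        raise ConfigError(f"unknown model {config.model!r}; choose from "
                          f"{sorted(MODEL_REGISTRY)}")
    if config.duration < 0:
        raise ConfigError("duration must be nonnegative")
    if missing:
        raise ConfigError(
            f"configuration is missing: {', '.join(missing)}")


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Validate, wire, and execute a configured simulation.

    The state is initialized to zeros unless ``initial_state`` is given;
    the delay history is pre-filled with the initial coupling-variable
    values.  Bit-reproducible given the seed.
    """
    validate_config(config)
    conn = _resolve_connectome(config)
    n = conn.n_regions

    params = config.model_params
    model = build_model(config.model, n, params)
    # models that own the coupling gain read it from their parameter set
    if model.applies_G and hasattr(model.params, "G"):
        model.params = model.params.with_(G=config.G)

    delays = None
    if config.conduction_speed is not None and conn.tract_lengths is not None:
        delays = delay_matrix(conn, config.conduction_speed,
                              config.integrator.dt)

    seed_seq = np.random.SeedSequence(config.seed)
    noise_seed = int(seed_seq.generate_state(1)[0] % (2 ** 31))
    spec = config.integrator
    if spec.noise is not None:
        spec = replace(spec, noise=replace(spec.noise, seed=noise_seed))
    rng = make_rng(noise_seed)

    monitors = [Monitor(m, spec.dt) for m in config.monitors]
    n_steps = simulate(model, spec, config.duration, weights=conn.weights,
                       delays=delays, G=config.G, monitors=monitors,
                       initial=config.initial_state, rng=rng)
    outputs = [m.finalize() for m in monitors]
    metadata = {
        "wbsim_version": __version__,
        "n_regions": n,
        "n_steps": n_steps,
        "seed": config.seed,
        "noise_seed": noise_seed,
        "model": config.model,
        "scheme": spec.scheme,
        "dt": spec.dt,
    }
    return SimulationResult(outputs=outputs, config=config,
                            metadata=metadata)


def run_many(configs: Sequence[SimulationConfig],
             n_processes: int = 1) -> List[SimulationResult]:
    """Run independent simulations, optionally across processes.

    Each configuration carries its own seed, so results are identical
    whether executed serially or in a process pool; order follows the
    input order.
    """
    if n_processes <= 1:
        return [run_simulation(c) for c in configs]
    from concurrent.futures import ProcessPoolExecutor
    with ProcessPoolExecutor(max_workers=n_processes) as pool:
        return list(pool.map(run_simulation, configs))


def get_model_parameters(config: SimulationConfig) -> Dict[str, Any]:
    """Name -> value mapping of the configured model's parameters."""
    if config.model not in MODEL_REGISTRY:
        raise ConfigError(f"unknown model {config.model!r}")
    _, params_cls = MODEL_REGISTRY[config.model]
    params = config.model_params
    if params is None:
        params = params_cls()
    elif isinstance(params, dict):
        params = params_cls(**params)
    return dataclasses.asdict(params)


def set_model_parameters(config: SimulationConfig,
                         mapping: Dict[str, Any]) -> SimulationConfig:
    """Return a new config with the given parameter overrides applied.

    Unknown names are rejected with a nearest-match suggestion.
    """
    current = get_model_parameters(config)
    _, params_cls = MODEL_REGISTRY[config.model]
    valid = {f.name for f in dataclasses.fields(params_cls)}
    for key in mapping:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(
                f"unknown parameter {key!r} for model "
                f"{config.model!r}{suffix}")
    current.update(mapping)
    # transfer coefficients come back from asdict as plain dicts
    from .models import TransferCoeffs
    for key in ("coeffs_e", "coeffs_i"):
        if key in current and isinstance(current[key], dict):
            current[key] = TransferCoeffs(**current[key])
    return replace(config, model_params=params_cls(**current))
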