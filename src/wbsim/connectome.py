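"""Structural connectome handling.

A connectome is a weighted directed graph over brain regions: a nonnegative
``weights`` matrix of coupling strengths (row ``k`` receives from column
``j``) and, optionally, a ``tract_lengths`` matrix in millimetres from which
conduction delays are derived.  Matrices are full and carry no symmetry
constraint; directed (asymmetric) connectomes are used as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConnectomeError, ValidationError

logger = logging.getLogger(__name__)

#: canonical NPZ keys; "lengths" is accepted as a read alias for
#: "tract_lengths" (common in existing datasets)
WEIGHT_KEY = "weights"
LENGTH_KEY = "tract_lengths"
LENGTH_ALIASES = ("tract_lengths", "lengths")


@dataclass
class Connectome:
    """Validated structural connectome.

    Parameters
    ----------
    weights
        ``(n, n)`` nonnegative coupling-strength matrix (dimensionless).
        Row ``k`` holds the incoming connections of region ``k``.
    tract_lengths
        Optional ``(n, n)`` nonnegative fibre-length matrix in mm.  When
        absent the network is simulated delay-free.
    labels
        Optional region identifiers.
    """

    weights: np.ndarray
    tract_lengths: Optional[np.ndarray] = None
    labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.weights = _validate_matrix(np.asarray(self.weights, dtype=float),
                                        "weights")
        if np.any(np.diag(self.weights) != 0.0):
            warnings.warn("self-connections found on the weights diagonal; "
                          "zeroing them (self-coupling is not modelled)")
            np.fill_diagonal(self.weights, 0.0)
        if self.tract_lengths is not None:
            tl = _validate_matrix(np.asarray(self.tract_lengths, dtype=float),
                                  "tract_lengths")
            if tl.shape != self.weights.shape:
                raise ConnectomeError(
                    f"tract_lengths shape {tl.shape} does not match weights "
                    f"shape {self.weights.shape}")
            self.tract_lengths = tl
        if self.labels is not None and len(self.labels) != self.n_regions:
            raise ConnectomeError(
                f"{len(self.labels)} labels for {self.n_regions} regions")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class DelaySteps:
    """Inter-regional conduction delays in whole integration steps."""

    steps: np.ndarray
    max_delay: int = field(init=False)
    delay_free: bool = False

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=np.int64)
        if np.any(self.steps < 0):
            raise ValidationError("delay steps must be nonnegative")
        self.max_delay = int(self.steps.max(initial=0))


def _validate_matrix(m: np.ndarray, name: str) -> np.ndarray:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeError(f"{name} must be square, got shape {m.shape}")
    bad = ~np.isfinite(m)
    if bad.any():
        k, j = np.argwhere(bad)[0]
        raise ConnectomeError(f"{name}[{k}, {j}] is not finite")
    neg = m < 0
    if neg.any():
        k, j = np.argwhere(neg)[0]
        raise ConnectomeError(f"{name}[{k}, {j}] = {m[k, j]} is negative")
    return m


def load_connectome(path, weight_key: str = WEIGHT_KEY,
                    length_key: Optional[str] = None) -> Connectome:
    """Load a connectome from an NPZ archive.

    ``length_key=None`` tries the aliases ``tract_lengths``/``lengths`` and
    falls back to a delay-free connectome when neither is present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"connectome archive not found: {path}")
    with np.load(path, allow_pickle=False) as npz:
        keys = list(npz.keys())
        if weight_key not in keys:
            raise KeyError(f"key {weight_key!r} not in {path} "
                           f"(available: {keys})")
        weights = npz[weight_key]
        lengths = None
        if length_key is not None:
            if length_key not in keys:
                raise KeyError(f"key {length_key!r} not in {path} "
                               f"(available: {keys})")
            lengths = npz[length_key]
        else:
            for alias in LENGTH_ALIASES:
                if alias in keys:
                    lengths = npz[alias]
                    break
        labels = list(npz["labels"]) if "labels" in keys else None
    return Connectome(weights=weights, tract_lengths=lengths, labels=labels)


def save_connectome(conn: Connectome, path) -> Path:
    """Write a connectome as NPZ with the canonical keys."""
    path = Path(path)
    payload = {WEIGHT_KEY: conn.weights}
    if conn.tract_lengths is not None:
        payload[LENGTH_KEY] = conn.tract_lengths
    if conn.labels is not None:
        payload["labels"] = np.asarray(conn.labels)
    np.savez(path, **payload)
    return path


def _load_mat(mat_path: Path) -> dict:
    """Read a MAT file (v5 via scipy, v7.3 via h5py) into plain arrays."""
    try:
        from scipy.io import loadmat
        raw = loadmat(mat_path)
        return {k: np.asarray(v) for k, v in raw.items()
                if not k.startswith("__")}
    except NotImplementedError:
        # MAT v7.3 files are HDF5 under the hood
        import h5py
        out = {}
        with h5py.File(mat_path, "r") as f:
            for k in f.keys():
                if isinstance(f[k], h5py.Dataset):
                    # MATLAB stores arrays column-major; transpose back
                    out[k] = np.asarray(f[k]).T
        return out


def convert_structural_archive(mat_path, out_path,
                               key_map: Mapping[str, str]) -> Path:
    """Convert a MAT structural archive to the canonical NPZ layout.

    ``key_map`` maps source variable names to the canonical roles
    ``"weights"`` and (optionally) ``"tract_lengths"``; values are copied
    numerically unchanged.
    """
    mat_path = Path(mat_path)
    if not mat_path.exists():
        raise FileNotFoundError(f"MAT archive not found: {mat_path}")
    variables = _load_mat(mat_path)
    payload = {}
    for src, role in key_map.items():
        if role not in (WEIGHT_KEY, LENGTH_KEY):
            raise KeyError(f"unknown target role {role!r}; expected "
                           f"{WEIGHT_KEY!r} or {LENGTH_KEY!r}")
        if src not in variables:
            raise KeyError(f"variable {src!r} not in {mat_path} "
                           f"(available: {sorted(variables)})")
        payload[role] = np.asarray(variables[src], dtype=float)
    if WEIGHT_KEY not in payload:
        raise KeyError(f"key_map must assign a source variable to "
                       f"{WEIGHT_KEY!r}")
    out_path = Path(out_path)
    np.savez(out_path, **payload)
    return out_path


def synthetic_connectome(n: int, density: float = 0.3,
                         weight_scale: float = 1.0,
                         length_range: tuple = (20.0, 160.0),
                         seed: int = 0) -> Connectome:
    """Generate a random directed connectome for testing and demos.

    Off-diagonal edges exist independently with probability ``density``;
    edge weights are log-normal, rescaled so the maximum equals
    ``weight_scale``; tract lengths are uniform over ``length_range`` (mm)
    on existing edges.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0.0 <= density <= 1.0:
        raise ValidationError(f"density must lie in [0, 1], got {density}")
    lo, hi = length_range
    if not (0.0 <= lo <= hi):
        raise ValidationError(f"degenerate length_range {length_range}")
    if weight_scale <= 0:
        raise ValidationError(f"weight_scale must be positive, got "
                              f"{weight_scale}")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    weights = np.zeros((n, n))
    if mask.any():
        weights[mask] = rng.lognormal(mean=0.0, sigma=1.0, size=mask.sum())
        weights *= weight_scale / weights.max()
    lengths = np.zeros((n, n))
    if mask.any():
        lengths[mask] = rng.uniform(lo, hi, size=mask.sum())
    return Connectome(weights=weights, tract_lengths=lengths,
                      labels=[f"R{i:03d}" for i in range(n)])


def load_regional_map(path, key: Optional[str] = None) -> np.ndarray:
    """Load a per-region scalar map (e.g. receptor densities).

    Accepts an NPZ archive (``key`` selects the array; defaults to the
    single/first array) or a single-column text file.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            name = key if key is not None else list(npz.keys())[0]
            if name not in npz:
                raise KeyError(f"key {name!r} not in {path} "
                               f"(available: {list(npz.keys())})")
            vec = np.asarray(npz[name], dtype=float).ravel()
    else:
        vec = np.atleast_1d(np.loadtxt(path, dtype=float)).ravel()
    if not np.all(np.isfinite(vec)):
        raise ValidationError(f"regional map {path} has non-finite entries")
    return vec


def delay_matrix(conn: Connectome, conduction_speed: float,
                 dt: float) -> DelaySteps:
    """Discretize tract lengths into integer-step conduction delays.

    ``steps[k, j] = round(L_kj / (v * dt))`` with ``v`` in mm/ms and ``dt``
    in ms; rounding is half-away-from-zero.  A connectome without tract
    lengths yields an all-zero, delay-free matrix.
    """
    if conduction_speed <= 0:
        raise ValidationError(f"conduction_speed must be positive, got "
                              f"{conduction_speed}")
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    n = conn.n_regions
    if conn.tract_lengths is None:
        return DelaySteps(steps=np.zeros((n, n), dtype=np.int64),
                          delay_free=True)
    raw = conn.tract_lengths / (conduction_speed * dt)
    steps = np.floor(raw + 0.5).astype(np.int64)  # half away from zero (L>=0)
    return DelaySteps(steps=steps, delay_free=False)
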