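"""Uniform neural-mass model contract.

A model exposes ordered state-variable names, the index of the variable
that feeds long-range coupling, and a derivative function
``dfun(values, coupling) -> (derivatives, observables)`` operating on a
``state_variable x region`` array.  Time is in milliseconds and firing
rates in hertz throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from ..errors import ValidationError


@dataclass
class ModelState:
    """State-variable-by-region matrix plus named observable outputs."""

    values: np.ndarray
    variable_names: Sequence[str]
    observables: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"state must be 2-D (variables x regions), got shape "
                f"{self.values.shape}")
        if self.values.shape[0] != len(self.variable_names):
            raise ValidationError(
                f"{self.values.shape[0]} state rows for "
                f"{len(self.variable_names)} variable names")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("state contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[list(self.variable_names).index(name)]


class NeuralMassModel:
    """Base class binding a parameter set to a region count.

    Subclasses set ``state_names``, ``coupling_var`` (row index of the
    variable broadcast over the connectome), ``applies_G`` (True when the
    global coupling gain lives in the model's own parameter set rather
    than in the engine's coupling function), and implement ``dfun``.
    """

    state_names: tuple = ()
    coupling_var: int = 0
    applies_G: bool = False

    def __init__(self, n_regions: int):
        self.n_regions = int(n_regions)

    @property
    def n_vars(self) -> int:
        return len(self.state_names)

    def initial_state(self) -> np.ndarray:
        """Default initial state: zeros (matching the reference platform)."""
        return np.zeros((self.n_vars, self.n_regions))

    def dfun(self, values: np.ndarray, coupling: Optional[np.ndarray]):
        raise NotImplementedError

    def deriv(self, values, coupling=None) -> np.ndarray:
        """Derivatives only (convenience wrapper around ``dfun``)."""
        return self.dfun(values, coupling)[0]

    def _check_shapes(self, values, coupling):
        if values.shape != (self.n_vars, self.n_regions):
            raise ValidationError(
                f"state shape {values.shape}, expected "
                f"({self.n_vars}, {self.n_regions})")
        if coupling is not None and \
                np.shape(coupling) not in ((), (self.n_regions,)):
            raise ValidationError(
                f"coupling shape {np.shape(coupling)}, expected "
                f"({self.n_regions},)")


def as_region_vector(x, n_regions: int, name: str = "parameter") -> np.ndarray:
    """Broadcast a scalar or validate a length-n vector."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        return np.full(n_regions, arr[0])
    if arr.shape != (n_regions,):
        raise ValidationError(
            f"{name} has shape {arr.shape}, expected ({n_regions},)")
    return arr
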