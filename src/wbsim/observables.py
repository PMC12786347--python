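"""Summary statistics of BOLD time series.

Static functional connectivity (FC), sliding-window FC dynamics (swFCD),
phase FC dynamics (phFCD), and the scalar distances used to compare
simulated against empirical observables (Kolmogorov-Smirnov, L2,
upper-triangle Pearson similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import hilbert
from scipy.stats import ks_2samp

from .bold import BoldSeries
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FCMatrix:
    """Pearson correlation matrix; NaN marks undefined (flat-signal) pairs."""

    values: np.ndarray
    n_undefined: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValidationError("FC matrix must be square")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle vector with NaNs removed."""
        iu = np.triu_indices(self.n_regions, k=1)
        vec = self.values[iu]
        return vec[~np.isnan(vec)]


@dataclass
class FCDSample:
    """Pairwise window-similarity sample (upper triangle, flattened)."""

    values: np.ndarray
    window: int = 0
    step: int = 0
    n_windows: int = 0


def _as_values(bold) -> np.ndarray:
    if isinstance(bold, BoldSeries):
        return bold.values
    return np.asarray(bold, dtype=float)


def static_fc(bold) -> FCMatrix:
    """Static FC: pairwise Pearson correlation across time.

    Regions with zero temporal variance get NaN rows/columns (flagged and
    excluded from downstream upper-triangle comparisons) and a unit
    diagonal is restored.
    """
    x = _as_values(bold)
    n, T = x.shape
    if T < 3:
        raise ValidationError(f"need at least 3 samples, got {T}")
    sd = x.std(axis=1)
    flat = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(x)
    fc = np.asarray(fc, dtype=float)
    fc[flat, :] = np.nan
    fc[:, flat] = np.nan
    np.fill_diagonal(fc, 1.0)
    n_undef = int(flat.sum())
    if n_undef:
        logger.warning("%d zero-variance region(s); correlations flagged "
                       "undefined", n_undef)
    return FCMatrix(values=np.clip(fc, -1.0, 1.0), n_undefined=n_undef)


def fc_similarity(sim: FCMatrix, emp: FCMatrix) -> float:
    """Pearson correlation of the two upper-triangle vectors."""
    if sim.n_regions != emp.n_regions:
        raise ValidationError(
            f"FC sizes differ: {sim.n_regions} vs {emp.n_regions}")
    iu = np.triu_indices(sim.n_regions, k=1)
    a, b = sim.values[iu], emp.values[iu]
    ok = ~(np.isnan(a) | np.isnan(b))
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def _window_starts(T: int, window: int, step: int) -> np.ndarray:
    if window > T:
        raise ValidationError(f"window {window} exceeds {T} samples")
    if step < 1:
        raise ValidationError("step must be >= 1")
    return np.arange(0, T - window + 1, step)


def sliding_window_fcd(bold, window: int = 30, step: int = 3) -> FCDSample:
    """Sliding-window FCD sample.

    Per window position, compute static FC; per window pair, Pearson
    correlation of the two upper-triangle FC vectors; return the upper
    triangle of the window-by-window similarity matrix.
    """
    x = _as_values(bold)
    starts = _window_starts(x.shape[1], window, step)
    w = len(starts)
    if w < 2:
        raise ValidationError(f"only {w} window(s); need at least 2")
    iu = np.triu_indices(x.shape[0], k=1)
    tri = np.stack([static_fc(x[:, s:s + window]).values[iu]
                    for s in starts])
    sims = np.corrcoef(tri)
    wu = np.triu_indices(w, k=1)
    return FCDSample(values=sims[wu], window=window, step=step, n_windows=w)


def instantaneous_phases(x: np.ndarray) -> np.ndarray:
    """Per-region instantaneous phase of the demeaned analytic signal."""
    x = np.asarray(x, dtype=float)
    flat = x.std(axis=1) == 0.0
    if flat.any():
        raise ValidationError(
            f"region {int(np.argwhere(flat)[0][0])} is constant; phase "
            f"undefined")
    demeaned = x - x.mean(axis=1, keepdims=True)
    return np.angle(hilbert(demeaned, axis=1))


def phase_fcd(bold, window: int = 30, step: int = 3) -> FCDSample:
    """Phase-based FCD sample.

    Instantaneous phases phi_k(t) from the analytic signal give a
    per-time-point coherence matrix P_ij(t) = cos(phi_i - phi_j); each
    window is summarized by its time-mean upper-triangle coherence
    vector, and window pairs are compared by cosine similarity.
    """
    x = _as_values(bold)
    phases = instantaneous_phases(x)
    starts = _window_starts(x.shape[1], window, step)
    w = len(starts)
    if w < 2:
        raise ValidationError(f"only {w} window(s); need at least 2")
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = phases[iu[0], :] - phases[iu[1], :]        # (pairs, T)
    coher = np.cos(diff)
    vecs = np.stack([coher[:, s:s + window].mean(axis=1) for s in starts])
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0.0] = 1.0
    unit = vecs / norms[:, None]
    sims = unit @ unit.T
    wu = np.triu_indices(w, k=1)
    return FCDSample(values=np.clip(sims[wu], -1.0, 1.0), window=window,
                     step=step, n_windows=w)


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup |ECDF_a - ECDF_b|."""
    a = np.ravel(np.asarray(a, dtype=float))
    b = np.ravel(np.asarray(b, dtype=float))
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("ks_distance requires nonempty samples")
    return float(ks_2samp(a, b).statistic)


def l2_distance(a, b) -> float:
    """Euclidean norm of the elementwise difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))
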