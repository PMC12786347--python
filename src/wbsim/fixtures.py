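"""Deterministic test fixtures.

Synthetic connectomes come from :func:`wbsim.connectome.synthetic_connectome`;
here we add BOLD-like series with known correlation structure, used to
validate the FC/FCD estimators against analytic ground truth.  Every
fixture regenerates bit-exactly from its seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .bold import BoldSeries
from .errors import ValidationError


def make_block_bold(n_regions: int, n_samples: int,
                    block_structure: Sequence[Sequence[int]],
                    noise_sd: float = 0.5, seed: int = 0,
                    sampling_period: float = 2.0) -> BoldSeries:
    """Block-correlated BOLD-like series.

    Regions within a block share a unit-variance latent Gaussian signal
    plus independent Gaussian noise of SD ``noise_sd``, so the expected
    within-block correlation is rho = 1 / (1 + noise_sd^2) and
    cross-block correlation is 0.  ``block_structure`` must partition
    ``range(n_regions)``.
    """
    flat = [r for block in block_structure for r in block]
    if sorted(flat) != list(range(n_regions)):
        raise ValidationError(
            "block_structure must partition the region indices exactly "
            f"once each; got {sorted(flat)} for n_regions={n_regions}")
    rng = np.random.default_rng(seed)
    values = np.empty((n_regions, n_samples))
    for block in block_structure:
        latent = rng.standard_normal(n_samples)
        for r in block:
            values[r] = latent + noise_sd * rng.standard_normal(n_samples)
    times = (np.arange(n_samples) + 1) * sampling_period
    return BoldSeries(times=times, values=values)


def expected_block_correlation(noise_sd: float) -> float:
    """Analytic within-block correlation of :func:`make_block_bold`."""
    return 1.0 / (1.0 + noise_sd ** 2)
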