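"""Canonical double-gamma haemodynamic response function.

The BOLD impulse response is modelled as the difference of two gamma
densities — a positive response peaking ~5 s after stimulus onset and a
later undershoot — the community-standard kernel for event-related GLMs.
Regressors are built on a microtime grid (default TR/16) and sampled back
at volume acquisition times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma

__all__ = ["HRFSpec", "hrf_kernel", "hrf_derivative_kernel"]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma parameters (seconds), SPM-convention defaults."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    length_s: float = 32.0
    oversample: int = 16

    def __post_init__(self) -> None:
        if self.length_s <= 0 or self.oversample < 1:
            raise ValueError("HRF length and oversampling must be positive")


def hrf_kernel(spec: HRFSpec, dt: float) -> np.ndarray:
    """Sample the double-gamma kernel at step ``dt``, normalised to unit sum."""
    t = np.arange(0.0, spec.length_s, dt)
    peak = gamma.pdf(t, spec.peak_delay_s / spec.peak_dispersion, scale=spec.peak_dispersion)
    under = gamma.pdf(
        t, spec.undershoot_delay_s / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
    )
    kernel = peak - under / spec.undershoot_ratio
    total = kernel.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("HRF kernel must integrate to a finite positive value")
    return kernel / total


def hrf_derivative_kernel(spec: HRFSpec, dt: float) -> np.ndarray:
    """Temporal derivative of the kernel (finite difference on the fine grid)."""
    return np.gradient(hrf_kernel(spec, dt), dt)
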