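"""Canonical double-gamma hemodynamic response function."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF kernel parameters (seconds).

    The response is a gamma density peaking near ``peak_delay_s`` minus a
    gamma undershoot scaled by ``1/ratio``; the sampled kernel is
    peak-normalized to 1.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.length_s < 24.0:
            raise ValueError("HRF kernel length must be >= 24 s")

    def kernel(self, dt_s: float) -> np.ndarray:
        """Sampled kernel at resolution ``dt_s``, peak-normalized."""
        t = np.arange(0.0, self.length_s, dt_s)
        h = _gamma.pdf(t, self.peak_delay_s / self.peak_dispersion_s,
                       scale=self.peak_dispersion_s)
        h = h - _gamma.pdf(t, self.undershoot_delay_s / self.undershoot_dispersion_s,
                           scale=self.undershoot_dispersion_s) / self.ratio
        if h.sum() * dt_s <= 0:
            raise ValueError("HRF kernel must integrate to a positive value")
        return h / h.max()
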