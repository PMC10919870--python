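"""Canonical double-gamma hemodynamic response function and event convolution.

The same kernel is used by the time-series simulator and by the GLM design
builder, so a noiseless simulation is exactly identifiable by the fit.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["double_gamma_hrf", "convolve_events"]

# canonical SPM-style parameters: response peak 6 s, undershoot peak 16 s,
# undershoot ratio 1/6, 32 s support
PEAK_DELAY = 6.0
UNDERSHOOT_DELAY = 16.0
DISPERSION = 1.0
UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_DURATION = 32.0


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    Normalized to unit peak amplitude.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, PEAK_DELAY / DISPERSION, scale=DISPERSION) - (
        UNDERSHOOT_RATIO
        * _gamma.pdf(t, UNDERSHOOT_DELAY / DISPERSION, scale=DISPERSION)
    )
    h = np.where(t < 0, 0.0, h)
    ref = _gamma.pdf(PEAK_DELAY - DISPERSION, PEAK_DELAY / DISPERSION, scale=DISPERSION)
    return h / ref


def convolve_events(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    n_timepoints: int,
    tr: float,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved regressor sampled at the TR grid.

    Events are placed as impulses on a fine grid (``dt`` seconds), convolved
    with the double-gamma kernel, then sampled at ``t = i*TR``.  Onsets need
    not align with the TR grid.
    """
    onsets = np.asarray(onsets, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if onsets.shape != amplitudes.shape:
        raise ValueError("onsets and amplitudes must have matching shapes")
    n_fine = int(np.ceil((n_timepoints * tr + HRF_DURATION) / dt)) + 1
    impulses = np.zeros(n_fine)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(impulses, idx, amplitudes)
    kernel = double_gamma_hrf(np.arange(0.0, HRF_DURATION + dt, dt))
    fine = np.convolve(impulses, kernel)[:n_fine]
    sample_idx = np.round(np.arange(n_timepoints) * tr / dt).astype(int)
    return fine[sample_idx]
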