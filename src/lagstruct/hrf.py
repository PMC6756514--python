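"""Canonical double-gamma hemodynamic response function and event regressors."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = ["canonical_hrf", "event_regressor"]

# SPM-canonical double-gamma constants (seconds / dimensionless)
HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_DISPERSION_S = 1.0
HRF_UNDERSHOOT_DISPERSION_S = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH_S = 32.0


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Double-gamma HRF sampled at times ``t`` (s), peak normalized to 1."""
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, HRF_PEAK_DELAY_S / HRF_DISPERSION_S, scale=HRF_DISPERSION_S)
    under = gamma_dist.pdf(t, HRF_UNDERSHOOT_DELAY_S / HRF_UNDERSHOOT_DISPERSION_S,
                           scale=HRF_UNDERSHOOT_DISPERSION_S)
    h = peak - HRF_UNDERSHOOT_RATIO * under
    h[t < 0] = 0.0
    m = np.max(np.abs(h))
    return h / m if m > 0 else h


def event_regressor(events: pd.DataFrame, n_frames: int, frame_interval_s: float,
                    oversample: int = 10) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at frame times, max-normalized.

    Each event contributes a boxcar of its duration (instantaneous events get
    one fine-grid sample). The regressor is scaled to unit peak so effect
    sizes are expressed in signal units per unit response.
    """
    if events is None or len(events) == 0:
        raise ValueError("event list is empty")
    dt = frame_interval_s / oversample
    total = n_frames * frame_interval_s
    t_fine = np.arange(0.0, total, dt)
    stim = np.zeros_like(t_fine)
    for onset, duration in zip(events["onset"], events["duration"]):
        if onset >= total:
            raise ValueError(f"event onset {onset} s beyond scan duration {total} s")
        i0 = int(np.floor(onset / dt))
        i1 = max(i0 + 1, int(np.ceil((onset + duration) / dt)))
        stim[i0:min(i1, stim.size)] = 1.0
    h = canonical_hrf(np.arange(0.0, HRF_LENGTH_S, dt))
    conv = np.convolve(stim, h)[: t_fine.size]
    reg = conv[::oversample][:n_frames]
    m = np.max(np.abs(reg))
    return reg / m if m > 0 else reg
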