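"""Dual-echo S0 / T2* decomposition under monoexponential decay.

The MR signal at echo time TE follows S(TE) = S0 * exp(-TE / T2*) (single
compartment). From two echoes S1 (at TE1) and S2 (at TE2 > TE1):

    T2* = (TE2 - TE1) / ln(S1 / S2)
    S0  = S1^(TE2/(TE2-TE1)) / S2^(TE1/(TE2-TE1))

Non-positive signals, S1 = S2, and T2* values that are negative or exceed
100 ms are treated as noise: the sample is marked invalid and carried as
missing, never interpolated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import TimeSeriesVolume

__all__ = ["MultiEchoPair", "DecayFields", "decompose", "decompose_arrays",
           "synthesize", "synthesize_arrays", "T2S_MAX_MS"]

T2S_MAX_MS = 100.0  # inclusive upper bound on physiologically valid T2*


@dataclass
class MultiEchoPair:
    """Simultaneous signals at two echo times (seconds)."""

    S1: TimeSeriesVolume
    S2: TimeSeriesVolume
    te1_s: float
    te2_s: float

    def __post_init__(self) -> None:
        if not 0 < self.te1_s < self.te2_s:
            raise ValueError("need 0 < TE1 < TE2")
        if self.S1.data.shape != self.S2.data.shape:
            raise ValueError("echo geometries/frame counts differ")
        if self.S1.frame_interval_s != self.S2.frame_interval_s:
            raise ValueError("echo frame intervals differ")


@dataclass
class DecayFields:
    """Per-frame T2* (ms) and S0 fields with a validity mask.

    Invalid samples (noise rule or degenerate input) hold NaN.
    """

    t2s_ms: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    frame_interval_s: float
    affine: np.ndarray


def decompose_arrays(s1: np.ndarray, s2: np.ndarray, te1_s: float, te2_s: float,
                     t2s_max_ms: float = T2S_MAX_MS):
    """Invert the two-point monoexponential model elementwise.

    Returns ``(t2s_ms, s0, valid)``. The 100-ms bound is inclusive (a value of
    exactly 100 ms is valid; only values *exceeding* it are noise).
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    dte = te2_s - te1_s
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = s1 / s2
        t2s = dte / np.log(ratio)
        s0 = s1 ** (te2_s / dte) / s2 ** (te1_s / dte)
    t2s_ms = t2s * 1e3
    # the upper bound is inclusive; a relative epsilon absorbs float round-trip
    # error when the decay constant sits exactly on the bound
    valid = (
        (s1 > 0) & (s2 > 0) & (s1 != s2)
        & np.isfinite(t2s_ms) & (t2s_ms > 0)
        & (t2s_ms <= t2s_max_ms * (1.0 + 1e-9))
    )
    t2s_ms = np.where(valid, t2s_ms, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return t2s_ms, s0, valid


def decompose(pair: MultiEchoPair, t2s_max_ms: float = T2S_MAX_MS) -> DecayFields:
    """Per-frame, per-voxel S0 and T2* from a dual-echo acquisition."""
    t2s_ms, s0, valid = decompose_arrays(pair.S1.data, pair.S2.data,
                                         pair.te1_s, pair.te2_s, t2s_max_ms)
    return DecayFields(t2s_ms=t2s_ms, s0=s0, valid=valid,
                       frame_interval_s=pair.S1.frame_interval_s,
                       affine=pair.S1.affine)


def synthesize_arrays(t2s_ms: np.ndarray, s0: np.ndarray, te_s: float) -> np.ndarray:
    """Forward model S(TE) = S0 exp(-TE/T2*); TE = 0 returns S0 itself."""
    if te_s < 0:
        raise ValueError("TE must be non-negative")
    with np.errstate(invalid="ignore", over="ignore"):
        return np.asarray(s0) * np.exp(-te_s / (np.asarray(t2s_ms) * 1e-3))


def synthesize(df: DecayFields, te_s: float) -> TimeSeriesVolume:
    data = synthesize_arrays(df.t2s_ms, df.s0, te_s)
    if te_s == 0:
        data = df.s0.copy()
    mask = np.nanstd(data, axis=-1) > 0
    return TimeSeriesVolume(data=data, frame_interval_s=df.frame_interval_s,
                            mask=mask, affine=df.affine)
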