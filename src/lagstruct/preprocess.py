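"""Data repair, motion nuisance regression, band-pass filtering, percent change.

Array-level routines operate on matrices of shape (n_frames, n_voxels); thin
wrappers accept :class:`~lagstruct.volume.TimeSeriesVolume`. The estimator
classes follow the scikit-learn transformer API so stages compose in a
``sklearn.pipeline.Pipeline``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .volume import MOTION_COLUMNS, TimeSeriesVolume

__all__ = [
    "RepairReport",
    "detect_spikes",
    "repair",
    "motion_design",
    "regress_out",
    "bandpass",
    "percent_change",
    "SpikeRepairer",
    "MotionRegressor",
    "BandpassFilter",
    "PercentSignalChange",
]

log = logging.getLogger(__name__)

SLFO_BAND = (0.008, 0.07)  # Hz; analysis band for the sLFO phase
GLOBAL_CHANGE_LIMIT = 0.01  # fraction of session mean
TRANSLATION_LIMIT_MM = 1.0
ROTATION_LIMIT_DEG = 1.0


# ---------------------------------------------------------------------------
# Spike detection and repair
# ---------------------------------------------------------------------------

@dataclass
class RepairReport:
    """Frames flagged for repair and the criterion each one hit.

    ``global_frames`` and ``motion_frames`` are kept separately so the
    conjunctive reading of the two criteria remains recoverable; ``frames``
    is their union (either criterion suffices to flag).
    """

    frames: list[int] = field(default_factory=list)
    global_frames: list[int] = field(default_factory=list)
    motion_frames: list[int] = field(default_factory=list)
    interpolation: str = "linear"


def _flag_excursions(values: np.ndarray, limit: float) -> list[int]:
    """Flag frames deviating more than ``limit`` from the last accepted frame.

    ``values`` is (T,) or (T, k); the per-frame deviation is the Euclidean norm
    of the difference from the most recent unflagged frame, so a single-frame
    excursion flags only the deviant frame, not the recovery frame.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float).T).T  # (T, k)
    flagged: list[int] = []
    ref = v[0]
    for t in range(1, len(v)):
        if np.linalg.norm(v[t] - ref) > limit:
            flagged.append(t)
        else:
            ref = v[t]
    return flagged


def detect_spikes(vol: TimeSeriesVolume, motion: pd.DataFrame | None = None) -> RepairReport:
    """Flag frames with a >1% global signal change or >1 mm / >1 deg motion step.

    The global criterion normalizes by the session-mean global signal. Steps
    are measured against the last accepted frame (see :func:`_flag_excursions`).
    Translations are combined by Euclidean norm; rotations are checked per axis.
    """
    g = vol.data[vol.mask].mean(axis=0)
    session_mean = g.mean()
    if session_mean == 0:
        raise ValueError("session-mean global signal is zero")
    global_frames = _flag_excursions(g / session_mean, GLOBAL_CHANGE_LIMIT)

    motion_frames: list[int] = []
    if motion is not None:
        if len(motion) != vol.n_frames:
            raise ValueError("motion rows must match frame count")
        trans = motion[MOTION_COLUMNS[:3]].to_numpy(float)
        rot = motion[MOTION_COLUMNS[3:]].to_numpy(float)
        motion_set = set(_flag_excursions(trans, TRANSLATION_LIMIT_MM))
        for j in range(3):
            motion_set.update(_flag_excursions(rot[:, j], ROTATION_LIMIT_DEG))
        motion_frames = sorted(motion_set)

    frames = sorted(set(global_frames) | set(motion_frames))
    return RepairReport(frames=frames, global_frames=global_frames, motion_frames=motion_frames)


def _repair_matrix(X: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    T = X.shape[0]
    bad = np.zeros(T, dtype=bool)
    bad[flagged] = True
    if bad.all():
        raise ValueError("all frames flagged; nothing to interpolate from")
    good = np.flatnonzero(~bad)
    out = X.copy()
    # np.interp semantics per column, vectorized: linear between nearest good
    # neighbors, nearest-value extension at the ends.
    idx = np.flatnonzero(bad)
    pos = np.searchsorted(good, idx)
    left = good[np.clip(pos - 1, 0, len(good) - 1)]
    right = good[np.clip(pos, 0, len(good) - 1)]
    span = (right - left).astype(float)
    w = np.where(span > 0, (idx - left) / np.where(span == 0, 1, span), 0.0)
    out[idx] = X[left] * (1 - w)[:, None] + X[right] * w[:, None]
    return out


def repair(vol: TimeSeriesVolume, report: RepairReport) -> TimeSeriesVolume:
    """Replace flagged frames with values linearly interpolated from neighbors."""
    if not report.frames:
        return vol.with_matrix(vol.to_matrix())
    flagged = np.asarray(report.frames, dtype=int)
    if flagged.min() < 0 or flagged.max() >= vol.n_frames:
        raise ValueError("flagged frame index out of range")
    return vol.with_matrix(_repair_matrix(vol.to_matrix(), flagged))


# ---------------------------------------------------------------------------
# Motion nuisance design
# ---------------------------------------------------------------------------

def motion_design(motion: pd.DataFrame) -> np.ndarray:
    """24-column motion nuisance matrix.

    Columns 1-6: first temporal derivatives of the six rigid-body parameters;
    7-12: the same derivatives delayed by one frame; 13-24: elementwise squares
    of columns 1-12. Undefined leading frames are zero-padded. The raw
    parameters themselves are deliberately excluded (they can be contaminated
    by the global signal in immobile subjects).
    """
    if len(motion) < 3:
        raise ValueError("need at least 3 frames for motion derivatives")
    m = motion[MOTION_COLUMNS].to_numpy(float)
    d = np.zeros_like(m)
    d[1:] = np.diff(m, axis=0)
    d_shift = np.zeros_like(d)
    d_shift[1:] = d[:-1]
    first12 = np.hstack([d, d_shift])
    return np.hstack([first12, first12**2])


def regress_out(X, design: np.ndarray):
    """Remove the least-squares fit of ``design`` (plus intercept) per voxel.

    The voxel mean is restored after regression. Rank-deficient designs are
    handled by the minimum-norm solution and logged.

    Accepts a (T, V) matrix or a TimeSeriesVolume; returns the same kind.
    """
    if isinstance(X, TimeSeriesVolume):
        return X.with_matrix(regress_out(X.to_matrix(), design))
    X = np.asarray(X, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    if design.shape[0] != X.shape[0]:
        raise ValueError("design rows must match frame count")
    A = np.column_stack([np.ones(X.shape[0]), design])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        log.warning("rank-deficient nuisance design (rank %d of %d columns)", rank, A.shape[1])
    beta, *_ = np.linalg.lstsq(A, X, rcond=None)
    resid = X - A @ beta
    return resid + X.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Band-pass filtering and percent change
# ---------------------------------------------------------------------------

def bandpass(X, lo: float, hi: float, frame_interval_s: float | None = None,
             taper_hz: float | None = None):
    """Zero-phase band-pass via a spectral mask with raised-cosine edges.

    Phase is exactly preserved inside the band (the mask is real), in-band
    amplitude is preserved, and out-of-band attenuation is far beyond 20 dB
    one octave outside the band. The series mean is removed when ``lo > 0``.
    """
    if isinstance(X, TimeSeriesVolume):
        return X.with_matrix(bandpass(X.to_matrix(), lo, hi, X.frame_interval_s, taper_hz))
    if frame_interval_s is None:
        raise ValueError("frame_interval_s required for array input")
    X = np.asarray(X, dtype=float)
    nyq = 0.5 / frame_interval_s
    if not (0 <= lo < hi):
        raise ValueError("need 0 <= lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper cutoff {hi} Hz is not below Nyquist {nyq} Hz")
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    T = X.shape[0]
    freqs = np.fft.rfftfreq(T, d=frame_interval_s)
    if taper_hz is None:
        taper_hz = max(0.25 * lo, 2.0 / (T * frame_interval_s))

    def edge(f, f0, width, rising):
        # raised cosine from 0 to 1 over [f0 - width, f0]
        x = np.clip((f - (f0 - width)) / width, 0.0, 1.0)
        ramp = 0.5 - 0.5 * np.cos(np.pi * x)
        return ramp if rising else 1.0 - ramp

    mask = np.ones_like(freqs)
    if lo > 0:
        mask *= edge(freqs, lo, taper_hz, rising=True)
        mask[freqs == 0] = 0.0
    mask *= edge(freqs, hi + taper_hz, taper_hz, rising=False)
    Y = np.fft.irfft(np.fft.rfft(X, axis=0) * mask[:, None], n=T, axis=0)
    return Y[:, 0] if one_d else Y


def percent_change(X, axis: int = 0):
    """Convert to percent signal change about the per-voxel temporal mean."""
    if isinstance(X, TimeSeriesVolume):
        M = X.to_matrix()
        mu = M.mean(axis=0)
        if np.any(mu == 0):
            raise ValueError("zero-mean voxel inside mask")
        return X.with_matrix(100.0 * (M - mu) / mu)
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=axis, keepdims=True)
    if np.any(mu == 0):
        raise ValueError("zero-mean series")
    return 100.0 * (X - mu) / mu


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class BandpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase band-pass transformer for (n_frames, n_voxels) matrices."""

    def __init__(self, lo: float = SLFO_BAND[0], hi: float = SLFO_BAND[1],
                 frame_interval_s: float = 0.5):
        self.lo = lo
        self.hi = hi
        self.frame_interval_s = frame_interval_s

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return bandpass(np.asarray(X, dtype=float), self.lo, self.hi, self.frame_interval_s)


class SpikeRepairer(TransformerMixin, BaseEstimator):
    """Detect and linearly interpolate spike frames in a (T, V) matrix.

    Pass the motion table at fit time: ``fit(X, motion=table)``. Fitted
    attributes: ``report_`` (the RepairReport), ``flagged_frames_``.
    """

    def __init__(self, global_limit: float = GLOBAL_CHANGE_LIMIT,
                 translation_limit_mm: float = TRANSLATION_LIMIT_MM,
                 rotation_limit_deg: float = ROTATION_LIMIT_DEG):
        self.global_limit = global_limit
        self.translation_limit_mm = translation_limit_mm
        self.rotation_limit_deg = rotation_limit_deg

    def fit(self, X, y=None, motion: pd.DataFrame | None = None):
        X = np.asarray(X, dtype=float)
        g = X.mean(axis=1)
        session_mean = g.mean()
        if session_mean == 0:
            raise ValueError("session-mean global signal is zero")
        global_frames = _flag_excursions(g / session_mean, self.global_limit)
        motion_frames: list[int] = []
        if motion is not None:
            trans = motion[MOTION_COLUMNS[:3]].to_numpy(float)
            rot = motion[MOTION_COLUMNS[3:]].to_numpy(float)
            s = set(_flag_excursions(trans, self.translation_limit_mm))
            for j in range(3):
                s.update(_flag_excursions(rot[:, j], self.rotation_limit_deg))
            motion_frames = sorted(s)
        frames = sorted(set(global_frames) | set(motion_frames))
        self.report_ = RepairReport(frames=frames, global_frames=global_frames,
                                    motion_frames=motion_frames)
        self.flagged_frames_ = frames
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if not self.flagged_frames_:
            return X.copy()
        return _repair_matrix(X, np.asarray(self.flagged_frames_))


class MotionRegressor(TransformerMixin, BaseEstimator):
    """Regress the 24-parameter motion nuisance design out of every voxel."""

    def __init__(self):
        pass

    def fit(self, X, y=None, motion: pd.DataFrame | None = None):
        if motion is None:
            raise ValueError("MotionRegressor.fit requires motion=<table>")
        self.design_ = motion_design(motion)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return regress_out(np.asarray(X, dtype=float), self.design_)


class PercentSignalChange(TransformerMixin, BaseEstimator):
    """Percent signal change about the per-voxel temporal mean."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return percent_change(np.asarray(X, dtype=float))
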