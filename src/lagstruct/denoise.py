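"""Lag-structure removal ("deperfusioning") and reference cleaning methods.

Deperfusioning is a dynamic form of global signal regression: instead of one
uniform global regressor, every voxel is regressed against the band-limited
seed time course of its own lag bin, so only the low-frequency sLFO component
is removed and the phase mismatch of uniform GSR is avoided. Comparison
methods: normal GSR, low-pass GSR, and frame-wise global scaling. A simple
event-related GLM with the canonical HRF quantifies the downstream effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .hrf import event_regressor
from .lagmap import LagStructure, track
from .preprocess import SLFO_BAND, bandpass
from .volume import TimeSeriesVolume

__all__ = ["GLMResult", "gsr", "global_scaling", "deperfusion", "glm",
           "GlobalSignalRegressor", "GlobalScaler", "DynamicGSR", "EventGLM"]

log = logging.getLogger(__name__)


def _as_matrix(data):
    if isinstance(data, TimeSeriesVolume):
        return data.to_matrix(), data.frame_interval_s, data
    return np.asarray(data, dtype=float), None, None


def _wrap(result, vol):
    return vol.with_matrix(result) if vol is not None else result


def _regress_series(X: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Remove per-voxel LS fit of one regressor (+intercept); means preserved."""
    r = regressor - regressor.mean()
    denom = float(r @ r)
    if denom == 0:
        return X.copy()
    beta = (r @ (X - X.mean(axis=0, keepdims=True))) / denom
    return X - np.outer(r, beta)


# ---------------------------------------------------------------------------
# Cleaning methods
# ---------------------------------------------------------------------------

def gsr(data, lowpass_only: bool = False, band: tuple[float, float] = SLFO_BAND,
        frame_interval_s: float | None = None):
    """Global signal regression; optionally with a band-limited global signal.

    With ``lowpass_only`` the global regressor is restricted to the sLFO band,
    so only low-frequency content is affected. Voxel means are preserved.
    """
    X, tr, vol = _as_matrix(data)
    tr = tr if tr is not None else frame_interval_s
    g = X.mean(axis=1)
    if lowpass_only:
        if tr is None:
            raise ValueError("frame_interval_s required for low-pass GSR on arrays")
        g = bandpass(g, band[0], band[1], tr)
    return _wrap(_regress_series(X, g), vol)


def global_scaling(data):
    """Frame-wise division by the frame's global mean, rescaled to the grand mean."""
    X, _, vol = _as_matrix(data)
    g = X.mean(axis=1)
    if np.any(g <= 0):
        raise ValueError("non-positive frame-wise global mean")
    out = X / g[:, None] * g.mean()
    return _wrap(out, vol)


def deperfusion(data, ls: LagStructure, band: tuple[float, float] = SLFO_BAND,
                frame_interval_s: float | None = None):
    """Remove the lag structure: per-bin seed regression ("dynamic GSR").

    Each voxel in lag bin b is regressed against the band-limited bin-b seed
    series; the fitted low-frequency component is subtracted, leaving content
    outside the sLFO band untouched. Voxels without a bin fall back to normal
    (low-pass) GSR, with a log record.
    """
    X, tr, vol = _as_matrix(data)
    tr = tr if tr is not None else frame_interval_s
    if tr is None:
        tr = ls.frame_interval_s
    if ls.seed_series.shape[0] != len(ls.bin_lags):
        raise ValueError("lag structure missing seed series for some bins")
    out = X.copy()
    binned = np.zeros(X.shape[1], dtype=bool)
    for b, members in enumerate(ls.bin_members):
        if members.size == 0:
            continue
        seed = bandpass(ls.seed_series[b], band[0], band[1], tr)
        out[:, members] = _regress_series(X[:, members], seed)
        binned[members] = True
    rest = np.flatnonzero(~binned)
    if rest.size:
        log.info("deperfusion: %d unbinned voxels fall back to low-pass GSR", rest.size)
        g = bandpass(X.mean(axis=1), band[0], band[1], tr)
        out[:, rest] = _regress_series(X[:, rest], g)
    return _wrap(out, vol)


# ---------------------------------------------------------------------------
# Event-related GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    """Per-voxel effect sizes from an event-related least-squares fit."""

    beta: np.ndarray
    tstat: np.ndarray
    residual_variance: np.ndarray
    dof: int
    design: pd.DataFrame


def glm(data, events: pd.DataFrame, frame_interval_s: float | None = None,
        duration_s: float | None = None) -> GLMResult:
    """OLS fit of the HRF-convolved event regressor (+ intercept and drift).

    ``duration_s`` overrides the per-event durations when given. The t-value
    is beta over its standard error with the nominal residual dof.
    """
    X, tr, _ = _as_matrix(data)
    tr = tr if tr is not None else frame_interval_s
    if tr is None:
        raise ValueError("frame_interval_s required for array input")
    if events is None or len(events) == 0:
        raise ValueError("event list is empty")
    ev = events.copy()
    if duration_s is not None:
        ev["duration"] = duration_s
    T = X.shape[0]
    reg = event_regressor(ev, T, tr)
    drift = np.linspace(-0.5, 0.5, T)
    A = np.column_stack([reg, np.ones(T), drift])
    beta_all, _, rank, _ = np.linalg.lstsq(A, X, rcond=None)
    resid = X - A @ beta_all
    dof = T - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    XtX_inv = np.linalg.pinv(A.T @ A)
    se = np.sqrt(sigma2 * XtX_inv[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta_all[0] / se, 0.0)
    design = pd.DataFrame({"task": reg, "intercept": 1.0, "drift": drift})
    return GLMResult(beta=beta_all[0], tstat=tvals,
                     residual_variance=sigma2, dof=dof, design=design)


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class GlobalSignalRegressor(TransformerMixin, BaseEstimator):
    """GSR transformer; ``lowpass_only`` restricts the regressor to the sLFO band."""

    def __init__(self, lowpass_only: bool = False, band: tuple = SLFO_BAND,
                 frame_interval_s: float = 0.5):
        self.lowpass_only = lowpass_only
        self.band = band
        self.frame_interval_s = frame_interval_s

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return gsr(np.asarray(X, dtype=float), self.lowpass_only, self.band,
                   self.frame_interval_s)


class GlobalScaler(TransformerMixin, BaseEstimator):
    """Frame-wise global-mean scaling transformer."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return global_scaling(np.asarray(X, dtype=float))


class DynamicGSR(TransformerMixin, BaseEstimator):
    """Deperfusioning transformer: fit tracks the lag structure, transform removes it.

    ``fit`` band-passes the input and runs the recursive tracker (or adopts a
    precomputed ``lag_structure``); ``transform`` regresses each voxel against
    its band-limited bin seed.
    """

    def __init__(self, corr_threshold: float = 0.3, step_s: float = 0.5,
                 range_s: float = 7.0, band: tuple = SLFO_BAND,
                 frame_interval_s: float = 0.5,
                 lag_structure: LagStructure | None = None):
        self.corr_threshold = corr_threshold
        self.step_s = step_s
        self.range_s = range_s
        self.band = band
        self.frame_interval_s = frame_interval_s
        self.lag_structure = lag_structure

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.lag_structure is not None:
            self.structure_ = self.lag_structure
        else:
            Xb = bandpass(X, self.band[0], self.band[1], self.frame_interval_s)
            self.structure_ = track(Xb, self.frame_interval_s, self.corr_threshold,
                                    self.step_s, self.range_s)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return deperfusion(np.asarray(X, dtype=float), self.structure_, self.band,
                           self.frame_interval_s)


class EventGLM(BaseEstimator):
    """Event-related GLM as an estimator; fitted attributes beta_, tstat_."""

    def __init__(self, events: pd.DataFrame | None = None,
                 frame_interval_s: float = 0.5, duration_s: float | None = None):
        self.events = events
        self.frame_interval_s = frame_interval_s
        self.duration_s = duration_s

    def fit(self, X, y=None):
        res = glm(np.asarray(X, dtype=float), self.events, self.frame_interval_s,
                  self.duration_s)
        self.result_ = res
        self.beta_ = res.beta
        self.tstat_ = res.tstat
        self.n_features_in_ = np.asarray(X).shape[1]
        return self
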