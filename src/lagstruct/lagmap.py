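"""Recursive cross-correlogram tracking of the sLFO phase.

The tracker starts from the voxels in phase with the global mean signal
(lag = 0) and recursively walks up- and downstream of the vascular tree in
0.5-s steps: at each step, the undetermined voxels whose cross-correlogram
against the previous seed's mean time course peaks at exactly +step (upstream)
or -step (downstream), with peak correlation at or above threshold, are
assigned that lag and averaged into the new seed.

Sign convention (project-wide, see :mod:`lagstruct.volume`): positive lag
means the voxel's signal leads the global-signal phase (arterial side), and
``xcorrelogram(x, y)`` reports a positive peak lag when ``x`` leads ``y``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .volume import TimeSeriesVolume

__all__ = [
    "Correlogram",
    "LagStructure",
    "xcorrelogram",
    "initial_seed",
    "track",
    "fill_holes",
    "LagMapper",
]

log = logging.getLogger(__name__)

DEFAULT_CORR_THRESHOLD = 0.3
DEFAULT_STEP_S = 0.5
DEFAULT_RANGE_S = 7.0


@dataclass
class Correlogram:
    """Normalized cross-correlation at integer-frame shifts."""

    lags_s: np.ndarray
    values: np.ndarray
    peak_lag_s: float
    peak_r: float


@dataclass
class LagStructure:
    """A lag map plus the ordered per-lag-bin seed time courses.

    ``lags`` holds one lag (s) per masked voxel, NaN where untracked.
    ``bin_lags`` is ordered from the most upstream (largest positive lag) to
    the most downstream bin; ``seed_series`` has one row per bin in the same
    order; ``bin_members`` lists the voxel indices of each bin. Tracked voxels
    belong to exactly one bin.
    """

    lags: np.ndarray
    bin_lags: np.ndarray
    seed_series: np.ndarray
    bin_members: list[np.ndarray]
    step_s: float
    range_s: float
    frame_interval_s: float
    corr_threshold: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_lags)

    def seed_frame(self) -> pd.DataFrame:
        """Seed series as a table, one column per lag bin (seconds in header)."""
        return pd.DataFrame(self.seed_series.T,
                            columns=[f"lag_{lag:+.1f}s" for lag in self.bin_lags])

    def to_map(self, vol: TimeSeriesVolume) -> np.ndarray:
        """Scatter voxel lags into a 3D map (NaN outside mask / untracked)."""
        return vol.map_from(self.lags)

    def bin_index_map(self, vol: TimeSeriesVolume) -> np.ndarray:
        idx = np.full(self.lags.shape, np.nan)
        for b, members in enumerate(self.bin_members):
            idx[members] = b
        return vol.map_from(idx)


# ---------------------------------------------------------------------------
# Cross-correlograms
# ---------------------------------------------------------------------------

def _corr_at_shift(X: np.ndarray, s: np.ndarray, k: int) -> np.ndarray:
    """Pearson correlation of each column of X with s, X leading s by k frames.

    x leads s by k (> 0) means x(t) = s(t + k): correlate X[:T-k] with s[k:].
    """
    T = X.shape[0]
    if abs(k) >= T - 1:
        raise ValueError("shift too large for series length")
    if k >= 0:
        xs, ss = X[: T - k], s[k:]
    else:
        xs, ss = X[-k:], s[: T + k]
    xc = xs - xs.mean(axis=0, keepdims=True)
    sc = ss - ss.mean()
    denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc.T @ sc) / denom


def _corr_matrix(X: np.ndarray, s: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """(n_shifts, n_voxels) Pearson correlations over all frame shifts."""
    return np.vstack([_corr_at_shift(X, s, int(k)) for k in shifts])


def xcorrelogram(x: np.ndarray, y: np.ndarray, max_lag_s: float,
                 frame_interval_s: float) -> Correlogram:
    """Cross-correlogram of two series at integer-frame shifts.

    A positive peak lag means ``x`` leads ``y``. The peak is the signed
    maximum (anti-correlated series report a negative-valued correlogram).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    max_k = int(round(max_lag_s / frame_interval_s))
    if x.size < 2 * max_k:
        raise ValueError("series shorter than twice the correlation range")
    shifts = np.arange(-max_k, max_k + 1)
    vals = _corr_matrix(x[:, None], y, shifts)[:, 0]
    peak = int(np.argmax(vals))
    return Correlogram(
        lags_s=shifts * frame_interval_s,
        values=vals,
        peak_lag_s=float(shifts[peak] * frame_interval_s),
        peak_r=float(vals[peak]),
    )


# ---------------------------------------------------------------------------
# Recursive tracking
# ---------------------------------------------------------------------------

def _as_matrix(data) -> tuple[np.ndarray, float | None]:
    if isinstance(data, TimeSeriesVolume):
        return data.to_matrix(), data.frame_interval_s
    return np.asarray(data, dtype=float), None


def _step_frames(step_s: float, frame_interval_s: float) -> int:
    k = step_s / frame_interval_s
    if abs(k - round(k)) > 1e-9:
        raise ValueError("tracking step must be an integer number of frames; "
                         "resample the data first")
    return int(round(k))


def _peaks(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row index of the (unique) signed maximum per column, its value, and
    whether the maximum is unique (ties are left unassigned)."""
    peak_idx = np.nanargmax(C, axis=0)
    peak_val = C[peak_idx, np.arange(C.shape[1])]
    unique = (C == peak_val[None, :]).sum(axis=0) == 1
    return peak_idx, peak_val, unique


def initial_seed(data, frame_interval_s: float | None = None,
                 corr_threshold: float = DEFAULT_CORR_THRESHOLD,
                 step_s: float = DEFAULT_STEP_S,
                 range_s: float = DEFAULT_RANGE_S):
    """Voxels whose correlogram vs the global mean peaks at lag 0.

    Returns ``(voxel_indices, reference_series)``; the mean series over the
    selected voxels defines lag = 0. Input must already be band-passed.
    """
    X, tr = _as_matrix(data)
    frame_interval_s = tr if tr is not None else frame_interval_s
    if frame_interval_s is None:
        raise ValueError("frame_interval_s required for array input")
    step = _step_frames(step_s, frame_interval_s)
    max_k = int(round(range_s / frame_interval_s)) + 2 * step
    shifts = np.arange(-max_k, max_k + 1)
    g = X.mean(axis=1)
    C = _corr_matrix(X, g, shifts)
    peak_idx, peak_val, unique = _peaks(C)
    zero_row = max_k
    sel = (peak_idx == zero_row) & unique & (peak_val >= corr_threshold)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError("empty initial seed: no voxel peaks at lag 0 above threshold")
    return idx, X[:, idx].mean(axis=1)


def track(data, frame_interval_s: float | None = None,
          corr_threshold: float = DEFAULT_CORR_THRESHOLD,
          step_s: float = DEFAULT_STEP_S,
          range_s: float = DEFAULT_RANGE_S) -> LagStructure:
    """Recursive up-/downstream tracking of the sLFO phase.

    The upstream and downstream recursions run independently from the initial
    seed; each stops at ``range_s`` or when a step yields no voxels. Voxels are
    never reassigned. The input must be band-passed so the phase is unique
    within the cross-correlation range.
    """
    X, tr = _as_matrix(data)
    frame_interval_s = tr if tr is not None else frame_interval_s
    if frame_interval_s is None:
        raise ValueError("frame_interval_s required for array input")
    step = _step_frames(step_s, frame_interval_s)
    max_k = int(round(range_s / frame_interval_s)) + 2 * step
    shifts = np.arange(-max_k, max_k + 1)
    V = X.shape[1]

    seed_idx, ref = initial_seed(X, frame_interval_s, corr_threshold, step_s, range_s)
    lags = np.full(V, np.nan)
    lags[seed_idx] = 0.0
    assigned = np.zeros(V, dtype=bool)
    assigned[seed_idx] = True
    bins: dict[float, np.ndarray] = {0.0: seed_idx}
    series: dict[float, np.ndarray] = {0.0: ref}

    n_steps = int(np.floor(range_s / step_s + 1e-9))
    for direction in (+1, -1):
        seed_series = ref
        target_row = max_k + direction * step  # row of the +/-step shift
        for j in range(1, n_steps + 1):
            lag_val = direction * j * step_s
            free = np.flatnonzero(~assigned)
            if free.size == 0:
                break
            C = _corr_matrix(X[:, free], seed_series, shifts)
            peak_idx, peak_val, unique = _peaks(C)
            sel = (peak_idx == target_row) & unique & (peak_val >= corr_threshold)
            members = free[sel]
            if members.size == 0:
                break
            lags[members] = lag_val
            assigned[members] = True
            seed_series = X[:, members].mean(axis=1)
            bins[lag_val] = members
            series[lag_val] = seed_series

    bin_lags = np.array(sorted(bins, reverse=True))
    return LagStructure(
        lags=lags,
        bin_lags=bin_lags,
        seed_series=np.vstack([series[lag] for lag in bin_lags]),
        bin_members=[bins[lag] for lag in bin_lags],
        step_s=step_s,
        range_s=range_s,
        frame_interval_s=frame_interval_s,
        corr_threshold=corr_threshold,
    )


def fill_holes(ls: LagStructure, vol: TimeSeriesVolume,
               corr_threshold: float = DEFAULT_CORR_THRESHOLD) -> LagStructure:
    """Fill untracked voxels; bin membership is left untouched.

    Pass 1 visits untracked voxels one at a time (flat index order): each
    receives the correlation-weighted mean lag of the already-lagged voxels it
    correlates with above threshold at zero shift, and then joins the donor
    pool. Pass 2 fills any remaining voxel whose six face-neighbors all have
    lags with their mean. Voxels still unresolved stay NaN.
    """
    X = vol.to_matrix()
    lags = ls.lags.copy()
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=0))
    norms[norms == 0] = np.inf

    donor = ~np.isnan(lags)
    for v in np.flatnonzero(np.isnan(lags)):
        d_idx = np.flatnonzero(donor)
        if d_idx.size == 0:
            break
        r = (Xc[:, d_idx].T @ Xc[:, v]) / (norms[d_idx] * norms[v])
        good = r > corr_threshold
        if good.any():
            w = r[good]
            lags[v] = float(np.sum(w * lags[d_idx[good]]) / np.sum(w))
            donor[v] = True

    # pass 2: 6-neighbor mean on the 3D grid
    lag_map = vol.map_from(lags)
    remaining = np.argwhere(vol.mask & np.isnan(lag_map))
    shape = lag_map.shape
    filled = {}
    for x, y, z in remaining:
        nb = []
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            i, j, k = x + dx, y + dy, z + dz
            if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
                break
            if np.isnan(lag_map[i, j, k]):
                break
            nb.append(lag_map[i, j, k])
        else:
            filled[(x, y, z)] = float(np.mean(nb))
    for pos, val in filled.items():
        lag_map[pos] = val
    lags = lag_map[vol.mask]
    return replace(ls, lags=lags)


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402


class LagMapper(BaseEstimator):
    """Estimate the sLFO lag structure of a (n_frames, n_voxels) matrix.

    Expects band-passed input (e.g. via :class:`~lagstruct.preprocess.BandpassFilter`
    in a pipeline). Fitted attributes: ``structure_`` (the LagStructure),
    ``lags_``, ``bin_lags_``, ``seed_series_``.
    """

    def __init__(self, corr_threshold: float = DEFAULT_CORR_THRESHOLD,
                 step_s: float = DEFAULT_STEP_S, range_s: float = DEFAULT_RANGE_S,
                 frame_interval_s: float = 0.5):
        self.corr_threshold = corr_threshold
        self.step_s = step_s
        self.range_s = range_s
        self.frame_interval_s = frame_interval_s

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.structure_ = track(X, self.frame_interval_s, self.corr_threshold,
                                self.step_s, self.range_s)
        self.lags_ = self.structure_.lags
        self.bin_lags_ = self.structure_.bin_lags
        self.seed_series_ = self.structure_.seed_series
        self.n_features_in_ = X.shape[1]
        return self
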