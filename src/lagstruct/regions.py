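"""Vascular partition by lag, regional summaries, and map-similarity ICC.

The inlet (arterial side), center, and outlet (venous side) of the gross
vasculature are defined purely by the lag value under the project sign
convention (positive lag = leads the global phase = inlet), never by anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lagmap import LagStructure, xcorrelogram
from .volume import TimeSeriesVolume

__all__ = ["VascularRegions", "partition", "regional_series", "slfo_magnitude",
           "phase_delay", "icc_2_1"]

DEFAULT_CENTER_HALFWIDTH_S = 2.5


@dataclass
class VascularRegions:
    """Mutually exclusive inlet/center/outlet masks over tracked voxels."""

    inlet: np.ndarray
    center: np.ndarray
    outlet: np.ndarray
    center_halfwidth_s: float

    def as_labels(self) -> np.ndarray:
        """Integer label map: 1 inlet, 2 center, 3 outlet, 0 elsewhere."""
        lab = np.zeros(self.inlet.shape, dtype=np.int8)
        lab[self.inlet] = 1
        lab[self.center] = 2
        lab[self.outlet] = 3
        return lab


def partition(lags: LagStructure | np.ndarray,
              center_halfwidth_s: float = DEFAULT_CENTER_HALFWIDTH_S) -> VascularRegions:
    """Threshold the lag map at +/- ``center_halfwidth_s``.

    Inlet: lag > +halfwidth; outlet: lag < -halfwidth; center: |lag| <=
    halfwidth. Accepts a :class:`LagStructure` (flat masks) or a lag array of
    any shape (NaN = untracked). Empty regions trigger a warning.
    """
    arr = lags.lags if isinstance(lags, LagStructure) else np.asarray(lags, dtype=float)
    tracked = np.isfinite(arr)
    inlet = tracked & (arr > center_halfwidth_s)
    outlet = tracked & (arr < -center_halfwidth_s)
    center = tracked & ~inlet & ~outlet
    for name, m in (("inlet", inlet), ("center", center), ("outlet", outlet)):
        if not m.any():
            warnings.warn(f"{name} region is empty at halfwidth {center_halfwidth_s} s")
    return VascularRegions(inlet=inlet, center=center, outlet=outlet,
                           center_halfwidth_s=center_halfwidth_s)


def regional_series(vol: TimeSeriesVolume, regions: VascularRegions) -> pd.DataFrame:
    """Unweighted voxel-mean time course per region (columns omitted if empty)."""
    out = {}
    for name in ("inlet", "center", "outlet"):
        m = getattr(regions, name)
        if m.shape != vol.spatial_shape:
            raise ValueError("region masks must match the volume's spatial shape")
        if m.any():
            out[name] = vol.data[m].mean(axis=0)
    return pd.DataFrame(out)


def slfo_magnitude(series: np.ndarray | pd.Series) -> float:
    """sLFO magnitude: sample SD of a band-passed percent-signal-change series."""
    s = np.asarray(series, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 2:
        return 0.0
    return float(np.std(s, ddof=1))


def phase_delay(series_a: np.ndarray, series_b: np.ndarray, frame_interval_s: float,
                max_lag_s: float = 7.0, ambiguity_tol: float = 0.02) -> float:
    """Cross-correlogram peak delay (s) with parabolic sub-sample refinement.

    Positive means ``series_a`` leads ``series_b``. A second local maximum
    within ``ambiguity_tol`` of the peak (periodic signals) raises a warning.
    """
    cg = xcorrelogram(np.asarray(series_a, float), np.asarray(series_b, float),
                      max_lag_s, frame_interval_s)
    v = cg.values
    p = int(np.argmax(v))
    if v.max() <= 0:
        raise ValueError("no positive correlation peak")
    # flag ambiguity: competing local maxima away from the main peak
    local_max = np.flatnonzero((np.r_[True, v[1:] > v[:-1]]) &
                               (np.r_[v[:-1] >= v[1:], True]))
    rivals = [i for i in local_max if abs(i - p) > 1 and v[i] >= v[p] - ambiguity_tol]
    if rivals:
        warnings.warn("ambiguous phase delay: multiple near-equal correlogram peaks")
    delay = cg.lags_s[p]
    if 0 < p < v.size - 1:
        cm, c0, cp = v[p - 1], v[p], v[p + 1]
        denom = cm - 2 * c0 + cp
        if abs(denom) > 1e-12:
            delay = delay + np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5) * frame_interval_s
    return float(delay)


def icc_2_1(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Voxels act as "subjects" (rows) and the two maps as "raters" (columns);
    NaNs are excluded pairwise. With n voxels, k = 2 raters and the two-way
    ANOVA mean squares MSR (rows), MSC (columns), MSE (error):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have equal size")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError("fewer than 3 common voxels")
    k = 2
    data = np.column_stack([a, b])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)
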