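"""Core data carriers and file I/O.

``TimeSeriesVolume`` is the universal 4D carrier between pipeline stages; motion
parameters and task events travel as plain :class:`pandas.DataFrame` tables.

Sign convention (project-wide): a *positive* lag means the voxel's signal LEADS
the global-signal phase, i.e. the voxel sits on the arterial ("upstream") side
of the vascular tree. All modules import this convention; none re-derives it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesVolume",
    "read_volume",
    "write_volume",
    "read_motion",
    "write_motion",
    "read_events",
    "write_events",
    "read_table",
    "write_table",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
EVENT_COLUMNS = ["onset", "duration", "label"]


@dataclass
class TimeSeriesVolume:
    """A 4D scalar field (x, y, z, t) with frame interval and brain mask.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n_frames)
        Signal in arbitrary units.
    frame_interval_s : float
        Seconds per frame (TR). Must be positive.
    mask : ndarray of bool, shape (nx, ny, nz), optional
        Brain mask; defaults to voxels with nonzero temporal variance.
    affine : ndarray (4, 4)
        Spatial metadata, passed through unmodified.
    """

    data: np.ndarray
    frame_interval_s: float
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got {self.data.ndim}D")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least 2 frames")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if self.mask is None:
            self.mask = self.data.std(axis=-1) > 0
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal spatial shape of data")

    # ---- matrix view ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_matrix(self) -> np.ndarray:
        """Return masked voxels as a (n_frames, n_voxels) matrix."""
        return self.data[self.mask].T.copy()

    def with_matrix(self, X: np.ndarray) -> "TimeSeriesVolume":
        """Return a copy with masked voxels replaced from a (T, V) matrix."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape != (self.n_frames, int(self.mask.sum())):
            raise ValueError("matrix shape does not match volume/mask")
        data = self.data.copy()
        data[self.mask] = X.T
        return replace(self, data=data, mask=self.mask.copy())

    def map_from(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-masked-voxel vector into a 3D map (``fill`` outside)."""
        out = np.full(self.spatial_shape, fill, dtype=np.float64)
        out[self.mask] = values
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> TimeSeriesVolume:
    """Read a 4D NIfTI-1 image into a :class:`TimeSeriesVolume`.

    The frame interval is taken from ``pixdim[4]`` and the default mask keeps
    voxels with nonzero temporal variance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path} is {data.ndim}D; a 4D time series is required")
    tr = float(img.header.get_zooms()[3])
    if not tr > 0:
        raise ValueError(f"{path}: non-positive frame interval in header (pixdim[4]={tr})")
    return TimeSeriesVolume(data=data, frame_interval_s=tr, affine=np.asarray(img.affine))


def write_volume(vol: TimeSeriesVolume, path: str | Path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1, recording the frame interval in pixdim[4]."""
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.frame_interval_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_map(map3d: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D float map (e.g. a lag map in seconds; untracked = NaN)."""
    nib.save(nib.Nifti1Image(np.asarray(map3d, dtype=np.float32), affine), str(path))


def read_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(np.float64)


# ---------------------------------------------------------------------------
# Tabular I/O (tab-separated text)
# ---------------------------------------------------------------------------

def read_motion(path: str | Path, n_frames: int | None = None) -> pd.DataFrame:
    """Read a 6-column rigid-body motion table (mm, mm, mm, deg, deg, deg)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {df.shape[1]}")
    df.columns = MOTION_COLUMNS
    if n_frames is not None and len(df) != n_frames:
        raise ValueError(f"motion rows ({len(df)}) != frame count ({n_frames})")
    return df


def write_motion(motion: pd.DataFrame, path: str | Path) -> None:
    motion.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    ev = events.copy()
    if (ev["onset"] < 0).any():
        raise ValueError("event onsets must be non-negative")
    if not ev["onset"].is_monotonic_increasing or ev["onset"].duplicated().any():
        raise ValueError("event onsets must be strictly increasing")
    if (ev["duration"] < 0).any():
        raise ValueError("event durations must be non-negative")
    return ev


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a task event list (onset s, duration s, label) from TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration") if c not in df.columns]
    if missing:
        raise ValueError(f"event file lacks columns: {missing}")
    if "label" not in df.columns:
        df["label"] = "event"
    return validate_events(df[EVENT_COLUMNS])


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
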