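"""Synthetic 4D BOLD generator with a known propagating sLFO.

The generator realizes the virtual-tracer picture of the resting BOLD signal:
a single band-limited low-frequency waveform w(t) arrives at each voxel with a
spatially smooth, voxel-specific delay tau(v), on top of which sit
HRF-convolved task responses in a compact active region, independent S0 and
T2* fluctuation channels (for dual-echo synthesis), Gaussian thermal noise,
and injected motion-spike frames.

Signals are built through the monoexponential decay model: the advected sLFO
and the neurovascular term modulate R2* = 1/T2*, and the S0 channels modulate
the echo-time-zero amplitude, so an emitted dual-echo pair satisfies
S(TE) = S0 exp(-TE/T2*) at both echoes exactly when noise is zero.

Velocity model (quasi-static): a relative-velocity profile vrel(t) rescales
every modulated voxel's delay instantaneously, tau_eff(v, t) = tau(v)/vrel(t).
Transit between adjacent 0.5-s lag bins then takes 0.5/vrel(t) seconds, giving
a closed-form ground truth for the rBTT stage. Positive tau means the voxel
leads the global phase (arterial side), per the project sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .hrf import event_regressor
from .multiecho import MultiEchoPair
from .preprocess import SLFO_BAND
from .volume import MOTION_COLUMNS, TimeSeriesVolume, validate_events

__all__ = ["SynthSpec", "SynthTruth", "make_slfo", "simulate", "default_events",
           "default_delay_field"]

FINE_DT_S = 0.02  # waveform sampling grid, s


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def band_limited_noise(n: int, dt: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian series with power confined to [lo, hi]."""
    nyq = 0.5 / dt
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band [{lo}, {hi}] Hz infeasible at Nyquist {nyq} Hz")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    w = np.fft.irfft(spec, n=n)
    sd = w.std()
    if sd == 0:
        raise ValueError("band too narrow for series length")
    return (w - w.mean()) / sd


def make_slfo(band_lo: float, band_hi: float, n_frames: int, frame_interval_s: float,
              rng_seed: int | np.random.Generator) -> np.ndarray:
    """Unit-variance sLFO waveform at the frame grid (>=95% in-band power)."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    return band_limited_noise(n_frames, frame_interval_s, band_lo, band_hi, rng)


def default_delay_field(shape: tuple[int, int, int], range_s: float = 4.0) -> np.ndarray:
    """Axial delay gradient from +range (arterial) to -range (venous).

    The ramp runs along the first axis with a fine sub-gradient along the
    second, so delays cover the range continuously and every 0.5-s lag bin is
    uniformly populated (bin means then sit at the nominal bin centers).
    """
    nx, ny, _ = shape
    ramp = np.linspace(range_s, -range_s, nx * ny).reshape(nx, ny)
    return np.broadcast_to(ramp[:, :, None], shape).copy()


def default_events(n_frames: int, frame_interval_s: float, isi_s: float = 20.0,
                   duration_s: float = 0.5, start_s: float = 10.0) -> pd.DataFrame:
    """Sparse event schedule: brief events every ``isi_s`` seconds."""
    total = n_frames * frame_interval_s
    onsets = np.arange(start_s, total - 40.0, isi_s)
    return validate_events(pd.DataFrame({
        "onset": onsets, "duration": duration_s, "label": "task"}))


# ---------------------------------------------------------------------------
# Specification and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Generation parameters; defaults are the study conditions.

    Amplitudes are percent of the baseline signal at the acquisition echo time.
    ``velocity_mask`` restricts the quasi-static velocity modulation to a
    subset of voxels (None = all voxels when a modulation is requested).
    """

    shape: tuple[int, int, int] = (20, 20, 10)
    frame_interval_s: float = 0.5
    n_frames: int = 1080
    delay_range_s: float = 4.0
    delay_field: np.ndarray | None = None
    slfo_band: tuple[float, float] = SLFO_BAND
    slfo_amplitude_pct: float = 1.0
    velocity_mod_amplitude: float = 0.0
    velocity_mod_freq_hz: float = 0.01
    velocity_profile: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None
    velocity_mask: np.ndarray | None = None
    events: pd.DataFrame | None = None
    active_mask: np.ndarray | None = None
    nvc_amplitude_pct: float = 0.0
    nvc_slfo_corr: float = 0.0
    s0_amplitude_pct: float = 0.0
    s0_freq_hz: float = 0.2
    s0_fluct_pct: float = 0.0
    t2s_fluct_pct: float | np.ndarray = 0.0
    noise_sd_pct: float = 0.0
    spike_frames: tuple[int, ...] = ()
    spike_deflection_pct: float = 2.0
    spike_translation_mm: float = 1.5
    baseline_s0: float = 1000.0
    t2s_baseline_ms: float = 50.0
    te_s: float = 0.035
    dual_te_s: tuple[float, float] | None = None
    motion_jitter_mm: float = 0.02
    rng_seed: int = 0


@dataclass
class SynthTruth:
    """Ground truth recorded by the generator for downstream scoring."""

    waveform: np.ndarray                 # w at frame times (lag-0 reference)
    waveform_fine: np.ndarray            # w on the padded fine grid
    t_fine: np.ndarray
    delay_field: np.ndarray
    vrel: np.ndarray                     # relative velocity per frame
    velocity_mask: np.ndarray            # voxels whose delay is modulated
    active_mask: np.ndarray
    nvc_beta_pct: float
    nvc_regressor: np.ndarray | None
    events: pd.DataFrame | None
    spike_frames: tuple[int, ...]
    motion: pd.DataFrame = field(repr=False, default=None)
    s0_field: np.ndarray | None = field(repr=False, default=None)      # S0(v,t)
    t2s_field_ms: np.ndarray | None = field(repr=False, default=None)  # T2*(v,t)


def _resolve_vrel(spec: SynthSpec, t: np.ndarray) -> np.ndarray:
    if spec.velocity_profile is not None:
        v = spec.velocity_profile(t) if callable(spec.velocity_profile) \
            else np.asarray(spec.velocity_profile, dtype=float)
        if v.shape != t.shape:
            raise ValueError("velocity_profile length must match n_frames")
    elif spec.velocity_mod_amplitude != 0.0:
        v = 1.0 + spec.velocity_mod_amplitude * np.sin(
            2 * np.pi * spec.velocity_mod_freq_hz * t)
    else:
        v = np.ones_like(t)
    if np.any(v <= 0):
        raise ValueError("relative velocity must stay positive")
    return v


def _default_active_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    cx, cy, cz = (s // 2 for s in shape)
    m[cx - 1:cx + 2, cy - 1:cy + 2, max(cz - 1, 0):cz + 1] = True
    return m


def _mix_correlated(w: np.ndarray, ref: np.ndarray, alpha: float) -> np.ndarray:
    """Return a unit-variance waveform with correlation ~alpha to ``ref``."""
    r = (ref - ref.mean())
    r /= r.std()
    c = float(np.mean(w * r))
    w_perp = w - c * r
    w_perp /= w_perp.std()
    out = alpha * r + np.sqrt(1.0 - alpha**2) * w_perp
    return (out - out.mean()) / out.std()


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate(spec: SynthSpec):
    """Generate a synthetic run and its ground truth.

    Returns ``(TimeSeriesVolume, SynthTruth)`` for single-echo specs or
    ``(MultiEchoPair, SynthTruth)`` when ``spec.dual_te_s`` is set. The motion
    table and event list travel inside the truth record.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.shape)
    V = int(np.prod(shape))
    n = spec.n_frames
    dt = spec.frame_interval_s
    t = np.arange(n) * dt

    delay = (np.asarray(spec.delay_field, dtype=float) if spec.delay_field is not None
             else default_delay_field(shape, spec.delay_range_s))
    if delay.shape != shape:
        raise ValueError("delay_field shape mismatch")
    tau = delay.reshape(V)
    if not np.all(np.isfinite(tau)):
        raise ValueError("delay field must be finite inside the mask")

    vrel = _resolve_vrel(spec, t)
    vmask3 = (np.asarray(spec.velocity_mask, dtype=bool) if spec.velocity_mask is not None
              else np.ones(shape, dtype=bool))
    vmask = vmask3.reshape(V)

    # --- common waveform on a padded fine grid -----------------------------
    pad = float(np.max(np.abs(tau)) / vrel.min()) + 2.0
    t_fine = np.arange(-pad, n * dt + pad + FINE_DT_S, FINE_DT_S)
    w_fine = band_limited_noise(t_fine.size, FINE_DT_S, *spec.slfo_band, rng)

    # --- neurovascular coupling --------------------------------------------
    nvc_reg = None
    events = spec.events
    if spec.nvc_amplitude_pct > 0:
        if events is None:
            events = default_events(n, dt)
        nvc_reg = event_regressor(events, n, dt)
        if spec.nvc_slfo_corr != 0.0:
            # band-limited projection of the regressor on the fine grid
            n_fine = t_fine.size
            stim_fine = np.interp(t_fine, t, nvc_reg, left=0.0, right=0.0)
            spec_f = np.fft.rfft(stim_fine)
            freqs = np.fft.rfftfreq(n_fine, d=FINE_DT_S)
            spec_f[(freqs < spec.slfo_band[0]) | (freqs > spec.slfo_band[1])] = 0.0
            ref = np.fft.irfft(spec_f, n=n_fine)
            if ref.std() > 0:
                w_fine = _mix_correlated(w_fine, ref, spec.nvc_slfo_corr)

    # max lag tracking feasibility is advisory only
    if np.max(np.abs(tau)) > 0.5 * n * dt:
        import warnings
        warnings.warn("delays exceed half the scan duration; tracking may fail")

    # --- per-voxel advected sLFO (quasi-static delay scaling) ---------------
    vinv = np.where(vmask[:, None], 1.0 / vrel[None, :], 1.0)
    t_eff = t[None, :] + tau[:, None] * vinv
    slfo_frac = (spec.slfo_amplitude_pct / 100.0) * np.interp(t_eff, t_fine, w_fine)

    bold_frac = slfo_frac
    active3 = (np.asarray(spec.active_mask, dtype=bool) if spec.active_mask is not None
               else _default_active_mask(shape))
    if spec.nvc_amplitude_pct > 0:
        act = active3.reshape(V)
        bold_frac = bold_frac + (spec.nvc_amplitude_pct / 100.0) * np.outer(act, nvc_reg)

    t2s_amp = np.asarray(spec.t2s_fluct_pct, dtype=float)
    if np.any(t2s_amp != 0):
        u = band_limited_noise(n, dt, *spec.slfo_band, rng)
        amp = (t2s_amp.reshape(V) if t2s_amp.ndim else np.full(V, float(t2s_amp)))
        bold_frac = bold_frac + (amp[:, None] / 100.0) * u[None, :]

    # --- S0 channel ---------------------------------------------------------
    s0_frac = np.zeros((V, n))
    if spec.s0_amplitude_pct != 0.0:
        sign = np.ones(shape)
        sign[:, shape[1] // 2:, :] = -1.0  # anterior/posterior flip
        s0_frac += (spec.s0_amplitude_pct / 100.0) * np.outer(
            sign.reshape(V), np.sin(2 * np.pi * spec.s0_freq_hz * t))
    if spec.s0_fluct_pct != 0.0:
        q = band_limited_noise(n, dt, *spec.slfo_band, rng)
        s0_frac += (spec.s0_fluct_pct / 100.0) * q[None, :]

    # --- compose via the monoexponential decay model ------------------------
    t2s0 = spec.t2s_baseline_ms * 1e-3
    r2s = 1.0 / t2s0 - bold_frac / spec.te_s  # dR2* = -frac/TE_ref
    if np.any(r2s <= 0):
        raise ValueError("modulations too large: non-positive R2*")
    s0_abs = spec.baseline_s0 * (1.0 + s0_frac)

    def echo_signal(te: float) -> np.ndarray:
        y = s0_abs * np.exp(-te * r2s)
        base = spec.baseline_s0 * np.exp(-te / t2s0)
        if spec.noise_sd_pct > 0:
            y = y + base * (spec.noise_sd_pct / 100.0) * rng.standard_normal(y.shape)
        for f in spec.spike_frames:
            y[:, f] *= 1.0 + spec.spike_deflection_pct / 100.0
        return y.reshape(shape + (n,))

    # --- motion table -------------------------------------------------------
    motion = pd.DataFrame(
        rng.normal(0.0, spec.motion_jitter_mm, size=(n, 6)), columns=MOTION_COLUMNS)
    for f in spec.spike_frames:
        motion.loc[f, "trans_x"] += spec.spike_translation_mm

    truth = SynthTruth(
        waveform=np.interp(t, t_fine, w_fine),
        waveform_fine=w_fine,
        t_fine=t_fine,
        delay_field=delay,
        vrel=vrel,
        velocity_mask=vmask3,
        active_mask=active3,
        nvc_beta_pct=spec.nvc_amplitude_pct,
        nvc_regressor=nvc_reg,
        events=events,
        spike_frames=tuple(spec.spike_frames),
        motion=motion,
    )

    full_mask = np.ones(shape, dtype=bool)
    if spec.dual_te_s is not None:
        te1, te2 = spec.dual_te_s
        truth.s0_field = s0_abs.reshape(shape + (n,))
        truth.t2s_field_ms = (1.0 / r2s).reshape(shape + (n,)) * 1e3
        pair = MultiEchoPair(
            S1=TimeSeriesVolume(echo_signal(te1), dt, mask=full_mask),
            S2=TimeSeriesVolume(echo_signal(te2), dt, mask=full_mask),
            te1_s=te1, te2_s=te2,
        )
        return pair, truth

    vol = TimeSeriesVolume(echo_signal(spec.te_s), dt, mask=full_mask)
    return vol, truth
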