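# lagstruct

Analysis of the perfusion lag structure of the BOLD fMRI signal: recursive
sLFO lag mapping, lag-structure removal ("deperfusioning"), relative BOLD
transit time (rBTT) velocimetry, and dual-echo S0/T2* decomposition — with a
ground-truth synthetic 4D generator for end-to-end validation.

## The problem

The spontaneous low-frequency oscillation (sLFO, < 0.1 Hz) of the resting
BOLD signal is largely of systemic, blood-borne origin: it arrives at each
brain voxel with a delay set by the voxel's position along the cerebral
vascular tree, behaving like a virtual intravascular tracer. This package is
for researchers who want to

- **map** that lag structure: a voxel-wise lag map plus the per-lag-bin seed
  time courses, obtained by recursive cross-correlation tracking of the sLFO
  phase in 0.5-s steps from the global-signal phase (lag 0) toward the
  arterial (positive lag) and venous (negative lag) sides;
- **remove** it ("deperfusioning"): a dynamic form of global signal
  regression in which every voxel is regressed against the band-limited seed
  series of its own lag bin instead of one uniform global regressor, avoiding
  the spurious deactivations uniform GSR introduces in task GLMs;
- **read blood velocity out of it**: the instantaneous phase difference
  between adjacent lag bins — estimated with a sliding 30-s Kaiser (β = 4)
  windowed cross-correlation on series resampled to 0.02 s — measures the
  time blood takes to cross a boundary that takes 0.5 s on average. Divided
  by 0.5 it gives the rBTT; its reciprocal is the relative blood velocity:

  ```
  rBTT(t) = Δφ(t) / 0.5        v_rel(t) = 1 / rBTT(t)
  ```

- **decompose dual-echo data** into non-BOLD (S0) and BOLD (T2*) channels
  under monoexponential decay, S(TE) = S0·exp(−TE/T2*), with
  T2* = (TE2−TE1)/ln(S1/S2); negative values or values exceeding 100 ms are
  treated as noise.

Because no public dataset accompanies the method, validation is
property-based: the `synth` module generates 4D volumes in which a
band-limited (0.008–0.07 Hz) common waveform propagates through a known
±4-s delay field, with optional velocity modulation (quasi-static:
τ_eff = τ/v_rel(t)), HRF-convolved task responses, independent S0/T2*
channels, thermal noise, and motion-spike frames — every stage is scored
against this ground truth.

## Worked example

```python
import numpy as np
from lagstruct import SynthSpec, simulate, bandpass, track, neighbor_pairs, rbtt_trace

# 20x20x10 voxels, 1080 frames at TR 0.5 s, +/-4 s delay gradient,
# 5% sinusoidal velocity modulation at 0.01 Hz
spec = SynthSpec(velocity_mod_amplitude=0.05, velocity_mod_freq_hz=0.01, rng_seed=2)
vol, truth = simulate(spec)

Xb = bandpass(vol.to_matrix(), 0.008, 0.12, 0.5)   # rBTT band, +/-4 s range
ls = track(Xb, 0.5, range_s=4.0)
print(f"{ls.n_bins} lag bins:", ls.bin_lags)

true = truth.delay_field[vol.mask]
ok = np.isfinite(ls.lags)
print("lag map r =", round(np.corrcoef(ls.lags[ok], true[ok])[0, 1], 3))

trace = rbtt_trace(neighbor_pairs(ls, range_s=4.0), 0.5)
print("mean rBTT =", round(np.nanmean(trace.rbtt), 3))
```

prints

```
17 lag bins: [ 4.   3.5  3.   2.5  2.   1.5  1.   0.5  0.  -0.5 -1.  -1.5 -2.  -2.5  -3.  -3.5 -4. ]
lag map r = 0.998
mean rBTT = 0.973
```

The tracker recovers the full ±4-s structure (17 bins, 16 adjacent pairs);
the lag map correlates 0.998 with the true delay field; the mean rBTT sits
near 1 (slightly below because the two outermost bins are truncated by the
edge of the delay field), and the 0.01-Hz modulation of `trace.relative_velocity`
recovers the generated 5% velocity oscillation.

The same stages are scriptable from the shell
(`lagstruct synth|preprocess|lagmap|deperfusion|rbtt|multiecho|regions|run`),
and `lagstruct run config.yaml --out dir/` executes a declarative multi-stage
pipeline whose parameters are all logged to `run_log.yaml`. The estimator
classes (`BandpassFilter`, `LagMapper`, `DynamicGSR`, `EventGLM`, ...) follow
the scikit-learn API and compose in `sklearn.pipeline.Pipeline`.

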