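# Methods

This note documents the models, estimators and numerical choices implemented
in `lagstruct`, and what the synthetic validation does and does not show.

## Signal model and sign convention

The resting BOLD signal is modelled as a common band-limited waveform w(t)
(the sLFO) advected through the vasculature: voxel v receives
w(t + τ_v), where τ_v is the voxel's lag. **Positive lag means the voxel's
signal leads the global-signal phase** — the arterial ("inlet") side; negative
lags are venous ("outlet"). `xcorrelogram(x, y)` reports a positive peak lag
when x leads y. This convention is fixed project-wide in `lagstruct.volume`
and never re-derived.

The baseline biophysics (`physio`) uses the standard power-law BOLD model
dS/S0 = M·(1 − (CMRO2 ratio)^β · (CBV ratio) · (CBF ratio)^−β) with
M = κ·TE·CBV0·δω^β and the off-resonance shift
δω = γ·(4/3)π·Δχ0·Hct·OEF·B0. Defaults: OEF 0.45, Hct 0.40, CBV0 0.03,
TE 30 ms, B0 3 T, γ 42.58 MHz/T, Δχ0 0.264 ppm, β 1.5. When the arterial
inflow is desaturated (SaO2 < 1) the baseline deoxy-Hb density becomes
Hct·[SaO2·OEF + (1−SaO2)], which makes the baseline signal fall monotonically
with SaO2 (`sao2_bold_shift`). κ is an arbitrary-units scale: only zeros,
signs, ratios and linearity of these expressions are asserted anywhere; no
absolute M value is relied on.

## Synthetic generator

`synth.simulate` composes signals through the monoexponential decay model
S(TE) = S0(v,t)·exp(−TE/T2*(v,t)): the advected sLFO, the HRF-convolved task
(NVC) term and an independent in-band T2* channel modulate R2* (ΔR2* =
−fraction/TE_ref), while the S0 channels (a 0.2-Hz respiration-locked
waveform with an anterior/posterior sign flip, plus an in-band fluctuation)
modulate the echo-time-zero amplitude. A dual-echo pair therefore satisfies
the decay model at both echoes exactly when noise is zero, and a single-echo
volume is the same model evaluated at one TE.

Key default conditions (chosen once, as the conditions under study):

- grid 20×20×10 voxels, 1080 frames at TR 0.5 s (a 9-minute fast-TR run);
- delay field: axial gradient +4 → −4 s along the first axis with a fine
  transverse sub-gradient, so delays cover the range continuously and every
  0.5-s lag bin is uniformly populated (bin means sit at bin centers);
- sLFO band 0.008–0.07 Hz, amplitude 1% of baseline; thermal noise given as
  percent of the baseline signal; baseline S0 1000 a.u., baseline T2* 50 ms,
  TE 35 ms.

**Velocity model (quasi-static).** A relative-velocity profile v_rel(t) > 0
rescales every modulated voxel's delay instantaneously:
τ_eff(v,t) = τ_v / v_rel(t). Transit between adjacent 0.5-s bins then takes
0.5/v_rel(t) s, which is the closed-form ground truth for the rBTT stage.
This is the minimal model with exact rBTT ground truth; it is appropriate
because the velocity modulations of interest (≤ 0.02 Hz) are slow relative
to inter-bin transit (0.5 s). It is *not* an advection simulation along a
branching vessel graph: dispersion, path-length heterogeneity and
draining-vein geometry are absent, so passing tests demonstrate estimator
correctness under the model, not robustness to vascular-tree realism.

**Task coupling.** When a nonzero sLFO/task-regressor correlation is
requested, the band-limited projection of the HRF-convolved regressor is
mixed into the sLFO waveform at the requested correlation (default target
+0.1), emulating the small positive coupling between the global signal and
the modelled response that produces spurious deactivations under uniform GSR.

**Spikes.** Spike frames multiply the whole volume by 1 + deflection (default
2%) and add a translation step (default 1.5 mm) to the emitted motion table,
on top of small Gaussian motion jitter (0.02 mm SD).

## Preprocessing

- **Spike detection**: a frame is flagged when its global mean deviates more
  than 1% of the session mean, or its translations (Euclidean norm) move more
  than 1 mm, or any rotation more than 1°, *relative to the last accepted
  frame*. Measuring steps against the last accepted frame rather than the
  immediately preceding frame means a single-frame excursion flags only the
  deviant frame, not the recovery frame; for clean data and sustained shifts
  the two rules coincide. Either criterion suffices to flag (OR), but the
  per-criterion lists are kept so a conjunctive reading remains recoverable.
  Mixing millimetres and degrees in one norm is ill-defined, hence rotations
  are checked per axis. Flagged frames are replaced by linear interpolation
  between the nearest accepted neighbors (nearest-value extension at the
  ends).
- **Motion nuisance**: 24 columns — the 6 rigid-body parameter first
  derivatives, the same delayed by one frame, and the squares of those 12.
  The raw parameters are excluded (they can be contaminated by the global
  signal in immobile subjects). Regression is per-voxel OLS with intercept;
  voxel means are restored.
- **Band-pass**: a zero-phase spectral mask with raised-cosine edges (default
  taper: a quarter of the lower cutoff). Phase is exactly preserved in-band —
  the property lag estimation depends on — in-band amplitude is preserved,
  and out-of-band rejection far exceeds 20 dB per octave. The mean is removed
  whenever the lower cutoff is positive.

## Lag mapping

Recursive tracking (`lagmap.track`) on band-passed data (0.008–0.07 Hz for
±7-s ranges; 0.008–0.12 Hz when the range is limited to ±4 s for velocity
analyses, so the phase stays unique within the cross-correlation range):

1. the initial seed is the set of voxels whose correlogram against the global
   mean peaks at lag 0 with r ≥ 0.3; their mean defines the lag-0 reference;
2. stepping up- and downstream independently from that seed, the undetermined
   voxels whose correlogram against the previous seed's mean peaks at exactly
   ±0.5 s with r ≥ threshold are assigned the new lag and averaged into the
   new seed; recursion stops at the range or when a step yields no voxels;
   voxels are never reassigned.

Numerical choices: peaks are located at integer frame shifts only (the bin
width *is* the step; data at other TRs should be resampled to 0.5 s first);
the peak is the signed maximum, so anti-correlated voxels are not tracked
(the method follows propagation of one waveform); a tie between two shifts
leaves the voxel unassigned for the later passes, since a misassignment would
propagate through the recursion.

Hole filling: pass 1 visits untracked voxels one at a time (flat index
order), assigning each the correlation-weighted mean lag of the
already-lagged voxels it correlates with above 0.3 at zero shift, after which
it joins the donor pool; the weighted mean is on the linear lag axis (lags
are bounded and linear, not circular). Pass 2 fills any remaining voxel whose
six face-neighbors all carry lags with their mean. Unresolved voxels stay
NaN, and lag maps are written as float NIfTI in seconds with NaN for
untracked voxels so sign and units survive to downstream tools.

## Denoising and GLM

Four cleaning methods share one contract (geometry and frame count unchanged,
voxel means preserved): uniform GSR, low-pass GSR (global regressor limited
to the sLFO band), frame-wise global scaling (division by the frame's global
mean, rescaled to the grand mean), and deperfusioning. Deperfusioning
regresses each binned voxel against the *band-limited* seed series of its own
bin and subtracts only the fitted component, so content outside the sLFO band
passes through untouched; voxels without a bin fall back to low-pass GSR and
the count is logged.

The event GLM uses the canonical double-gamma HRF (peak delay 6 s, undershoot
delay 16 s, ratio 1:6 — named constants) convolved with the event boxcars,
plus an intercept and a linear drift term (a minimal stand-in for the
high-pass filtering a full fMRI package would apply). Betas are in input
units per unit response (the regressor is max-normalized); t-values use the
nominal residual dof.

## rBTT and velocity

For each of the 16 adjacent-bin pairs within ±4 s, both seed series are
cubic-spline resampled to 0.02 s; at every output time a 30-s Kaiser (β = 4)
tapered segment is cross-correlated over lags 0.5 ± 0.25 s and the peak
abscissa, refined parabolically between the 0.02-s grid points, is the
instantaneous phase difference. A windowed correlation peak is used rather
than analytic-signal (Hilbert) phase because the sLFO is broadband within its
band; the ±0.25-s search span prevents cycle hopping, since the differences
are perturbations around the nominal 0.5-s step. Times without a stable
interior peak above r = 0.3 (flat segments, window edges, independent noise)
yield NaN. Per-pair differences are averaged across pairs (optionally
event-locked over a configurable peri-event window, default −10…+60 s, with
the pre-event mean as baseline), divided by 0.5 to give the rBTT, and
inverted for relative velocity. Averaging before or after the division by
0.5 is equivalent for these linear means.

Two known biases, both visible in the validation numbers: the sliding window
low-passes the recovered modulation (a 0.01-Hz, 5% modulation recovers at
~0.047 amplitude with a ~0.5-s phase shift), and the outermost bins of a
delay field that ends exactly at ±4 s are half-width, which pulls the mean
rBTT slightly below 1 (~0.97 under the default conditions). Neither affects
the modulation-amplitude readout, which is relative.

## Multi-echo decomposition

Single-compartment monoexponential decay is assumed throughout. Per frame and
voxel: T2* = (TE2−TE1)/ln(S1/S2) and S0 = S1^(TE2/ΔTE)/S2^(TE1/ΔTE). Samples
with non-positive signals, S1 = S2, or T2* negative or exceeding 100 ms are
noise: marked invalid and carried as NaN. The 100-ms bound is inclusive
(values *exceeding* 100 ms are rejected), with a 1e-9 relative epsilon so a
decay constant sitting exactly on the bound survives float round-trip. Invalid
samples are never interpolated at this stage; any temporal interpolation is
deferred to the analysis that consumes the fields, with counts logged.

## Regional analysis and ICC

Inlet/center/outlet are defined purely by lag under the sign convention
(inlet: lag > +h; outlet: lag < −h; center: |lag| ≤ h; default halfwidth
2.5 s for ±7-s structures). sLFO magnitude is the sample SD of the
band-passed percent-signal-change series, which makes it invariant to the
voxel baseline. Map similarity uses ICC(2,1) — two-way random effects,
absolute agreement, single measure — computed from the two-way ANOVA mean
squares with voxels as subjects and maps as raters:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

NaNs are excluded pairwise. `phase_delay` reports the sub-sample-refined
correlogram peak and warns when a competing near-equal peak exists (periodic
signals are ambiguous by half a period).

## Validation design and problem sizes

All acceptance-style checks run on generated data at 20×20×10 × 1080 frames
(the bias-ordering study uses 12×12×6 × 1080 frames across 20 generator
seeds, enough for the sign tests while keeping the whole run around a minute
on one CPU). The spurious-deactivation ordering (uniform GSR < deperfusioning
≤ raw for the mean non-active beta, GSR strictly negative) is asserted on the
across-seed means plus per-seed sign tests: the GSR-vs-deperfusioning gap is
small relative to between-seed variability (paired t ≈ 2.5 over 20 seeds), so
the ordering is a property of the means, not of every individual realization.

## Known limitations

- The quasi-static velocity model omits dispersion and path-length effects; a
  vessel-graph advection simulator is out of scope.
- Lag tracking assumes one propagating waveform; anti-correlated or
  multi-source dynamics are untracked by design.
- The GLM is single-run, fixed-effects, with a linear drift term only; no
  group inference, cluster correction or template-space analysis.
- The generator's delay field is spatially smooth and monotone; real lag maps
  interleave arterial and venous territories, which mainly affects how
  compact activations distribute over lag bins.
- Slice-timing, distortion correction, spatial smoothing and normalization
  are out of scope; inputs are assumed motion-corrected 4D NIfTI.
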