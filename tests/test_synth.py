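import numpy as np
import pytest

from lagstruct.lagmap import xcorrelogram
from lagstruct.multiecho import decompose
from lagstruct.synth import (SynthSpec, default_delay_field, make_slfo, simulate)


def band_power_fraction(w, dt, lo, hi):
    freqs = np.fft.rfftfreq(w.size, d=dt)
    p = np.abs(np.fft.rfft(w - w.mean())) ** 2
    return p[(freqs >= lo) & (freqs <= hi)].sum() / p.sum()


class TestMakeSlfo:
    def test_unit_variance_and_band_power(self):
        w = make_slfo(0.008, 0.07, 1080, 0.5, rng_seed=1)
        assert w.mean() == pytest.approx(0.0, abs=1e-12)
        assert w.std() == pytest.approx(1.0, rel=1e-9)
        assert band_power_fraction(w, 0.5, 0.008, 0.07) >= 0.95

    def test_deterministic(self):
        np.testing.assert_array_equal(make_slfo(0.008, 0.07, 200, 0.5, 7),
                                      make_slfo(0.008, 0.07, 200, 0.5, 7))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_slfo(0.008, 1.5, 200, 0.5, 0)

    def test_autocorrelation_matches_band_spectrum(self):
        # Wiener-Khinchin: flat band [lo, hi] implies
        # rho(d) = [sin(2 pi hi d) - sin(2 pi lo d)] / (2 pi d (hi - lo))
        lo, hi, d = 0.008, 0.07, 0.5
        w = make_slfo(lo, hi, 40000, d, rng_seed=3)
        rho_hat = np.corrcoef(w[:-1], w[1:])[0, 1]
        rho = (np.sin(2 * np.pi * hi * d) - np.sin(2 * np.pi * lo * d)) \
            / (2 * np.pi * d * (hi - lo))
        assert rho_hat == pytest.approx(rho, abs=0.03)


class TestSimulate:
    def test_null_signal_is_constant(self):
        spec = SynthSpec(shape=(4, 4, 2), n_frames=50, slfo_amplitude_pct=0.0,
                         noise_sd_pct=0.0, rng_seed=0)
        vol, _ = simulate(spec)
        assert vol.data.std() == pytest.approx(0.0, abs=1e-12)

    def test_two_voxel_lag_oracle(self):
        # voxel with tau = +0.5 s leads the tau = 0 voxel by exactly one frame
        delay = np.array([0.5, 0.0]).reshape(2, 1, 1)
        spec = SynthSpec(shape=(2, 1, 1), n_frames=600, delay_field=delay,
                         noise_sd_pct=0.0, rng_seed=5)
        vol, _ = simulate(spec)
        x = vol.data[0, 0, 0]
        y = vol.data[1, 0, 0]
        # independent brute-force correlogram
        best = max(range(-6, 7),
                   key=lambda k: np.corrcoef(x[: 600 - k], y[k:])[0, 1] if k >= 0
                   else np.corrcoef(x[-k:], y[:600 + k])[0, 1])
        assert best == 1
        cg = xcorrelogram(x, y, 3.0, 0.5)
        assert cg.peak_lag_s == pytest.approx(0.5)
        assert cg.peak_r > 0.99

    def test_exact_time_shift_invariant(self):
        # noise-free, vrel = 1: signals are exact time-shifted copies
        delay = np.array([0.5, 0.0]).reshape(2, 1, 1)
        spec = SynthSpec(shape=(2, 1, 1), n_frames=400, delay_field=delay,
                         noise_sd_pct=0.0, rng_seed=9)
        vol, _ = simulate(spec)
        lead = vol.data[0, 0, 0]
        ref = vol.data[1, 0, 0]
        np.testing.assert_allclose(lead[:-1], ref[1:], atol=1e-10)

    def test_quasi_static_velocity_scales_delay(self):
        # generator closed form: effective delay = tau / vrel(t)
        n, dt = 400, 0.5
        t = np.arange(n) * dt
        vrel = 1.0 + 0.05 * np.sin(2 * np.pi * 0.01 * t)
        delay = np.array([0.5, 0.0]).reshape(2, 1, 1)
        spec = SynthSpec(shape=(2, 1, 1), n_frames=n, delay_field=delay,
                         velocity_profile=vrel, noise_sd_pct=0.0, rng_seed=10)
        vol, truth = simulate(spec)
        # the generator's own closed form: modulated voxel samples w(t + tau/vrel)
        x = vol.data[0, 0, 0]
        expected = np.interp(t + 0.5 / vrel, truth.t_fine, truth.waveform_fine)
        got = np.log(x / x.mean()) / 0.01  # invert the 1% exponential modulation
        assert np.corrcoef(got, expected)[0, 1] > 0.999
        # reference voxel (tau = 0) is unaffected by the velocity profile
        np.testing.assert_allclose(vol.data[1, 0, 0],
                                   vol.data[1, 0, 0, 0] * np.exp(
                                       0.01 * (truth.waveform - truth.waveform[0])),
                                   rtol=1e-10)

    def test_variance_decomposition(self):
        # independent channels: total variance splits into sLFO + noise parts
        spec = SynthSpec(shape=(6, 6, 3), n_frames=1080, slfo_amplitude_pct=1.0,
                         noise_sd_pct=0.5, rng_seed=12)
        vol, truth = simulate(spec)
        base = vol.data.mean()
        pct = 100.0 * (vol.to_matrix() / vol.to_matrix().mean(axis=0) - 1.0)
        total = pct.var(axis=0).mean()
        expected = 1.0**2 * truth.waveform.var() + 0.5**2
        assert total == pytest.approx(expected, rel=0.05)
        assert base > 0

    def test_spike_injection_exceeds_thresholds(self):
        spec = SynthSpec(shape=(6, 6, 3), n_frames=100, noise_sd_pct=0.1,
                         spike_frames=(30, 60), rng_seed=2)
        vol, truth = simulate(spec)
        g = vol.data.mean(axis=(0, 1, 2))
        step = abs(g[30] - g[29]) / g.mean()
        assert step > 0.01
        assert truth.motion.loc[30, "trans_x"] > 1.0
        assert list(truth.spike_frames) == [30, 60]

    def test_dual_echo_satisfies_decay_model_exactly(self):
        spec = SynthSpec(shape=(5, 5, 3), n_frames=80, s0_amplitude_pct=0.5,
                         t2s_fluct_pct=0.5, noise_sd_pct=0.0,
                         dual_te_s=(11.2e-3, 32.78e-3), rng_seed=4)
        pair, truth = simulate(spec)
        for echo, te in ((pair.S1, pair.te1_s), (pair.S2, pair.te2_s)):
            pred = truth.s0_field * np.exp(-te / (truth.t2s_field_ms * 1e-3))
            np.testing.assert_allclose(echo.data, pred, rtol=1e-12)
        df = decompose(pair)
        np.testing.assert_allclose(df.t2s_ms, truth.t2s_field_ms, rtol=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="shape"):
            simulate(SynthSpec(shape=(4, 4, 2), delay_field=np.zeros((3, 3, 3))))
        with pytest.raises(ValueError, match="positive"):
            simulate(SynthSpec(shape=(2, 2, 2), n_frames=50,
                               velocity_profile=np.zeros(50)))
        with pytest.raises(ValueError, match="finite"):
            simulate(SynthSpec(shape=(2, 1, 1), n_frames=50,
                               delay_field=np.array([np.nan, 0.0]).reshape(2, 1, 1)))


def test_default_delay_field_spans_range():
    f = default_delay_field((20, 20, 10), 4.0)
    assert f.max() == pytest.approx(4.0)
    assert f.min() == pytest.approx(-4.0)
    # constant along z, monotone along the unrolled x-y ramp
    assert np.ptp(f, axis=2).max() == 0.0
    ramp = f[:, :, 0].ravel()
    assert np.all(np.diff(ramp) < 0)
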