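import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagstruct.preprocess import (RepairReport, bandpass, detect_spikes, motion_design,
                                  percent_change, regress_out, repair)
from lagstruct.synth import SynthSpec, simulate
from lagstruct.volume import MOTION_COLUMNS, TimeSeriesVolume


def _vol_from_global(g):
    data = np.tile(np.asarray(g, float), (2, 2, 2, 1))
    return TimeSeriesVolume(data, 0.5, mask=np.ones(data.shape[:3], bool))


def _zero_motion(n):
    return pd.DataFrame(np.zeros((n, 6)), columns=MOTION_COLUMNS)


class TestDetectSpikes:
    def test_clean_data_unflagged(self):
        vol = _vol_from_global(np.full(50, 100.0))
        rep = detect_spikes(vol, _zero_motion(50))
        assert rep.frames == []

    def test_subthreshold_excursions_unflagged(self):
        g = np.full(50, 100.0)
        g[20] = 100.9  # 0.9% jump
        mot = _zero_motion(50)
        mot.loc[30, ["trans_x", "trans_y"]] = [0.3, 0.4]  # 0.5 mm step
        rep = detect_spikes(_vol_from_global(g), mot)
        assert rep.frames == []

    def test_each_criterion_fires(self):
        g = np.full(50, 100.0)
        g[10] = 101.5
        mot = _zero_motion(50)
        mot.loc[20, "trans_x"] = 1.2
        mot.loc[25, "rot_z"] = 1.5
        rep = detect_spikes(_vol_from_global(g), mot)
        assert rep.global_frames == [10]
        assert rep.motion_frames == [20, 25]
        assert rep.frames == [10, 20, 25]

    def test_generator_spikes_recovered_exactly(self):
        spec = SynthSpec(shape=(8, 8, 4), n_frames=150, noise_sd_pct=0.3,
                         spike_frames=(25, 80, 81, 140), rng_seed=6)
        vol, truth = simulate(spec)
        rep = detect_spikes(vol, truth.motion)
        assert rep.frames == [25, 80, 81, 140]

    def test_mismatched_motion_length(self):
        with pytest.raises(ValueError):
            detect_spikes(_vol_from_global(np.full(50, 100.0)), _zero_motion(49))


class TestRepair:
    def test_midpoint(self):
        g = np.array([10.0, 20.0, 35.0, 40.0])
        vol = _vol_from_global(g)
        out = repair(vol, RepairReport(frames=[2]))
        np.testing.assert_allclose(out.data[0, 0, 0], [10, 20, 30, 40])

    def test_no_flags_identity(self):
        vol = _vol_from_global(np.array([1.0, 5.0, 2.0, 8.0]))
        out = repair(vol, RepairReport())
        np.testing.assert_array_equal(out.data, vol.data)

    def test_consecutive_flags_on_line(self):
        g = np.array([0.0, 99.0, 99.0, 3.0])
        out = repair(_vol_from_global(g), RepairReport(frames=[1, 2]))
        np.testing.assert_allclose(out.data[0, 0, 0], [0.0, 1.0, 2.0, 3.0])

    def test_edge_flags_nearest_extension(self):
        g = np.array([99.0, 1.0, 2.0, 99.0])
        out = repair(_vol_from_global(g), RepairReport(frames=[0, 3]))
        np.testing.assert_allclose(out.data[0, 0, 0], [1.0, 1.0, 2.0, 2.0])

    def test_all_flagged_error(self):
        with pytest.raises(ValueError):
            repair(_vol_from_global(np.arange(4.0)), RepairReport(frames=[0, 1, 2, 3]))

    def test_detect_repair_idempotent(self):
        spec = SynthSpec(shape=(8, 8, 4), n_frames=150, noise_sd_pct=0.3,
                         spike_frames=(25, 80), rng_seed=8)
        vol, truth = simulate(spec)
        repaired = repair(vol, detect_spikes(vol, None))
        assert detect_spikes(repaired, None).frames == []


class TestMotionDesign:
    def test_constant_motion_all_zero(self):
        mot = pd.DataFrame(np.ones((10, 6)), columns=MOTION_COLUMNS)
        np.testing.assert_array_equal(motion_design(mot), np.zeros((10, 24)))

    def test_linear_drift_constant_derivative(self):
        mot = _zero_motion(10)
        mot["trans_y"] = 0.3 * np.arange(10)
        D = motion_design(mot)
        np.testing.assert_allclose(D[1:, 1], 0.3)
        np.testing.assert_allclose(D[2:, 7], 0.3)  # shifted copy

    def test_squares_definition(self, rng):
        mot = pd.DataFrame(rng.normal(size=(30, 6)), columns=MOTION_COLUMNS)
        D = motion_design(mot)
        assert D.shape == (30, 24)
        np.testing.assert_allclose(D[:, 12:], D[:, :12] ** 2)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            motion_design(_zero_motion(2))


class TestRegressOut:
    def test_perfect_fit_leaves_constant(self, rng):
        d = rng.normal(size=50)
        X = np.column_stack([d, 2 * d + 1])
        out = regress_out(X, d)
        assert out.std(axis=0) == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(out.mean(axis=0), X.mean(axis=0))

    def test_orthogonal_design_no_change(self):
        t = np.arange(100)
        voxel = np.sin(2 * np.pi * t / 20)
        d = np.cos(2 * np.pi * t / 20)  # orthogonal over full periods
        out = regress_out(voxel[:, None], d)
        np.testing.assert_allclose(out[:, 0], voxel, atol=1e-10)

    def test_variance_never_increases(self, rng):
        X = rng.normal(size=(80, 30))
        D = rng.normal(size=(80, 5))
        out = regress_out(X, D)
        assert np.all(out.var(axis=0) <= X.var(axis=0) + 1e-12)

    def test_rank_deficient_handled(self, rng, caplog):
        d = rng.normal(size=40)
        X = rng.normal(size=(40, 3))
        out = regress_out(X, np.column_stack([d, d]))  # duplicated column
        assert np.all(np.isfinite(out))


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(1080) * 0.5
        x = np.sin(2 * np.pi * 0.03 * t)
        y = bandpass(x, 0.008, 0.07, 0.5)
        amp = np.sqrt(2 * np.mean(y[100:-100] ** 2))
        assert amp == pytest.approx(1.0, rel=0.05)
        # zero phase: peak of cross-correlation at zero shift
        phase = np.angle(np.sum(y * np.exp(-2j * np.pi * 0.03 * t))
                         / np.sum(x * np.exp(-2j * np.pi * 0.03 * t)))
        assert abs(phase) / (2 * np.pi * 0.03) < 0.05  # seconds

    def test_out_of_band_attenuated(self):
        t = np.arange(1080) * 0.5
        x = np.sin(2 * np.pi * 0.5 * t)
        y = bandpass(x, 0.008, 0.07, 0.5)
        assert np.abs(y).max() <= 0.1 * np.abs(x).max()  # >= 20 dB

    def test_constant_removed(self):
        y = bandpass(np.full(300, 7.0), 0.008, 0.07, 0.5)
        assert np.abs(y).max() < 1e-10

    def test_infeasible_band(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 0.008, 2.0, 0.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 200))
        lhs = bandpass(a * x + b * y, 0.008, 0.07, 0.5)
        rhs = a * bandpass(x, 0.008, 0.07, 0.5) + b * bandpass(y, 0.008, 0.07, 0.5)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestPercentChange:
    def test_examples(self):
        x = np.full((10, 1), 200.0)
        np.testing.assert_array_equal(percent_change(x), np.zeros((10, 1)))
        x = np.array([[100.0], [101.0], [99.0]])
        assert percent_change(x)[1, 0] == pytest.approx(1.0)

    def test_sd_closed_form(self, rng):
        # SD of percent change of a*w + m equals 100*a*SD(w)/mean
        w = rng.normal(size=500)
        a, m = 3.0, 120.0
        series = a * w + m
        got = np.std(percent_change(series[:, None]), ddof=1)
        assert got == pytest.approx(100.0 * a * np.std(w, ddof=1) / series.mean(),
                                    rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_change(np.array([[1.0], [-1.0]]))
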