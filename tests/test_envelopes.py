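"""Envelope extraction: mean envelope, significant peaks, condition inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitdoppler as gd
from gaitdoppler.envelopes import significant_peaks
from gaitdoppler.spectrogram import Spectrogram
from conftest import constant_velocity_trajectory


def toy_spectrogram(power_rows, velocities):
    """Build a minimal spectrogram from explicit per-frame power rows."""
    power = np.atleast_2d(np.asarray(power_rows, dtype=float))
    n = power.shape[0]
    return Spectrogram(
        frame_times=np.arange(n) / 75.0,
        velocities=np.asarray(velocities, dtype=float),
        power=power,
        window_len=len(velocities),
        hop=8,
        fs=600.0,
        config=gd.RadarConfig(),
    )


class TestMeanEnvelope:
    def test_point_mass(self):
        spec = toy_spectrogram([[0, 0, 5.0, 0]], [-1.0, 0.0, 1.2, 2.0])
        assert gd.mean_envelope(spec)[0] == pytest.approx(1.2)

    def test_equal_power_in_two_bins(self):
        spec = toy_spectrogram([[0, 1.0, 0, 1.0]], [0.0, 1.0, 1.5, 2.0])
        assert gd.mean_envelope(spec)[0] == pytest.approx(1.5)

    def test_weighted_mean(self):
        spec = toy_spectrogram([[3.0, 0, 1.0]], [0.0, 1.0, 2.0])
        assert gd.mean_envelope(spec)[0] == pytest.approx(0.5)

    def test_all_zero_spectrogram_rejected(self):
        spec = toy_spectrogram([[0.0, 0.0]], [0.0, 1.0])
        with pytest.raises(ValueError, match="all-zero"):
            gd.mean_envelope(spec)

    def test_zero_power_frame_flagged_undefined(self):
        spec = toy_spectrogram([[1.0, 0], [0, 0]], [0.0, 1.0])
        v_m = gd.mean_envelope(spec)
        assert v_m[0] == 0.0
        assert np.isnan(v_m[1])


class TestSignificantPeaks:
    grid = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])

    def test_two_peaks_above_threshold(self):
        v, a = significant_peaks([0.1, 1.0, 0.2, 0.3, 0.1], self.grid, rho=0.2)
        assert list(v) == [-1.0, 1.0]
        assert list(a) == [1.0, 0.3]

    def test_second_peak_below_threshold_excluded(self):
        v, _ = significant_peaks([0.1, 1.0, 0.15, 0.18, 0.1], self.grid, rho=0.2)
        assert list(v) == [-1.0]

    def test_single_nonzero_interior_bin(self):
        v, a = significant_peaks([0.0, 0.0, 0.7, 0.0, 0.0], self.grid, rho=0.2)
        assert list(v) == [0.0] and list(a) == [0.7]

    def test_all_zero_frame_gives_empty_set(self):
        v, a = significant_peaks(np.zeros(5), self.grid, rho=0.2)
        assert v.size == 0 and a.size == 0

    def test_plateau_counts_once_at_leftmost_bin(self):
        grid = np.arange(7.0)
        v, _ = significant_peaks([0.0, 0.1, 0.8, 0.8, 0.8, 0.1, 0.0], grid, rho=0.2)
        assert list(v) == [2.0]

    def test_endpoint_and_endpoint_plateau_ineligible(self):
        grid = np.arange(5.0)
        v, _ = significant_peaks([1.0, 0.2, 0.9, 0.5, 0.5], grid, rho=0.2)
        assert list(v) == [2.0]  # only the interior local max survives

    def test_invalid_rho_rejected(self):
        for rho in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError, match="rho"):
                significant_peaks([0.1, 0.5, 0.1], np.arange(3.0), rho=rho)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            significant_peaks([-0.1, 0.5, 0.1], np.arange(3.0), rho=0.2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        amps=st.lists(st.floats(0.0, 10.0), min_size=5, max_size=40),
        rho_pair=st.tuples(st.floats(0.05, 0.9), st.floats(0.05, 0.9)),
    )
    def test_raising_threshold_never_adds_peaks(self, amps, rho_pair):
        lo, hi = sorted(rho_pair)
        grid = np.arange(len(amps), dtype=float)
        n_lo = significant_peaks(amps, grid, rho=lo)[0].size
        n_hi = significant_peaks(amps, grid, rho=hi)[0].size
        assert n_hi <= n_lo


class TestExtractEnvelopes:
    def test_single_scatterer_envelopes_within_one_bin(self, radar):
        traj = constant_velocity_trajectory(v=1.0, duration=1.5)
        sig = gd.synthesize_baseband(traj, radar, noise_sd=0.0)
        spec = gd.compute_spectrogram(sig, config=radar)
        env = gd.extract_envelopes(spec)
        b = spec.velocity_bin
        for series in (env.v_u, env.v_l, env.v_m):
            assert np.all(np.abs(series - 1.0) <= b)

    def test_rho_invariance_for_single_scatterer(self, radar):
        traj = constant_velocity_trajectory(v=0.8, duration=1.0)
        sig = gd.synthesize_baseband(traj, radar, noise_sd=0.0)
        spec = gd.compute_spectrogram(sig, config=radar)
        ref = gd.extract_envelopes(spec, rho=0.5)
        for rho in (0.05, 0.2, 0.9):
            env = gd.extract_envelopes(spec, rho=rho)
            assert np.array_equal(env.v_u, ref.v_u)
            assert np.array_equal(env.v_l, ref.v_l)

    def test_ordering_invariant_on_simulated_walkers(self):
        for label, seed in (("young", 21), ("elderly", 22)):
            p = gd.sample_class_params(label, seed)
            traj = gd.simulate_walker(p, n_cycles=4, rng_seed=seed)
            sig = gd.synthesize_baseband(traj, gd.RadarConfig(), noise_sd=0.03,
                                         rng_seed=seed)
            crop = gd.select_analysis_interval(gd.compute_spectrogram(sig))
            env = gd.extract_envelopes(crop)
            b = crop.velocity_bin
            assert np.all(env.v_l <= env.v_m + b)
            assert np.all(env.v_m <= env.v_u + b)

    def test_swing_peak_recovered_from_upper_envelope(self, young_walker, young_envelopes):
        params, _, _ = young_walker
        vmax = young_envelopes.v_u.max()
        assert abs(vmax - params.swing_peak_velocity_mean) <= (
            0.1 * params.swing_peak_velocity_mean
        )

    def test_subthreshold_background_leaves_envelopes_unchanged(self, young_crop):
        """Background components whose amplitude stays below rho times the
        frame maximum cannot become significant peaks, so the upper and lower
        envelopes ignore them (noise-cancellation property of the relative
        threshold).  The background occupies the empty receding-velocity band
        the walker never visits."""
        rho = 0.2
        ref = gd.extract_envelopes(young_crop, rho=rho)
        amps = young_crop.amplitude.copy()
        rng = np.random.default_rng(0)
        band = young_crop.velocities < -0.3  # approaching walker never gets here
        cap = 0.9 * rho * amps.max(axis=1, keepdims=True)
        background = cap * rng.uniform(0.1, 1.0, size=(amps.shape[0], int(band.sum())))
        amps[:, band] = np.maximum(amps[:, band], background)
        noisy = Spectrogram(
            frame_times=young_crop.frame_times,
            velocities=young_crop.velocities,
            power=amps**2,
            window_len=young_crop.window_len,
            hop=young_crop.hop,
            fs=young_crop.fs,
            config=young_crop.config,
        )
        env = gd.extract_envelopes(noisy, rho=rho)
        assert np.array_equal(env.v_u, ref.v_u)
        assert np.array_equal(env.v_l, ref.v_l)

    def test_peakless_frame_carries_previous_envelope_forward(self):
        rows = [[0, 1.0, 0.1, 0, 0], [0, 0, 0, 0, 0], [0, 0, 0.1, 1.0, 0]]
        spec = toy_spectrogram(rows, [-2.0, -1.0, 0.0, 1.0, 2.0])
        env = gd.extract_envelopes(spec)
        assert env.v_u[1] == env.v_u[0] == -1.0
        assert env.v_l[1] == env.v_l[0] == -1.0
        assert env.v_u[2] == 1.0

    def test_peakless_first_frame_rejected(self):
        rows = [[0, 0, 0, 0, 0], [0, 1.0, 0, 0, 0]]
        spec = toy_spectrogram(rows, [-2.0, -1.0, 0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="first frame"):
            gd.extract_envelopes(spec)


class TestConditionInput:
    def test_condition_three_is_lower_envelope(self, young_envelopes):
        x = gd.build_condition_input(young_envelopes, 3)
        assert x.shape == (1, young_envelopes.n_frames)
        assert np.array_equal(x[0], young_envelopes.v_l)

    def test_condition_seven_stacks_all_three_in_order(self, young_envelopes):
        x = gd.build_condition_input(young_envelopes, 7)
        assert np.array_equal(x[0], young_envelopes.v_u)
        assert np.array_equal(x[1], young_envelopes.v_m)
        assert np.array_equal(x[2], young_envelopes.v_l)

    @pytest.mark.parametrize("condition", [0, 8, -1, "three", None])
    def test_invalid_condition_rejected(self, young_envelopes, condition):
        with pytest.raises(ValueError, match="1..7"):
            gd.build_condition_input(young_envelopes, condition)

    def test_channel_counts_match_condition_table(self, young_envelopes):
        sizes = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2, 7: 3}
        for cond, n in sizes.items():
            assert gd.build_condition_input(young_envelopes, cond).shape[0] == n


class TestEnvelopeIO:
    def test_roundtrip(self, tmp_path, young_envelopes):
        path = tmp_path / "env.csv"
        gd.write_envelopes(young_envelopes, path)
        back = gd.read_envelopes(path)
        assert back.rho == young_envelopes.rho
        assert np.allclose(back.v_u, young_envelopes.v_u)
        assert np.allclose(back.v_m, young_envelopes.v_m)
        assert np.allclose(back.v_l, young_envelopes.v_l)

    def test_inverted_envelopes_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            gd.EnvelopeSet(
                frame_times=np.array([0.0]),
                v_u=np.array([0.5]),
                v_m=np.array([1.0]),
                v_l=np.array([1.5]),
            )
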