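"""Shared fixtures: small simulated walkers and their downstream products."""

import numpy as np
import pytest

import gaitdoppler as gd
from gaitdoppler.synthetic_gait import ROLES, ScattererTrajectorySet


def constant_velocity_trajectory(v=1.0, eta=1.0, duration=2.0, fs=600.0,
                                 start_range=9.0, n_scatterers=1):
    """A hand-built trajectory of scatterers moving at constant radial velocity."""
    times = np.arange(int(round(duration * fs))) / fs
    v = np.atleast_1d(np.asarray(v, dtype=float))
    eta = np.broadcast_to(np.atleast_1d(eta), v.shape).astype(float)
    velocities = np.tile(v[:, None], (1, times.size))
    ranges = start_range - v[:, None] * times[None, :]
    return ScattererTrajectorySet(
        times=times,
        ranges=ranges,
        radial_velocities=velocities,
        reflectivities=eta,
        roles=ROLES[: len(v)],
        fs=fs,
        true_params=None,
        provenance="constant-velocity fixture",
    )


@pytest.fixture(scope="session")
def radar():
    return gd.RadarConfig()


@pytest.fixture(scope="session")
def young_walker():
    """One simulated young walker: (params, trajectory, signal)."""
    params = gd.sample_class_params("young", 11)
    traj = gd.simulate_walker(params, n_cycles=4, rng_seed=11)
    signal = gd.synthesize_baseband(traj, gd.RadarConfig(), noise_sd=0.03, rng_seed=11)
    return params, traj, signal


@pytest.fixture(scope="session")
def young_spectrogram(young_walker, radar):
    _, _, signal = young_walker
    return gd.compute_spectrogram(signal, config=radar)


@pytest.fixture(scope="session")
def young_crop(young_spectrogram):
    return gd.select_analysis_interval(young_spectrogram)


@pytest.fixture(scope="session")
def young_envelopes(young_crop):
    return gd.extract_envelopes(young_crop)
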