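"""Continuous-wave Doppler radar baseband signal model.

A monostatic continuous-wave radar transmits a pure sinusoid at carrier
frequency ``f0`` (24 GHz by default).  The echo from a point scatterer at
radial distance :math:`R_i(t)` returns with a two-way propagation phase, and
after coherent demodulation the complex baseband signal is a sum over the
``N`` scatterers making up the target:

.. math::

    s_R(t) = \\sum_{i=1}^{N} \\eta_i A \\, e^{j\\phi_i(t)}, \\qquad
    \\phi_i(t) = -\\frac{4\\pi R_i(t)}{\\lambda},

where :math:`\\eta_i \\le 1` is the reflectivity of scatterer *i*, ``A`` the
transmit amplitude and :math:`\\lambda = c/f_0` the carrier wavelength.  A
scatterer approaching the radar at radial velocity ``v`` produces a positive
Doppler shift :math:`f_d = 2v/\\lambda`.

The phase is evaluated from the full time-varying range track, which reduces
to the familiar constant-velocity form :math:`\\phi_i = -4\\pi(R_i - v t)/
\\lambda` when the scatterer moves uniformly, but also supports the strongly
non-uniform limb motion of a walking person.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RadarConfig:
    """Parameters of the continuous-wave radar front end.

    Attributes
    ----------
    f0 : float
        Carrier frequency in Hz (default 24 GHz).
    fs : float
        Sampling frequency of the demodulated baseband signal in Hz.
    amplitude : float
        Transmit amplitude ``A`` (unitless; echoes are scaled by ``eta * A``).
    phi0 : float
        Initial carrier phase in radians.
    """

    f0: float = 24.0e9
    fs: float = 600.0
    amplitude: float = 1.0
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError(f"carrier frequency must be positive, got {self.f0}")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c / f0 in metres."""
        return SPEED_OF_LIGHT / self.f0

    @property
    def nyquist_velocity(self) -> float:
        """Largest unambiguous radial velocity (fs/2) * lambda/2 in m/s."""
        return (self.fs / 2.0) * self.wavelength / 2.0


@dataclass
class BasebandSignal:
    """Complex demodulated radar echo.

    ``samples`` is the complex baseband time series sampled at ``fs``;
    ``provenance`` records where it came from (a trajectory/seed reference
    for simulated data, or ``"measured"``).
    """

    samples: np.ndarray
    fs: float
    provenance: str = "measured"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D complex array")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs


def doppler_frequency(v: float | np.ndarray, config: RadarConfig | None = None):
    """Doppler shift f_d = 2 v / lambda for radial velocity ``v`` (m/s).

    Positive for motion toward the radar.  Antisymmetric in ``v``.
    """
    config = config or RadarConfig()
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("radial velocity must be finite")
    out = 2.0 * v / config.wavelength
    return float(out) if out.ndim == 0 else out


def velocity_from_doppler(fd: float | np.ndarray, config: RadarConfig | None = None):
    """Inverse of :func:`doppler_frequency`: v = f_d * lambda / 2."""
    config = config or RadarConfig()
    fd = np.asarray(fd, dtype=float)
    out = fd * config.wavelength / 2.0
    return float(out) if out.ndim == 0 else out


def synthesize_baseband(
    traj,
    config: RadarConfig | None = None,
    noise_sd: float = 0.0,
    rng_seed: int | None = None,
) -> BasebandSignal:
    """Synthesize the demodulated echo of a multi-scatterer trajectory.

    Each scatterer contributes ``eta_i * A * exp(-j 4 pi R_i(t) / lambda)``;
    contributions add coherently.  Circular complex white Gaussian noise with
    per-component standard deviation ``noise_sd`` is added on top.

    Parameters
    ----------
    traj : ScattererTrajectorySet
        Scatterer range tracks sampled at ``config.fs`` (see
        :mod:`gaitdoppler.synthetic_gait`).
    config : RadarConfig, optional
    noise_sd : float
        Standard deviation of the real and imaginary noise components.
    rng_seed : int, optional
        Seed for the noise generator.

    Notes
    -----
    Range attenuation is deliberately omitted: reflectivities ``eta_i`` are
    fixed per-scatterer amplitude ratios.  If the trajectory implies a Doppler
    shift beyond fs/2 a warning is emitted (the simulator upstream refuses to
    generate aliased ground truth; measured or hand-built trajectories only
    get the warning).
    """
    config = config or RadarConfig()
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if not np.isclose(traj.fs, config.fs, rtol=1e-9):
        raise ValueError(
            f"trajectory sampled at {traj.fs} Hz but radar config expects {config.fs} Hz"
        )
    ranges = np.asarray(traj.ranges, dtype=float)
    if np.any(ranges <= 0):
        raise ValueError("all scatterer ranges must stay positive")

    max_fd = float(np.max(np.abs(2.0 * np.asarray(traj.radial_velocities) / config.wavelength)))
    if max_fd > config.fs / 2.0:
        warnings.warn(
            f"max Doppler shift {max_fd:.1f} Hz exceeds fs/2 = {config.fs / 2:.1f} Hz; "
            "the synthesized signal is aliased",
            stacklevel=2,
        )

    eta = np.asarray(traj.reflectivities, dtype=float)[:, None]
    phase = config.phi0 - 4.0 * np.pi * ranges / config.wavelength
    samples = np.sum(eta * config.amplitude * np.exp(1j * phase), axis=0)

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        noise = noise_sd * (
            rng.standard_normal(samples.size) + 1j * rng.standard_normal(samples.size)
        )
        samples = samples + noise
        logger.debug("synthesized %d samples at SNR %.1f dB",
                     samples.size, snr_db(traj, config, noise_sd))

    provenance = getattr(traj, "provenance", None) or (
        f"synthetic(seed={rng_seed})" if rng_seed is not None else "synthetic"
    )
    return BasebandSignal(samples=samples, fs=config.fs, provenance=provenance)


def snr_db(traj, config: RadarConfig | None = None, noise_sd: float = 0.0) -> float:
    """Nominal SNR of a synthesis: sum((eta A)^2) / (2 noise_sd^2), in dB."""
    config = config or RadarConfig()
    if noise_sd == 0:
        return float("inf")
    signal_power = float(np.sum((np.asarray(traj.reflectivities) * config.amplitude) ** 2))
    return 10.0 * np.log10(signal_power / (2.0 * noise_sd**2))


def write_baseband(signal: BasebandSignal, path) -> None:
    """Write a baseband signal as columnar text ``t,I,Q`` with a metadata header."""
    t = np.arange(signal.n) / signal.fs
    header = f"fs={signal.fs!r}\nprovenance={signal.provenance}\ncolumns=t,I,Q"
    data = np.column_stack([t, signal.samples.real, signal.samples.imag])
    np.savetxt(path, data, header=header, delimiter=",", fmt="%.12g")


def read_baseband(path) -> BasebandSignal:
    """Read a baseband signal written by :func:`write_baseband`."""
    fs = None
    provenance = "measured"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").strip().partition("=")
            if key == "fs":
                fs = float(value)
            elif key == "provenance":
                provenance = value
    if fs is None:
        raise ValueError(f"{path}: missing 'fs' in header")
    data = np.loadtxt(path, delimiter=",")
    data = np.atleast_2d(data)
    return BasebandSignal(samples=data[:, 1] + 1j * data[:, 2], fs=fs, provenance=provenance)
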