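"""Time-velocity spectrogram of the baseband echo.

The short-time Fourier transform of the complex baseband signal,

.. math::

    S_R(t, v_d) = \\int s_R(t + \\tau) W(\\tau)\\, d\\tau,

with a symmetric Hamming window ``W`` of 128 samples, gives a complex
time-frequency map whose frequency axis is relabelled as radial velocity via
the Doppler relation :math:`v = f \\lambda / 2` (motion toward the radar is a
positive velocity).  The squared magnitude ``|S_R|^2`` is the power
spectrogram a walking person paints with a bright torso band and periodic
leg flashes.

Frames are center-aligned and fully interior (no edge padding), the forward
DFT is unnormalized, and velocity bins span ``(-fs/2, fs/2] * lambda/2`` with
exactly ``window_len`` bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .radar_model import BasebandSignal, RadarConfig


class PeriodicityError(ValueError):
    """Raised when no significant gait periodicity can be found."""


@dataclass
class Spectrogram:
    """Power time-velocity map of one recording.

    ``power`` has shape (n_frames, n_bins) with ``frame_times`` the window
    centers (s) and ``velocities`` the zero-centered, strictly increasing
    velocity grid (m/s).
    """

    frame_times: np.ndarray
    velocities: np.ndarray
    power: np.ndarray
    window_len: int
    hop: int
    fs: float
    config: RadarConfig

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.frame_times), len(self.velocities)):
            raise ValueError("power must be (n_frames, n_bins)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    @property
    def frame_dt(self) -> float:
        return self.hop / self.fs

    @property
    def velocity_bin(self) -> float:
        """Velocity resolution (fs / window_len) * lambda / 2 in m/s."""
        return (self.fs / self.window_len) * self.config.wavelength / 2.0

    @property
    def amplitude(self) -> np.ndarray:
        """|S_R(t, v)|, the quantity the peak threshold is applied to."""
        return np.sqrt(self.power)

    def total_power(self) -> np.ndarray:
        """Per-frame total power (the series used for period estimation)."""
        return self.power.sum(axis=1)


def _velocity_axis(window_len: int, fs: float, config: RadarConfig):
    """DFT bin order and velocity labels spanning (-fs/2, fs/2] * lambda/2."""
    freqs = np.fft.fftfreq(window_len, d=1.0 / fs)
    if window_len % 2 == 0:
        freqs[window_len // 2] = fs / 2.0  # put the ambiguous Nyquist bin on top
    order = np.argsort(freqs)
    return order, freqs[order] * config.wavelength / 2.0


def compute_spectrogram(
    signal: BasebandSignal,
    window_len: int = 128,
    hop: int = 8,
    config: RadarConfig | None = None,
) -> Spectrogram:
    """Compute the power time-velocity spectrogram of a baseband recording.

    Per frame: unnormalized DFT of the Hamming-windowed segment, frequency
    axis rotated so zero is central and relabelled as velocity.  Frames start
    every ``hop`` samples and must lie fully inside the signal.

    The hop default of 8 samples (75 frames/s at fs=600) makes a two-cycle
    steady-state gait interval come out at roughly 150 frames.
    """
    config = config or RadarConfig(fs=signal.fs)
    if signal.n < window_len:
        raise ValueError(
            f"signal has {signal.n} samples but the window needs at least {window_len}"
        )
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")

    window = np.hamming(window_len)  # symmetric: 0.54 - 0.46 cos(2 pi n / (L-1))
    starts = np.arange(0, signal.n - window_len + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(signal.samples, window_len)[starts]
    spectra = np.fft.fft(frames * window, axis=1)
    order, velocities = _velocity_axis(window_len, signal.fs, config)
    power = np.abs(spectra[:, order]) ** 2
    frame_times = (starts + (window_len - 1) / 2.0) / signal.fs
    return Spectrogram(
        frame_times=frame_times,
        velocities=velocities,
        power=power,
        window_len=window_len,
        hop=hop,
        fs=signal.fs,
        config=config,
    )


def estimate_gait_period(
    spec: Spectrogram,
    min_step: float = 0.3,
    max_lag: float = 1.8,
    min_corr: float = 0.5,
    rel_height: float = 0.8,
) -> float:
    """Estimate the gait-cycle duration from the spectrogram's periodicity.

    The per-bin mean-removed power frames are autocorrelated along time and
    summed over velocity bins, giving a normalized similarity between the
    time-velocity pattern and itself shifted by each lag.  Walking produces
    near-unity peaks at every multiple of the *step* period (the two legs
    paint nearly identical half-cycle patterns), so the estimator locates
    the smallest significant peak lag — the step period — within
    [min_step, max_lag] seconds and returns twice that lag as the gait-cycle
    duration (a cycle is two steps).  A peak counts as significant when its
    correlation reaches ``min_corr`` and ``rel_height`` times the highest
    peak; genuine gait gives near-unity peaks while smoothed noise (frames
    share samples through the overlapping windows) stays below ~0.35, so the
    0.5 default separates the two regimes.  Raises
    :class:`PeriodicityError` when no significant peak exists.
    """
    P = spec.power
    X = P - P.mean(axis=0, keepdims=True)
    n = X.shape[0]
    total_var = float(np.sum(X * X)) / n
    if total_var == 0:
        raise PeriodicityError("spectrogram is constant over time; no gait periodicity")

    lo = max(1, int(np.floor(min_step / spec.frame_dt)))
    hi = min(n - 2, int(np.ceil(max_lag / spec.frame_dt)))
    if hi <= lo:
        raise PeriodicityError(
            "recording too short to contain a gait cycle; provide a longer signal "
            "or select the interval manually"
        )
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(X, n=nfft, axis=0)
    ac = np.fft.irfft((F * np.conj(F)).sum(axis=1), n=nfft)[:n]
    lags = np.arange(n)
    r = ac / (n - lags) / total_var  # unbiased, normalized

    seg = r[lo : hi + 1]
    peaks = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
    idx = np.flatnonzero(peaks) + 1
    idx = idx[seg[idx] >= min_corr]
    if idx.size == 0:
        raise PeriodicityError(
            "no significant periodicity found in the spectrogram; "
            "select the analysis interval manually"
        )
    significant = idx[seg[idx] >= rel_height * np.max(seg[idx])]
    step_lag = int(significant[0]) + lo
    return float(2 * step_lag * spec.frame_dt)


def select_analysis_interval(spec: Spectrogram, n_cycles: int = 2) -> Spectrogram:
    """Crop the spectrogram to ``n_cycles`` steady-state gait cycles.

    The cycle duration is estimated with :func:`estimate_gait_period`; the
    crop of ``round(n_cycles * period / frame_dt)`` frames is centered in the
    recording, emulating a steady-state analysis interval away from gait
    initiation and termination.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    period = estimate_gait_period(spec)
    n_keep = int(round(n_cycles * period / spec.frame_dt))
    if n_keep > spec.n_frames:
        raise PeriodicityError(
            f"recording holds only {spec.n_frames} frames but {n_keep} are needed "
            f"for {n_cycles} cycles of {period:.2f} s"
        )
    start = (spec.n_frames - n_keep) // 2
    return replace(
        spec,
        frame_times=spec.frame_times[start : start + n_keep],
        power=spec.power[start : start + n_keep],
    )


def write_spectrogram(spec: Spectrogram, path) -> None:
    """Write a spectrogram as a plain-text matrix with coordinate header rows."""
    header = (
        f"window_len={spec.window_len}\nhop={spec.hop}\nfs={spec.fs!r}\n"
        f"f0={spec.config.f0!r}\n"
        "rows: frame_times then velocities then power (one frame per line)"
    )
    blocks = [spec.frame_times, spec.velocities]
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        for block in blocks:
            fh.write(",".join(f"{v:.12g}" for v in block) + "\n")
        np.savetxt(fh, spec.power, delimiter=",", fmt="%.12g")


def read_spectrogram(path) -> Spectrogram:
    """Read a spectrogram written by :func:`write_spectrogram`."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, value = line.lstrip("# ").partition("=")
                if sep:
                    meta[key.strip()] = value.strip()
                continue
            rows.append(np.array(line.split(","), dtype=float))
    frame_times, velocities = rows[0], rows[1]
    power = np.vstack(rows[2:])
    fs = float(meta["fs"])
    return Spectrogram(
        frame_times=frame_times,
        velocities=velocities,
        power=power,
        window_len=int(meta["window_len"]),
        hop=int(meta["hop"]),
        fs=fs,
        config=RadarConfig(f0=float(meta.get("f0", 24.0e9)), fs=fs),
    )
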