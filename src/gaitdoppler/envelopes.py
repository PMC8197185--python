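"""Velocity envelope extraction from the time-velocity spectrogram.

Three velocity time series summarize the gait spectrogram frame by frame:

* the **mean envelope** ``v_m(t)``, the power-weighted mean velocity

  .. math:: v_m(t) = \\frac{\\int v_d |S_R(t, v_d)|^2 dv_d}
                          {\\int |S_R(t, v_d)|^2 dv_d},

  which tracks the torso (the dominant scatterer);

* the **upper envelope** ``v_u(t)``, the largest *significant-peak* velocity,
  tracking the swinging leg; and

* the **lower envelope** ``v_l(t)``, the smallest significant-peak velocity,
  tracking the leg planted on the ground during the stance phase.

A significant peak at frame ``t`` is a local maximum of the amplitude
``|S_R(t, v_d)|`` over velocity whose amplitude exceeds a fraction ``rho`` of
the frame's maximum amplitude (``rho = 0.2`` by default).  The relative
threshold is what makes the envelopes robust to background noise: any
component whose amplitude stays below ``rho`` times the frame maximum cannot
create or move a peak, so ``v_u`` and ``v_l`` are unchanged by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectrogram import Spectrogram

logger = logging.getLogger(__name__)

#: Channel combinations fed to the sequence classifier, keyed by condition
#: number.  Channel order is fixed as listed.
CONDITION_CHANNELS = {
    1: ("v_u",),
    2: ("v_m",),
    3: ("v_l",),
    4: ("v_u", "v_m"),
    5: ("v_u", "v_l"),
    6: ("v_m", "v_l"),
    7: ("v_u", "v_m", "v_l"),
}


@dataclass
class EnvelopeSet:
    """The three velocity envelopes of one recording.

    ``v_u`` and ``v_l`` lie on the spectrogram velocity grid; ``v_m`` is a
    power-weighted mean and may fall between grid points.  Frames whose total
    power is zero have ``v_m = nan``.
    """

    frame_times: np.ndarray
    v_u: np.ndarray
    v_m: np.ndarray
    v_l: np.ndarray
    rho: float = 0.2
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.frame_times)
        for name in ("v_u", "v_m", "v_l"):
            series = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, series)
            if series.shape != (n,):
                raise ValueError(f"{name} must have the same length as frame_times")
        if np.any(self.v_l > self.v_u):
            raise ValueError("lower envelope exceeds upper envelope")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def channels(self, names) -> np.ndarray:
        """Stack the named envelope series into a (n_channels, n_frames) array."""
        return np.vstack([getattr(self, name) for name in names])


def mean_envelope(spec: Spectrogram) -> np.ndarray:
    """Power-weighted mean velocity per frame, over the full velocity axis.

    Frames with zero total power are flagged undefined (nan).  Raises if the
    whole spectrogram is zero.
    """
    totals = spec.power.sum(axis=1)
    if not np.any(totals > 0):
        raise ValueError("all-zero spectrogram: mean envelope undefined")
    with np.errstate(invalid="ignore"):
        v_m = (spec.power @ spec.velocities) / totals
    v_m[totals == 0] = np.nan
    return v_m


def significant_peaks(frame_amplitudes, velocities, rho: float = 0.2):
    """Significant spectral peaks of one frame, in ascending velocity order.

    A peak is a bin strictly greater than both neighbours; for a plateau (a
    maximal run of equal values) the leftmost bin of the run counts once,
    provided the run exceeds both run-neighbours.  Array endpoints are
    ineligible.  Peaks must exceed ``rho`` times the frame's maximum
    amplitude.  Returns ``(peak_velocities, peak_amplitudes)``.
    """
    if not 0 < rho < 1:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    amps = np.asarray(frame_amplitudes, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if amps.shape != velocities.shape:
        raise ValueError("amplitudes and velocity grid must have the same length")
    if np.any(amps < 0):
        raise ValueError("amplitudes must be non-negative")
    frame_max = amps.max()
    if frame_max == 0:
        return np.empty(0), np.empty(0)

    # compress equal-valued runs, then compare each run to its neighbours
    change = np.flatnonzero(np.diff(amps)) + 1
    starts = np.concatenate(([0], change))
    values = amps[starts]
    interior = (
        (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
        if values.size >= 3
        else np.empty(0, dtype=bool)
    )
    # starts[1:-1] skips the first and last run: endpoint plateaus are ineligible
    peak_idx = starts[1:-1][interior]
    keep = amps[peak_idx] > rho * frame_max
    peak_idx = peak_idx[keep]
    return velocities[peak_idx], amps[peak_idx]


def extract_envelopes(spec: Spectrogram, rho: float = 0.2) -> EnvelopeSet:
    """Extract the three velocity envelopes from a power spectrogram.

    ``v_u``/``v_l`` are the max/min significant-peak velocities per frame
    (threshold ``rho`` on amplitude ``|S_R|``); ``v_m`` is the power-weighted
    mean.  Frames with no significant peak carry the previous frame's
    ``v_u``/``v_l`` forward (logged); an empty first frame is an error.
    """
    v_m = mean_envelope(spec)
    amplitude = spec.amplitude
    n = spec.n_frames
    v_u = np.empty(n)
    v_l = np.empty(n)
    n_carried = 0
    for i in range(n):
        peak_v, _ = significant_peaks(amplitude[i], spec.velocities, rho)
        if peak_v.size:
            v_u[i] = peak_v[-1]
            v_l[i] = peak_v[0]
        elif i == 0:
            raise ValueError(
                "no significant peaks in the first frame; cannot seed the envelopes"
            )
        else:
            v_u[i] = v_u[i - 1]
            v_l[i] = v_l[i - 1]
            n_carried += 1
    if n_carried:
        logger.info("carried envelopes forward over %d peak-free frames", n_carried)
    return EnvelopeSet(
        frame_times=np.asarray(spec.frame_times, dtype=float).copy(),
        v_u=v_u,
        v_m=v_m,
        v_l=v_l,
        rho=rho,
        source=f"spectrogram(window={spec.window_len},hop={spec.hop})",
    )


def build_condition_input(env: EnvelopeSet, condition: int) -> np.ndarray:
    """Assemble the classifier input channels for one input condition.

    Conditions 1-7 select, in fixed order: {v_u}, {v_m}, {v_l}, {v_u, v_m},
    {v_u, v_l}, {v_m, v_l}, {v_u, v_m, v_l}.  Returns a
    (n_channels, n_frames) array.
    """
    try:
        names = CONDITION_CHANNELS[condition]
    except (KeyError, TypeError):
        raise ValueError(
            f"condition must be an integer in 1..7, got {condition!r}"
        ) from None
    return env.channels(names)


def write_envelopes(env: EnvelopeSet, path) -> None:
    """Write envelopes as columnar text ``frame_time,v_u,v_m,v_l``."""
    header = f"rho={env.rho!r}\nsource={env.source}\ncolumns=frame_time,v_u,v_m,v_l"
    data = np.column_stack([env.frame_times, env.v_u, env.v_m, env.v_l])
    np.savetxt(path, data, header=header, delimiter=",", fmt="%.12g")


def read_envelopes(path) -> EnvelopeSet:
    """Read an envelope file written by :func:`write_envelopes`."""
    rho = 0.2
    source = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").strip().partition("=")
            if key == "rho":
                rho = float(value)
            elif key == "source":
                source = value
    data = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return EnvelopeSet(
        frame_times=data[:, 0], v_u=data[:, 1], v_m=data[:, 2], v_l=data[:, 3],
        rho=rho, source=source,
    )
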