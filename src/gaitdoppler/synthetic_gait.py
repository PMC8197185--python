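"""Parametric multi-scatterer kinematics of a walking human.

The body is reduced to five point scatterers — torso, two feet, two tibiae —
walking toward the radar along a straight line.  The torso translates at a
mean speed with a small sinusoidal fluctuation at two oscillations per gait
cycle (one per step).  Each foot alternates between a stance phase, in which
its radial velocity stays within a small residual band around zero, and a
swing phase, in which it accelerates through a raised-cosine-flanked velocity
pulse that plateaus at the swing peak velocity.  Tibiae move midway between
the torso and the foot on their side.  The two legs are half a cycle out of
phase.

Young and elderly gait classes are emulated purely through the parameter
distributions (class-conditional torso speed, swing peak, cycle duration and
stance-phase residual fluctuation): the kinematic model itself is shared, so
any downstream class separability is controlled by the configuration alone.

This simulator is a synthetic stand-in for measured walking data; it aims at
the spectrogram morphology of real micro-Doppler gait recordings (a strong
torso band with periodic leg flashes), not at biomechanical fidelity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .radar_model import BasebandSignal, RadarConfig, synthesize_baseband

LABELS = ("young", "elderly")
ROLES = ("torso", "left_foot", "right_foot", "left_tibia", "right_tibia")

#: Default study configuration.  Class parameter values are configuration
#: choices of this package (the velocity contrast between healthy young and
#: elderly walkers is directionally supported by the gait-slowing literature,
#: but the magnitudes here are not measured effect sizes) and every achievable
#: velocity stays below the 1.874 m/s Nyquist velocity of a 600 Hz / 24 GHz
#: radar.  Override any entry via a YAML config file.
DEFAULT_CONFIG: dict = {
    "radar": {"f0": 24.0e9, "fs": 600.0},
    "simulation": {
        "n_cycles": 4,
        "start_range": 9.0,
        "noise_sd": 0.03,
        "stance_fraction": 0.45,
        "swing_plateau": 0.65,
        "truncate_sd": 2.0,
        "swing_speed_coupling": 1.0,
    },
    "gait": {
        "young": {
            "torso_speed_mean": 1.3,
            "torso_speed_sd": 0.08,
            "torso_fluct_amp": 0.15,
            "cycle_duration_mean": 1.05,
            "cycle_duration_sd": 0.05,
            "swing_peak_velocity_mean": 1.7,
            "swing_peak_velocity_sd": 0.03,
            "stance_residual_velocity": 0.06,
            "limb_reflectivities": {
                "torso": 1.0,
                "left_foot": 0.24,
                "right_foot": 0.24,
                "left_tibia": 0.06,
                "right_tibia": 0.06,
            },
        },
        "elderly": {
            "torso_speed_mean": 1.0,
            "torso_speed_sd": 0.15,
            "torso_fluct_amp": 0.19,
            "cycle_duration_mean": 1.15,
            "cycle_duration_sd": 0.08,
            "swing_peak_velocity_mean": 1.4,
            "swing_peak_velocity_sd": 0.03,
            "stance_residual_velocity": 0.12,
            "limb_reflectivities": {
                "torso": 1.0,
                "left_foot": 0.24,
                "right_foot": 0.24,
                "left_tibia": 0.06,
                "right_tibia": 0.06,
            },
        },
    },
}


def default_config() -> dict:
    """A deep copy of the default study configuration."""
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    """Load a YAML config file, merged over the defaults.

    Only the keys present in the file are overridden; everything else keeps
    its default.  The file mirrors the structure of ``DEFAULT_CONFIG`` with a
    ``gait: {young: ..., elderly: ...}`` section per class.
    """
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}

    def merge(base, override):
        for key, value in override.items():
            if isinstance(value, dict) and isinstance(base.get(key), dict):
                merge(base[key], value)
            else:
                base[key] = value

    cfg = default_config()
    merge(cfg, user)
    return cfg


@dataclass(frozen=True)
class GaitClassParams:
    """Gait parameters of a class (distribution) or of one participant (draw).

    As a class configuration the ``*_mean``/``*_sd`` pairs describe the
    population distribution; :func:`sample_class_params` returns a
    participant draw of the same type with the drawn values in the ``*_mean``
    slots and the ``*_sd`` slots zeroed.
    """

    label: str
    torso_speed_mean: float
    torso_speed_sd: float
    torso_fluct_amp: float
    cycle_duration_mean: float
    cycle_duration_sd: float
    swing_peak_velocity_mean: float
    swing_peak_velocity_sd: float
    stance_residual_velocity: float
    limb_reflectivities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"unknown gait class {self.label!r}; admissible labels: {LABELS}"
            )
        for name in ("torso_speed_mean", "cycle_duration_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "torso_speed_sd",
            "torso_fluct_amp",
            "cycle_duration_sd",
            "swing_peak_velocity_mean",
            "swing_peak_velocity_sd",
            "stance_residual_velocity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if 0 < self.swing_peak_velocity_mean <= self.torso_speed_mean:
            raise ValueError(
                "swing_peak_velocity_mean must exceed torso_speed_mean "
                "(the swing leg overtakes the torso)"
            )
        for role, eta in self.limb_reflectivities.items():
            if not 0 < eta <= 1:
                raise ValueError(f"reflectivity of {role} must be in (0, 1], got {eta}")

    def max_achievable_velocity(self) -> float:
        """Largest radial velocity any scatterer can reach under these parameters."""
        torso_max = self.torso_speed_mean + self.torso_speed_sd * 5 + self.torso_fluct_amp
        return max(torso_max, self.swing_peak_velocity_mean, self.stance_residual_velocity)

    @classmethod
    def from_config(cls, label: str, config: dict | None = None) -> "GaitClassParams":
        config = config or DEFAULT_CONFIG
        try:
            entry = config["gait"][label]
        except KeyError:
            raise ValueError(
                f"unknown gait class {label!r}; admissible labels: "
                f"{tuple(config.get('gait', DEFAULT_CONFIG['gait']))}"
            ) from None
        return cls(label=label, **entry)


@dataclass
class ScattererTrajectorySet:
    """Radial kinematics of the five scatterers of one simulated walker.

    ``ranges`` and ``radial_velocities`` are (n_scatterers, n_samples) arrays;
    radial velocity is positive toward the radar, so it equals the negative
    time derivative of range.
    """

    times: np.ndarray
    ranges: np.ndarray
    radial_velocities: np.ndarray
    reflectivities: np.ndarray
    roles: tuple
    fs: float
    true_params: GaitClassParams
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.ranges = np.atleast_2d(np.asarray(self.ranges, dtype=float))
        self.radial_velocities = np.atleast_2d(np.asarray(self.radial_velocities, dtype=float))
        self.reflectivities = np.asarray(self.reflectivities, dtype=float)
        if self.ranges.shape != self.radial_velocities.shape:
            raise ValueError("ranges and radial_velocities must have the same shape")
        if np.any(self.ranges <= 0):
            raise ValueError("ranges must stay strictly positive over the walk")
        if np.any(self.reflectivities <= 0) or np.any(self.reflectivities > 1):
            raise ValueError("reflectivities must lie in (0, 1]")

    @property
    def n_scatterers(self) -> int:
        return self.ranges.shape[0]


class AliasingError(ValueError):
    """Raised when gait parameters imply a Doppler shift beyond fs/2."""


def sample_class_params(
    label: str, rng_seed: int, config: dict | None = None
) -> GaitClassParams:
    """Draw one participant's gait parameters from a class distribution.

    Torso speed and cycle duration come from truncated normals
    (+/- ``truncate_sd`` standard deviations, symmetric so the class mean is
    preserved and every draw stays strictly positive).  The swing peak
    velocity scales with the participant's own torso-speed draw (faster
    walkers swing faster) with a small independent jitter of the configured
    ``swing_peak_velocity_sd``, and is capped just below the radar's Nyquist
    velocity so no draw can request aliased ground truth.  Deterministic in
    ``rng_seed``.
    """
    config = config or DEFAULT_CONFIG
    cls = GaitClassParams.from_config(label, config)
    sim_cfg = config["simulation"]
    k = float(sim_cfg.get("truncate_sd", 2.0))
    coupling = float(sim_cfg.get("swing_speed_coupling", 1.0))
    rng = np.random.default_rng(rng_seed)

    def trunc_normal(mean, sd):
        if sd == 0:
            return mean
        while True:
            x = rng.normal(mean, sd)
            if abs(x - mean) <= k * sd:
                return float(x)

    torso = trunc_normal(cls.torso_speed_mean, cls.torso_speed_sd)
    speed_factor = 1.0 + coupling * (torso / cls.torso_speed_mean - 1.0)
    swing = trunc_normal(
        cls.swing_peak_velocity_mean * speed_factor, cls.swing_peak_velocity_sd
    )
    radar = RadarConfig(f0=config["radar"]["f0"], fs=config["radar"]["fs"])
    swing = min(swing, 0.98 * radar.nyquist_velocity)

    return GaitClassParams(
        label=label,
        torso_speed_mean=torso,
        torso_speed_sd=0.0,
        torso_fluct_amp=cls.torso_fluct_amp,
        cycle_duration_mean=trunc_normal(cls.cycle_duration_mean, cls.cycle_duration_sd),
        cycle_duration_sd=0.0,
        swing_peak_velocity_mean=swing,
        swing_peak_velocity_sd=0.0,
        stance_residual_velocity=cls.stance_residual_velocity,
        limb_reflectivities=dict(cls.limb_reflectivities),
    )


def _swing_pulse(w: np.ndarray, plateau: float) -> np.ndarray:
    """Unit-peak velocity pulse over normalized swing time w in [0, 1).

    Raised-cosine flanks with a flat top of fractional width ``plateau``;
    zero at both ends, so foot velocity is continuous across phase changes.
    """
    a = (1.0 - plateau) / 2.0
    out = np.ones_like(w)
    rising = w < a
    falling = w > 1.0 - a
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * w[rising] / a))
    out[falling] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - w[falling]) / a))
    return out


def _foot_velocity(
    u: np.ndarray, params: GaitClassParams, stance_fraction: float, plateau: float
) -> np.ndarray:
    """Radial velocity of a foot as a function of cycle phase u in [0, 1)."""
    v = np.empty_like(u)
    stance = u < stance_fraction
    # stance: a slow half-sine bump bounded by the residual velocity (slow so
    # the planted foot stays a spectrally concentrated, detectable tone)
    v[stance] = params.stance_residual_velocity * np.sin(
        np.pi * u[stance] / stance_fraction
    )
    w = (u[~stance] - stance_fraction) / (1.0 - stance_fraction)
    v[~stance] = params.swing_peak_velocity_mean * _swing_pulse(w, plateau)
    return v


def simulate_walker(
    params: GaitClassParams,
    n_cycles: int = 4,
    fs: float = 600.0,
    start_range: float = 9.0,
    rng_seed: int | None = None,
    config: dict | None = None,
    wavelength: float | None = None,
) -> ScattererTrajectorySet:
    """Generate the five scatterer tracks of one walker approaching the radar.

    Parameters
    ----------
    params : GaitClassParams
        A participant draw (the ``*_mean`` fields are used as the walker's
        actual values).
    n_cycles : int
        Number of gait cycles to simulate (>= 2).
    fs : float
        Sampling rate of the kinematic grid, matching the radar.
    start_range : float
        Initial torso range in metres; must keep every range positive.
    rng_seed : int, optional
        Seeds the initial gait phase and small per-scatterer range offsets.
    config : dict, optional
        Supplies ``stance_fraction`` and ``swing_plateau`` (defaults 0.6, 0.3).
    wavelength : float, optional
        Carrier wavelength used for the no-aliasing guard (default 24 GHz).

    Raises
    ------
    AliasingError
        If the parameters imply a radial velocity at or above the Nyquist
        velocity (fs/2) * lambda / 2: the simulator refuses to generate
        aliased ground truth.
    """
    if n_cycles < 2:
        raise ValueError(f"n_cycles must be >= 2, got {n_cycles}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    sim_cfg = (config or DEFAULT_CONFIG)["simulation"]
    stance_fraction = float(sim_cfg.get("stance_fraction", 0.6))
    plateau = float(sim_cfg.get("swing_plateau", 0.3))

    if wavelength is None:
        wavelength = RadarConfig(fs=fs).wavelength
    v_nyq = (fs / 2.0) * wavelength / 2.0
    v_top = max(
        params.torso_speed_mean + params.torso_fluct_amp,
        params.swing_peak_velocity_mean,
        params.stance_residual_velocity,
    )
    if v_top >= v_nyq:
        raise AliasingError(
            f"parameters reach {v_top:.3f} m/s, at or above the Nyquist velocity "
            f"{v_nyq:.3f} m/s for fs={fs} Hz; reduce speeds or raise fs"
        )

    rng = np.random.default_rng(rng_seed)
    T = params.cycle_duration_mean
    n_samples = int(round(n_cycles * T * fs))
    times = np.arange(n_samples) / fs
    phase0 = rng.uniform(0.0, 1.0)

    v_torso = params.torso_speed_mean + params.torso_fluct_amp * np.sin(
        2.0 * np.pi * 2.0 * (times / T + phase0)
    )

    if params.swing_peak_velocity_mean == 0.0:
        # degenerate rigid body: no stepping, all scatterers ride the torso
        velocities = np.tile(v_torso, (len(ROLES), 1))
    else:
        u_left = np.mod(times / T + phase0, 1.0)
        u_right = np.mod(times / T + phase0 + 0.5, 1.0)
        v_lfoot = _foot_velocity(u_left, params, stance_fraction, plateau)
        v_rfoot = _foot_velocity(u_right, params, stance_fraction, plateau)
        # tibia midpoint moves between the hip (torso speed) and the foot
        v_ltib = 0.5 * (v_torso + v_lfoot)
        v_rtib = 0.5 * (v_torso + v_rfoot)
        velocities = np.vstack([v_torso, v_lfoot, v_rfoot, v_ltib, v_rtib])

    # small independent range offsets decorrelate the initial carrier phases
    offsets = rng.uniform(0.0, 0.05, size=len(ROLES))
    displacement = cumulative_trapezoid(velocities, dx=1.0 / fs, initial=0.0, axis=1)
    ranges = (start_range + offsets)[:, None] - displacement
    if np.any(ranges <= 0):
        raise ValueError(
            f"start_range={start_range} m is too short: the walker reaches the radar"
        )

    eta = np.array([params.limb_reflectivities.get(role, 1.0) for role in ROLES])
    return ScattererTrajectorySet(
        times=times,
        ranges=ranges,
        radial_velocities=velocities,
        reflectivities=eta,
        roles=ROLES,
        fs=fs,
        true_params=params,
        provenance=f"synthetic(label={params.label},seed={rng_seed})",
    )


@dataclass
class DatasetRecord:
    """One simulated trial: identifier, class label, seed, parameter draw, signal."""

    id: str
    label: str
    seed: int
    params: GaitClassParams
    signal: BasebandSignal


@dataclass
class SimulatedDataset:
    """A labelled collection of simulated baseband recordings with a manifest."""

    records: list
    master_seed: int
    config: dict

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list:
        return [r.label for r in self.records]

    @property
    def signals(self) -> list:
        return [r.signal for r in self.records]

    def manifest(self) -> pd.DataFrame:
        """One row per trial: id, label, seed and the full parameter draw."""
        rows = []
        for r in self.records:
            row = {"id": r.id, "label": r.label, "seed": r.seed}
            for key, value in asdict(r.params).items():
                if key == "limb_reflectivities":
                    for role, eta in value.items():
                        row[f"eta_{role}"] = eta
                elif key != "label":
                    row[key] = value
            rows.append(row)
        return pd.DataFrame(rows)


def make_dataset(
    n_young: int,
    n_elderly: int,
    config: dict | None = None,
    rng_seed: int = 0,
    noise_sd: float | None = None,
) -> SimulatedDataset:
    """Simulate a labelled cohort of baseband gait recordings.

    Each participant gets an independent parameter draw, gait phase and noise
    realization, all derived deterministically from ``rng_seed``.  The
    manifest records every per-participant seed and parameter draw, so any
    trial can be regenerated in isolation.
    """
    if n_young < 0 or n_elderly < 0:
        raise ValueError("participant counts must be non-negative")
    config = config or DEFAULT_CONFIG
    sim_cfg = config["simulation"]
    radar = RadarConfig(f0=config["radar"]["f0"], fs=config["radar"]["fs"])
    if noise_sd is None:
        noise_sd = float(sim_cfg.get("noise_sd", 0.0))

    n_total = n_young + n_elderly
    child_seeds = np.random.SeedSequence(rng_seed).generate_state(n_total) % (2**31)
    records = []
    labels = ["young"] * n_young + ["elderly"] * n_elderly
    for i, label in enumerate(labels):
        seed = int(child_seeds[i])
        params = sample_class_params(label, seed, config)
        traj = simulate_walker(
            params,
            n_cycles=int(sim_cfg.get("n_cycles", 4)),
            fs=radar.fs,
            start_range=float(sim_cfg.get("start_range", 9.0)),
            rng_seed=seed,
            config=config,
            wavelength=radar.wavelength,
        )
        signal = synthesize_baseband(traj, radar, noise_sd=noise_sd, rng_seed=seed)
        records.append(
            DatasetRecord(id=f"{label}_{i:04d}", label=label, seed=seed,
                          params=params, signal=signal)
        )
    return SimulatedDataset(records=records, master_seed=rng_seed, config=config)
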