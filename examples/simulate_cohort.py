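"""Simulate a small labelled cohort of radar gait recordings.

Builds ten young and ten elderly walkers with the default class parameter
distributions, synthesizes their 24 GHz baseband echoes, and prints the
manifest that makes every trial reproducible from its seed.
"""

import gaitdoppler as gd

dataset = gd.make_dataset(n_young=10, n_elderly=10, rng_seed=1)
manifest = dataset.manifest()

print(manifest[["id", "label", "seed", "torso_speed_mean",
                "swing_peak_velocity_mean", "cycle_duration_mean"]]
      .to_string(index=False))

sig = dataset.records[0].signal
print(f"\nfirst recording: {sig.n} complex samples at {sig.fs:.0f} Hz "
      f"({sig.duration:.2f} s of walking, about 4 gait cycles)")
print("Torso speeds cluster near 1.3 m/s (young) vs 1.0 m/s (elderly);")
print("swing peaks scale with each walker's own speed and stay below the")
print(f"radar's Nyquist velocity of {gd.RadarConfig().nyquist_velocity:.2f} m/s.")
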