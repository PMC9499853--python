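"""Bite-locked band-power contrast for an in-lab buffet session.

Simulates a half-hour buffet with loss-of-control (LOC) and standard-meal
bites, cleans the signal, Morlet-transforms the 2 s before each bite, and
compares per-band dB power between the two bite conditions with a pooled
t-test.  The expected picture: a clear low-frequency (2-8 Hz) elevation
before LOC bites and no effect in the bands above it.
"""

import nacloop as nl

config = nl.SimulationConfig.buffet(rng_seed=1, channels=nl.VENTRAL_ROLES)
rec, log = nl.simulate(config)
table = nl.buffet_analysis(rec, log)

print(table[["channel", "band", "mean_loc_db", "sem_loc_db", "n_loc",
             "mean_standard_db", "sem_standard_db", "n_standard",
             "t", "p"]].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("mean_loc_db is the LOC-bite band power in dB relative to the mean")
print("standard-meal power of the same channel/band.  Expect a clear")
print("low_frequency (and delta/theta, its halves) elevation with p < 0.05,")
print("quiet beta/gamma/high_gamma, and at most a faint alpha echo from the")
print("shared 8 Hz band edge.")
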