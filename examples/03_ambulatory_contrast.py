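"""Ambulatory pre-swipe contrast: craving vs. hunger vs. control.

Simulates four awake hours with magnet swipes of all three kinds, computes
the Welch PSD of the 60 s before each swipe, averages the 2-8 Hz density
per event, and runs a one-way ANOVA with Bonferroni-corrected pairwise
t-tests per ventral channel.
"""

from datetime import datetime

import nacloop as nl

config = nl.SimulationConfig(
    duration_s=4 * 3600.0, rng_seed=1, channels=nl.VENTRAL_ROLES,
    start_clock=datetime(2021, 1, 1, 9, 0),
    event_rates={"magnet_craving": 4.0, "magnet_hunger": 4.0, "magnet_control": 4.0},
)
rec, log = nl.simulate(config)
results = nl.ambulatory_analysis(rec, log)

for channel, res in results.items():
    print(f"{channel}: {res.summary()}")
    for pair, sub in res.posthoc.items():
        print(f"   {pair}: t={sub.statistic:.3f}, p_adj={sub.p_value:.4f}")
print()
print("Group values are mean 2-8 Hz spectral density (uV^2/Hz) per event.")
print("Craving should sit well above hunger and control, with the ANOVA")
print("rejecting and only the craving contrasts surviving correction.")
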