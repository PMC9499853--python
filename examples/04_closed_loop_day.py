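"""Closed-loop day: area detection, bilateral gating, stimulation policy.

Simulates one ambulatory day on the ventral channels, runs the 2-s vs
2-min area detector on each side, gates detections on bilateral
coincidence, applies the stimulation policy (awake hours 07:00-22:00, 700
bouts/day cap, 10-s bouts), and summarizes what the device would have done.
"""

import numpy as np

import nacloop as nl
from nacloop.clock import hour_intervals

config = nl.SimulationConfig(rng_seed=1, channels=nl.VENTRAL_ROLES)
rec, log = nl.simulate(config)
cleaned = nl.clean(rec)

det_cfg = nl.DetectorConfig()  # 2 s vs 2 min, 63% threshold, 2-8 Hz band
det = nl.detect_bilateral(cleaned, det_cfg)
print(f"detections: left {len(det['left'])}, right {len(det['right'])}, "
      f"bilateral {len(det['bilateral'])}")

sleep = hour_intervals(config.start_clock, config.duration_s, 22, 7)
n_sleep = sum(1 for d in det["left"] if any(a <= d.time_s < b for a, b in sleep))
print(f"left-side detections during sleep hours: {n_sleep} "
      f"(adaptive long-term trend suppresses the sustained sleep delta)")

policy = nl.StimulationPolicy()
stims = nl.apply_policy(det["bilateral"], policy, rec.start_clock)
minutes = sum(s.duration_s for s in stims) / 60.0
print(f"stimulation: {len(stims)} bouts, {minutes:.1f} min "
      f"(cap {policy.daily_bout_cap} bouts / "
      f"{nl.daily_budget_minutes(policy)} min per day)")

pre = nl.pre_detection_spectrum(cleaned, det["bilateral"])
print(f"pre-detection spectra: {100 * pre.fraction_elevated:.1f}% of "
      f"detections show 2-8 Hz power above the 2-min baseline")

awake = hour_intervals(config.start_clock, config.duration_s, 7, 22)
awake_dets = [d for d in det["bilateral"] if any(a <= d.time_s < b for a, b in awake)]
perf = nl.detection_performance(awake_dets, log, positive_kinds=("magnet_craving",))
print(f"performance vs labeled events: sensitivity {perf.sensitivity:.2f}, "
      f"specificity {perf.specificity:.2f} "
      f"({perf.n_hits}/{perf.n_positives} craving events detected)")
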