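"""Run the whole pipeline end to end and list the artifacts it writes.

Equivalent to `nacloop run --out runs/demo` with a scaled-down config: a
short buffet session is simulated, cleaned, detected, stimulated, analyzed
and evaluated, and every output lands in one run directory with a manifest
that reproduces the run.
"""

import json
from pathlib import Path

import nacloop as nl

config = nl.RunConfig(
    simulation=nl.SimulationConfig.buffet(duration_s=600.0, channels=nl.VENTRAL_ROLES),
    analysis=nl.AnalysisConfig(bands=("low_frequency", "beta")),
    seed=1,
)
out = nl.run_pipeline(config, Path("runs") / "demo")

manifest = json.loads((out / "manifest.json").read_text())
print("artifacts written:")
for name in manifest["artifacts"]:
    print(f"  {name}")
print("stages:")
for stage, info in manifest["stages"].items():
    print(f"  {stage}: {info}")
print((out / "stats_report.txt").read_text())
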