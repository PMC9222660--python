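#!/usr/bin/env python
"""Generate the synthetic accelerated-storage study used by the later stages.

Writes the full bundle (replicate-level quality table, e-tongue profiles, NIR
spectra + manifest, ground-truth JSON) under scratch/study/ and a small
summary under results/.
"""

import json
from pathlib import Path

from aslt.synth import SimulationConfig, gen_full_bundle

ROOT = Path(__file__).resolve().parents[1]

cfg = SimulationConfig(seed=7)
paths = gen_full_bundle(cfg, ROOT / "scratch" / "study")

summary = {
    "seed": cfg.seed,
    "temperatures_C": [t - 273.15 for t in cfg.temperatures_K],
    "durations_d": list(cfg.durations_d),
    "sampling_intervals_d": list(cfg.sampling_intervals_d),
    "replicates": cfg.replicates,
    "nir_samples": cfg.nir_samples,
    "paths": paths,
}
out = ROOT / "results" / "study_summary.json"
out.parent.mkdir(exist_ok=True)
out.write_text(json.dumps(summary, indent=2))

print("Simulated storage study (seed 7):")
print(f"  quality indices at 25/35/45 °C for {cfg.durations_d} days, "
      f"{cfg.replicates} replicates per point")
print(f"  75 e-tongue profiles, {cfg.nir_samples} NIR spectra")
for k, v in paths.items():
    print(f"  {k}: {v}")
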