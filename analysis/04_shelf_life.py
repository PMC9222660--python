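#!/usr/bin/env python
"""Shelf-life and end-of-shelf-life critical values.

Part A uses the packaged prediction models (printed constants): sensory-score
shelf-life at the three storage temperatures and the critical quality values
at the 45 °C e-tongue endpoint (day 56).

Part B checks cross-index consensus on the simulated study: each index's
model is refitted from noisy data (03), then inverted at the true day-56
critical value; the spread of the implied shelf-lives measures how consistent
independent indices are as shelf-life predictors.
"""

import json
from pathlib import Path

from aslt.constants import celsius_to_kelvin
from aslt.fixtures import load_prediction_models
from aslt.pipeline import models_from_thermal
from aslt.shelf_life import consensus_check, critical_values_at, invert_shelf_life

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

T45 = celsius_to_kelvin(45)
models = {m.index_name: m for m in load_prediction_models()}
report = {}

print("Sensory-score shelf-life (critical score 1):")
report["sensory_shelf_life_days"] = {}
for temp_c in (25, 35, 45):
    est = invert_shelf_life(models["sensory_score"], celsius_to_kelvin(temp_c), 1.0)
    report["sensory_shelf_life_days"][str(temp_c)] = est.t_days
    print(f"  {temp_c} °C: {est.t_days:6.1f} d")

non_sensory = [m for n, m in models.items() if n != "sensory_score"]
true_criticals = critical_values_at(non_sensory, T45, 56.0)
report["critical_values_45C_day56"] = true_criticals
print("Critical values at the 45 °C e-tongue endpoint (day 56):")
for name, v in true_criticals.items():
    print(f"  {name:>20}: {v:8.2f}")

fitted = {
    m.index_name: m
    for m in models_from_thermal(
        json.loads((RESULTS / "thermal_simulated.json").read_text())
    )
}
ests = [
    invert_shelf_life(fitted[name], T45, crit)
    for name, crit in true_criticals.items()
]
ok, spread = consensus_check(ests)
report["consensus_45C_fitted"] = {
    "pass": bool(ok),
    "max_relative_spread": spread,
    "shelf_life_days": {e.index_name: e.t_days for e in ests},
}
print("Shelf-life at 45 °C implied by each refitted index "
      "(inverted at the true critical values):")
for e in ests:
    print(f"  {e.index_name:>20}: {e.t_days:6.1f} d")
print(f"Consensus spread = {100 * spread:.1f}% "
      f"({'within' if ok else 'outside'} the 15% tolerance)")

(RESULTS / "shelf_life.json").write_text(json.dumps(report, indent=2))
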