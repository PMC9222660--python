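#!/usr/bin/env python
"""Fit Arrhenius and Eyring temperature models to the per-temperature rate
constants from 02 and compare the recovered activation parameters with the
generator's ground truth.
"""

import json
from pathlib import Path

from aslt.pipeline import thermal_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

kin = json.loads((RESULTS / "kinetics_simulated.json").read_text())
thermo = thermal_report(kin)
(RESULTS / "thermal_simulated.json").write_text(json.dumps(thermo, indent=2))

truth = json.loads((ROOT / "scratch" / "study" / "truth.json").read_text())
true_ea = {(t["index"], t["component"]): t["Ea"] for t in truth["indices"]}

print("Arrhenius fits on the simulated study (log-linear, |k| vs 1/T):")
print(f"{'index':>22}  {'Ea fit kJ/mol':>13}  {'Ea true':>8}  {'err %':>6}  "
      f"{'ΔH* kJ/mol':>10}  {'ΔS* J/(mol·K)':>13}")
for m in thermo["models"]:
    ea = m["arrhenius"]["Ea_J_mol"]
    te = true_ea[(m["index"], m["component"])]
    label = f"{m['index']}/{m['component']}"
    print(f"{label:>22}  {ea / 1e3:13.2f}  {te / 1e3:8.2f}  "
          f"{100 * abs(ea - te) / te:6.2f}  "
          f"{m['eyring']['dH_J_mol'] / 1e3:10.2f}  {m['eyring']['dS_J_mol_K']:13.2f}")
print("ΔH* sits below Ea by roughly R·T̄ (≈2.6 kJ/mol), as the transition-state "
      "form predicts on this temperature span.")
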