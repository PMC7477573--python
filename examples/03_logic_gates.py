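"""Predict gate truth tables and recover them from simulated assay plates.

For each reference circuit the composition model enumerates all ligand
subsets and names the gate; a 12-replicate plate is then simulated at
default noise and evaluated with ANOVA + Tukey HSD to binarize the measured
conditions.  "predicted" is the composition model's gate name, "measured"
the name recovered from the noisy plate.  They agree except for the series
NOR gates: there the OFF conditions leak at different levels (core vs
proximal operators), which Tukey can resolve at this noise level, leaving
those conditions indeterminate rather than logical 0 — the binarization
reports "unclassified" instead of guessing.
"""

from txlogic.circuits import catalog
from txlogic.logic_gates import classify_gate, evaluate_gate, predict_truth_table
from txlogic.synthetic_data import NoiseModel, simulate_gate_plate

for name, circuit in catalog().items():
    table = predict_truth_table(circuit)
    predicted = classify_gate(table)
    plate = simulate_gate_plate(circuit, NoiseModel(), n_reps=12, seed=123)
    ev = evaluate_gate(plate, expected=table)
    rows = " ".join(
        f"{'+'.join(sorted(k)) or 'none'}={int(v[0])}"
        for k, v in sorted(table.rows.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    )
    print(f"{name:<14} predicted={predicted:<28} measured={ev.matched_gate:<28}")
    print(f"               {rows}")
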