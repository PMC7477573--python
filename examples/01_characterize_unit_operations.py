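"""Characterize simulated unit operations: plate -> phenotype calls.

Simulates a 6-replicate characterization plate for four TFs of known
phenotype on their cognate operator, normalizes to OD and blank, scales to
the lac_null maximum, and classifies each unit.  The printed p-value is the
Welch two-tailed test between ligand states (alpha 0.001) and the means are
fractions of maximum output — an anti-repressor shows high/low, a repressor
low/high, and the nonsignificant classes split on the 50% rule.
"""

from txlogic.synthetic_data import (
    IPTG, NoiseModel, Phenotype, TFSpec, profile_from_phenotype, simulate_buo_plate,
)
from txlogic.phenotyping import classify_phenotype, normalize_plate, standardize_to_max

tfs = [
    TFSpec("IA5_HQN", IPTG, "HQN", Phenotype.X_ANTI),
    TFSpec("I+_YQR", IPTG, "YQR", Phenotype.X_PLUS),
    TFSpec("IS_HQN", IPTG, "HQN", Phenotype.X_SUPER),
    TFSpec("Inull", IPTG, "HQN", Phenotype.X_NULL),
]
profiles = [profile_from_phenotype(tf, "Ottg", "proximal") for tf in tfs]

plate = simulate_buo_plate(profiles, NoiseModel(), n_reps=6, seed=42)
normalized, excluded = normalize_plate(plate)
buos, _ = standardize_to_max(normalized)

print(f"{'unit':<12} {'call':<8} {'p':>9} {'d':>7}  mean (no lig, with lig)")
for buo in buos:
    call = classify_phenotype(buo)
    print(f"{buo.tf_id:<12} {call.phenotype.value:<8} {call.p_value:>9.2e} "
          f"{min(call.cohen_d, 999):>7.1f}  ({call.mean_levels[0]:.3f}, "
          f"{call.mean_levels[1]:.3f})")
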