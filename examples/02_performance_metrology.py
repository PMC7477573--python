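"""Performance cards and traceability against the reference unit operation.

Builds the reference BUFFER card (wild-type LacI repressor on a proximal O1
operator) and an anti-repressor NOT card from simulated plates, then prints
each card's dynamic range (fold change), repression strength, and its
traceability scores — metric ratios against the reference, so the reference
scores exactly 1.0 against itself.  A NOT unit with traceability near 1 is
as strong a regulator as the wild-type standard.
"""

from txlogic.circuits import IA5_HQN, reference_buffer_tf
from txlogic.metrology import pairing_compatibility, performance_card, traceability_scores
from txlogic.phenotyping import classify_phenotype, normalize_plate, standardize_to_max
from txlogic.synthetic_data import NoiseModel, profile_from_phenotype, simulate_buo_plate


def card_for(tf, operator, position, seed):
    profile = profile_from_phenotype(tf, operator, position)
    plate = simulate_buo_plate([profile], NoiseModel(), seed=seed)
    buos, _ = standardize_to_max(normalize_plate(plate)[0])
    buo = buos[0]
    return performance_card(buo, classify_phenotype(buo))


reference = card_for(reference_buffer_tf(), "O1", "proximal", seed=7)
not_card = card_for(IA5_HQN, "Ottg", "proximal", seed=8)

for label, card in (("reference (I+_YQR | O1 prox)", reference),
                    ("NOT unit (IA5_HQN | Ottg prox)", not_card)):
    t_dr, t_ru = traceability_scores(card, reference)
    unit = "IU" if card.phenotype.value == "X_plus" else "AIU"
    print(f"{label}:")
    print(f"  dynamic range {card.dynamic_range:6.2f}   RU(raw) {card.ru_raw:6.2f}")
    print(f"  traceability  {unit} {t_dr:.3f}   RU {t_ru:.3f}")

report = pairing_compatibility(reference, not_card)
print(f"pairing verdict: {report.verdict} (RU ratio {report.ru_ratio:.2f})")
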