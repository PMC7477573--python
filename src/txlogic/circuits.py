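"""Catalog of reference transcription factors and gate circuits.

Factory functions assembling the characterized gate layouts: series-parallel
AND gates from repressor (BUFFER) pairs, series-parallel and series NOR
gates from anti-repressor (NOT) pairs, a three-input NOR, a parallel NAND,
and a parallel NOR+AND XNOR.  These are the circuits the composition model
is validated against.
"""

from __future__ import annotations

from .logic_gates import Channel, Circuit, OperatorNode
from .synthetic_data import FRUCTOSE, IPTG, RIBOSE, Phenotype, TFSpec

__all__ = [
    "I_PLUS_YQR", "I_PLUS_YQR_Q", "R_PLUS_YQR",
    "IA5_HQN", "IA9_HQN", "RA1_HQN", "RA1_KSL", "FA2_KSL",
    "reference_buffer_tf",
    "and_gate", "nor_sepa", "nor_series", "nor3_series", "nand_gate", "xnor_gate",
    "not_gate",
    "catalog",
]

# Reference repressors (BUFFER units) and engineered anti-repressors (NOT
# units).  Naming: scaffold letter (I=LacI, R=RbsR, F=FruR), phenotype
# superscript flattened into the id, then the DBD code.
I_PLUS_YQR = TFSpec("I+_YQR", IPTG, "YQR", Phenotype.X_PLUS, 1.0)
I_PLUS_YQR_Q = TFSpec("I+_YQR(q)", IPTG, "YQR", Phenotype.X_PLUS, 10.0)
R_PLUS_YQR = TFSpec("R+_YQR", RIBOSE, "YQR", Phenotype.X_PLUS, 1.0)
IA5_HQN = TFSpec("IA5_HQN", IPTG, "HQN", Phenotype.X_ANTI, 1.0)
IA9_HQN = TFSpec("IA9_HQN", IPTG, "HQN", Phenotype.X_ANTI, 1.0)
RA1_HQN = TFSpec("RA1_HQN", RIBOSE, "HQN", Phenotype.X_ANTI, 1.0)
RA1_KSL = TFSpec("RA1_KSL", RIBOSE, "KSL", Phenotype.X_ANTI, 1.0)
FA2_KSL = TFSpec("FA2_KSL", FRUCTOSE, "KSL", Phenotype.X_ANTI, 1.0)


def reference_buffer_tf() -> TFSpec:
    """The wild-type LacI reference BUFFER unit's TF (I+_YQR)."""
    return I_PLUS_YQR


def and_gate(operator: str = "OSYM", position: str = "proximal",
             strong_iptg_repressor: bool = False) -> Circuit:
    """Series-parallel AND from the two BUFFER units I+_YQR and R+_YQR.

    Both repressors share the YQR DBD and exchange on one operator; output
    flows only when both ligands are present.  With ``operator="O1"`` and
    ``position="core"`` at wild-type expression the LacI arm is nullified by
    RNA-polymerase competition and the gate degrades to a single-input
    (D-ribose) BUFFER; ``strong_iptg_repressor=True`` swaps in the ten-fold
    LacI^q variant, one of the two documented rescues (the other being the
    O^SYM operator itself).
    """
    i_tf = I_PLUS_YQR_Q if strong_iptg_repressor else I_PLUS_YQR
    ch = Channel(promoter="trc", nodes=(OperatorNode(operator, position),))
    return Circuit(name=f"AND{position[0]}_{operator}",
                   tfs=(i_tf, R_PLUS_YQR), channels=(ch,))


def nor_sepa(position: str = "proximal") -> Circuit:
    """Series-parallel NOR: two NOT units (IA5_HQN, RA1_HQN) on one O^ttg."""
    ch = Channel(promoter="trc", nodes=(OperatorNode("Ottg", position),))
    return Circuit(name=f"NOR{position[0]}", tfs=(IA5_HQN, RA1_HQN), channels=(ch,))


def nor_series() -> Circuit:
    """Series NOR (NORcp): RA1_KSL on a core O^agg, IA5_HQN on a proximal O^ttg."""
    ch = Channel(promoter="trc", nodes=(OperatorNode("Oagg", "core"),
                                        OperatorNode("Ottg", "proximal")))
    return Circuit(name="NORcp", tfs=(RA1_KSL, IA5_HQN), channels=(ch,))


def nor3_series() -> Circuit:
    """Three-input NOR: FA2_KSL joins RA1_KSL on the core O^agg (SE-PA),
    in series with IA5_HQN on the proximal O^ttg."""
    ch = Channel(promoter="trc", nodes=(OperatorNode("Oagg", "core"),
                                        OperatorNode("Ottg", "proximal")))
    return Circuit(name="NOR3cp", tfs=(RA1_KSL, FA2_KSL, IA5_HQN), channels=(ch,))


def nand_gate() -> Circuit:
    """Parallel NAND: IA9_HQN on a core O^ttg channel, RA1_KSL on a core
    O^agg channel, both driving the same reporter."""
    ch1 = Channel(promoter="trc", nodes=(OperatorNode("Ottg", "core"),))
    ch2 = Channel(promoter="pL", nodes=(OperatorNode("Oagg", "core"),))
    return Circuit(name="NAND", tfs=(IA9_HQN, RA1_KSL), channels=(ch1, ch2))


def xnor_gate() -> Circuit:
    """Parallel XNOR: a proximal SE-PA NOR channel (IA9_HQN + RA1_HQN on
    O^ttg) coupled with a proximal SE-PA AND channel (I+_YQR + R+_YQR on
    O^SYM)."""
    ch_nor = Channel(promoter="trc", nodes=(OperatorNode("Ottg", "proximal"),))
    ch_and = Channel(promoter="pL_mut", nodes=(OperatorNode("OSYM", "proximal"),))
    return Circuit(name="XNOR", tfs=(IA9_HQN, RA1_HQN, I_PLUS_YQR, R_PLUS_YQR),
                   channels=(ch_nor, ch_and))


def not_gate(tf: TFSpec = IA5_HQN, operator: str = "Ottg",
             position: str = "proximal") -> Circuit:
    """Single NOT unit operation as a one-TF circuit."""
    ch = Channel(promoter="trc", nodes=(OperatorNode(operator, position),))
    return Circuit(name=f"NOT{position[0]}_{tf.id}", tfs=(tf,), channels=(ch,))


def catalog() -> dict[str, Circuit]:
    """All named reference circuits keyed by a short label."""
    return {
        "ANDp_OSYM": and_gate("OSYM", "proximal"),
        "ANDp_O1": and_gate("O1", "proximal"),
        "ANDc_OSYM": and_gate("OSYM", "core"),
        "ANDc_O1": and_gate("O1", "core"),
        "ANDc_O1_lacIq": and_gate("O1", "core", strong_iptg_repressor=True),
        "NORp": nor_sepa("proximal"),
        "NORc": nor_sepa("core"),
        "NORcp": nor_series(),
        "NOR3cp": nor3_series(),
        "NAND": nand_gate(),
        "XNOR": xnor_gate(),
    }
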