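"""Circuit composition model: predict and evaluate transcriptional logic.

A circuit is one or two transcription channels feeding a common reporter.
Each channel carries at most one *core* operator (intercalated between the
-35/-10 promoter hexamers, where a bound TF competes with RNA polymerase)
and one *proximal* operator (downstream of -10, no direct competition).
Transcription through a channel requires every operator in it to be free
(series conjunction); with two channels coupled to the same output, the
reporter is on if either channel transmits (parallel disjunction).  Several
TFs sharing a DNA-binding domain can exchange on a single operator
(series-parallel): the operator is occupied if *any* of them binds.

Binding follows the phenotype truth semantics: a repressor (``X_plus``)
binds until its ligand appears, an anti-repressor (``X_anti``) binds only
when its ligand is present, a super-repressor always, a null never.  Core
position occupancy additionally requires the TF to win the competition with
RNA polymerase; this is encoded as a per-(TF, operator, position)
effectiveness table rather than a thermodynamic model.  The default table
captures the one documented failure — the wild-type-strength LacI BUFFER is
nullified at an O1 core operator — and its two rescues (the
higher-affinity O^SYM operator, or ten-fold LacI^q expression).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .synthetic_data import (
    IPTG,
    ExpressionProfile,
    Phenotype,
    SimPlate,
    TFSpec,
    profile_from_phenotype,
)

__all__ = [
    "DEFAULT_COGNATE_MAP",
    "OperatorNode",
    "Channel",
    "Circuit",
    "TruthTable",
    "GateEval",
    "binds",
    "operator_occupied",
    "channel_permitted",
    "circuit_output",
    "default_profiles",
    "quantitative_output",
    "predict_truth_table",
    "classify_gate",
    "evaluate_gate",
    "circuit_from_json",
    "circuit_to_json",
]

#: DNA-binding-domain code -> cognate operator set.  YQR (wild-type LacI
#: DBD) recognizes both the natural O1 and the symmetric O^SYM variant; the
#: alternate-recognition pairs HQN|O^ttg, KSL|O^agg and NAR|O^gta follow the
#: engineered orthogonal pairings.  TAN and the wild-type RbsR/FruR domains
#: get placeholder cognates; override per circuit as needed.
DEFAULT_COGNATE_MAP: Mapping[str, frozenset] = {
    "YQR": frozenset({"O1", "OSYM"}),
    "HQN": frozenset({"Ottg"}),
    "KSL": frozenset({"Oagg"}),
    "NAR": frozenset({"Ogta"}),
    "TAN": frozenset({"Otan"}),
    "RBS": frozenset({"rbsDACBK"}),
    "FRU": frozenset({"fruBKA"}),
}


@dataclass(frozen=True)
class OperatorNode:
    """One operator site in a channel."""

    operator: str
    position: str  # core | proximal

    def __post_init__(self) -> None:
        if self.position not in ("core", "proximal"):
            raise ValueError(f"position must be 'core' or 'proximal', got {self.position!r}")


@dataclass(frozen=True)
class Channel:
    """One promoter/operator layout driving an output gene."""

    promoter: str
    nodes: tuple[OperatorNode, ...]
    output_gene: str = "gfp"

    def __post_init__(self) -> None:
        positions = [n.position for n in self.nodes]
        if len(self.nodes) > 2 or any(positions.count(p) > 1 for p in positions):
            raise ValueError("a channel holds at most one core and one proximal node")


@dataclass(frozen=True)
class Circuit:
    """TF complement plus one or two channels coupled to a shared output."""

    name: str
    tfs: tuple[TFSpec, ...]
    channels: tuple[Channel, ...]
    cognate_map: Mapping[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_COGNATE_MAP))
    effectiveness_overrides: Mapping[tuple[str, str, str], bool] = field(
        default_factory=dict)

    def validate(self) -> None:
        if not 1 <= len(self.channels) <= 2:
            raise ValueError("a circuit has 1 or 2 channels")
        genes = {ch.output_gene for ch in self.channels}
        if len(genes) != 1:
            raise ValueError("parallel channels must share one output gene")
        for ch in self.channels:
            ch.__post_init__()

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(sorted({tf.rcd_ligand for tf in self.tfs}))

    def cognate_operators(self, dbd: str) -> frozenset:
        return frozenset(self.cognate_map.get(dbd, frozenset()))

    def is_effective(self, tf: TFSpec, operator: str, position: str) -> bool:
        """Can a bound TF at this site actually block transcription?

        Proximal sites are always effective.  At a core site the TF must
        out-compete RNA polymerase; the default rule marks the
        wild-type-strength LacI BUFFER (X_plus, YQR) ineffective at an O1
        core, while O^SYM affinity or >= 10x expression restores it.
        """
        override = self.effectiveness_overrides.get((tf.id, operator, position))
        if override is not None:
            return override
        if (
            position == "core"
            and operator == "O1"
            and tf.dbd == "YQR"
            and tf.rcd_ligand == IPTG
            and tf.phenotype is Phenotype.X_PLUS
            and tf.expression_strength < 10.0
        ):
            return False
        return True


@dataclass
class TruthTable:
    """Predicted (or measured) gate behaviour over all input subsets."""

    inputs: tuple[str, ...]
    rows: dict[frozenset, tuple[bool | None, float | None]]

    def boolean(self) -> dict[frozenset, bool | None]:
        return {k: v[0] for k, v in self.rows.items()}

    def as_tuple(self) -> tuple:
        """Canonical row order: by subset size then lexicographic."""
        keys = sorted(self.rows, key=lambda s: (len(s), tuple(sorted(s))))
        return tuple((tuple(sorted(k)), self.rows[k][0]) for k in keys)


@dataclass
class GateEval:
    """Statistical evaluation of a measured gate plate."""

    condition_means: dict[frozenset, tuple[float, float]]  # (mean, sd) normalized
    nou: dict[frozenset, float]  # normalized output units (max condition = 1)
    anova_p: float
    tukey_states: dict[frozenset, int | None]  # 1 on-group, 0 off-group, None indeterminate
    matched_gate: str
    alpha: float = 0.01
    agrees_expected: bool | None = None


# --------------------------------------------------------------------------
# boolean composition

def binds(tf: TFSpec, ligands: Iterable[str]) -> bool:
    """Is the TF bound to (any) cognate DNA under this ligand condition?"""
    present = tf.rcd_ligand in set(ligands)
    phen = Phenotype(tf.phenotype)
    if phen is Phenotype.X_PLUS:
        return not present
    if phen is Phenotype.X_ANTI:
        return present
    if phen is Phenotype.X_SUPER:
        return True
    return False  # X_null


def operator_occupied(node: OperatorNode, circuit: Circuit, ligands: Iterable[str]) -> bool:
    """True iff any cognate, position-effective TF is bound under ``ligands``."""
    ligands = set(ligands)
    return any(
        node.operator in circuit.cognate_operators(tf.dbd)
        and circuit.is_effective(tf, node.operator, node.position)
        and binds(tf, ligands)
        for tf in circuit.tfs
    )


def channel_permitted(channel: Channel, circuit: Circuit, ligands: Iterable[str]) -> bool:
    """A channel transmits iff every operator in it is unoccupied."""
    ligands = set(ligands)
    return all(not operator_occupied(n, circuit, ligands) for n in channel.nodes)


def circuit_output(circuit: Circuit, ligands: Iterable[str]) -> bool:
    """Reporter is on iff any channel transmits."""
    circuit.validate()
    ligands = set(ligands)
    return any(channel_permitted(ch, circuit, ligands) for ch in circuit.channels)


# --------------------------------------------------------------------------
# quantitative composition

def default_profiles(
    circuit: Circuit, params: Mapping[str, object] | None = None
) -> dict[tuple[str, str, str], ExpressionProfile]:
    """Default expression profiles for every cognate (TF, node) pairing."""
    profiles: dict[tuple[str, str, str], ExpressionProfile] = {}
    for ch in circuit.channels:
        for node in ch.nodes:
            for tf in circuit.tfs:
                if node.operator in circuit.cognate_operators(tf.dbd):
                    profiles[(tf.id, node.operator, node.position)] = \
                        profile_from_phenotype(tf, node.operator, node.position,
                                               cognate=True, params=params)
    return profiles


def quantitative_output(
    circuit: Circuit,
    ligands: Iterable[str],
    profiles: Mapping[tuple[str, str, str], ExpressionProfile],
) -> float:
    """Fractional reporter output in [0, 1] under a ligand condition.

    Each operator transmits at the minimum level of its cognate effective
    TFs' profiles under the condition (tightest repression wins on a shared
    operator), or 1 if no TF addresses it; a channel multiplies its nodes'
    transmissions in series, and parallel channels couple through the
    maximum — reproducing the ON plateau the per-gate normalization anchors
    to.
    """
    circuit.validate()
    ligands = set(ligands)
    best = 0.0
    for ch in circuit.channels:
        trans = 1.0
        for node in ch.nodes:
            levels = []
            for tf in circuit.tfs:
                if node.operator not in circuit.cognate_operators(tf.dbd):
                    continue
                if not circuit.is_effective(tf, node.operator, node.position):
                    continue
                key = (tf.id, node.operator, node.position)
                if key not in profiles:
                    raise KeyError(
                        f"missing expression profile for {key}; provide one for every "
                        "cognate (tf, operator, position) in the circuit")
                levels.append(profiles[key].level(ligands))
            trans *= min(levels) if levels else 1.0
        best = max(best, trans)
    return best


def predict_truth_table(
    circuit: Circuit,
    profiles: Mapping[tuple[str, str, str], ExpressionProfile] | None = None,
) -> TruthTable:
    """Enumerate all 2^k ligand subsets and predict the gate's outputs."""
    circuit.validate()
    inputs = circuit.inputs
    if not 1 <= len(inputs) <= 4:
        raise ValueError(f"circuit must have 1-4 input ligands, has {len(inputs)}")
    if profiles is None:
        profiles = default_profiles(circuit)
    rows: dict[frozenset, tuple[bool, float]] = {}
    for k in range(len(inputs) + 1):
        for combo in itertools.combinations(inputs, k):
            subset = frozenset(combo)
            rows[subset] = (circuit_output(circuit, subset),
                            quantitative_output(circuit, subset, profiles))
    return TruthTable(inputs=inputs, rows=rows)


# --------------------------------------------------------------------------
# gate naming

def _named_patterns(inputs: tuple[str, ...]):
    subsets = [frozenset(c) for k in range(len(inputs) + 1)
               for c in itertools.combinations(inputs, k)]
    k = len(inputs)
    defs = {
        "AND": lambda s: len(s) == k,
        "OR": lambda s: len(s) >= 1,
        "NOR": lambda s: len(s) == 0,
        "NAND": lambda s: len(s) < k,
        "XOR": lambda s: len(s) % 2 == 1,
        "XNOR": lambda s: len(s) % 2 == 0,
        "constant 1": lambda s: True,
        "constant 0": lambda s: False,
    }
    if k == 1:
        lig = inputs[0]
        defs = {
            "BUFFER": lambda s: lig in s,
            "NOT": lambda s: lig not in s,
            "constant 1": lambda s: True,
            "constant 0": lambda s: False,
        }
    order = (["BUFFER", "NOT"] if k == 1
             else ["AND", "OR", "NOR", "NAND", "XOR", "XNOR"])
    order += ["constant 1", "constant 0"]
    return subsets, {name: {s: defs[name](s) for s in subsets} for name in order}


def classify_gate(table: TruthTable) -> str:
    """Name the gate a boolean truth table implements.

    Canonical names (BUFFER, NOT, AND, OR, NOR, NAND, XOR, XNOR, constants)
    are matched first; a multi-input table that depends on only one input is
    reported as a single-input reduction, e.g. ``"single-input (d-ribose
    BUFFER)"``; anything else (including tables with indeterminate rows) is
    ``"unclassified"``.
    """
    k = len(table.inputs)
    if not 1 <= k <= 3:
        raise ValueError("classification defined for 1-3 inputs")
    pattern = table.boolean()
    if any(v is None for v in pattern.values()):
        return "unclassified"
    subsets, named = _named_patterns(table.inputs)
    for name, want in named.items():
        if all(pattern[s] == want[s] for s in subsets):
            return name
    if k >= 2:
        for lig in table.inputs:
            by_lig = {}
            reduced = True
            for s in subsets:
                key = lig in s
                if key in by_lig and by_lig[key] != pattern[s]:
                    reduced = False
                    break
                by_lig[key] = pattern[s]
            if reduced:
                kind = "BUFFER" if by_lig[True] else "NOT"
                return f"single-input ({lig} {kind})"
    return "unclassified"


# --------------------------------------------------------------------------
# measured-gate evaluation

def evaluate_gate(
    measurements: SimPlate,
    expected: TruthTable | None = None,
    alpha: float = 0.01,
) -> GateEval:
    """Evaluate a measured gate plate against ANOVA + Tukey HSD statistics.

    Condition means (blank-subtracted, OD-normalized) are scaled to the
    highest condition mean (normalized output units, N.O.U.).  A one-way
    ANOVA across conditions (gate-level alpha 0.01) is followed by Tukey's
    HSD: conditions statistically indistinguishable from the maximum
    condition read as logical 1, those indistinguishable from the minimum as
    0, and conditions separable from both (or from neither) are
    indeterminate.  The binarized pattern is matched to a canonical gate
    name; a nonsignificant ANOVA reads as ``"constant"``.
    """
    from .phenotyping import normalize_plate

    norm, _ = normalize_plate(measurements)
    tf = norm[norm.sample_type == "tf"]
    groups: list[np.ndarray] = []
    conds: list[frozenset] = []
    for lig, grp in tf.groupby("ligands", sort=True):
        cond = frozenset(x for x in str(lig).split(";") if x)
        vals = grp.normalized.to_numpy()
        if vals.size < 2:
            raise ValueError(f"condition {sorted(cond)} has < 2 replicates")
        conds.append(cond)
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need >= 2 ligand conditions to evaluate a gate")

    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    nou = means / means.max()

    scale = max(1.0, float(np.abs(means).max()))
    if all(g.var(ddof=1) <= (1e-9 * scale) ** 2 for g in groups):
        # deterministic plate: separation is exact, no sampling distribution
        anova_p = 1.0 if np.allclose(means, means[0]) else 0.0
        same_max = np.isclose(means, means.max())
        same_min = np.isclose(means, means.min())
    else:
        anova_p = float(stats.f_oneway(*groups).pvalue)
        hsd = stats.tukey_hsd(*groups)
        i_max = int(np.argmax(means))
        i_min = int(np.argmin(means))
        pv = hsd.pvalue
        same_max = pv[:, i_max] >= alpha
        same_min = pv[:, i_min] >= alpha

    states: dict[frozenset, int | None] = {}
    if anova_p >= alpha:
        states = {c: None for c in conds}
        matched = "constant"
    else:
        for i, c in enumerate(conds):
            if same_max[i] and not same_min[i]:
                states[c] = 1
            elif same_min[i] and not same_max[i]:
                states[c] = 0
            else:
                states[c] = None
        inputs = tuple(sorted(set().union(*conds))) if any(conds) else ()
        if any(v is None for v in states.values()) or not inputs:
            matched = "unclassified"
        else:
            table = TruthTable(inputs=inputs,
                               rows={c: (bool(states[c]), float(nou[i]))
                                     for i, c in enumerate(conds)})
            try:
                matched = classify_gate(table)
            except ValueError:
                matched = "unclassified"

    agrees = None
    if expected is not None:
        agrees = matched == classify_gate(expected)
    return GateEval(
        condition_means={c: (float(m), float(s)) for c, m, s in zip(conds, means, sds)},
        nou={c: float(v) for c, v in zip(conds, nou)},
        anova_p=anova_p, tukey_states=states, matched_gate=matched,
        alpha=alpha, agrees_expected=agrees,
    )


# --------------------------------------------------------------------------
# JSON interface

def circuit_to_json(circuit: Circuit) -> dict:
    return {
        "name": circuit.name,
        "inputs": list(circuit.inputs),
        "tfs": [
            {"id": tf.id, "rcd_ligand": tf.rcd_ligand, "dbd": tf.dbd,
             "phenotype": tf.phenotype.value,
             "expression_strength": tf.expression_strength}
            for tf in circuit.tfs
        ],
        "channels": [
            {"promoter": ch.promoter,
             "nodes": [{"operator": n.operator, "position": n.position}
                       for n in ch.nodes],
             "output_gene": ch.output_gene}
            for ch in circuit.channels
        ],
        "cognate_map": {d: sorted(ops) for d, ops in circuit.cognate_map.items()},
        "effectiveness_overrides": [
            {"tf_id": k[0], "operator": k[1], "position": k[2], "effective": v}
            for k, v in circuit.effectiveness_overrides.items()
        ],
    }


def circuit_from_json(source) -> Circuit:
    """Load a circuit from a JSON dict, string, or file path."""
    if isinstance(source, (str, bytes)):
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
    elif hasattr(source, "read"):
        data = json.load(source)
    else:
        data = source
    tfs = tuple(
        TFSpec(id=t["id"], rcd_ligand=t["rcd_ligand"], dbd=t["dbd"],
               phenotype=Phenotype(t["phenotype"]),
               expression_strength=float(t.get("expression_strength", 1.0)))
        for t in data["tfs"]
    )
    channels = tuple(
        Channel(promoter=c["promoter"],
                nodes=tuple(OperatorNode(n["operator"], n["position"])
                            for n in c["nodes"]),
                output_gene=c.get("output_gene", "gfp"))
        for c in data["channels"]
    )
    cmap = {d: frozenset(ops) for d, ops in
            data.get("cognate_map", DEFAULT_COGNATE_MAP).items()}
    overrides = {
        (o["tf_id"], o["operator"], o["position"]): bool(o["effective"])
        for o in data.get("effectiveness_overrides", [])
    }
    circuit = Circuit(name=data.get("name", "circuit"), tfs=tfs, channels=channels,
                      cognate_map=cmap, effectiveness_overrides=overrides)
    circuit.validate()
    return circuit
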