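"""Promoter/operator cassette builders and layout validation.

DNA layout rules for the reporter architectures:

* **core** — a 17-bp operator is inserted between the -35 (``TTGACA``) and
  -10 hexamers of the promoter, so a bound TF competes with RNA polymerase;
* **proximal** — the operator starts 15 bp downstream of the end of the -10
  box, clear of the polymerase footprint;
* **series** — one core and one proximal operator ahead of a single gene;
* **parallel** — two complete cassettes (two promoters, two gene copies of
  the shared output) concatenated, each behind a *different* self-cleaving
  ribozyme insulator (RiboJ vs RiboJ10) to decouple 5' UTR sequence from
  expression.

Operator, insulator, gene and terminator sequences here are synthetic
placeholders with authoritative symbolic labels — the layouts, lengths and
spacings are the contract, not the base identities.  All coordinates are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PromoterScaffold",
    "TRC", "PL", "PL_MUT", "SCAFFOLDS",
    "OPERATOR_SEQS",
    "Feature",
    "CassetteRecord",
    "LayoutReport",
    "build_core_promoter",
    "build_proximal_cassette",
    "build_series_cassette",
    "build_parallel_record",
    "validate_layout",
]

MINUS35 = "TTGACA"
ALLOWED_MINUS10 = {"TATAAT", "GATACT", "GACTAT"}

CORE_OPERATOR_LEN = 17
PROXIMAL_OFFSET = 15


@dataclass(frozen=True)
class PromoterScaffold:
    """A named promoter defined by its -35 and -10 hexamers."""

    name: str
    minus35: str = MINUS35
    minus10: str = "TATAAT"

    def __post_init__(self) -> None:
        if self.minus35 != MINUS35:
            raise ValueError(f"-35 box must be {MINUS35} for all scaffolds")
        if self.minus10 not in ALLOWED_MINUS10:
            raise ValueError(f"-10 box must be one of {sorted(ALLOWED_MINUS10)}")


TRC = PromoterScaffold("trc", minus10="TATAAT")
PL = PromoterScaffold("pL", minus10="GATACT")
PL_MUT = PromoterScaffold("pL_mut", minus10="GACTAT")  # pL -10 mutated (J23116-style)
SCAFFOLDS = {"trc": TRC, "pL": PL, "pL_mut": PL_MUT}

#: Synthetic placeholder 17-mers for the named operators; symbolic IDs are
#: authoritative.  Replace via config for sequence-accurate work.
OPERATOR_SEQS: dict[str, str] = {
    "O1": "AATTGTGAGCGGATAAC",
    "OSYM": "AATTGTGAGCGCTCACA",
    "Ottg": "TTGTGTGAGCGGATAAC",
    "Oagg": "AGGTGTGAGCGGATAAC",
    "Ogta": "GTATGTGAGCGGATAAC",
    "Otan": "TANTGTGAGCGGATAAC".replace("N", "C"),
    "rbsDACBK": "ACTGAAACGTTTCAGTC",
    "fruBKA": "GCTGAATCGATTCAGCA",
}

# placeholder part motifs (labels authoritative, sequences synthetic)
_PAD5 = "GGCAG"
_NEUTRAL17 = "CTAGGTCTAACGTTAGA"  # neutral core filler when no core operator
_SPACER_BASE = "ACGTAGCTAGGATCCAGTCAAGCTTGGCAT"  # sliced to the wanted spacer length
_INSULATORS = {
    "RiboJ": "AGCTGTCACCGGATGTGCTT",
    "RiboJ10": "AGTTGTCACCGGTAGCACTT",
}
_GENE = "ATGCGTAAAGGCGAAGAGCTGTTCACTGGTTAA"  # sfGFP stand-in ORF
_TERMINATOR = "CCAGGCATCAAATAAAACGAAAGGCTCAG"  # rrnb1 stand-in


@dataclass(frozen=True)
class Feature:
    """An annotated interval, 0-based half-open."""

    label: str
    start: int
    end: int
    kind: str = "misc"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CassetteRecord:
    """An annotated DNA cassette."""

    sequence: str
    features: list[Feature] = field(default_factory=list)
    name: str = "cassette"

    def __post_init__(self) -> None:
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"feature {f.label} exceeds sequence bounds")
        ops = sorted((f for f in self.features if f.kind == "operator"),
                     key=lambda f: f.start)
        for a, b in zip(ops, ops[1:]):
            if b.start < a.end:
                raise ValueError(f"operator features overlap: {a.label} / {b.label}")

    def by_kind(self, kind: str) -> list[Feature]:
        return sorted((f for f in self.features if f.kind == kind),
                      key=lambda f: f.start)

    def to_seqrecord(self) -> SeqRecord:
        rec = SeqRecord(Seq(self.sequence), id=self.name, name=self.name[:16],
                        description="", annotations={"molecule_type": "DNA"})
        for f in self.features:
            rec.features.append(SeqFeature(FeatureLocation(f.start, f.end),
                                           type=f.kind,
                                           qualifiers={"label": [f.label]}))
        return rec

    def write(self, path, fmt: str = "genbank") -> None:
        from Bio import SeqIO
        SeqIO.write(self.to_seqrecord(), path, fmt)


@dataclass
class LayoutReport:
    """What ``validate_layout`` found in a cassette."""

    minus35_seqs: list[str]
    minus10_seqs: list[str]
    core_spacings: list[int]  # distance between each -35 end and -10 start
    proximal_offsets: list[int]  # operator start minus preceding -10 end
    insulators: list[str]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


# --------------------------------------------------------------------------
# builders

def _downstream(parts: list[tuple[str, str, str]], insulator: str, gene_label: str):
    parts.append((_INSULATORS[insulator], insulator, "insulator"))
    parts.append((_GENE, gene_label, "gene"))
    parts.append((_TERMINATOR, "rrnb1", "terminator"))


def _assemble(parts: list[tuple[str, str, str]], name: str) -> CassetteRecord:
    seq = ""
    feats = []
    for chunk, label, kind in parts:
        if kind != "pad" and kind != "spacer":
            feats.append(Feature(label, len(seq), len(seq) + len(chunk), kind))
        seq += chunk
    return CassetteRecord(sequence=seq, features=feats, name=name)


def build_core_promoter(
    scaffold: PromoterScaffold,
    operator_seq: str,
    operator_label: str = "operator",
    insulator: str = "RiboJ",
    gene_label: str = "gfp",
) -> CassetteRecord:
    """Promoter with a 17-bp operator intercalated between the hexamers."""
    if len(operator_seq) != CORE_OPERATOR_LEN:
        raise ValueError(
            f"core operator must be exactly {CORE_OPERATOR_LEN} bp "
            f"(got {len(operator_seq)} bp): it replaces the inter-hexamer spacer")
    parts = [
        (_PAD5, "", "pad"),
        (scaffold.minus35, "-35", "minus35"),
        (operator_seq.upper(), operator_label, "operator"),
        (scaffold.minus10, "-10", "minus10"),
    ]
    _downstream(parts, insulator, gene_label)
    return _assemble(parts, f"core_{scaffold.name}_{operator_label}")


def build_proximal_cassette(
    scaffold: PromoterScaffold,
    operator_seq: str,
    spacer_len: int = PROXIMAL_OFFSET,
    operator_label: str = "operator",
    insulator: str = "RiboJ",
    gene_label: str = "gfp",
) -> CassetteRecord:
    """Promoter with the operator ``spacer_len`` bp past the -10 box."""
    if not operator_seq:
        raise ValueError("operator sequence must be non-empty")
    if spacer_len < 0:
        raise ValueError("spacer length must be >= 0")
    spacer = (_SPACER_BASE * (spacer_len // len(_SPACER_BASE) + 1))[:spacer_len]
    parts = [
        (_PAD5, "", "pad"),
        (scaffold.minus35, "-35", "minus35"),
        (_NEUTRAL17, "", "spacer"),
        (scaffold.minus10, "-10", "minus10"),
        (spacer, "", "spacer"),
        (operator_seq.upper(), operator_label, "operator"),
    ]
    _downstream(parts, insulator, gene_label)
    return _assemble(parts, f"proximal_{scaffold.name}_{operator_label}")


def build_series_cassette(
    core_operator: str,
    proximal_operator: str,
    scaffold: PromoterScaffold = TRC,
    core_label: str = "core_operator",
    proximal_label: str = "proximal_operator",
    insulator: str = "RiboJ",
    gene_label: str = "gfp",
) -> CassetteRecord:
    """Series layout: core operator in the promoter, proximal at +15."""
    if len(core_operator) != CORE_OPERATOR_LEN:
        raise ValueError(
            f"core operator must be exactly {CORE_OPERATOR_LEN} bp "
            f"(got {len(core_operator)} bp)")
    if not proximal_operator:
        raise ValueError("proximal operator must be non-empty")
    spacer = _SPACER_BASE[:PROXIMAL_OFFSET]
    parts = [
        (_PAD5, "", "pad"),
        (scaffold.minus35, "-35", "minus35"),
        (core_operator.upper(), core_label, "operator"),
        (scaffold.minus10, "-10", "minus10"),
        (spacer, "", "spacer"),
        (proximal_operator.upper(), proximal_label, "operator"),
    ]
    _downstream(parts, insulator, gene_label)
    return _assemble(parts, f"series_{scaffold.name}")


def build_parallel_record(channel1: CassetteRecord, channel2: CassetteRecord) -> CassetteRecord:
    """Concatenate two channel cassettes into one parallel record.

    The channels must carry distinct insulator labels (sequence diversity in
    the repeated 5' UTR region); each keeps its own gene and terminator, so
    channel 1's terminator separates the two transcription units.
    """
    ins1 = [f.label for f in channel1.by_kind("insulator")]
    ins2 = [f.label for f in channel2.by_kind("insulator")]
    shared = set(ins1) & set(ins2)
    if shared:
        raise ValueError(
            f"parallel channels must use distinct insulators, both use {sorted(shared)}")
    if not (channel1.by_kind("terminator") and channel1.by_kind("gene")):
        raise ValueError("channel 1 must be a complete cassette (gene + terminator)")
    offset = len(channel1.sequence)
    feats = list(channel1.features) + [
        Feature(f.label, f.start + offset, f.end + offset, f.kind)
        for f in channel2.features
    ]
    return CassetteRecord(sequence=channel1.sequence + channel2.sequence,
                          features=feats,
                          name=f"parallel_{channel1.name}_{channel2.name}")


# --------------------------------------------------------------------------
# validation

def validate_layout(record: CassetteRecord) -> LayoutReport:
    """Measure a cassette's promoter layout and flag violations.

    For each annotated -35/-10 pair (in positional order) the inter-hexamer
    spacing is measured; any operator feature inside that window must fill it
    exactly (17 bp, contiguous).  Operators downstream of a -10 box report
    their offset from the end of that box.  Violations are listed, never
    raised.
    """
    violations: list[str] = []
    m35s = record.by_kind("minus35")
    m10s = record.by_kind("minus10")
    ops = record.by_kind("operator")
    insulators = [f.label for f in record.by_kind("insulator")]

    minus35_seqs = [record.sequence[f.start:f.end] for f in m35s]
    minus10_seqs = [record.sequence[f.start:f.end] for f in m10s]
    for s in minus35_seqs:
        if s != MINUS35:
            violations.append(f"-35 box reads {s}, expected {MINUS35}")
    for s in minus10_seqs:
        if s not in ALLOWED_MINUS10:
            violations.append(f"-10 box reads {s}, not a known scaffold hexamer")
    if len(m35s) != len(m10s):
        violations.append(f"unpaired promoter hexamers: {len(m35s)} x -35, {len(m10s)} x -10")

    core_spacings: list[int] = []
    proximal_offsets: list[int] = []
    for f35, f10 in zip(m35s, m10s):
        if f10.start <= f35.end:
            violations.append("-10 box does not follow its -35 box")
            continue
        spacing = f10.start - f35.end
        core_spacings.append(spacing)
        inside = [o for o in ops if f35.end <= o.start < f10.start]
        if inside:
            o = inside[0]
            if o.start != f35.end or o.end != f10.start:
                violations.append(
                    f"core operator {o.label} not contiguous with promoter hexamers")
            if spacing != CORE_OPERATOR_LEN:
                violations.append(
                    f"inter-hexamer spacing is {spacing} bp, expected "
                    f"{CORE_OPERATOR_LEN} bp around a core operator")
        # first operator after this -10 and before the next -35 (if any)
        next35_start = None
        later35 = [f for f in m35s if f.start >= f10.end]
        if later35:
            next35_start = later35[0].start
        after = [o for o in ops
                 if o.start >= f10.end and (next35_start is None or o.end <= next35_start)]
        if after:
            proximal_offsets.append(after[0].start - f10.end)

    return LayoutReport(minus35_seqs=minus35_seqs, minus10_seqs=minus10_seqs,
                        core_spacings=core_spacings,
                        proximal_offsets=proximal_offsets,
                        insulators=insulators, violations=violations)
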