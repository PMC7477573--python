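"""Mutagenesis-library math and the FACS sort-plan simulator.

Library design calculators: NNS degenerate-codon site saturation (N = any
base, S = G/C: 32 codons covering all 20 amino acids with a single stop),
sampling coverage of those codons, and error-prone PCR substitution
statistics (binomial per-base model).  The sort simulator runs a labeled
mutant library through scatter gating and FITC threshold sorts — the
two-step anti-repressor discovery plan sorts low fluorescence *with* ligand
(keeping super- and anti-repressors, discarding residual repressors and
nonfunctional clones), then high fluorescence *without* ligand (separating
anti- from super-repressors), each step repeated once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from Bio.Data import CodonTable

from .synthetic_data import (
    CytometryParams,
    CytometrySample,
    ExpressionProfile,
    simulate_sort_library,
)

__all__ = [
    "SortGate",
    "SortStep",
    "SortPlan",
    "SortResult",
    "LibraryCoverage",
    "EpPcrStats",
    "nns_codon_set",
    "per_codon_coverage",
    "all_codons_coverage",
    "picks_for_coverage",
    "library_coverage",
    "ep_pcr_mutation_stats",
    "design_space_size",
    "putative_design_space",
    "singlet_mask",
    "default_fa_sort_plan",
    "run_sort_plan",
]

FITC_SORT_THRESHOLD = 1e4  # raw FITC-A units separating low/high bins
DOUBLET_RATIO_CUTOFF = 1.5  # area/height above this is discarded as a doublet


@dataclass(frozen=True)
class SortGate:
    """A one-channel threshold gate on FITC-A."""

    threshold: float = FITC_SORT_THRESHOLD
    collect: str = "low"  # low: < threshold; high: >= threshold
    channel: str = "fitc"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.collect not in ("low", "high"):
            raise ValueError("collect must be 'low' or 'high'")


@dataclass(frozen=True)
class SortStep:
    condition: frozenset
    gate: SortGate
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class SortPlan:
    steps: tuple[SortStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a sort plan needs at least one step")


@dataclass
class SortResult:
    """Genotype composition before and after each executed sort pass."""

    history: list[dict[str, float]]  # composition after each pass; [0] is initial
    survival: list[float]  # overall surviving event fraction per pass
    failed: bool = False  # True if a pass left no survivors

    @property
    def final_composition(self) -> dict[str, float]:
        return self.history[-1]


@dataclass(frozen=True)
class LibraryCoverage:
    n_codons: int
    n_picks: int
    per_codon_prob: float
    all_covered_prob: float


@dataclass
class EpPcrStats:
    """Per-clone substitution-count distribution for an EP-PCR library."""

    region_len: int
    error_rate: float
    mean: float
    variance: float
    pmf: np.ndarray  # P(k substitutions), k = 0..region_len
    expected_residues_hit: float


# --------------------------------------------------------------------------
# codon / coverage math

def nns_codon_set() -> list[tuple[str, str]]:
    """The 32 NNS codons ({A,C,G,T} x {A,C,G,T} x {G,C}) with translations.

    Standard genetic code; stops translate to ``*`` (only TAG ends in S).
    """
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    out = []
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "GC":
                codon = b1 + b2 + b3
                aa = "*" if codon in table.stop_codons else table.forward_table[codon]
                out.append((codon, aa))
    return out


def per_codon_coverage(n_picks: int, n_codons: int = 32) -> float:
    """P(one particular codon appears among ``n_picks`` equiprobable draws).

    ``1 - ((n_codons - 1)/n_codons)^n_picks``; 96 picks from 32 codons give
    the conventional 95%.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if n_picks < 0:
        raise ValueError("n_picks must be >= 0")
    return 1.0 - ((n_codons - 1) / n_codons) ** n_picks


def all_codons_coverage(n_picks: int, n_codons: int = 32) -> float:
    """P(every one of ``n_codons`` appears among ``n_picks`` draws).

    Coupon-collector inclusion-exclusion:
    ``sum_j (-1)^j C(k, j) ((k - j)/k)^n``.  Markedly below the per-codon
    probability — at 96 picks of 32 codons it is ~0.2, not 95%.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if n_picks < 0:
        raise ValueError("n_picks must be >= 0")
    if n_picks < n_codons:
        return 0.0
    k = n_codons
    total = 0.0
    for j in range(k + 1):
        total += (-1) ** j * math.comb(k, j) * ((k - j) / k) ** n_picks
    return min(max(total, 0.0), 1.0)


def picks_for_coverage(target: float, n_codons: int = 32, mode: str = "per_codon") -> int:
    """Smallest pick count whose coverage probability reaches ``target``."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie strictly between 0 and 1")
    fn = {"per_codon": per_codon_coverage, "all": all_codons_coverage}.get(mode)
    if fn is None:
        raise ValueError("mode must be 'per_codon' or 'all'")
    n = 0 if mode == "per_codon" else n_codons
    while fn(n, n_codons) < target:
        n += 1
    return n


def library_coverage(n_picks: int, n_codons: int = 32) -> LibraryCoverage:
    return LibraryCoverage(
        n_codons=n_codons, n_picks=n_picks,
        per_codon_prob=per_codon_coverage(n_picks, n_codons),
        all_covered_prob=all_codons_coverage(n_picks, n_codons),
    )


def ep_pcr_mutation_stats(region_len: int = 815, error_rate: float = 0.007) -> EpPcrStats:
    """Binomial substitution model for an error-prone PCR library.

    Per-clone substitution count ~ Binomial(region_len, error_rate): the
    defaults (~0.7% per base over an 815-bp region) give 5-7 substitutions
    per clone on average.  The residue-level estimate counts codons hit at
    least once assuming independent per-base errors.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if region_len < 1:
        raise ValueError("region_len must be >= 1")
    dist = stats.binom(region_len, error_rate)
    ks = np.arange(region_len + 1)
    n_codons = region_len // 3
    p_codon_hit = 1.0 - (1.0 - error_rate) ** 3
    return EpPcrStats(
        region_len=region_len, error_rate=error_rate,
        mean=float(dist.mean()), variance=float(dist.var()),
        pmf=dist.pmf(ks),
        expected_residues_hit=float(n_codons * p_codon_hit),
    )


def design_space_size(n_ercd: int = 8, n_adr: int = 6) -> int:
    """Putative variants from pairing engineered cores with DNA-recognition
    modules — 8 allosteric solutions x 6 modules = 48 in the base design."""
    return n_ercd * n_adr


def putative_design_space(n_core_scaffolds: int = 1000, n_dbds: int = 200) -> int:
    """The larger combinatorial space: >1000 compatible regulatory cores x
    ~200 engineered DNA-binding domains (~2 x 10^5 non-synonymous designs)."""
    return n_core_scaffolds * n_dbds


# --------------------------------------------------------------------------
# sort simulation

def singlet_mask(sample: CytometrySample,
                 ssc_threshold: float = CytometryParams.ssc_threshold,
                 doublet_ratio_cutoff: float = DOUBLET_RATIO_CUTOFF) -> np.ndarray:
    """Scatter gate: above the side-scatter threshold and not a doublet
    (FSC area/height at or below the cutoff)."""
    ev = sample.events
    return ((ev.ssc_a.to_numpy() >= ssc_threshold)
            & (ev.fsc_a.to_numpy() / ev.fsc_h.to_numpy() <= doublet_ratio_cutoff))


def _fitc_mask(sample: CytometrySample, gate: SortGate) -> np.ndarray:
    fitc = sample.events.fitc_a.to_numpy()
    return fitc < gate.threshold if gate.collect == "low" else fitc >= gate.threshold


def default_fa_sort_plan(ligand: str, repeats: int = 2) -> SortPlan:
    """The two-step anti-repressor discovery plan.

    Step 1: with ligand, collect the low-FITC bin (< 1e4) — anti- and
    super-repressors.  Step 2: without ligand, collect the high bin (>= 1e4)
    — anti-repressors only.  Each step runs ``repeats`` passes (each sort
    step repeated once to filter false positives).
    """
    return SortPlan(steps=(
        SortStep(condition=frozenset({ligand}), gate=SortGate(collect="low"),
                 repeats=repeats),
        SortStep(condition=frozenset(), gate=SortGate(collect="high"),
                 repeats=repeats),
    ))


def run_sort_plan(
    genotype_mix: Sequence[tuple[ExpressionProfile, float]],
    plan: SortPlan,
    n_events: int = 25_000,
    seed: int = 0,
    params: CytometryParams | None = None,
) -> SortResult:
    """Run a labeled library through a sequential sort plan.

    Each pass draws ``n_events`` from the current composition, applies the
    scatter (singlet) gate and the step's FITC gate, and updates the
    composition by each genotype's conditional survival rate in the drawn
    sample.  An empty surviving population marks the screen failed (no
    exception) and stops the plan.
    """
    params = params or CytometryParams()
    labels = [p.tf_id for p, _ in genotype_mix]
    if len(set(labels)) != len(labels):
        raise ValueError("genotype labels must be unique")
    comp = {p.tf_id: float(f) for p, f in genotype_mix}
    total = sum(comp.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"genotype fractions must sum to 1, got {total:.6f}")
    profiles = {p.tf_id: p for p, _ in genotype_mix}
    rng = np.random.default_rng(seed)
    history = [dict(comp)]
    survival: list[float] = []
    for step in plan.steps:
        for _ in range(step.repeats):
            mix = [(profiles[g], comp[g]) for g in labels]
            sub = int(rng.integers(0, 2**31 - 1))
            sample = simulate_sort_library(mix, step.condition, n_events=n_events,
                                           seed=sub, params=params)
            keep = singlet_mask(sample, params.ssc_threshold) & _fitc_mask(sample, step.gate)
            genotypes = sample.events.genotype.to_numpy()
            new_comp: dict[str, float] = {}
            for g in labels:
                drawn = genotypes == g
                n_drawn = int(drawn.sum())
                rate = float(keep[drawn].sum() / n_drawn) if n_drawn else 0.0
                new_comp[g] = comp[g] * rate
            mass = sum(new_comp.values())
            survival.append(float(keep.mean()))
            if mass == 0.0:
                history.append({g: 0.0 for g in labels})
                return SortResult(history=history, survival=survival, failed=True)
            comp = {g: v / mass for g, v in new_comp.items()}
            history.append(dict(comp))
    return SortResult(history=history, survival=survival, failed=False)
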