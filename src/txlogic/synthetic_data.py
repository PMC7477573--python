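"""Synthetic plate-reader and cytometry data with the replicate structure the analysis assumes.

Engineered LacI-family transcription factors (TFs) are characterized in
*E. coli* reporter assays: a TF regulates a GFP reporter through a DNA
operator placed either inside the promoter (core) or just downstream of it
(proximal), and wells are measured with and without the TF's inducer ligand.
This module generates those measurements — including the blank wells and the
``lac_null`` maximum-output control that the downstream normalization
requires — plus single-cell cytometry event tables, so every analysis stage
is testable without wet-lab data.

Phenotype vocabulary (shared across the package):

``X_plus``
    repressor — binds the operator until induced; a biological BUFFER gate.
``X_anti``
    anti-repressor — DNA affinity *increases* with ligand; a biological NOT.
``X_super``
    super-repressor — binds constitutively, output low in both states.
``X_null``
    nonfunctional — never binds, output constitutively high.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phenotype",
    "IPTG",
    "FRUCTOSE",
    "RIBOSE",
    "LIGAND_CONC_MM",
    "TFSpec",
    "ExpressionProfile",
    "NoiseModel",
    "CytometryParams",
    "SimPlate",
    "CytometrySample",
    "DEFAULT_PROFILE_PARAMS",
    "profile_from_phenotype",
    "simulate_buo_plate",
    "simulate_gate_plate",
    "simulate_cytometry",
    "simulate_sort_library",
]

#: The three inducer ligands used throughout; all at a fixed working
#: concentration (metadata only — induction is modeled as binary).
IPTG = "IPTG"
FRUCTOSE = "fructose"
RIBOSE = "d-ribose"
LIGAND_CONC_MM = 10.0

_KNOWN_LIGANDS = (IPTG, FRUCTOSE, RIBOSE)

PLATE_COLUMNS = [
    "plate_id",
    "well",
    "sample_type",
    "tf_id",
    "operator",
    "position",
    "ligands",
    "replicate",
    "od600",
    "fluorescence",
]


class Phenotype(str, enum.Enum):
    """Allosteric phenotype classes of an engineered TF."""

    X_PLUS = "X_plus"
    X_ANTI = "X_anti"
    X_SUPER = "X_super"
    X_NULL = "X_null"


@dataclass(frozen=True)
class TFSpec:
    """An engineered transcription factor.

    Parameters
    ----------
    id : str
        Free-form label, e.g. ``"RA1_HQN"``.
    rcd_ligand : str
        The inducer sensed by the regulatory core domain.
    dbd : str
        Three-letter DNA-binding-domain code (residue identities at LacI
        positions 17/18/22), e.g. ``"YQR"``.
    phenotype : Phenotype
    expression_strength : float
        Dimensionless expression multiplier: 1.0 for the constitutive LacI
        promoter, 10.0 for the stronger LacI^q promoter.
    """

    id: str
    rcd_ligand: str
    dbd: str
    phenotype: Phenotype
    expression_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.expression_strength <= 0:
            raise ValueError("expression_strength must be > 0")
        if len(self.dbd) != 3:
            raise ValueError(f"dbd code must have length 3, got {self.dbd!r}")
        object.__setattr__(self, "phenotype", Phenotype(self.phenotype))


@dataclass(frozen=True)
class ExpressionProfile:
    """Fractional reporter output of one TF/operator/position pairing.

    Levels are fractions of the maximum output (the ``lac_null`` level) in
    the two ligand states.  ``ligand`` records which inducer toggles between
    the two states.
    """

    tf_id: str
    operator: str
    position: str
    level_no_ligand: float
    level_with_ligand: float
    ligand: str = IPTG

    def __post_init__(self) -> None:
        for lv in (self.level_no_ligand, self.level_with_ligand):
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"levels must lie in [0, 1], got {lv}")
        if self.position not in ("core", "proximal"):
            raise ValueError(f"position must be 'core' or 'proximal', got {self.position!r}")

    def level(self, ligands: Iterable[str]) -> float:
        """Output level under a ligand condition (set of ligand names)."""
        return self.level_with_ligand if self.ligand in set(ligands) else self.level_no_ligand


@dataclass(frozen=True)
class NoiseModel:
    """Measurement/noise model of the plate-reader assay.

    Noise is multiplicative log-normal on both fluorescence and OD600 —
    plate-reader error scales with signal.  ``max_output`` is the raw
    fluorescence of a fully unrepressed (lac_null) culture at nominal
    density; 75,000 r.f.u. matches the observed assay ceiling.
    """

    cv_fluorescence: float = 0.05
    cv_od: float = 0.05
    blank_fluor_mean: float = 500.0
    blank_od_mean: float = 0.04
    max_output: float = 75_000.0
    od_culture_mean: float = 0.5  # mean net OD600 above blank, genotype-independent

    def __post_init__(self) -> None:
        for v in (self.cv_fluorescence, self.cv_od, self.blank_fluor_mean,
                  self.blank_od_mean, self.od_culture_mean):
            if v < 0:
                raise ValueError("noise-model parameters must be non-negative")
        if self.max_output <= self.blank_fluor_mean:
            raise ValueError("max_output must exceed blank_fluor_mean")


@dataclass(frozen=True)
class CytometryParams:
    """Single-cell fluorescence and scatter model.

    FITC is log-normal around a geometric mean ``autofluor + level * fitc_scale``
    with shape ``sigma_log`` (natural-log SD).  Forward/side scatter are drawn
    from a debris + singlet + doublet mixture so that scatter gating has work
    to do: debris falls below the side-scatter threshold, doublets double the
    area channels while keeping height, giving an area/height ratio near 2.
    """

    autofluor: float = 150.0
    fitc_scale: float = 55_000.0
    sigma_log: float = 0.3
    debris_frac: float = 0.05
    doublet_frac: float = 0.05
    ssc_threshold: float = 5_000.0


@dataclass
class SimPlate:
    """A replicate-structured microwell plate.

    ``wells`` is a tidy DataFrame with columns ``plate_id, well, sample_type
    {tf, lac_null, blank}, tf_id, operator, position, ligands
    (semicolon-joined), replicate, od600, fluorescence``.
    """

    wells: pd.DataFrame
    seed: int

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False, columns=PLATE_COLUMNS)

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "SimPlate":
        df = pd.read_csv(path, keep_default_na=False, dtype={"ligands": str})
        missing = set(PLATE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
        return cls(wells=df, seed=seed)

    def strata(self) -> list[tuple[str, str]]:
        tf = self.wells[self.wells.sample_type == "tf"]
        return sorted(set(zip(tf.operator, tf.position)))


@dataclass
class CytometrySample:
    """Single-cell events for one culture under one ligand condition.

    ``events`` columns: ``fsc_a, fsc_h, ssc_a, ssc_h, fitc_a, genotype``.
    """

    events: pd.DataFrame
    condition: frozenset
    seed: int = -1

    def to_csv(self, path) -> None:
        df = self.events.copy()
        df.insert(0, "event", np.arange(len(df)))
        df["condition"] = ";".join(sorted(self.condition))
        df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# expression profiles

#: Default cognate output levels (fractions of lac_null maximum).  These are
#: package defaults, overridable via the ``params`` argument: the source
#: assays report standardized heatmaps, not per-unit numeric levels.  The
#: core position gives tighter anti-induced leak than the proximal position
#: (direct competition with RNA polymerase), so core dynamic ranges are
#: at least as large by construction.
DEFAULT_PROFILE_PARAMS: Mapping[str, object] = {
    "on_level": 0.9,
    "anti_leak": {"proximal": 0.09, "core": 0.03},
    "super_leak": 0.03,
    "null_level": 0.95,
    "noncognate_level": 0.95,
}


def profile_from_phenotype(
    tf: TFSpec,
    operator: str,
    position: str,
    cognate: bool = True,
    params: Mapping[str, object] | None = None,
) -> ExpressionProfile:
    """Expression profile implied by a TF's phenotype at an operator/position.

    Non-cognate pairings return both levels near 1 (no regulation).  Cognate
    pairings are phenotype-consistent: an anti-repressor is high without
    ligand and low with it, a repressor the reverse, a super-repressor low in
    both states, a null high in both.
    """
    p = dict(DEFAULT_PROFILE_PARAMS)
    if params:
        p.update(params)
    if position not in ("core", "proximal"):
        raise ValueError(f"position must be 'core' or 'proximal', got {position!r}")
    phen = Phenotype(tf.phenotype)
    on = float(p["on_level"])
    if phen is Phenotype.X_NULL:
        lv = float(p["null_level"])
        levels = (lv, lv)
    elif not cognate:
        lv = float(p["noncognate_level"])
        levels = (lv, lv)
    elif phen is Phenotype.X_SUPER:
        lv = float(p["super_leak"])
        levels = (lv, lv)
    elif phen is Phenotype.X_ANTI:
        levels = (on, float(p["anti_leak"][position]))  # type: ignore[index]
    elif phen is Phenotype.X_PLUS:
        levels = (float(p["anti_leak"][position]), on)  # type: ignore[index]
    else:  # pragma: no cover - Phenotype() above rejects unknowns
        raise ValueError(f"unknown phenotype {tf.phenotype!r}")
    return ExpressionProfile(
        tf_id=tf.id,
        operator=operator,
        position=position,
        level_no_ligand=levels[0],
        level_with_ligand=levels[1],
        ligand=tf.rcd_ligand,
    )


# --------------------------------------------------------------------------
# plate simulation

def _log_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal noise with mean exactly 1."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _culture_well(rng: np.random.Generator, level: float, noise: NoiseModel):
    """Raw (od600, fluorescence) for a culture well at a fractional level.

    Fluorescence follows ``blank + level * (max - blank) * density`` where
    ``density`` is the realized net OD relative to its nominal mean, then a
    multiplicative reader error; normalizing to net OD therefore cancels the
    culture-density draw exactly.
    """
    net_od = noise.od_culture_mean * _log_factor(rng, noise.cv_od)
    od600 = noise.blank_od_mean + net_od
    signal = level * (noise.max_output - noise.blank_fluor_mean)
    fluor = noise.blank_fluor_mean + signal * (net_od / noise.od_culture_mean) \
        * _log_factor(rng, noise.cv_fluorescence)
    return od600, fluor


def _blank_well(rng: np.random.Generator, noise: NoiseModel):
    od600 = noise.blank_od_mean * _log_factor(rng, noise.cv_od)
    fluor = noise.blank_fluor_mean * _log_factor(rng, noise.cv_fluorescence)
    return od600, fluor


def _well_name(i: int) -> str:
    return f"{'ABCDEFGHIJKLMNOP'[(i // 24) % 16]}{i % 24 + 1:02d}"


def simulate_buo_plate(
    profiles: Sequence[ExpressionProfile],
    noise: NoiseModel | None = None,
    n_reps: int = 6,
    seed: int = 0,
    n_blanks: int = 6,
    plate_id: str = "BUO1",
) -> SimPlate:
    """Simulate a characterization plate for single-TF unit operations.

    Each profile gets ``n_reps`` replicate wells in each ligand state
    (characterization assays use replicates of 6), every (operator, position)
    stratum gets ``n_reps`` ``lac_null`` maximum-output control wells, and the
    plate carries blank wells.  The same seed reproduces the plate exactly.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (replicate statistics undefined)")
    if not profiles:
        raise ValueError("profiles must be non-empty")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []

    def add(sample_type, tf_id, operator, position, ligands, rep, od, fl):
        rows.append((plate_id, _well_name(len(rows)), sample_type, tf_id,
                     operator, position, ligands, rep, od, fl))

    for prof in profiles:
        for ligands, level in (("", prof.level_no_ligand),
                               (prof.ligand, prof.level_with_ligand)):
            for rep in range(n_reps):
                od, fl = _culture_well(rng, level, noise)
                add("tf", prof.tf_id, prof.operator, prof.position, ligands, rep, od, fl)
    for operator, position in sorted({(p.operator, p.position) for p in profiles}):
        for rep in range(n_reps):
            od, fl = _culture_well(rng, 1.0, noise)
            add("lac_null", "lac_null", operator, position, "", rep, od, fl)
    for rep in range(n_blanks):
        od, fl = _blank_well(rng, noise)
        add("blank", "", "", "", "", rep, od, fl)

    return SimPlate(wells=pd.DataFrame(rows, columns=PLATE_COLUMNS), seed=seed)


def simulate_gate_plate(
    circuit,
    noise: NoiseModel | None = None,
    n_reps: int = 12,
    seed: int = 0,
    n_blanks: int = 6,
    profiles=None,
    plate_id: str = "GATE1",
) -> SimPlate:
    """Simulate a logic-gate assay plate: one block per ligand subset.

    For a circuit with *k* input ligands the plate holds 2^k condition blocks
    of ``n_reps`` replicates each (gate assays use replicates of 12).  Well
    means follow the quantitative circuit composition model.
    """
    from . import logic_gates  # deferred: logic_gates imports this module

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    circuit.validate()
    inputs = circuit.inputs
    if not inputs:
        raise ValueError("circuit has no input ligands")
    if profiles is None:
        profiles = logic_gates.default_profiles(circuit)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for subset in _powerset(inputs):
        level = logic_gates.quantitative_output(circuit, subset, profiles)
        ligands = ";".join(sorted(subset))
        for rep in range(n_reps):
            od, fl = _culture_well(rng, level, noise)
            rows.append((plate_id, _well_name(len(rows)), "tf", circuit.name,
                         "", "", ligands, rep, od, fl))
    for rep in range(n_blanks):
        od, fl = _blank_well(rng, noise)
        rows.append((plate_id, _well_name(len(rows)), "blank", "", "", "", "", rep, od, fl))
    return SimPlate(wells=pd.DataFrame(rows, columns=PLATE_COLUMNS), seed=seed)


def _powerset(items: Sequence[str]) -> list[frozenset]:
    items = sorted(items)
    out = []
    for mask in range(1 << len(items)):
        out.append(frozenset(it for i, it in enumerate(items) if mask >> i & 1))
    out.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return out


# --------------------------------------------------------------------------
# cytometry simulation

def _scatter_events(rng: np.random.Generator, n: int, params: CytometryParams):
    """Draw (kind, fsc_a, fsc_h, ssc_a, ssc_h) for n events.

    kind: 0 debris, 1 singlet, 2 doublet.
    """
    kind = rng.choice(3, size=n, p=[params.debris_frac,
                                    1 - params.debris_frac - params.doublet_frac,
                                    params.doublet_frac])
    fsc_h = rng.lognormal(mean=math.log(5e4), sigma=0.25, size=n)
    ssc_h = rng.lognormal(mean=math.log(3e4), sigma=0.30, size=n)
    ratio = np.clip(rng.normal(1.0, 0.05, size=n), 0.85, None)
    fsc_a = fsc_h * ratio
    ssc_a = ssc_h * ratio
    debris = kind == 0
    fsc_h[debris] = rng.lognormal(math.log(3e3), 0.5, size=int(debris.sum()))
    ssc_h[debris] = rng.lognormal(math.log(1.5e3), 0.5, size=int(debris.sum()))
    fsc_a[debris] = fsc_h[debris] * ratio[debris]
    ssc_a[debris] = ssc_h[debris] * ratio[debris]
    doub = kind == 2
    fsc_a[doub] *= 2.0
    ssc_a[doub] *= 2.0
    return kind, fsc_a, fsc_h, ssc_a, ssc_h


def _fitc_events(rng, n, level, params: CytometryParams, kind):
    gm = params.autofluor + level * params.fitc_scale
    fitc = gm * rng.lognormal(mean=0.0, sigma=params.sigma_log, size=n)
    fitc[kind == 0] = params.autofluor * rng.lognormal(
        0.0, params.sigma_log, size=int((kind == 0).sum()))
    fitc[kind == 2] *= 2.0  # two cells' worth of signal
    return fitc


def simulate_cytometry(
    profile: ExpressionProfile,
    condition: Iterable[str] = (),
    n_events: int = 25_000,
    seed: int = 0,
    params: CytometryParams | None = None,
    genotype_label: str | None = None,
) -> CytometrySample:
    """Simulate ``n_events`` single-cell events for one culture.

    FITC is log-normal with geometric mean proportional to the profile's
    level under the condition (a level-0 profile sits at the autofluorescence
    floor).  At least 25,000 events per analysis sample is the convention.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    params = params or CytometryParams()
    condition = frozenset(condition)
    rng = np.random.default_rng(seed)
    kind, fsc_a, fsc_h, ssc_a, ssc_h = _scatter_events(rng, n_events, params)
    fitc = _fitc_events(rng, n_events, profile.level(condition), params, kind)
    events = pd.DataFrame({
        "fsc_a": fsc_a, "fsc_h": fsc_h, "ssc_a": ssc_a, "ssc_h": ssc_h,
        "fitc_a": fitc,
        "genotype": genotype_label if genotype_label is not None else profile.tf_id,
    })
    return CytometrySample(events=events, condition=condition, seed=seed)


def simulate_sort_library(
    genotype_mix: Sequence[tuple[ExpressionProfile, float]],
    condition: Iterable[str],
    n_events: int = 25_000,
    seed: int = 0,
    params: CytometryParams | None = None,
) -> CytometrySample:
    """Simulate a mixed mutant library run through the cytometer.

    ``genotype_mix`` pairs each genotype's expression profile with its
    fraction of the library (fractions must sum to 1).  Events carry the
    genotype label of the cell they came from; per-genotype FITC follows that
    genotype's profile under the sample's condition.
    """
    fracs = np.array([f for _, f in genotype_mix], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"genotype fractions must sum to 1, got {fracs.sum():.6f}")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    params = params or CytometryParams()
    condition = frozenset(condition)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, fracs)
    kind, fsc_a, fsc_h, ssc_a, ssc_h = _scatter_events(rng, n_events, params)
    fitc = np.empty(n_events)
    genotype = np.empty(n_events, dtype=object)
    start = 0
    for (prof, _), cnt in zip(genotype_mix, counts):
        sl = slice(start, start + cnt)
        fitc[sl] = _fitc_events(rng, cnt, prof.level(condition), params, kind[sl])
        genotype[sl] = prof.tf_id
        start += cnt
    order = rng.permutation(n_events)
    events = pd.DataFrame({
        "fsc_a": fsc_a[order], "fsc_h": fsc_h[order],
        "ssc_a": ssc_a[order], "ssc_h": ssc_h[order],
        "fitc_a": fitc[order], "genotype": genotype[order],
    })
    return CytometrySample(events=events, condition=condition, seed=seed)
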