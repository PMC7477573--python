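"""Plate normalization and allosteric phenotype classification.

The analysis chain mirrors the reporter-assay convention for LacI-family
regulators: blank-subtract and OD-normalize each well, standardize to the
maximum output of the matching ``lac_null`` control stratum (same operator
and operator position), then test the induced vs. uninduced replicate
vectors.  A significant difference (Welch's two-tailed t-test) calls the
regulated phenotypes — repressor ``X_plus`` if induction raises output,
anti-repressor ``X_anti`` if it lowers it.  Nonsignificant pairs split on a
50%-of-maximum rule: high output means nonfunctional ``X_null``, low output
means constitutive super-repression ``X_super``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import Phenotype, SimPlate

__all__ = [
    "NormalizedBUO",
    "PhenotypeCall",
    "ResponseMatrix",
    "normalize_plate",
    "standardize_to_max",
    "welch_two_tailed",
    "cohens_d",
    "classify_phenotype",
    "build_response_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001  # per-unit significance level for phenotype calls


@dataclass
class NormalizedBUO:
    """Standardized replicate vectors for one TF/operator/position unit.

    Values are fractions of the stratum's ``lac_null`` maximum output.
    """

    tf_id: str
    operator: str
    position: str
    s_no_ligand: np.ndarray
    s_with_ligand: np.ndarray
    reference: float  # mean normalized lac_null output used as divisor

    def __post_init__(self) -> None:
        self.s_no_ligand = np.asarray(self.s_no_ligand, dtype=float)
        self.s_with_ligand = np.asarray(self.s_with_ligand, dtype=float)
        for v in (self.s_no_ligand, self.s_with_ligand):
            if v.size < 2:
                raise ValueError("need >= 2 replicates per ligand state")
            if not np.all(np.isfinite(v)):
                raise ValueError("standardized outputs must be finite")

    @property
    def n(self) -> int:
        return min(self.s_no_ligand.size, self.s_with_ligand.size)


@dataclass
class PhenotypeCall:
    """Classification of one unit operation with its test statistics."""

    phenotype: Phenotype
    p_value: float
    cohen_d: float
    mean_levels: tuple[float, float]  # (no-ligand, with-ligand) fractions of max
    significant: bool
    alpha: float = DEFAULT_ALPHA


@dataclass
class ResponseMatrix:
    """Grid of phenotype calls over (DNA-binding domain x operator).

    Cells where the operator is cognate to the DBD form the matrix
    "diagonal"; anti-repression there is the design goal, significant
    regulation elsewhere is crosstalk.
    """

    calls: Mapping[tuple[str, str], PhenotypeCall]
    dbds: tuple[str, ...]
    operators: tuple[str, ...]
    cognate_map: Mapping[str, frozenset]
    cognate_anti_count: int = 0
    noncognate_significant_count: int = 0

    def to_frame(self) -> pd.DataFrame:
        data = {op: [self.calls[(d, op)].phenotype.value for d in self.dbds]
                for op in self.operators}
        return pd.DataFrame(data, index=list(self.dbds))


# --------------------------------------------------------------------------

def normalize_plate(plate: SimPlate | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank-subtract and OD-normalize every non-blank well.

    normalized = (fluorescence - mean blank fluorescence) / (od600 - mean blank OD)

    Negative numerators are clipped to zero.  Wells whose OD does not exceed
    the blank OD have an undefined density normalization; they are excluded
    and logged.  Returns ``(normalized wells, excluded wells)``.
    """
    df = plate.wells if isinstance(plate, SimPlate) else plate
    blanks = df[df.sample_type == "blank"]
    if blanks.empty:
        raise ValueError("plate contains no blank wells")
    blank_fluor = float(blanks.fluorescence.mean())
    blank_od = float(blanks.od600.mean())
    work = df[df.sample_type != "blank"].copy()
    denom = work.od600 - blank_od
    bad = denom <= 0
    if bad.any():
        for w in work.loc[bad, "well"]:
            logger.warning("well %s excluded: OD600 does not exceed blank OD", w)
    work = work[~bad].copy()
    numer = (work.fluorescence - blank_fluor).clip(lower=0.0)
    work["normalized"] = numer / (work.od600 - blank_od)
    return work, df[df.sample_type != "blank"][bad].copy()


def standardize_to_max(
    normalized: pd.DataFrame,
) -> tuple[list[NormalizedBUO], pd.DataFrame]:
    """Divide each well by its stratum's mean normalized ``lac_null`` output.

    Each (operator, position) stratum standardizes independently, so the
    lac_null wells of a stratum average to 1.0 by construction.  Returns the
    per-unit replicate vectors plus the standardized well table.
    """
    df = normalized.copy()
    df["standardized"] = np.nan
    buos: list[NormalizedBUO] = []
    for (operator, position), grp in df.groupby(["operator", "position"], sort=True):
        if operator == "" and position == "":
            # gate wells carry no operator stratum; leave them unstandardized
            continue
        ln = grp[grp.sample_type == "lac_null"]
        if ln.empty:
            raise ValueError(
                f"missing lac_null control in stratum (operator={operator!r}, "
                f"position={position!r})")
        ref = float(ln.normalized.mean())
        df.loc[grp.index, "standardized"] = grp.normalized / ref
        for tf_id, tgrp in grp[grp.sample_type == "tf"].groupby("tf_id", sort=True):
            s_no = (tgrp[tgrp.ligands == ""].normalized / ref).to_numpy()
            s_with = (tgrp[tgrp.ligands != ""].normalized / ref).to_numpy()
            buos.append(NormalizedBUO(tf_id, operator, position, s_no, s_with, ref))
    return buos, df


def welch_two_tailed(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed Welch (unequal-variance) t-test probability.

    Degenerate zero-variance inputs are resolved by the means: identical
    groups give p = 1, separated ones p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    # zero variance up to float roundoff: the test degenerates to comparing means
    tol = (1e-9 * max(1.0, abs(a.mean()), abs(b.mean()))) ** 2
    if a.var(ddof=1) <= tol and b.var(ddof=1) <= tol:
        return 1.0 if math.isclose(a.mean(), b.mean(), rel_tol=1e-9, abs_tol=1e-12) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """|mean difference| / pooled standard deviation.

    A zero pooled SD with unequal means returns ``inf`` (infinite-effect
    sentinel); with equal means, 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = abs(a.mean() - b.mean())
    tol = (1e-9 * max(1.0, abs(a.mean()), abs(b.mean()))) ** 2
    if pooled_var <= tol:
        return math.inf if diff > math.sqrt(tol) else 0.0
    return float(diff / math.sqrt(pooled_var))


def classify_phenotype(buo: NormalizedBUO, alpha: float = DEFAULT_ALPHA) -> PhenotypeCall:
    """Call the allosteric phenotype of one unit operation.

    Significant induced-vs-uninduced difference: higher with ligand is a
    repressor (``X_plus``), lower is an anti-repressor (``X_anti``).  No
    significant difference: pooled mean above 50% of the stratum maximum is
    nonfunctional (``X_null``), below is super-repressed (``X_super``); an
    exact 50% tie is called ``X_null`` (conservative — avoids claiming
    super-repression on a knife edge).
    """
    p = welch_two_tailed(buo.s_no_ligand, buo.s_with_ligand)
    d = cohens_d(buo.s_no_ligand, buo.s_with_ligand)
    m_no = float(buo.s_no_ligand.mean())
    m_with = float(buo.s_with_ligand.mean())
    significant = p < alpha
    if significant:
        phen = Phenotype.X_PLUS if m_with > m_no else Phenotype.X_ANTI
    else:
        pooled = float(np.concatenate([buo.s_no_ligand, buo.s_with_ligand]).mean())
        phen = Phenotype.X_NULL if pooled >= 0.5 else Phenotype.X_SUPER
    return PhenotypeCall(phenotype=phen, p_value=p, cohen_d=d,
                         mean_levels=(m_no, m_with), significant=significant,
                         alpha=alpha)


def build_response_matrix(
    calls: Mapping[tuple[str, str], PhenotypeCall],
    cognate_map: Mapping[str, frozenset | set | tuple],
) -> ResponseMatrix:
    """Assemble per-(DBD, operator) calls into a response matrix.

    The call set must cover the complete grid of the DBDs and operators it
    mentions; cognate cells are those where the operator belongs to the
    DBD's cognate set.  Summary counts tally cognate anti-repressor hits and
    significant non-cognate (crosstalk) interactions.
    """
    dbds = tuple(sorted({d for d, _ in calls}))
    operators = tuple(sorted({o for _, o in calls}))
    missing = [(d, o) for d in dbds for o in operators if (d, o) not in calls]
    if missing:
        raise ValueError(f"incomplete response grid; missing cells: {missing}")
    cmap = {d: frozenset(ops) for d, ops in cognate_map.items()}
    cognate_anti = 0
    noncognate_sig = 0
    for (d, o), call in calls.items():
        cognate = o in cmap.get(d, frozenset())
        if cognate and call.significant and call.phenotype is Phenotype.X_ANTI:
            cognate_anti += 1
        if not cognate and call.significant:
            noncognate_sig += 1
    return ResponseMatrix(calls=dict(calls), dbds=dbds, operators=operators,
                          cognate_map=cmap, cognate_anti_count=cognate_anti,
                          noncognate_significant_count=noncognate_sig)
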