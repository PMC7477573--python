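"""Performance cards, traceability scores, and compatibility metrology.

A characterized unit operation gets a *performance card*: its standardized
ON/OFF levels (fractions of maximum output, F.M.O.), dynamic range (fold
induction for a repressor/BUFFER, fold anti-induction for an
anti-repressor/NOT), and repression strength.  Cards are compared to the
wild-type LacI reference unit (I+_YQR | O1, proximal) through *traceability
scores* — the card's metric divided by the reference's, so the reference
scores exactly 1.0 against itself.  Fold-change traceability is expressed in
anti-induction units (AIU) for a NOT unit and induction units (IU) for a
BUFFER; repression-strength traceability in repression units (RU).

The raw-unit formulas are this package's definitions (no standardized
expressions exist for these units): raw AIU/IU is the fold change itself,
and raw RU is the max-relative attenuation of the no-ligand state,
``RU = 1 / s_no_ligand``.  Under these definitions RU approaches AIU
exactly as a NOT unit's ON state is attenuated toward super-repression,
which is what the compatibility proximity rule probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenotyping import NormalizedBUO, PhenotypeCall
from .synthetic_data import Phenotype

__all__ = [
    "PerformanceCard",
    "CompatibilityReport",
    "AssayConcordance",
    "FOLD_FLOOR",
    "performance_card",
    "cards_to_frame",
    "traceability_scores",
    "pairing_compatibility",
    "rank_vs_reference",
    "assay_concordance",
]

#: Denominator floor for fold changes, in fraction-of-maximum units
#: (approximately the assay detection limit).  Applied (and flagged on the
#: card) whenever an OFF or ON state underflows it.
FOLD_FLOOR = 0.005


@dataclass
class PerformanceCard:
    """Standardized performance summary of one unit operation."""

    buo_id: tuple[str, str, str]  # (tf_id, operator, position)
    phenotype: Phenotype
    s_on: tuple[float, float]  # (mean, sd) standardized ON level
    s_off: tuple[float, float]
    fmo_on: float
    fmo_off: float
    dynamic_range: float | None  # fold change; None for X_super / X_null cards
    repression_strength: float  # raw RU = 1 / s_no_ligand (floored)
    aiu_or_iu_raw: float | None  # raw fold units: AIU for X_anti, IU for X_plus
    ru_raw: float
    floored: bool = False
    traceability_dr: float | None = None
    traceability_ru: float | None = None

    @property
    def has_fold_metrics(self) -> bool:
        return self.dynamic_range is not None

    def to_dict(self) -> dict:
        return {
            "tf_id": self.buo_id[0], "operator": self.buo_id[1],
            "position": self.buo_id[2], "phenotype": self.phenotype.value,
            "s_on_mean": self.s_on[0], "s_on_sd": self.s_on[1],
            "s_off_mean": self.s_off[0], "s_off_sd": self.s_off[1],
            "fmo_on": self.fmo_on, "fmo_off": self.fmo_off,
            "dynamic_range": self.dynamic_range,
            "repression_strength": self.repression_strength,
            "aiu_or_iu_raw": self.aiu_or_iu_raw, "ru_raw": self.ru_raw,
            "floored": self.floored,
            "traceability_dr": self.traceability_dr,
            "traceability_ru": self.traceability_ru,
        }


@dataclass
class CompatibilityReport:
    """Pairing verdict for two unit operations in one circuit."""

    pair: tuple[tuple[str, str, str], tuple[str, str, str]]
    ru_ratio: float
    proximity_flag: bool
    verdict: str  # compatible | caution | incompatible


@dataclass
class AssayConcordance:
    """Linear agreement between plate-level and single-cell summaries."""

    pairs: pd.DataFrame  # columns: plate, cytometry
    slope: float
    intercept: float
    r_squared: float


# --------------------------------------------------------------------------

def performance_card(
    buo: NormalizedBUO,
    phenotype: PhenotypeCall,
    max_output: float = 75_000.0,
) -> PerformanceCard:
    """Build the performance card for one unit operation.

    The ON state is assigned by phenotype (no-ligand for an anti-repressor,
    with-ligand for a repressor); fold metrics are defined only for those two
    regulated phenotypes — super-repressor and null cards carry levels only.
    ``max_output`` records the raw ceiling the F.M.O. scale refers to.
    """
    phen = Phenotype(phenotype.phenotype)
    m_no, s_no_sd = float(buo.s_no_ligand.mean()), float(buo.s_no_ligand.std(ddof=1))
    m_with, s_with_sd = float(buo.s_with_ligand.mean()), float(buo.s_with_ligand.std(ddof=1))
    if phen is Phenotype.X_PLUS:
        on, off = (m_with, s_with_sd), (m_no, s_no_sd)
    else:
        # anti-repressor ON is the uninduced state; degenerate phenotypes
        # order by magnitude so "ON" is just the higher state
        if phen is Phenotype.X_ANTI or m_no >= m_with:
            on, off = (m_no, s_no_sd), (m_with, s_with_sd)
        else:
            on, off = (m_with, s_with_sd), (m_no, s_no_sd)
    floored = off[0] < FOLD_FLOOR or m_no < FOLD_FLOOR
    if phen in (Phenotype.X_PLUS, Phenotype.X_ANTI):
        dr = on[0] / max(off[0], FOLD_FLOOR)
        aiu_or_iu = dr
    else:
        dr = None
        aiu_or_iu = None
    ru = 1.0 / max(m_no, FOLD_FLOOR)
    return PerformanceCard(
        buo_id=(buo.tf_id, buo.operator, buo.position),
        phenotype=phen, s_on=on, s_off=off,
        fmo_on=on[0], fmo_off=off[0],
        dynamic_range=dr, repression_strength=ru,
        aiu_or_iu_raw=aiu_or_iu, ru_raw=ru, floored=floored,
    )


def cards_to_frame(cards: Sequence[PerformanceCard]) -> pd.DataFrame:
    """Flat card table (one row per unit operation) for CSV/JSON export."""
    return pd.DataFrame([c.to_dict() for c in cards])


def traceability_scores(
    card: PerformanceCard, reference: PerformanceCard
) -> tuple[float, float]:
    """Traceability of a card against the reference unit operation.

    Returns ``(traceability_dr, traceability_ru)`` — the fold-change ratio
    (AIU for a NOT card, IU for a BUFFER) and the repression-strength ratio.
    The reference against itself scores exactly (1.0, 1.0).
    """
    if reference.phenotype is not Phenotype.X_PLUS:
        raise ValueError("reference must be a BUFFER (X_plus) unit operation")
    if not reference.has_fold_metrics or reference.dynamic_range <= 0:
        raise ValueError("reference dynamic range must be positive")
    if not card.has_fold_metrics:
        raise ValueError("card carries no fold metrics (X_super / X_null)")
    t_dr = card.dynamic_range / reference.dynamic_range
    t_ru = card.repression_strength / reference.repression_strength
    card.traceability_dr = t_dr
    card.traceability_ru = t_ru
    return t_dr, t_ru


def pairing_compatibility(
    a: PerformanceCard,
    b: PerformanceCard,
    ru_fold_threshold: float = 10.0,
    proximity_threshold: float = 1.5,
    dr_threshold: float = 5.0,
) -> CompatibilityReport:
    """Judge whether two unit operations can be paired in one circuit.

    Units whose repression strengths differ by ~10-fold or more are
    incompatible: the stronger unit nullifies the weaker one's contribution.
    Short of that, a unit whose raw fold units and repression units sit in
    proximity (|AIU - RU| below ~1.5) while its dynamic range is >= 5 earns a
    caution — its ON state is already attenuated toward super-repression.
    """
    if not (a.has_fold_metrics and b.has_fold_metrics):
        raise ValueError("both cards must carry fold metrics")
    ru_ratio = max(a.ru_raw, b.ru_raw) / min(a.ru_raw, b.ru_raw)
    proximity = any(
        abs(c.aiu_or_iu_raw - c.ru_raw) < proximity_threshold
        and c.dynamic_range >= dr_threshold
        for c in (a, b)
    )
    if ru_ratio >= ru_fold_threshold:
        verdict = "incompatible"
    elif proximity:
        verdict = "caution"
    else:
        verdict = "compatible"
    return CompatibilityReport(pair=(a.buo_id, b.buo_id), ru_ratio=float(ru_ratio),
                               proximity_flag=bool(proximity), verdict=verdict)


def rank_vs_reference(
    cards: Sequence[PerformanceCard], reference: PerformanceCard
) -> tuple[dict[str, int], pd.DataFrame]:
    """Rank cards against the reference dynamic range.

    Returns per-position counts of cards whose dynamic range is at least the
    reference's, and the full table ordered by dynamic range descending
    (ties broken by unit id, deterministically).
    """
    if not cards:
        raise ValueError("cards must be non-empty")
    if not reference.has_fold_metrics:
        raise ValueError("reference carries no fold metrics")
    rows = [
        {
            "tf_id": c.buo_id[0], "operator": c.buo_id[1], "position": c.buo_id[2],
            "phenotype": c.phenotype.value,
            "dynamic_range": c.dynamic_range if c.has_fold_metrics else np.nan,
            "ru_raw": c.ru_raw,
            "at_or_above_reference": bool(
                c.has_fold_metrics and c.dynamic_range >= reference.dynamic_range),
        }
        for c in cards
    ]
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["dynamic_range", "tf_id", "operator", "position"],
        ascending=[False, True, True, True], na_position="last",
    ).reset_index(drop=True)
    counts = (
        table[table.at_or_above_reference]
        .groupby("position").size().to_dict()
    )
    for pos in ("core", "proximal"):
        counts.setdefault(pos, 0)
    return counts, table


def assay_concordance(
    plate_values: Sequence[float], cytometry_values: Sequence[float]
) -> AssayConcordance:
    """Ordinary least squares between matched plate and cytometry summaries.

    ``plate_values`` are standardized plate means and ``cytometry_values``
    the matching single-cell geometric means (log-normal populations are
    summarized geometrically).  Requires >= 3 matched pairs.
    """
    x = np.asarray(plate_values, dtype=float)
    y = np.asarray(cytometry_values, dtype=float)
    if x.size != y.size:
        raise ValueError("plate and cytometry summaries must be matched 1:1")
    if x.size < 3:
        raise ValueError("need >= 3 matched pairs for a concordance fit")
    fit = stats.linregress(x, y)
    return AssayConcordance(
        pairs=pd.DataFrame({"plate": x, "cytometry": y}),
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
    )
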