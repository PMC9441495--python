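"""Severity classification of at-risk couples and the decision analysis.

At-risk couples (ARCs) are tiered by the highest-ranked severity among their
at-risk genes.  The decision analysis asks whether couples facing a
profound/severe condition take preventive measures (PGT-M, gamete donation,
pregnancy termination — aggregated here) more often than couples facing a
moderate/mild condition, via an uncorrected Pearson chi-square test on the
2x2 table {profound/severe, moderate/mild} x {measures taken, no measures}.

Couples lost to follow-up are pooled into the no-measures column of the 2x2
(they demonstrably took no targeted measure through the programme); the
three-way taken / none / lost split is reported separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats as _scipy_stats

from .carrier_stats import round_half_up
from .cohort_io import Decision
from .panel_model import (
    GenePanelEntry,
    Severity,
    ValidationError,
    severity_rank,
)
from .screening_rules import ARCResult

__all__ = [
    "Contingency2x2",
    "Chi2Result",
    "couple_severity",
    "severity_counts",
    "decision_table",
    "three_way_decision_split",
    "pearson_chi2_2x2",
    "measures_taken_rate",
]

HIGH_TIERS = (Severity.PROFOUND, Severity.SEVERE)
LOW_TIERS = (Severity.MODERATE, Severity.MILD)


@dataclass(frozen=True)
class Contingency2x2:
    """Rows: severity group {profound/severe, moderate/mild}; columns:
    {measures taken, no measures}."""

    a: int  # profound/severe, measures taken
    b: int  # profound/severe, no measures
    c: int  # moderate/mild, measures taken
    d: int  # moderate/mild, no measures

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def couple_severity(arc: ARCResult, panel: Sequence[GenePanelEntry]) -> Severity:
    """Couple-level tier: the highest-ranked tier among the at-risk genes.

    Raises when any at-risk gene is unclassified — supply a severity-override
    config for the gene instead of silently tiering it.
    """
    by_gene = {g.symbol: g for g in panel}
    tiers = []
    for risk in arc.at_risk_genes:
        entry = by_gene.get(risk.gene)
        if entry is None:
            raise ValidationError(f"couple {arc.couple_id}: gene {risk.gene} "
                                  "is not on the panel")
        if entry.severity is Severity.UNCLASSIFIED:
            raise ValidationError(
                f"couple {arc.couple_id}: gene {risk.gene} has no severity tier; "
                "add it to the severity-override config or exclude it"
            )
        tiers.append(entry.severity)
    return max(tiers, key=severity_rank)


def severity_counts(arcs: Sequence[ARCResult]) -> dict[Severity, int]:
    """Pair counts per tier over all four named tiers; sums to len(arcs)."""
    counts: Counter[Severity] = Counter()
    for arc in arcs:
        if arc.severity is None or arc.severity is Severity.UNCLASSIFIED:
            raise ValidationError(
                f"couple {arc.couple_id} is untiered; resolve severity first"
            )
        counts[arc.severity] += 1
    return {t: counts.get(t, 0)
            for t in (Severity.PROFOUND, Severity.SEVERE,
                      Severity.MODERATE, Severity.MILD)}


def _decision_for(arc: ARCResult, decisions: Mapping[str, Decision]) -> Decision:
    d = decisions.get(arc.couple_id, Decision.NA)
    if d is Decision.NA:
        raise ValidationError(
            f"at-risk couple {arc.couple_id} has no decision record"
        )
    return Decision(d)


def decision_table(arcs: Sequence[ARCResult],
                   decisions: Mapping[str, Decision]) -> Contingency2x2:
    """Collapse ARCs into the severity-group x decision 2x2 table.

    Lost-to-follow-up couples land in the no-measures column; an ARC without
    a decision record raises.
    """
    a = b = c = d = 0
    for arc in arcs:
        if arc.severity is None or arc.severity is Severity.UNCLASSIFIED:
            raise ValidationError(
                f"couple {arc.couple_id} is untiered; resolve severity first"
            )
        dec = _decision_for(arc, decisions)
        high = arc.severity in HIGH_TIERS
        taken = dec is Decision.MEASURES_TAKEN
        if high and taken:
            a += 1
        elif high:
            b += 1
        elif taken:
            c += 1
        else:
            d += 1
    return Contingency2x2(a, b, c, d)


def three_way_decision_split(arcs: Sequence[ARCResult],
                             decisions: Mapping[str, Decision],
                             ) -> tuple[int, int, int]:
    """(measures taken, no measures, lost to follow-up) over all ARCs."""
    taken = none = lost = 0
    for arc in arcs:
        dec = _decision_for(arc, decisions)
        if dec is Decision.MEASURES_TAKEN:
            taken += 1
        elif dec is Decision.LOST_TO_FOLLOWUP:
            lost += 1
        else:
            none += 1
    return taken, none, lost


def pearson_chi2_2x2(t: Contingency2x2) -> Chi2Result:
    """Uncorrected Pearson chi-square on a 2x2 table, df = 1.

    No Yates continuity correction is applied.  Expected cells come from the
    row x column marginals; a zero marginal leaves the statistic undefined
    and raises.
    """
    if t.total <= 0:
        raise ValidationError("chi-square undefined on an empty table")
    row1, row2 = t.a + t.b, t.c + t.d
    col1, col2 = t.a + t.c, t.b + t.d
    if min(row1, row2, col1, col2) == 0:
        raise ValidationError("chi-square undefined: a table marginal is zero")
    res = _scipy_stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)
    return Chi2Result(statistic=float(res.statistic), df=int(res.dof),
                      p_value=float(res.pvalue))


def measures_taken_rate(arcs: Sequence[ARCResult],
                        decisions: Mapping[str, Decision],
                        ) -> tuple[float, int, int]:
    """Fraction of ARCs that took targeted measures.

    Denominator is all ARCs including lost-to-follow-up; returns
    ``(fraction, n_taken, n_total)``.  Display at 2 dp.
    """
    if not arcs:
        return 0.0, 0, 0
    taken = sum(
        _decision_for(arc, decisions) is Decision.MEASURES_TAKEN for arc in arcs
    )
    return taken / len(arcs), taken, len(arcs)
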