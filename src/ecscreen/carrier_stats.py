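"""Aggregate carrier statistics over a screened cohort.

Conventions (chosen to match how clinical ECS programmes report):

* A *reportable* carrier variant is P/LP in an autosomal-recessive or
  X-linked panel gene and not phenotype-related (variants explaining the
  individual's own symptoms are diagnostic findings, not carrier status).
  Autosomal-dominant P/LP variants feed the secondary-findings channel and
  never count toward carrier statistics.
* The denominator for every carrier frequency is the full screened cohort —
  both sexes, including for X-linked genes.
* A homozygote counts once as a carrier of the gene but contributes two to
  the allele count of the variant.
* Display rounding: 2 dp for percentage frequencies, 1 dp for the positive
  rate, nearest integer ("1 in N", half away from zero) for variant rates;
  internal values are unrounded.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cohort_io import Individual, Zygosity
from .panel_model import GenePanelEntry, Inheritance, ValidationError

__all__ = [
    "CohortStats",
    "round_half_up",
    "is_reportable",
    "positive_carrier_rate",
    "gene_carrier_frequency",
    "one_in_n",
    "gene_detection_summary",
    "burden_distribution",
    "cohort_stats",
]


def round_half_up(x: float, nd: int = 0) -> float:
    """Round half away from zero at ``nd`` decimals (display convention)."""
    scale = 10 ** nd
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def is_reportable(variant, entry: GenePanelEntry | None) -> bool:
    """Reportable carrier variant: P/LP, AR or XL gene, not phenotype-related."""
    return (
        entry is not None
        and entry.inheritance in (Inheritance.AR, Inheritance.XL)
        and variant.acmg_class.is_plp
        and not variant.phenotype_related
    )


def _by_gene(panel: Sequence[GenePanelEntry]) -> dict[str, GenePanelEntry]:
    return {g.symbol: g for g in panel}


def positive_carrier_rate(individuals: Sequence[Individual],
                          panel: Sequence[GenePanelEntry],
                          ) -> tuple[float, int, int]:
    """Fraction of individuals carrying at least one reportable variant.

    Returns ``(fraction, n_positive, n_individuals)``.  VUS and AD-gene
    variants do not make a positive carrier.  Raises on an empty cohort.
    """
    if not individuals:
        raise ValidationError("positive carrier rate undefined on an empty cohort")
    gene_map = _by_gene(panel)
    n_pos = sum(
        any(is_reportable(v, gene_map.get(v.gene)) for v in ind.variants)
        for ind in individuals
    )
    return n_pos / len(individuals), n_pos, len(individuals)


def gene_carrier_frequency(individuals: Sequence[Individual],
                           panel: Sequence[GenePanelEntry],
                           gene: str) -> float:
    """Carrier frequency of one gene: distinct individuals with >=1
    reportable variant in it (het/hom count once) over the whole cohort."""
    gene_map = _by_gene(panel)
    if gene not in gene_map:
        raise ValidationError(f"gene {gene!r} is not on the panel")
    if not individuals:
        raise ValidationError("carrier frequency undefined on an empty cohort")
    entry = gene_map[gene]
    carriers = sum(
        any(v.gene == gene and is_reportable(v, entry) for v in ind.variants)
        for ind in individuals
    )
    return carriers / len(individuals)


def one_in_n(allele_count: int, n_individuals: int) -> int:
    """Variant rate expressed as "1 in N": round(n/count), half away from zero."""
    if allele_count < 1:
        raise ValidationError("allele_count must be >= 1")
    return int(math.floor(n_individuals / allele_count + 0.5))


def gene_detection_summary(individuals: Sequence[Individual],
                           panel: Sequence[GenePanelEntry],
                           ) -> tuple[int, int, int, int]:
    """(n_AR_detected, n_AR_recurrent, n_XL_detected, n_XL_recurrent).

    A gene is detected when at least one individual carries a reportable
    variant in it, recurrent when at least two do.
    """
    gene_map = _by_gene(panel)
    carriers: Counter[str] = Counter()
    for ind in individuals:
        genes = {
            v.gene for v in ind.variants if is_reportable(v, gene_map.get(v.gene))
        }
        carriers.update(genes)
    n_ar = n_ar_rec = n_xl = n_xl_rec = 0
    for gene, k in carriers.items():
        if gene_map[gene].inheritance is Inheritance.AR:
            n_ar += 1
            n_ar_rec += k >= 2
        else:
            n_xl += 1
            n_xl_rec += k >= 2
    return n_ar, n_ar_rec, n_xl, n_xl_rec


def burden_distribution(individuals: Sequence[Individual],
                        panel: Sequence[GenePanelEntry]) -> dict[int, int]:
    """Histogram of reportable-variant count per individual; the values sum
    to the cohort size."""
    gene_map = _by_gene(panel)
    hist: Counter[int] = Counter()
    for ind in individuals:
        k = sum(is_reportable(v, gene_map.get(v.gene)) for v in ind.variants)
        hist[k] += 1
    return dict(sorted(hist.items()))


@dataclass
class CohortStats:
    """Aggregate tables for one cohort.

    ``gene_table`` is indexed by gene symbol with columns inheritance,
    positive_count, carrier_frequency (fraction) and carrier_frequency_pct
    (2 dp); ``variant_table`` is indexed by (gene, hgvs_c) with allele_count
    and one_in_n; ``burden_hist`` maps reportable-variant count to number of
    individuals.
    """

    n_individuals: int
    n_positive: int
    gene_table: pd.DataFrame
    variant_table: pd.DataFrame
    burden_hist: dict[int, int]

    @property
    def positive_rate(self) -> float:
        return self.n_positive / self.n_individuals

    @property
    def positive_rate_pct(self) -> float:
        return round_half_up(100.0 * self.positive_rate, 1)


def cohort_stats(individuals: Sequence[Individual],
                 panel: Sequence[GenePanelEntry]) -> CohortStats:
    """Compute the full aggregate-statistics bundle in one pass."""
    if not individuals:
        raise ValidationError("cohort statistics undefined on an empty cohort")
    gene_map = _by_gene(panel)
    n = len(individuals)

    gene_carriers: Counter[str] = Counter()
    allele_counts: Counter[tuple[str, str]] = Counter()
    hist: Counter[int] = Counter()
    n_positive = 0
    for ind in individuals:
        genes: set[str] = set()
        k = 0
        for v in ind.variants:
            if not is_reportable(v, gene_map.get(v.gene)):
                continue
            k += 1
            genes.add(v.gene)
            allele_counts[(v.gene, v.hgvs_c)] += 2 if v.zygosity is Zygosity.HOM else 1
        gene_carriers.update(genes)
        hist[k] += 1
        n_positive += bool(genes)

    gene_rows = []
    for entry in panel:
        if entry.inheritance is Inheritance.AD:
            continue
        count = gene_carriers.get(entry.symbol, 0)
        freq = count / n
        gene_rows.append({
            "gene": entry.symbol,
            "inheritance": entry.inheritance.value,
            "positive_count": count,
            "carrier_frequency": freq,
            "carrier_frequency_pct": round_half_up(100.0 * freq, 2),
        })
    gene_table = (
        pd.DataFrame(gene_rows, columns=["gene", "inheritance", "positive_count",
                                         "carrier_frequency", "carrier_frequency_pct"])
        .sort_values(["positive_count", "gene"], ascending=[False, True])
        .set_index("gene")
    )

    var_rows = [
        {
            "gene": gene,
            "hgvs_c": hgvs,
            "allele_count": count,
            "one_in_n": one_in_n(count, n),
        }
        for (gene, hgvs), count in allele_counts.items()
    ]
    variant_table = (
        pd.DataFrame(var_rows, columns=["gene", "hgvs_c", "allele_count", "one_in_n"])
        .sort_values(["allele_count", "gene", "hgvs_c"], ascending=[False, True, True])
        .set_index(["gene", "hgvs_c"])
    )

    return CohortStats(
        n_individuals=n,
        n_positive=n_positive,
        gene_table=gene_table,
        variant_table=variant_table,
        burden_hist=dict(sorted(hist.items())),
    )
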