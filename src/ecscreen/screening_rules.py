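"""Core screening decision logic.

Four stages operate on a triaged cohort:

1. **Phenotype triage** — variants whose gene matches the individual's own
   reported phenotypes are diagnostic candidates and are excluded from
   carrier statistics and secondary findings.
2. **Individual diagnosis** — a diagnostic-candidate genotype consistent with
   the gene's inheritance mode (biallelic for AR, heterozygous for AD,
   hemizygous for XL males) yields a diagnosis; a fitting genotype without a
   matching phenotype is flagged as a penetrance observation instead.
3. **At-risk-couple (ARC) calling** — per gene, a couple is at risk when
   (a) both partners carry a P/LP variant of the same autosomal recessive
   gene, (b) the female partner carries a P/LP variant in an X-linked gene,
   (c) one partner carries P/LP and the other a VUS of the same gene, or
   (d) both carry a VUS of the same gene.  Rules involving a VUS require
   supporting evidence: confirmed segregation in a proband, or an in-silico
   consensus that every involved VUS is deleterious.
4. **Secondary findings** — P/LP variants in autosomal-dominant genes that
   are unrelated to the individual's phenotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort_io import ClassifiedVariant, Couple, Individual, Zygosity
from .panel_model import (
    AcmgClass,
    GenePanelEntry,
    Inheritance,
    PredictorScores,
    Severity,
    ValidationError,
    severity_rank,
)

__all__ = [
    "Consensus",
    "ArcRule",
    "DiagnosisResult",
    "GeneRisk",
    "ARCResult",
    "SecondaryFinding",
    "triage_phenotype_related",
    "diagnose_individual",
    "in_silico_consensus",
    "call_arc",
    "detect_secondary_findings",
    "arc_rate_by_subgroup",
    "sf_gene_summary",
    "penetrance_estimate",
    "load_sf_gene_list",
    "load_phenotype_map",
]


class Consensus(str, Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    INDETERMINATE = "indeterminate"


class ArcRule(str, Enum):
    BOTH_PLP_AR = "both_PLP_AR"
    FEMALE_PLP_XL = "female_PLP_XL"
    PLP_PLUS_VUS = "PLP_plus_VUS"
    BOTH_VUS = "both_VUS"


@dataclass
class DiagnosisResult:
    """Genotype/phenotype assessment of one gene in one individual.

    ``diagnosed`` requires both a fitting genotype and a phenotype match;
    a fitting genotype without the phenotype sets ``penetrance_note``.
    Two heterozygous P/LP variants in an AR gene have unknown phase and are
    flagged ``phase_unconfirmed`` rather than silently called biallelic.
    """

    individual_id: str
    gene: str
    pattern: str  # biallelic / potentially_biallelic / het-AD / hemi-XL
    diagnosed: bool
    penetrance_note: bool = False
    phase_unconfirmed: bool = False


@dataclass
class GeneRisk:
    gene: str
    rule: ArcRule
    female_class: AcmgClass | None
    male_class: AcmgClass | None
    evidence: str = ""  # proband / in_silico / "" for pure P-LP rules


@dataclass
class ARCResult:
    couple_id: str
    at_risk_genes: list[GeneRisk]
    severity: Severity | None = None
    vus_involved: bool = False


@dataclass
class SecondaryFinding:
    individual_id: str
    gene: str
    variant: ClassifiedVariant
    acmg_sf_listed: bool


# ---------------------------------------------------------------------------
# Phenotype triage
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")
# generic words that would over-match across unrelated disease names
_STOPWORDS = {"related", "type", "syndrome", "disease", "disorder"}


def _tokens(text: str) -> set[str]:
    return {t for t in _TOKEN_RE.findall(text.lower()) if t not in _STOPWORDS}


def _phenotype_matches(individual: Individual, entry: GenePanelEntry,
                       mapping: Mapping[str, set[str]] | None) -> bool:
    if not individual.phenotypes:
        return False
    pheno_tokens: set[str] = set()
    norm_terms: set[str] = set()
    for term in individual.phenotypes:
        norm_terms.add(term.strip().lower())
        pheno_tokens |= _tokens(term)
    if pheno_tokens & _tokens(entry.disease):
        return True
    if mapping and entry.symbol in mapping:
        mapped = mapping[entry.symbol]
        if norm_terms & mapped:
            return True
        mapped_tokens: set[str] = set()
        for term in mapped:
            mapped_tokens |= _tokens(term)
        if pheno_tokens & mapped_tokens:
            return True
    return False


def triage_phenotype_related(
    individual: Individual,
    panel: Sequence[GenePanelEntry],
    mapping: Mapping[str, set[str]] | None = None,
) -> tuple[list[ClassifiedVariant], list[ClassifiedVariant]]:
    """Partition an individual's variants into diagnostic candidates and the
    carrier set, setting ``phenotype_related`` on each variant.

    A variant is a diagnostic candidate iff its gene's disease name shares at
    least one (non-generic) token with one of the individual's phenotype
    terms, or an explicit gene-to-phenotype mapping entry matches.
    """
    by_gene = {g.symbol: g for g in panel}
    diagnostic: list[ClassifiedVariant] = []
    carrier: list[ClassifiedVariant] = []
    for v in individual.variants:
        entry = by_gene.get(v.gene)
        related = entry is not None and _phenotype_matches(individual, entry, mapping)
        v.phenotype_related = related
        (diagnostic if related else carrier).append(v)
    return diagnostic, carrier


def load_phenotype_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV (gene symbol, phenotype term) mapping file."""
    from pathlib import Path

    out: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cells = raw.split("\t")
        if len(cells) < 2 or cells[0].strip().lower() == "symbol":
            continue
        out.setdefault(cells[0].strip(), set()).add(cells[1].strip().lower())
    return out


# ---------------------------------------------------------------------------
# Individual diagnosis
# ---------------------------------------------------------------------------

def diagnose_individual(
    individual: Individual,
    panel: Sequence[GenePanelEntry],
    mapping: Mapping[str, set[str]] | None = None,
) -> list[DiagnosisResult]:
    """Assess every gene with a diagnosis-consistent genotype.

    Genotype patterns: AR — homozygous P/LP (``biallelic``) or two or more
    distinct heterozygous P/LP variants (``potentially_biallelic``, phase
    unconfirmed); AD — any P/LP (``het-AD``); XL male — hemizygous P/LP
    (``hemi-XL``).  ``diagnosed`` additionally requires a phenotype match;
    otherwise the result carries ``penetrance_note`` (genotype-positive,
    phenotype-negative).  Heterozygous XL carriage in a female is a carrier
    event, not a diagnosis.
    """
    by_gene = {g.symbol: g for g in panel}
    results: list[DiagnosisResult] = []
    plp_by_gene: dict[str, list[ClassifiedVariant]] = {}
    for v in individual.variants:
        if v.acmg_class.is_plp and v.gene in by_gene:
            plp_by_gene.setdefault(v.gene, []).append(v)
    for gene, variants in plp_by_gene.items():
        entry = by_gene[gene]
        pattern: str | None = None
        phase_unconfirmed = False
        if entry.inheritance is Inheritance.AR:
            if any(v.zygosity is Zygosity.HOM for v in variants):
                pattern = "biallelic"
            elif len(variants) >= 2:
                pattern = "potentially_biallelic"
                phase_unconfirmed = True
        elif entry.inheritance is Inheritance.AD:
            pattern = "het-AD"
        elif entry.inheritance is Inheritance.XL and individual.sex == "M":
            if any(v.zygosity in (Zygosity.HEMI, Zygosity.HOM) for v in variants):
                pattern = "hemi-XL"
        if pattern is None:
            continue
        matched = _phenotype_matches(individual, entry, mapping)
        results.append(DiagnosisResult(
            individual_id=individual.id,
            gene=gene,
            pattern=pattern,
            diagnosed=matched,
            penetrance_note=not matched,
            phase_unconfirmed=phase_unconfirmed,
        ))
    return results


def penetrance_estimate(diagnoses: Iterable[DiagnosisResult],
                        gene: str) -> tuple[float, int, int]:
    """Penetrant fraction among genotype-positive individuals for one gene.

    Returns ``(fraction, n_affected, n_genotype_positive)`` where affected
    means phenotype-matched (diagnosed) and the denominator includes the
    penetrance-note (phenotype-negative) observations.
    """
    hits = [d for d in diagnoses if d.gene == gene]
    n = len(hits)
    if n == 0:
        raise ValidationError(f"no genotype-positive individuals for {gene}")
    affected = sum(d.diagnosed for d in hits)
    return affected / n, affected, n


# ---------------------------------------------------------------------------
# In-silico consensus
# ---------------------------------------------------------------------------

# published tool cutoffs: SIFT < 0.05 deleterious; PolyPhen-2 >= 0.909
# probably damaging, 0.447-0.909 possibly damaging (both treated as a
# deleterious vote), <= 0.446 benign; PROVEAN <= -2.5 deleterious;
# MutationTaster A/D disease-causing, N/P polymorphism.
SIFT_DELETERIOUS_BELOW = 0.05
POLYPHEN2_DAMAGING_AT_LEAST = 0.447
POLYPHEN2_PROBABLY_DAMAGING_AT_LEAST = 0.909
PROVEAN_DELETERIOUS_AT_MOST = -2.5


def in_silico_consensus(scores: PredictorScores | None) -> Consensus:
    """Majority vote over the available predictor tools.

    Deleterious iff strictly more than half of the available tools call
    deleterious; neutral iff strictly more than half call neutral; otherwise
    (ties, or no scores at all) indeterminate.
    """
    if scores is None or scores.n_available == 0:
        return Consensus.INDETERMINATE
    votes: list[bool] = []
    if scores.sift is not None:
        votes.append(scores.sift < SIFT_DELETERIOUS_BELOW)
    if scores.polyphen2 is not None:
        votes.append(scores.polyphen2 >= POLYPHEN2_DAMAGING_AT_LEAST)
    if scores.provean is not None:
        votes.append(scores.provean <= PROVEAN_DELETERIOUS_AT_MOST)
    if scores.mutationtaster is not None:
        votes.append(scores.mutationtaster in ("A", "D"))
    n = len(votes)
    n_del = sum(votes)
    if n_del * 2 > n:
        return Consensus.DELETERIOUS
    if (n - n_del) * 2 > n:
        return Consensus.NEUTRAL
    return Consensus.INDETERMINATE


# ---------------------------------------------------------------------------
# ARC rule engine
# ---------------------------------------------------------------------------

def _gene_variants(individual: Individual, gene: str) -> list[ClassifiedVariant]:
    return [v for v in individual.variants if v.gene == gene]


def _best_plp(variants: Sequence[ClassifiedVariant]) -> ClassifiedVariant | None:
    plp = [v for v in variants if v.acmg_class.is_plp]
    if not plp:
        return None
    return max(plp, key=lambda v: v.acmg_class.reportability)


def _supported_vus(variants: Sequence[ClassifiedVariant], gene: str,
                   proband_evidence: set[str]) -> tuple[ClassifiedVariant, str] | None:
    """Pick a VUS with supporting evidence, preferring proband segregation."""
    vus = [v for v in variants if v.acmg_class is AcmgClass.VUS]
    if not vus:
        return None
    if gene in proband_evidence:
        return vus[0], "proband"
    for v in vus:
        if in_silico_consensus(v.scores) is Consensus.DELETERIOUS:
            return v, "in_silico"
    return None


def call_arc(couple: Couple, panel: Sequence[GenePanelEntry],
             mapping: Mapping[str, set[str]] | None = None) -> ARCResult | None:
    """Evaluate the four at-risk rules for every shared gene of a couple.

    Matching uses the highest class first: a partner carrying both a P/LP and
    a VUS in the same gene is matched through the P/LP, so a both-P/LP
    pairing is never reported as P/LP-plus-VUS.  The X-linked rule fires on
    the female's P/LP irrespective of the male.  All at-risk genes are
    reported; the couple-level severity is the highest-ranked tier among them
    (``None`` when any at-risk gene is unclassified).

    A diagnosed individual's variants still participate: a couple whose
    genotypes satisfy a rule is at risk regardless of diagnostic status.
    """
    by_gene = {g.symbol: g for g in panel}
    genes = sorted(
        {v.gene for v in couple.female.variants} | {v.gene for v in couple.male.variants}
    )
    risks: list[GeneRisk] = []
    for gene in genes:
        entry = by_gene.get(gene)
        if entry is None or entry.inheritance is Inheritance.AD:
            continue
        fvars = _gene_variants(couple.female, gene)
        mvars = _gene_variants(couple.male, gene)
        f_plp = _best_plp(fvars)
        m_plp = _best_plp(mvars)

        if entry.inheritance is Inheritance.XL:
            if f_plp is not None:
                risks.append(GeneRisk(gene, ArcRule.FEMALE_PLP_XL,
                                      f_plp.acmg_class, None))
            continue

        # autosomal recessive
        if f_plp is not None and m_plp is not None:
            risks.append(GeneRisk(gene, ArcRule.BOTH_PLP_AR,
                                  f_plp.acmg_class, m_plp.acmg_class))
            continue
        if f_plp is not None or m_plp is not None:
            plp_side, vus_side = (
                (f_plp, mvars) if f_plp is not None else (m_plp, fvars)
            )
            hit = _supported_vus(vus_side, gene, couple.proband_evidence)
            if hit is not None:
                vus_v, evidence = hit
                fc, mc = (
                    (plp_side.acmg_class, vus_v.acmg_class)
                    if f_plp is not None
                    else (vus_v.acmg_class, plp_side.acmg_class)
                )
                risks.append(GeneRisk(gene, ArcRule.PLP_PLUS_VUS, fc, mc, evidence))
            continue
        f_hit = _supported_vus(fvars, gene, couple.proband_evidence)
        m_hit = _supported_vus(mvars, gene, couple.proband_evidence)
        if f_hit is not None and m_hit is not None:
            evidence = "proband" if f_hit[1] == m_hit[1] == "proband" else (
                "proband" if "proband" in (f_hit[1], m_hit[1]) else "in_silico"
            )
            risks.append(GeneRisk(gene, ArcRule.BOTH_VUS, AcmgClass.VUS,
                                  AcmgClass.VUS, evidence))

    if not risks:
        return None
    tiers = [by_gene[r.gene].severity for r in risks]
    if any(t is Severity.UNCLASSIFIED for t in tiers):
        severity: Severity | None = None
    else:
        severity = max(tiers, key=severity_rank)
    return ARCResult(
        couple_id=couple.id,
        at_risk_genes=risks,
        severity=severity,
        vus_involved=any(r.rule in (ArcRule.PLP_PLUS_VUS, ArcRule.BOTH_VUS)
                         for r in risks),
    )


# ---------------------------------------------------------------------------
# Secondary findings
# ---------------------------------------------------------------------------

def detect_secondary_findings(
    individual: Individual,
    panel: Sequence[GenePanelEntry],
    sf_list: set[str] | frozenset[str] = frozenset(),
) -> list[SecondaryFinding]:
    """P/LP variants in autosomal-dominant genes unrelated to the
    individual's phenotype; ``acmg_sf_listed`` marks genes on the ACMG
    secondary-findings list supplied via config."""
    by_gene = {g.symbol: g for g in panel}
    out: list[SecondaryFinding] = []
    for v in individual.variants:
        entry = by_gene.get(v.gene)
        if entry is None or entry.inheritance is not Inheritance.AD:
            continue
        if not v.acmg_class.is_plp or v.phenotype_related:
            continue
        out.append(SecondaryFinding(
            individual_id=individual.id,
            gene=v.gene,
            variant=v,
            acmg_sf_listed=v.gene in sf_list,
        ))
    return out


def load_sf_gene_list(path) -> set[str]:
    """Read a secondary-findings gene list (one symbol per line)."""
    from pathlib import Path

    return {
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    }


def sf_gene_summary(findings: Sequence[SecondaryFinding]) -> pd.DataFrame:
    """Per-gene secondary-finding table.

    ``positive_case`` counts distinct individuals with an SF in the gene and
    ``pct_of_positive`` is that count over all SF-positive individuals, as a
    percentage rounded to 2 dp.
    """
    positive_ids = {f.individual_id for f in findings}
    n_positive = len(positive_ids)
    per_gene: dict[str, set[str]] = {}
    listed: dict[str, bool] = {}
    for f in findings:
        per_gene.setdefault(f.gene, set()).add(f.individual_id)
        listed[f.gene] = listed.get(f.gene, False) or f.acmg_sf_listed
    rows = [
        {
            "gene": gene,
            "positive_case": len(ids),
            "pct_of_positive": _round_half_up(100.0 * len(ids) / n_positive, 2),
            "acmg_sf_listed": listed[gene],
        }
        for gene, ids in per_gene.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "positive_case", "pct_of_positive",
                                     "acmg_sf_listed"])
    return df.sort_values(["positive_case", "gene"],
                          ascending=[False, True]).set_index("gene")


# ---------------------------------------------------------------------------
# Subgroup ARC rates
# ---------------------------------------------------------------------------

def _round_half_up(x: float, nd: int = 0) -> float:
    import math

    scale = 10 ** nd
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def arc_rate_by_subgroup(couples: Sequence[Couple],
                         arc_results: Sequence[ARCResult | None] | Sequence[ARCResult],
                         ) -> pd.DataFrame:
    """ARC rate per reason-for-screening subgroup, plus the overall rate.

    ``arc_results`` may be the per-couple outcome list (aligned with
    ``couples``, ``None`` for negative couples) or a bare list of ARCResult.
    Rates are percentages at 2 dp; empty subgroups report NA.
    """
    from .cohort_io import Subgroup

    arc_ids = {a.couple_id for a in arc_results if a is not None}
    rows = []
    for sg in Subgroup:
        members = [c for c in couples if c.subgroup is sg]
        n = len(members)
        k = sum(c.id in arc_ids for c in members)
        rate = _round_half_up(100.0 * k / n, 2) if n else float("nan")
        rows.append({"subgroup": sg.value, "n_couples": n, "n_arc": k,
                     "arc_rate_pct": rate})
    n_all = len(couples)
    k_all = sum(c.id in arc_ids for c in couples)
    rows.append({
        "subgroup": "all",
        "n_couples": n_all,
        "n_arc": k_all,
        "arc_rate_pct": _round_half_up(100.0 * k_all / n_all, 2) if n_all else float("nan"),
    })
    return pd.DataFrame(rows).set_index("subgroup")
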