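"""Published summary counts of a large ART-couple ECS programme, as inputs.

The programme this package models screened 2,234 couples (4,468 individuals)
on a 4,158-gene medical-exome panel and published only aggregate tables —
subgroup sizes, per-gene carrier counts, recurrent-variant allele counts,
secondary-finding counts, severity-tier pair counts and the decision split.
Those printed counts are recorded here as inputs, together with builders
that expand them into minimal in-memory cohorts/fixtures so that every
aggregate can be *recomputed* by the package's own operations and checked
against the printed value.

Synthetic filler entries (marked ``SYN``) pad the fixtures where the
publication aggregates (e.g. the long tail of rarely carried genes) without
printing per-item detail.
"""

from __future__ import annotations

from .cohort_io import (
    ClassifiedVariant,
    Couple,
    Decision,
    Individual,
    Subgroup,
    Zygosity,
)
from .panel_model import (
    AcmgClass,
    GenePanelEntry,
    Inheritance,
    PanelVariant,
    Severity,
)

__all__ = [
    "N_COUPLES",
    "N_INDIVIDUALS",
    "N_POSITIVE",
    "SUBGROUP_COUPLES",
    "SUBGROUP_ARCS",
    "GENE_POSITIVES",
    "VARIANT_ALLELES",
    "SF_GENE_CASES",
    "SF_TOTAL_POSITIVE",
    "SEVERITY_PAIRS",
    "DECISION_SPLIT_BY_GROUP",
    "N_PATIENT_INDIVIDUALS",
    "N_DIAGNOSED",
    "V37I_HOMOZYGOTES",
    "V37I_PENETRANT",
    "reference_panel",
    "build_carrier_fixture",
    "build_arc_decision_fixture",
    "build_patient_fixture",
    "build_penetrance_fixture",
    "build_sf_fixture",
]

N_COUPLES = 2234
N_INDIVIDUALS = 4468
N_POSITIVE = 4242  # individuals with >=1 reportable carrier variant

# couples screened / at-risk couples per reason-for-screening subgroup
SUBGROUP_COUPLES: dict[Subgroup, int] = {
    Subgroup.RECURRENT_MISCARRIAGE_STILLBORN: 878,
    Subgroup.INFERTILITY: 587,
    Subgroup.BIRTH_DEFECT_ULTRASOUND_ANOMALY: 447,
    Subgroup.PATIENTS: 127,
    Subgroup.ROUTINE_SCREENING: 170,
    Subgroup.CONSANGUINEOUS_MARRIAGE: 25,
}
SUBGROUP_ARCS: dict[Subgroup, int] = {
    Subgroup.RECURRENT_MISCARRIAGE_STILLBORN: 57,
    Subgroup.INFERTILITY: 57,
    Subgroup.BIRTH_DEFECT_ULTRASOUND_ANOMALY: 70,
    Subgroup.PATIENTS: 13,
    Subgroup.ROUTINE_SCREENING: 14,
    Subgroup.CONSANGUINEOUS_MARRIAGE: 8,
}

# per-gene distinct-carrier counts (top AR genes plus the X-linked genes)
GENE_POSITIVES: dict[str, int] = {
    "GJB2": 901, "CFTR": 455, "DUOX2": 321, "SERPINB7": 167, "IL36RN": 127,
    "GALC": 94, "CD36": 84, "HBB": 81, "USH2A": 77, "MYORG": 74,
    "G6PD": 40, "DMD": 10, "CACNA1F": 5,
}

# recurrent-variant allele counts: gene -> {hgvs: alleles}
VARIANT_ALLELES: dict[str, dict[str, int]] = {
    "GJB2": {"c.109G>A": 797, "c.235delC": 73},
    "CFTR": {"c.1210-11T>G": 352},
    "IL36RN": {"c.115+6T>C": 126},
    "SERPINB7": {"c.796C>T": 123},
    "DUOX2": {"c.1588A>T": 121, "c.2654G>T": 72},
    "GALC": {"c.1901T>C": 91},
    "MYORG": {"c.40dupC": 74},
    "C9": {"c.346C>T": 70},
}

SF_TOTAL_POSITIVE = 272
SF_GENE_CASES: dict[str, int] = {
    "TTN": 26, "PDE11A": 10, "MYH6": 8, "LAMA4": 6, "ABCA7": 5, "COMP": 5,
    "SLC39A5": 5, "SYNE2": 5, "TUBB1": 5, "FLNC": 5, "TMEM127": 1, "BRCA2": 1,
}
ACMG_SF_LISTED = {"TTN", "FLNC", "TMEM127", "BRCA2"}

SEVERITY_PAIRS: dict[Severity, int] = {
    Severity.PROFOUND: 13, Severity.SEVERE: 93,
    Severity.MODERATE: 100, Severity.MILD: 13,
}
# (measures taken, no measures, lost) per severity group; lost couples are
# split 3/2 across the groups (any split consistent with the printed margins)
DECISION_SPLIT_BY_GROUP: dict[str, tuple[int, int, int]] = {
    "high": (48, 55, 3),   # profound/severe, 106 pairs
    "low": (23, 88, 2),    # moderate/mild, 113 pairs
}

N_PATIENT_INDIVIDUALS = 254
N_DIAGNOSED = 56
V37I_HOMOZYGOTES = 20
V37I_PENETRANT = 6


def _gene(symbol: str, omim: int, disease: str, inh: Inheritance,
          sev: Severity, variants: list[PanelVariant]) -> GenePanelEntry:
    return GenePanelEntry(symbol=symbol, omim_id=omim, disease=disease,
                          inheritance=inh, severity=sev, carrier_freq=0.0,
                          variants=variants)


def reference_panel() -> list[GenePanelEntry]:
    """Fixture panel covering every gene the builders reference.

    Carrier frequencies are zero (the fixtures assign carriers explicitly);
    spectra are placeholders.  ``SYNFILL*`` genes are synthetic fillers for
    the unprinted tail.
    """
    AR, XL, AD = Inheritance.AR, Inheritance.XL, Inheritance.AD
    S = Severity
    pv = lambda hgvs: [PanelVariant(hgvs, AcmgClass.P, 1.0)]
    panel = [
        _gene("GJB2", 121011, "GJB2-related hearing loss", AR, S.MODERATE, pv("c.109G>A")),
        _gene("CFTR", 602421, "Cystic fibrosis", AR, S.SEVERE, pv("c.1210-11T>G")),
        _gene("DUOX2", 606759, "Thyroid dyshormonogenesis 6", AR, S.MODERATE, pv("c.1588A>T")),
        _gene("SERPINB7", 603357, "Palmoplantar keratoderma nagashima type", AR, S.MILD, pv("c.796C>T")),
        _gene("IL36RN", 605507, "Pustular psoriasis generalized", AR, S.MODERATE, pv("c.115+6T>C")),
        _gene("GALC", 606890, "Krabbe disease", AR, S.PROFOUND, pv("c.1901T>C")),
        _gene("CD36", 173510, "Platelet glycoprotein IV deficiency", AR, S.MODERATE, pv("c.329_330delAC")),
        _gene("HBB", 141900, "Beta-thalassemia", AR, S.SEVERE, pv("c.126_129delCTTT")),
        _gene("USH2A", 608400, "Usher syndrome type 2A", AR, S.SEVERE, pv("c.2802T>G")),
        _gene("MYORG", 618255, "Idiopathic basal ganglia calcification-7", AR, S.MODERATE, pv("c.40dupC")),
        _gene("C9", 120940, "Complement component 9 deficiency", AR, S.MILD, pv("c.346C>T")),
        _gene("SYNFILL1", 999001, "Synthetic recessive condition 1", AR, S.MODERATE, pv("c.1A>G")),
        _gene("G6PD", 305900, "Glucose 6 phosphate dehydrogenase deficiency", XL, S.MILD, pv("c.1388G>A")),
        _gene("DMD", 300377, "Duchenne muscular dystrophy", XL, S.PROFOUND, pv("c.9100C>T")),
        _gene("CACNA1F", 300110, "Congenital stationary night blindness type 2A", XL, S.MILD, pv("c.2234T>C")),
        _gene("TTN", 188840, "Dilated cardiomyopathy-1G", AD, S.UNCLASSIFIED, pv("c.490del")),
        _gene("PDE11A", 604961, "Primary pigmented nodular adrenocortical disease-2", AD, S.UNCLASSIFIED, pv("c.171del")),
        _gene("MYH6", 160710, "Dilated cardiomyopathy-1EE", AD, S.UNCLASSIFIED, pv("c.2033G>A")),
        _gene("LAMA4", 600133, "Dilated cardiomyopathy-1JJ", AD, S.UNCLASSIFIED, pv("c.3029T>C")),
        _gene("ABCA7", 605414, "Susceptibility to late-onset Alzheimer disease-9", AD, S.UNCLASSIFIED, pv("c.2126_2132del")),
        _gene("COMP", 600310, "Multiple epiphyseal dysplasia-1", AD, S.UNCLASSIFIED, pv("c.1153G>A")),
        _gene("SLC39A5", 608730, "Myopia-24", AD, S.UNCLASSIFIED, pv("c.911T>C")),
        _gene("SYNE2", 608442, "Emery-Dreifuss muscular dystrophy-5", AD, S.UNCLASSIFIED, pv("c.1721T>C")),
        _gene("TUBB1", 612901, "Macrothrombocytopenia", AD, S.UNCLASSIFIED, pv("c.952C>T")),
        _gene("FLNC", 102565, "Dilated cardiomyopathy", AD, S.UNCLASSIFIED, pv("c.5791C>T")),
        _gene("TMEM127", 613403, "Hereditary paraganglioma-pheochromocytoma syndrome", AD, S.UNCLASSIFIED, pv("c.245G>A")),
        _gene("BRCA2", 600185, "Hereditary breast and ovarian cancer", AD, S.UNCLASSIFIED, pv("c.5946del")),
        _gene("PAX6", 607108, "Aniridia", AD, S.UNCLASSIFIED, pv("c.718C>T")),
        _gene("SYNFILL2", 999002, "Synthetic dominant condition 1", AD, S.UNCLASSIFIED, pv("c.2T>C")),
    ]
    return panel


def _het(gene: str, hgvs: str) -> ClassifiedVariant:
    return ClassifiedVariant(gene=gene, hgvs_c=hgvs, acmg_class=AcmgClass.P,
                             zygosity=Zygosity.HET)


def build_carrier_fixture() -> list[Individual]:
    """Expand the printed carrier counts into 4,468 minimal individuals.

    Individual ``i`` carries gene ``g`` iff ``i < GENE_POSITIVES[g]``; within
    a gene, printed recurrent alleles are assigned first (heterozygous, so
    allele counts equal carrier counts), remaining carriers get a residual
    allele.  Individuals beyond the largest gene count, up to the printed
    total of positive carriers, carry the synthetic filler gene, making the
    distinct-positive count equal the printed 4,242.
    """
    individuals = [
        Individual(id=f"I{i:04d}", sex="F" if i % 2 == 0 else "M")
        for i in range(N_INDIVIDUALS)
    ]
    for gene, count in GENE_POSITIVES.items():
        alleles = VARIANT_ALLELES.get(gene, {})
        start = 0
        for hgvs, k in alleles.items():
            for i in range(start, start + k):
                individuals[i].variants.append(_het(gene, hgvs))
            start += k
        for i in range(start, count):
            individuals[i].variants.append(_het(gene, "c.residual"))
    # C9 appears among recurrent variants but not the per-gene table
    for i in range(VARIANT_ALLELES["C9"]["c.346C>T"]):
        individuals[i].variants.append(_het("C9", "c.346C>T"))
    max_assigned = max(GENE_POSITIVES.values())
    for i in range(max_assigned, N_POSITIVE):
        individuals[i].variants.append(_het("SYNFILL1", "c.1A>G"))
    return individuals


_TIER_GENE = {
    Severity.PROFOUND: "GALC",
    Severity.SEVERE: "CFTR",
    Severity.MODERATE: "GJB2",
    Severity.MILD: "SERPINB7",
}


def build_arc_decision_fixture() -> tuple[list[Couple], dict[str, Decision]]:
    """2,234 couples whose rule-engine outcomes reproduce the printed
    subgroup ARC counts, severity-tier counts and decision split.

    Within each subgroup the first ``SUBGROUP_ARCS`` couples are made at
    risk (both partners heterozygous P in the same gene); at-risk genes are
    assigned across tiers in tier order, and decisions follow the printed
    severity-group split with lost-to-follow-up allocated 3/2.
    """
    tiers: list[Severity] = []
    for tier, k in SEVERITY_PAIRS.items():
        tiers.extend([tier] * k)

    decisions_seq: dict[Severity, list[Decision]] = {}
    high = [Decision.MEASURES_TAKEN] * DECISION_SPLIT_BY_GROUP["high"][0] + \
           [Decision.NO_MEASURES] * DECISION_SPLIT_BY_GROUP["high"][1] + \
           [Decision.LOST_TO_FOLLOWUP] * DECISION_SPLIT_BY_GROUP["high"][2]
    low = [Decision.MEASURES_TAKEN] * DECISION_SPLIT_BY_GROUP["low"][0] + \
          [Decision.NO_MEASURES] * DECISION_SPLIT_BY_GROUP["low"][1] + \
          [Decision.LOST_TO_FOLLOWUP] * DECISION_SPLIT_BY_GROUP["low"][2]

    couples: list[Couple] = []
    decisions: dict[str, Decision] = {}
    arc_idx = 0
    high_idx = low_idx = 0
    cid = 0
    for sg, n_cpl in SUBGROUP_COUPLES.items():
        n_arc = SUBGROUP_ARCS[sg]
        for j in range(n_cpl):
            f = Individual(id=f"F{cid:04d}", sex="F")
            m = Individual(id=f"M{cid:04d}", sex="M")
            decision = Decision.NA
            if j < n_arc:
                tier = tiers[arc_idx]
                gene = _TIER_GENE[tier]
                hgvs = next(iter(VARIANT_ALLELES.get(gene, {"c.1A>G": 0})))
                f.variants.append(_het(gene, hgvs))
                m.variants.append(_het(gene, hgvs))
                if tier in (Severity.PROFOUND, Severity.SEVERE):
                    decision = high[high_idx]
                    high_idx += 1
                else:
                    decision = low[low_idx]
                    low_idx += 1
                arc_idx += 1
            couple = Couple(id=f"C{cid:04d}", female=f, male=m, subgroup=sg,
                            decision=decision)
            couples.append(couple)
            if decision is not Decision.NA:
                decisions[couple.id] = decision
            cid += 1
    return couples, decisions


def build_patient_fixture() -> list[Individual]:
    """254 symptomatic individuals of whom 56 have a diagnosis-consistent
    genotype with a matching phenotype (homozygous P in the hearing-loss
    gene); the rest are heterozygous carriers whose phenotype no gene
    explains."""
    individuals = []
    for i in range(N_PATIENT_INDIVIDUALS):
        ind = Individual(id=f"P{i:03d}", sex="F" if i % 2 == 0 else "M")
        if i < N_DIAGNOSED:
            ind.phenotypes = ["hearing loss"]
            ind.variants = [ClassifiedVariant(
                gene="GJB2", hgvs_c="c.109G>A", acmg_class=AcmgClass.P,
                zygosity=Zygosity.HOM)]
        else:
            ind.phenotypes = ["intellectual disability"]
            ind.variants = [_het("CFTR", "c.1210-11T>G")]
        individuals.append(ind)
    return individuals


def build_penetrance_fixture() -> list[Individual]:
    """20 homozygotes of the hearing-loss hypomorph, 6 with hearing loss."""
    out = []
    for i in range(V37I_HOMOZYGOTES):
        ind = Individual(id=f"H{i:02d}", sex="F" if i % 2 == 0 else "M")
        ind.variants = [ClassifiedVariant(
            gene="GJB2", hgvs_c="c.109G>A", acmg_class=AcmgClass.P,
            zygosity=Zygosity.HOM)]
        if i < V37I_PENETRANT:
            ind.phenotypes = ["hearing loss"]
        out.append(ind)
    return out


def build_sf_fixture() -> list[Individual]:
    """272 asymptomatic individuals, each with one P variant in an
    autosomal-dominant gene, per the printed per-gene case counts; the
    remainder carry the synthetic dominant filler gene."""
    individuals = []
    i = 0
    for gene, k in SF_GENE_CASES.items():
        for _ in range(k):
            ind = Individual(id=f"S{i:03d}", sex="F" if i % 2 == 0 else "M")
            ind.variants = [_het(gene, "c.sf")]
            individuals.append(ind)
            i += 1
    while i < SF_TOTAL_POSITIVE:
        ind = Individual(id=f"S{i:03d}", sex="F" if i % 2 == 0 else "M")
        ind.variants = [_het("SYNFILL2", "c.2T>C")]
        individuals.append(ind)
        i += 1
    return individuals
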