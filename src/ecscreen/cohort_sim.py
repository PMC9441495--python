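"""Synthetic ECS cohort simulator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so that every stage is testable without access to sequencing data:

* per gene and individual, carrier status is Bernoulli(carrier_freq),
  independent across genes and across partners (random mating);
* a carried allele is drawn from the gene's variant spectrum by relative
  frequency; its class is the panel default, downgraded to VUS with
  probability ``vus_fraction`` (downgraded records receive predictor scores,
  deleterious-leaning with probability ``vus_deleterious_support``);
* X-linked genes are sampled as female heterozygous carriage only (male
  hemizygotes would present as patients, not carriers; an option enables
  them for diagnostic testing);
* autosomal-dominant genes are sampled as heterozygous carriage and feed the
  secondary-findings pool;
* at most one carried variant per gene per individual — multi-variant burden
  arises across genes;
* consanguinity is modelled as a probability that the male partner shares
  each AR gene the female carries, identically by descent;
* reproductive decisions are assigned post hoc, only to couples the rule
  engine calls at risk, with severity-dependent uptake probabilities.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

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
    PredictorScores,
    Severity,
    ValidationError,
    plp_spectrum_fraction,
)
from .screening_rules import call_arc

__all__ = ["SimConfig", "DEFAULT_SUBGROUP_MIX", "simulate_cohort",
           "expected_arc_rate"]

# Couple-level subgroup shares of the modelled screening programme
# (2,234 couples: 878 recurrent miscarriage/stillborn, 587 infertility,
# 447 birth defect/ultrasound anomaly, 127 patients, 170 routine,
# 25 consanguineous).
DEFAULT_SUBGROUP_MIX: dict[Subgroup, float] = {
    Subgroup.RECURRENT_MISCARRIAGE_STILLBORN: 878 / 2234,
    Subgroup.INFERTILITY: 587 / 2234,
    Subgroup.BIRTH_DEFECT_ULTRASOUND_ANOMALY: 447 / 2234,
    Subgroup.PATIENTS: 127 / 2234,
    Subgroup.ROUTINE_SCREENING: 170 / 2234,
    Subgroup.CONSANGUINEOUS_MARRIAGE: 25 / 2234,
}

_MIX_TOL = 1e-9


@dataclass
class SimConfig:
    """Simulation parameters.

    Decision-uptake defaults are the observed severity-group fractions of
    the modelled programme (48/106 for profound/severe, 23/113 for
    moderate/mild, 5/219 lost to follow-up); the subgroup mix defaults to
    the programme's couple counts.  ``consang_share_prob`` is the
    probability that the male partner of a consanguineous couple shares,
    identically by descent, each AR gene the female carries — its default
    reproduces the strongly elevated at-risk rate seen in that subgroup.
    """

    n_couples: int = 2234
    seed: int = 0
    subgroup_mix: dict[Subgroup, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_MIX))
    vus_fraction: float = 0.05
    decision_prob_high: float = 48 / 106
    decision_prob_low: float = 23 / 113
    lost_prob: float = 5 / 219
    consang_share_prob: float = 0.5
    vus_deleterious_support: float = 0.5
    proband_evidence_prob: float = 0.3
    xl_male_hemi: bool = False

    def __post_init__(self) -> None:
        self.subgroup_mix = {Subgroup(k): float(v)
                             for k, v in self.subgroup_mix.items()}
        for name in ("vus_fraction", "decision_prob_high", "decision_prob_low",
                     "lost_prob", "consang_share_prob",
                     "vus_deleterious_support", "proband_evidence_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if any(w < 0 for w in self.subgroup_mix.values()):
            raise ValidationError("subgroup weights must be nonnegative")
        if abs(sum(self.subgroup_mix.values()) - 1.0) > _MIX_TOL:
            raise ValidationError("subgroup weights must sum to 1")


def _deleterious_scores(rng: np.random.Generator) -> PredictorScores:
    return PredictorScores(
        sift=float(rng.uniform(0.0, 0.049)),
        polyphen2=float(rng.uniform(0.909, 1.0)),
        provean=float(rng.uniform(-8.0, -2.5)),
        mutationtaster="D",
    )


def _neutral_scores(rng: np.random.Generator) -> PredictorScores:
    return PredictorScores(
        sift=float(rng.uniform(0.1, 1.0)),
        polyphen2=float(rng.uniform(0.0, 0.3)),
        provean=float(rng.uniform(0.0, 5.0)),
        mutationtaster="N",
    )


def _sample_variant(entry: GenePanelEntry, rng: np.random.Generator,
                    config: SimConfig, zygosity: Zygosity) -> ClassifiedVariant:
    if not entry.variants:
        raise ValidationError(
            f"{entry.symbol}: carrier_freq > 0 requires a variant spectrum"
        )
    freqs = np.array([v.rel_freq for v in entry.variants])
    idx = int(rng.choice(len(entry.variants), p=freqs / freqs.sum()))
    pv = entry.variants[idx]
    cls = pv.default_class
    scores = None
    if cls.is_plp and rng.random() < config.vus_fraction:
        cls = AcmgClass.VUS
    if cls is AcmgClass.VUS:
        scores = (_deleterious_scores(rng)
                  if rng.random() < config.vus_deleterious_support
                  else _neutral_scores(rng))
    return ClassifiedVariant(
        gene=entry.symbol, hgvs_c=pv.hgvs_c, transcript=pv.transcript,
        acmg_class=cls, zygosity=zygosity, scores=scores,
    )


def simulate_cohort(panel: Sequence[GenePanelEntry],
                    config: SimConfig) -> tuple[list[Individual], list[Couple]]:
    """Draw a full synthetic cohort and assign post-hoc decisions.

    Returns ``(individuals, couples)`` in the cohort_io containers; couples
    are female–male pairs in order, with couple ``Cnnnnn`` joining
    ``Fnnnnn`` and ``Mnnnnn``.  Byte-identical for identical configs.
    """
    if not panel:
        raise ValidationError("panel must be non-empty")
    if config.n_couples <= 0:
        raise ValidationError("n_couples must be positive")
    rng = np.random.default_rng(config.seed)
    n = config.n_couples

    females = [Individual(id=f"F{i:05d}", sex="F") for i in range(n)]
    males = [Individual(id=f"M{i:05d}", sex="M") for i in range(n)]
    everyone = females + males

    for entry in panel:
        cf = entry.carrier_freq
        if cf == 0:
            continue
        if entry.inheritance is Inheritance.XL:
            mask = rng.random(n) < cf
            for i in np.nonzero(mask)[0]:
                females[i].variants.append(
                    _sample_variant(entry, rng, config, Zygosity.HET))
            if config.xl_male_hemi:
                mask = rng.random(n) < cf
                for i in np.nonzero(mask)[0]:
                    males[i].variants.append(
                        _sample_variant(entry, rng, config, Zygosity.HEMI))
        else:
            mask = rng.random(2 * n) < cf
            for i in np.nonzero(mask)[0]:
                everyone[i].variants.append(
                    _sample_variant(entry, rng, config, Zygosity.HET))

    subgroup_order = list(Subgroup)
    weights = np.array([config.subgroup_mix.get(sg, 0.0) for sg in subgroup_order])
    assignments = rng.choice(len(subgroup_order), size=n, p=weights / weights.sum())

    by_gene = {g.symbol: g for g in panel}

    # consanguinity: the male partner shares each female-carried AR gene IBD
    for i in range(n):
        if subgroup_order[assignments[i]] is not Subgroup.CONSANGUINEOUS_MARRIAGE:
            continue
        male_genes = {v.gene for v in males[i].variants}
        for v in list(females[i].variants):
            entry = by_gene[v.gene]
            if entry.inheritance is not Inheritance.AR or v.gene in male_genes:
                continue
            if rng.random() < config.consang_share_prob:
                males[i].variants.append(ClassifiedVariant(
                    gene=v.gene, hgvs_c=v.hgvs_c, transcript=v.transcript,
                    acmg_class=v.acmg_class, zygosity=Zygosity.HET,
                    scores=v.scores,
                ))

    # patient-subgroup couples: one partner reports a phenotype drawn from
    # the panel's disease spectrum (diagnostic yield is not targeted)
    diseases = [g.disease for g in panel]
    for i in range(n):
        if subgroup_order[assignments[i]] is not Subgroup.PATIENTS:
            continue
        target = females[i] if rng.random() < 0.5 else males[i]
        target.phenotypes.append(diseases[int(rng.integers(len(diseases)))].lower())

    couples: list[Couple] = []
    for i in range(n):
        sg = subgroup_order[assignments[i]]
        females[i].subgroup = sg
        males[i].subgroup = sg
        vus_genes = {
            v.gene
            for ind in (females[i], males[i])
            for v in ind.variants
            if v.acmg_class is AcmgClass.VUS
        }
        evidence = {
            g for g in sorted(vus_genes)
            if rng.random() < config.proband_evidence_prob
        }
        couples.append(Couple(
            id=f"C{i:05d}", female=females[i], male=males[i], subgroup=sg,
            proband_evidence=evidence, decision=Decision.NA,
        ))

    # post-hoc decisions, only for couples the rule engine calls at risk
    for couple in couples:
        arc = call_arc(couple, panel)
        if arc is None:
            continue
        if rng.random() < config.lost_prob:
            couple.decision = Decision.LOST_TO_FOLLOWUP
            continue
        high = arc.severity in (Severity.PROFOUND, Severity.SEVERE)
        p_take = config.decision_prob_high if high else config.decision_prob_low
        couple.decision = (Decision.MEASURES_TAKEN if rng.random() < p_take
                           else Decision.NO_MEASURES)

    individuals: list[Individual] = []
    for f, m in zip(females, males):
        individuals.extend((f, m))
    return individuals, couples


def expected_arc_rate(panel: Sequence[GenePanelEntry]) -> float:
    """Analytic at-risk probability under independence, P/LP pathways only.

    Per AR gene the both-carrier probability is ``(cf * q)^2`` with ``q`` the
    P/LP fraction of the spectrum (the VUS evidence pathways are excluded
    from the closed form — it is an approximation whenever VUS can arise);
    per XL gene the female-carrier probability is ``cf * q``.  The rate is
    one minus the product of the per-gene negative probabilities.

    This is the validation oracle for the simulator: with ``vus_fraction = 0``
    and no consanguinity boost the simulated ARC rate converges to it.
    """
    p_negative = 1.0
    for entry in panel:
        q = plp_spectrum_fraction(entry)
        if entry.inheritance is Inheritance.AR:
            p_negative *= 1.0 - (entry.carrier_freq * q) ** 2
        elif entry.inheritance is Inheritance.XL:
            p_negative *= 1.0 - entry.carrier_freq * q
    return 1.0 - p_negative
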