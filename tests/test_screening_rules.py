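import itertools
import random

import pytest

from ecscreen import (
    AcmgClass,
    Consensus,
    Couple,
    GenePanelEntry,
    Inheritance,
    PanelVariant,
    PredictorScores,
    Severity,
    Subgroup,
    ValidationError,
    Zygosity,
    arc_rate_by_subgroup,
    call_arc,
    detect_secondary_findings,
    diagnose_individual,
    in_silico_consensus,
    penetrance_estimate,
    positive_carrier_rate,
    sf_gene_summary,
    triage_phenotype_related,
)
from ecscreen.screening_rules import ArcRule, load_phenotype_map

from conftest import DELETERIOUS, NEUTRAL, make_couple, make_individual, \
    make_variant


# ---------------------------------------------------------------------------
# in-silico consensus
# ---------------------------------------------------------------------------

class TestInSilicoConsensus:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            (PredictorScores(0.01, 0.95, -3.0, "D"), Consensus.DELETERIOUS),
            (PredictorScores(0.8, 0.1, 5.0, "N"), Consensus.NEUTRAL),
            (PredictorScores(sift=0.01, polyphen2=0.1), Consensus.INDETERMINATE),
            # boundary behaviour of each tool cutoff
            (PredictorScores(sift=0.05), Consensus.NEUTRAL),
            (PredictorScores(sift=0.049), Consensus.DELETERIOUS),
            (PredictorScores(polyphen2=0.447), Consensus.DELETERIOUS),
            (PredictorScores(polyphen2=0.446), Consensus.NEUTRAL),
            (PredictorScores(provean=-2.5), Consensus.DELETERIOUS),
            (PredictorScores(provean=-2.4), Consensus.NEUTRAL),
            (PredictorScores(mutationtaster="A"), Consensus.DELETERIOUS),
            (PredictorScores(mutationtaster="P"), Consensus.NEUTRAL),
            # 3-1 split: strict majority deleterious
            (PredictorScores(0.01, 0.95, -3.0, "N"), Consensus.DELETERIOUS),
            (None, Consensus.INDETERMINATE),
            (PredictorScores(), Consensus.INDETERMINATE),
        ],
    )
    def test_majority_rule_over_available_tools(self, scores, expected):
        assert in_silico_consensus(scores) is expected

    @pytest.mark.parametrize(
        "kwargs",
        [{"sift": 1.5}, {"polyphen2": -0.1}, {"provean": 20.0},
         {"mutationtaster": "X"}],
    )
    def test_out_of_range_scores_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PredictorScores(**kwargs)


# ---------------------------------------------------------------------------
# phenotype triage
# ---------------------------------------------------------------------------

class TestTriage:
    def test_token_overlap_marks_diagnostic_candidate(self, mini_panel):
        ind = make_individual("I1", "F", phenotypes=["hearing loss"],
                              variants=[make_variant("GJB2")])
        diagnostic, carrier = triage_phenotype_related(ind, mini_panel)
        assert [v.gene for v in diagnostic] == ["GJB2"]
        assert carrier == [] and ind.variants[0].phenotype_related

    def test_asymptomatic_individual_sends_all_to_carrier_set(self, mini_panel):
        ind = make_individual("I1", "F", variants=[make_variant("GJB2")])
        diagnostic, carrier = triage_phenotype_related(ind, mini_panel)
        assert diagnostic == [] and len(carrier) == 1

    def test_no_token_overlap_stays_carrier(self, bundled_panel):
        # psoriasis gene vs an unrelated complaint: no shared token
        ind = make_individual("I1", "F", phenotypes=["infertility"],
                              variants=[make_variant("IL36RN")])
        diagnostic, carrier = triage_phenotype_related(ind, bundled_panel)
        assert diagnostic == [] and len(carrier) == 1

    def test_explicit_mapping_extends_matching(self, mini_panel):
        mapping = load_phenotype_map(
            __import__("ecscreen").bundled_path("phenotype_map.tsv"))
        ind = make_individual("I1", "M", phenotypes=["deafness"],
                              variants=[make_variant("GJB2")])
        diagnostic, _ = triage_phenotype_related(ind, mini_panel, mapping)
        assert [v.gene for v in diagnostic] == ["GJB2"]

    def test_diagnostic_variants_leave_carrier_stats(self, mini_panel):
        """A diagnosed individual's diagnostic variants never count toward
        the positive-carrier numerator."""
        symptomatic = make_individual(
            "I1", "F", phenotypes=["hearing loss"],
            variants=[make_variant("GJB2", zyg=Zygosity.HOM)])
        silent = make_individual("I2", "F",
                                 variants=[make_variant("GJB2")])
        for ind in (symptomatic, silent):
            triage_phenotype_related(ind, mini_panel)
        frac, n_pos, n = positive_carrier_rate([symptomatic, silent], mini_panel)
        assert (n_pos, n) == (1, 2)


# ---------------------------------------------------------------------------
# diagnosis
# ---------------------------------------------------------------------------

class TestDiagnosis:
    def test_biallelic_with_matching_phenotype_is_diagnosed(self, mini_panel):
        ind = make_individual("I1", "F", phenotypes=["hearing loss"],
                              variants=[make_variant("GJB2", zyg=Zygosity.HOM)])
        (res,) = diagnose_individual(ind, mini_panel)
        assert res.diagnosed and res.pattern == "biallelic"
        assert not res.penetrance_note

    def test_single_het_in_ar_gene_is_not_diagnosed(self, mini_panel):
        ind = make_individual("I1", "F", phenotypes=["hearing loss"],
                              variants=[make_variant("GJB2")])
        assert diagnose_individual(ind, mini_panel) == []

    def test_compound_het_flagged_phase_unconfirmed(self, mini_panel):
        ind = make_individual(
            "I1", "F", phenotypes=["hearing loss"],
            variants=[make_variant("GJB2", "c.109G>A"),
                      make_variant("GJB2", "c.235delC")])
        (res,) = diagnose_individual(ind, mini_panel)
        assert res.diagnosed and res.phase_unconfirmed
        assert res.pattern == "potentially_biallelic"

    def test_genotype_positive_phenotype_negative_is_penetrance_note(
            self, mini_panel):
        ind = make_individual("I1", "M",
                              variants=[make_variant("GJB2", zyg=Zygosity.HOM)])
        (res,) = diagnose_individual(ind, mini_panel)
        assert not res.diagnosed and res.penetrance_note

    def test_hemizygous_male_xl_diagnosed(self, mini_panel):
        ind = make_individual(
            "I1", "M", phenotypes=["muscular dystrophy"],
            variants=[make_variant("DMD", zyg=Zygosity.HEMI)])
        (res,) = diagnose_individual(ind, mini_panel)
        assert res.diagnosed and res.pattern == "hemi-XL"

    def test_xl_het_female_is_carrier_not_diagnosis(self, mini_panel):
        ind = make_individual("I1", "F", phenotypes=["muscular dystrophy"],
                              variants=[make_variant("DMD")])
        assert diagnose_individual(ind, mini_panel) == []

    def test_ad_het_with_phenotype_diagnosed(self, mini_panel):
        ind = make_individual("I1", "F", phenotypes=["dilated cardiomyopathy"],
                              variants=[make_variant("TTN")])
        (res,) = diagnose_individual(ind, mini_panel)
        assert res.diagnosed and res.pattern == "het-AD"

    def test_penetrance_estimate_over_homozygote_series(self, mini_panel):
        """20 hypomorph homozygotes of whom 6 report the phenotype give a
        penetrant fraction of 30%."""
        cohort = []
        for i in range(20):
            ind = make_individual(
                f"H{i}", "F",
                phenotypes=["hearing loss"] if i < 6 else [],
                variants=[make_variant("GJB2", zyg=Zygosity.HOM)])
            cohort.append(ind)
        diagnoses = [d for ind in cohort
                     for d in diagnose_individual(ind, mini_panel)]
        frac, affected, total = penetrance_estimate(diagnoses, "GJB2")
        assert (affected, total) == (6, 20)
        assert frac == pytest.approx(0.30)


# ---------------------------------------------------------------------------
# ARC rule engine: examples
# ---------------------------------------------------------------------------

P, LP, VUS = AcmgClass.P, AcmgClass.LP, AcmgClass.VUS


class TestCallArcExamples:
    def test_both_plp_same_ar_gene(self, mini_panel):
        couple = make_couple("C1", [make_variant("GJB2")],
                             [make_variant("GJB2")])
        arc = call_arc(couple, mini_panel)
        assert arc.at_risk_genes[0].rule is ArcRule.BOTH_PLP_AR
        assert arc.severity is Severity.MODERATE and not arc.vus_involved

    def test_female_plp_xl_fires_irrespective_of_male(self, mini_panel):
        couple = make_couple("C1", [make_variant("DMD", "c.9100C>T")], [])
        arc = call_arc(couple, mini_panel)
        assert arc.at_risk_genes[0].rule is ArcRule.FEMALE_PLP_XL
        assert arc.severity is Severity.PROFOUND

    def test_male_xl_carriage_alone_does_not_fire(self, mini_panel):
        couple = make_couple("C1", [], [make_variant("DMD", "c.9100C>T")])
        assert call_arc(couple, mini_panel) is None

    def test_disjoint_gene_sets_are_negative(self, mini_panel):
        couple = make_couple("C1", [make_variant("GJB2")],
                             [make_variant("TTN")])
        assert call_arc(couple, mini_panel) is None

    @pytest.mark.parametrize(
        "vus_scores, evidence, expect_arc",
        [
            (DELETERIOUS, (), True),     # in-silico support alone suffices
            (NEUTRAL, (), False),        # no proband, consensus neutral
            (NEUTRAL, ("GJB2",), True),  # proband segregation overrides
            (None, (), False),           # indeterminate consensus, no proband
            (None, ("GJB2",), True),
        ],
    )
    def test_plp_plus_vus_requires_evidence(self, mini_panel, vus_scores,
                                            evidence, expect_arc):
        couple = make_couple(
            "C1",
            [make_variant("GJB2", cls=P)],
            [make_variant("GJB2", cls=VUS, scores=vus_scores)],
            evidence=evidence,
        )
        arc = call_arc(couple, mini_panel)
        if expect_arc:
            assert arc.at_risk_genes[0].rule is ArcRule.PLP_PLUS_VUS
            assert arc.vus_involved
        else:
            assert arc is None

    def test_both_vus_requires_evidence_on_both_sides(self, mini_panel):
        fv = make_variant("GJB2", cls=VUS, scores=DELETERIOUS)
        mv = make_variant("GJB2", cls=VUS, scores=NEUTRAL)
        assert call_arc(make_couple("C1", [fv], [mv]), mini_panel) is None
        mv2 = make_variant("GJB2", cls=VUS, scores=DELETERIOUS)
        arc = call_arc(make_couple("C2", [fv], [mv2]), mini_panel)
        assert arc.at_risk_genes[0].rule is ArcRule.BOTH_VUS

    def test_highest_class_first_matching(self, mini_panel):
        """A partner with both P and VUS in a gene is matched through the P:
        never reported as PLP_plus_VUS."""
        fvars = [make_variant("GJB2", "c.109G>A", cls=P),
                 make_variant("GJB2", "c.235delC", cls=VUS, scores=DELETERIOUS)]
        mvars = [make_variant("GJB2", "c.109G>A", cls=LP)]
        arc = call_arc(make_couple("C1", fvars, mvars), mini_panel)
        (risk,) = arc.at_risk_genes
        assert risk.rule is ArcRule.BOTH_PLP_AR
        assert risk.female_class is P and risk.male_class is LP

    def test_multiple_at_risk_genes_all_reported_highest_severity(self,
                                                                  mini_panel):
        couple = make_couple(
            "C1",
            [make_variant("GJB2"), make_variant("DMD", "c.9100C>T")],
            [make_variant("GJB2")])
        arc = call_arc(couple, mini_panel)
        assert {r.gene for r in arc.at_risk_genes} == {"GJB2", "DMD"}
        assert arc.severity is Severity.PROFOUND

    def test_rule_exclusivity_over_class_pairs(self, mini_panel):
        """For one AR gene, the rules are mutually exclusive over every
        combination of per-partner class sets."""
        options = {
            "none": [],
            "P": [make_variant("GJB2", "c.1", cls=P)],
            "VUS": [make_variant("GJB2", "c.2", cls=VUS, scores=DELETERIOUS)],
            "P+VUS": [make_variant("GJB2", "c.1", cls=P),
                      make_variant("GJB2", "c.2", cls=VUS, scores=DELETERIOUS)],
        }
        for fkey, mkey in itertools.product(options, repeat=2):
            couple = make_couple("C1", options[fkey], options[mkey])
            arc = call_arc(couple, mini_panel)
            if arc is None:
                continue
            assert len(arc.at_risk_genes) == 1  # exactly one rule per gene


# ---------------------------------------------------------------------------
# ARC rule engine: brute-force oracle equivalence + monotonicity
# ---------------------------------------------------------------------------

def oracle_call_arc(couple, panel):
    """Direct enumeration of every (gene, female-variant, male-variant)
    combination against the rule text; independent of the engine."""
    def supported(v, gene):
        return (gene in couple.proband_evidence
                or in_silico_consensus(v.scores) is Consensus.DELETERIOUS)

    hits = {}
    for entry in panel:
        g = entry.symbol
        fvars = [v for v in couple.female.variants if v.gene == g]
        mvars = [v for v in couple.male.variants if v.gene == g]
        if entry.inheritance is Inheritance.XL:
            if any(v.acmg_class.is_plp for v in fvars):
                hits[g] = ArcRule.FEMALE_PLP_XL
            continue
        if entry.inheritance is not Inheritance.AR:
            continue
        if any(f.acmg_class.is_plp and m.acmg_class.is_plp
               for f in fvars for m in mvars):
            hits[g] = ArcRule.BOTH_PLP_AR
        elif any(f.acmg_class.is_plp and m.acmg_class is VUS and supported(m, g)
                 for f in fvars for m in mvars) or \
            any(m.acmg_class.is_plp and f.acmg_class is VUS and supported(f, g)
                for f in fvars for m in mvars):
            hits[g] = ArcRule.PLP_PLUS_VUS
        elif any(f.acmg_class is VUS and m.acmg_class is VUS
                 and supported(f, g) and supported(m, g)
                 for f in fvars for m in mvars):
            hits[g] = ArcRule.BOTH_VUS
    return hits


def random_cohort(rng, panel, n_couples=5):
    genes = [g.symbol for g in panel]
    couples = []
    for i in range(n_couples):
        def draw_variants(prefix):
            out = []
            for g in rng.sample(genes, k=rng.randint(0, 3)):
                cls = rng.choice([P, LP, VUS, VUS])
                scores = rng.choice([DELETERIOUS, NEUTRAL, None])
                out.append(make_variant(g, f"c.{rng.randint(1, 3)}A>G",
                                        cls=cls, scores=scores))
            return out
        evidence = set(rng.sample(genes, k=rng.randint(0, 2)))
        couples.append(make_couple(f"C{i}", draw_variants("F"),
                                   draw_variants("M"), evidence=evidence))
    return couples


@pytest.fixture(scope="module")
def oracle_panel():
    entries = []
    for i, inh in enumerate([Inheritance.AR] * 4 + [Inheritance.XL] * 2):
        entries.append(GenePanelEntry(
            symbol=f"G{i}", omim_id=100000 + i, disease=f"condition {i}",
            inheritance=inh, severity=Severity.MODERATE, carrier_freq=0.1,
            variants=[PanelVariant("c.1A>G", AcmgClass.P, 1.0)]))
    return entries


def test_engine_matches_rule_text_oracle(oracle_panel):
    rng = random.Random(20260101)
    for _ in range(300):
        for couple in random_cohort(rng, oracle_panel):
            arc = call_arc(couple, oracle_panel)
            engine = ({r.gene: r.rule for r in arc.at_risk_genes}
                      if arc else {})
            assert engine == oracle_call_arc(couple, oracle_panel)


def test_removing_vus_never_creates_or_alters_plp_calls(oracle_panel):
    """Dropping all VUS records never creates a new at-risk couple and never
    changes a pure-P/LP rule call."""
    rng = random.Random(20260202)
    for _ in range(200):
        for couple in random_cohort(rng, oracle_panel):
            before = call_arc(couple, oracle_panel)
            stripped = make_couple(
                couple.id,
                [v for v in couple.female.variants if v.acmg_class is not VUS],
                [v for v in couple.male.variants if v.acmg_class is not VUS],
                evidence=couple.proband_evidence)
            after = call_arc(stripped, oracle_panel)
            plp_rules = (ArcRule.BOTH_PLP_AR, ArcRule.FEMALE_PLP_XL)
            before_plp = {(r.gene, r.rule) for r in
                          (before.at_risk_genes if before else [])
                          if r.rule in plp_rules}
            after_all = {(r.gene, r.rule) for r in
                         (after.at_risk_genes if after else [])}
            assert after_all == before_plp  # nothing new, P/LP calls intact


# ---------------------------------------------------------------------------
# secondary findings
# ---------------------------------------------------------------------------

class TestSecondaryFindings:
    def test_asymptomatic_ad_plp_is_sf(self, mini_panel):
        ind = make_individual("I1", "M", variants=[make_variant("TTN")])
        triage_phenotype_related(ind, mini_panel)
        (sf,) = detect_secondary_findings(ind, mini_panel, {"TTN"})
        assert sf.gene == "TTN" and sf.acmg_sf_listed

    def test_phenotype_related_ad_variant_is_not_sf(self, bundled_panel):
        ind = make_individual("I1", "F", phenotypes=["aniridia"],
                              variants=[make_variant("PAX6", "c.718C>T")])
        triage_phenotype_related(ind, bundled_panel)
        assert detect_secondary_findings(ind, bundled_panel, {"PAX6"}) == []
        # and it is a diagnostic finding instead
        (res,) = diagnose_individual(ind, bundled_panel)
        assert res.diagnosed

    def test_ad_vus_and_recessive_genes_excluded(self, mini_panel):
        ind = make_individual("I1", "M",
                              variants=[make_variant("TTN", cls=VUS),
                                        make_variant("GJB2")])
        triage_phenotype_related(ind, mini_panel)
        assert detect_secondary_findings(ind, mini_panel, {"TTN"}) == []

    def test_sf_gene_summary_shares(self, mini_panel):
        inds = [make_individual(f"I{i}", "M", variants=[make_variant("TTN")])
                for i in range(3)]
        inds.append(make_individual("I9", "F",
                                    variants=[make_variant("TTN"),
                                              make_variant("GJB2")]))
        findings = [f for ind in inds
                    for f in detect_secondary_findings(ind, mini_panel, set())]
        table = sf_gene_summary(findings)
        assert table.loc["TTN", "positive_case"] == 4
        assert table.loc["TTN", "pct_of_positive"] == 100.0


# ---------------------------------------------------------------------------
# subgroup rates
# ---------------------------------------------------------------------------

def test_arc_rate_by_subgroup_counts_and_na(mini_panel):
    couples = []
    for i in range(4):
        couples.append(make_couple(f"A{i}", [make_variant("GJB2")],
                                   [make_variant("GJB2")],
                                   subgroup=Subgroup.CONSANGUINEOUS_MARRIAGE))
    for i in range(21):
        couples.append(make_couple(f"B{i}",
                                   subgroup=Subgroup.CONSANGUINEOUS_MARRIAGE))
    for i in range(10):
        couples.append(make_couple(f"R{i}",
                                   subgroup=Subgroup.ROUTINE_SCREENING))
    arcs = [a for a in (call_arc(c, mini_panel) for c in couples) if a]
    rates = arc_rate_by_subgroup(couples, arcs)
    assert rates.loc["consanguineous_marriage", "arc_rate_pct"] == 16.0
    assert rates.loc["routine_screening", "arc_rate_pct"] == 0.0
    assert rates.loc["patients", "arc_rate_pct"] != \
        rates.loc["patients", "arc_rate_pct"]  # empty subgroup -> NaN
    assert rates.loc["all", "n_arc"] == 4
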