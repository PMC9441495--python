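import pytest

from ecscreen import (
    AcmgClass,
    ClassifiedVariant,
    Couple,
    GenePanelEntry,
    Individual,
    Inheritance,
    PanelVariant,
    PredictorScores,
    Severity,
    Subgroup,
    Zygosity,
    bundled_path,
    load_panel,
)


def make_variant(gene, hgvs="c.1A>G", cls=AcmgClass.P, zyg=Zygosity.HET,
                 scores=None):
    return ClassifiedVariant(gene=gene, hgvs_c=hgvs, acmg_class=cls,
                             zygosity=zyg, scores=scores)


def make_individual(iid, sex="F", phenotypes=(), variants=()):
    return Individual(id=iid, sex=sex, phenotypes=list(phenotypes),
                      variants=list(variants))


def make_couple(cid, fvars=(), mvars=(), subgroup=Subgroup.ROUTINE_SCREENING,
                evidence=()):
    return Couple(
        id=cid,
        female=make_individual(f"{cid}F", "F", variants=fvars),
        male=make_individual(f"{cid}M", "M", variants=mvars),
        subgroup=subgroup,
        proband_evidence=set(evidence),
    )


DELETERIOUS = PredictorScores(sift=0.01, polyphen2=0.95, provean=-3.0,
                              mutationtaster="D")
NEUTRAL = PredictorScores(sift=0.8, polyphen2=0.1, provean=5.0,
                          mutationtaster="N")


@pytest.fixture(scope="session")
def bundled_panel():
    return load_panel(bundled_path("example_panel.tsv"))


@pytest.fixture()
def mini_panel():
    """Three genes: one AR, one XL, one AD, with simple spectra."""
    return [
        GenePanelEntry(
            symbol="GJB2", omim_id=121011, disease="GJB2-related hearing loss",
            inheritance=Inheritance.AR, severity=Severity.MODERATE,
            carrier_freq=0.2,
            variants=[PanelVariant("c.109G>A", AcmgClass.P, 0.9),
                      PanelVariant("c.235delC", AcmgClass.P, 0.1)],
        ),
        GenePanelEntry(
            symbol="DMD", omim_id=300377, disease="Duchenne muscular dystrophy",
            inheritance=Inheritance.XL, severity=Severity.PROFOUND,
            carrier_freq=0.01,
            variants=[PanelVariant("c.9100C>T", AcmgClass.P, 1.0)],
        ),
        GenePanelEntry(
            symbol="TTN", omim_id=188840, disease="Dilated cardiomyopathy",
            inheritance=Inheritance.AD, severity=Severity.UNCLASSIFIED,
            carrier_freq=0.005,
            variants=[PanelVariant("c.490del", AcmgClass.P, 1.0)],
        ),
    ]
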