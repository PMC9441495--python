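"""Cohort I/O: per-individual classified variant call sets and couple manifests.

The canonical interchange format is a pair of TSV files:

* individuals TSV — columns ``id, sex, subgroup, phenotypes, variants``;
  phenotypes are ``|``-separated free-text terms; variants are ``;``-separated
  tokens ``gene:hgvs:class:zygosity[:sift,pp2,provean,mt]`` (empty score slots
  mean the tool was not run).
* couples TSV — columns ``couple_id, female_id, male_id, subgroup,
  proband_evidence, decision``; proband_evidence is a ``|``-separated list of
  gene symbols for which segregation was confirmed in a proband.

A minimal VCF ingestion path is provided as a convenience: only genotype and
two INFO tags (gene symbol, ACMG class) are interpreted — no coordinates, no
normalisation; the classification labels are authoritative inputs.

Benign and likely-benign observed variants are dropped at ingestion (with a
logged count): the analysis is restricted to P/LP plus VUS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .panel_model import (
    AcmgClass,
    ParseError,
    PredictorScores,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Zygosity",
    "Subgroup",
    "Decision",
    "ClassifiedVariant",
    "Individual",
    "Couple",
    "read_cohort",
    "write_cohort",
    "read_vcf_minimal",
    "write_reports",
]


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Subgroup(str, Enum):
    """Reason-for-screening subgroup of a couple (exactly one of six)."""

    INFERTILITY = "infertility"
    RECURRENT_MISCARRIAGE_STILLBORN = "recurrent_miscarriage_stillborn"
    BIRTH_DEFECT_ULTRASOUND_ANOMALY = "birth_defect_ultrasound_anomaly"
    PATIENTS = "patients"
    CONSANGUINEOUS_MARRIAGE = "consanguineous_marriage"
    ROUTINE_SCREENING = "routine_screening"


class Decision(str, Enum):
    """Post-test reproductive decision of an at-risk couple."""

    MEASURES_TAKEN = "measures_taken"
    NO_MEASURES = "no_measures"
    LOST_TO_FOLLOWUP = "lost_to_followup"
    NA = "NA"


@dataclass
class ClassifiedVariant:
    """One observed, already-classified variant in one individual.

    ``phenotype_related`` is set by phenotype triage (see screening_rules):
    variants that can explain the individual's own symptoms are diagnostic
    candidates and are excluded from carrier statistics.
    """

    gene: str
    hgvs_c: str
    acmg_class: AcmgClass
    zygosity: Zygosity
    transcript: str = ""
    scores: PredictorScores | None = None
    phenotype_related: bool = False

    def __post_init__(self) -> None:
        self.acmg_class = AcmgClass(self.acmg_class)
        self.zygosity = Zygosity(self.zygosity)


@dataclass
class Individual:
    id: str
    sex: str  # "F" or "M"
    phenotypes: list[str] = field(default_factory=list)
    variants: list[ClassifiedVariant] = field(default_factory=list)
    subgroup: Subgroup | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"individual {self.id}: sex must be F or M")
        if self.sex == "F" and any(v.zygosity is Zygosity.HEMI for v in self.variants):
            raise ValidationError(
                f"individual {self.id}: female individuals cannot carry "
                "hemizygous records"
            )
        seen: set[tuple[str, str]] = set()
        for v in self.variants:
            key = (v.gene, v.hgvs_c)
            if key in seen:
                raise ValidationError(
                    f"individual {self.id}: duplicate variant {v.gene}:{v.hgvs_c}"
                )
            seen.add(key)


@dataclass
class Couple:
    id: str
    female: Individual
    male: Individual
    subgroup: Subgroup
    proband_evidence: set[str] = field(default_factory=set)
    decision: Decision = Decision.NA

    def __post_init__(self) -> None:
        self.subgroup = Subgroup(self.subgroup)
        self.decision = Decision(self.decision)
        if self.female.sex != "F" or self.male.sex != "M":
            raise ValidationError(
                f"couple {self.id}: pairing does not match individual sexes "
                f"({self.female.id}={self.female.sex}, {self.male.id}={self.male.sex})"
            )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_IND_HEADER = ("id", "sex", "subgroup", "phenotypes", "variants")
_CPL_HEADER = ("couple_id", "female_id", "male_id", "subgroup",
               "proband_evidence", "decision")


def _fmt_float(x: float) -> str:
    return repr(float(x))  # shortest round-trip representation


def _encode_scores(s: PredictorScores) -> str:
    return ",".join([
        _fmt_float(s.sift) if s.sift is not None else "",
        _fmt_float(s.polyphen2) if s.polyphen2 is not None else "",
        _fmt_float(s.provean) if s.provean is not None else "",
        s.mutationtaster or "",
    ])


def _decode_scores(cell: str, *, where: str) -> PredictorScores | None:
    parts = cell.split(",")
    if len(parts) != 4:
        raise ParseError(f"{where}: score field {cell!r} is not sift,pp2,provean,mt")
    try:
        return PredictorScores(
            sift=float(parts[0]) if parts[0] else None,
            polyphen2=float(parts[1]) if parts[1] else None,
            provean=float(parts[2]) if parts[2] else None,
            mutationtaster=parts[3] or None,
        )
    except ValueError as exc:
        raise ParseError(f"{where}: bad score field {cell!r}") from exc


def _encode_variant(v: ClassifiedVariant) -> str:
    tok = f"{v.gene}:{v.hgvs_c}:{v.acmg_class.value}:{v.zygosity.value}"
    if v.scores is not None:
        tok += ":" + _encode_scores(v.scores)
    return tok


def _decode_variant(token: str, *, where: str) -> ClassifiedVariant:
    parts = token.split(":")
    if len(parts) not in (4, 5):
        raise ParseError(
            f"{where}: variant token {token!r} is not "
            "gene:hgvs:class:zygosity[:scores]"
        )
    try:
        cls = AcmgClass(parts[2])
        zyg = Zygosity(parts[3])
    except ValueError as exc:
        raise ParseError(f"{where}: bad class/zygosity in {token!r}") from exc
    scores = _decode_scores(parts[4], where=where) if len(parts) == 5 else None
    return ClassifiedVariant(gene=parts[0], hgvs_c=parts[1], acmg_class=cls,
                             zygosity=zyg, scores=scores)


def _read_tsv(path: Path, expected_header: Sequence[str]) -> list[tuple[int, dict]]:
    lines = [
        (i + 1, ln)
        for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ParseError(f"{path.name}: empty file (no header)")
    header = [c.strip() for c in lines[0][1].split("\t")]
    missing = [c for c in expected_header if c not in header]
    if missing:
        raise ParseError(f"{path.name}: header lacks column(s) {missing}")
    rows = []
    for lineno, raw in lines[1:]:
        cells = raw.split("\t")
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        rows.append((lineno, dict(zip(header, cells))))
    return rows


def read_cohort(individuals_path: str | Path,
                couples_path: str | Path) -> tuple[list[Individual], list[Couple]]:
    """Read and validate a cohort from the individuals + couples TSVs.

    Benign/likely-benign variant records are dropped (count logged).  Raises
    on dangling individual references, sex mismatches, duplicate ids, and any
    malformed row (naming the line).
    """
    individuals_path, couples_path = Path(individuals_path), Path(couples_path)
    individuals: list[Individual] = []
    by_id: dict[str, Individual] = {}
    n_benign_dropped = 0
    for lineno, rec in _read_tsv(individuals_path, _IND_HEADER):
        where = f"{individuals_path.name} line {lineno}"
        variants = []
        for token in filter(None, (t.strip() for t in rec["variants"].split(";"))):
            v = _decode_variant(token, where=where)
            if v.acmg_class in (AcmgClass.B, AcmgClass.LB):
                n_benign_dropped += 1
                continue
            variants.append(v)
        phenotypes = [p.strip() for p in rec["phenotypes"].split("|") if p.strip()]
        subgroup = Subgroup(rec["subgroup"]) if rec["subgroup"].strip() else None
        ind = Individual(id=rec["id"].strip(), sex=rec["sex"].strip(),
                         phenotypes=phenotypes, variants=variants, subgroup=subgroup)
        if ind.id in by_id:
            raise ValidationError(f"{where}: duplicate individual id {ind.id}")
        individuals.append(ind)
        by_id[ind.id] = ind
    if n_benign_dropped:
        logger.info("dropped %d benign/likely-benign variant records at ingestion",
                    n_benign_dropped)

    couples: list[Couple] = []
    seen_cids: set[str] = set()
    for lineno, rec in _read_tsv(couples_path, _CPL_HEADER):
        where = f"{couples_path.name} line {lineno}"
        cid = rec["couple_id"].strip()
        if cid in seen_cids:
            raise ValidationError(f"{where}: duplicate couple id {cid}")
        seen_cids.add(cid)
        for ref in (rec["female_id"].strip(), rec["male_id"].strip()):
            if ref not in by_id:
                raise ValidationError(
                    f"couple {cid}: references unknown individual id {ref!r}"
                )
        evidence = {g.strip() for g in rec["proband_evidence"].split("|") if g.strip()}
        decision = Decision(rec["decision"]) if rec["decision"].strip() else Decision.NA
        couples.append(Couple(
            id=cid,
            female=by_id[rec["female_id"].strip()],
            male=by_id[rec["male_id"].strip()],
            subgroup=Subgroup(rec["subgroup"].strip()),
            proband_evidence=evidence,
            decision=decision,
        ))
    return individuals, couples


def write_cohort(individuals: Sequence[Individual], couples: Sequence[Couple],
                 out_dir: str | Path) -> tuple[Path, Path]:
    """Write the cohort TSVs (inverse of :func:`read_cohort`)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ind_path = out_dir / "individuals.tsv"
    cpl_path = out_dir / "couples.tsv"

    rows = ["\t".join(_IND_HEADER)]
    for ind in individuals:
        rows.append("\t".join([
            ind.id,
            ind.sex,
            ind.subgroup.value if ind.subgroup else "",
            "|".join(ind.phenotypes),
            ";".join(_encode_variant(v) for v in ind.variants),
        ]))
    ind_path.write_text("\n".join(rows) + "\n")

    rows = ["\t".join(_CPL_HEADER)]
    for c in couples:
        rows.append("\t".join([
            c.id, c.female.id, c.male.id, c.subgroup.value,
            "|".join(sorted(c.proband_evidence)), c.decision.value,
        ]))
    cpl_path.write_text("\n".join(rows) + "\n")
    return ind_path, cpl_path


# ---------------------------------------------------------------------------
# Minimal VCF ingestion
# ---------------------------------------------------------------------------

def read_vcf_minimal(path: str | Path, class_tag: str = "ACMG",
                     gene_tag: str = "GENE", hgvs_tag: str = "HGVS",
                     sex: str | None = None) -> list[ClassifiedVariant]:
    """Read classified variants from a single-sample VCF.

    Only genotype and the named INFO tags are interpreted.  GT mapping:
    0/1 -> het, 1/1 -> hom, a haploid non-reference call -> hemi.  Records
    lacking the class tag are skipped (count logged); benign/likely-benign
    records are dropped like in the TSV path.  A diploid het call on chrX for
    a declared male is accepted but logged as anomalous and kept as het.
    """
    import pysam

    variants: list[ClassifiedVariant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ParseError(f"{Path(path).name}: VCF has no sample column")
        sample = samples[0]
        for rec in vf:
            info = rec.info
            if class_tag not in info:
                n_skipped += 1
                continue
            cls_value = info[class_tag]
            if isinstance(cls_value, tuple):
                cls_value = cls_value[0]
            try:
                cls = AcmgClass(str(cls_value))
            except ValueError as exc:
                raise ValidationError(
                    f"{Path(path).name}: unknown ACMG class {cls_value!r} at "
                    f"{rec.chrom}:{rec.pos}"
                ) from exc
            gene = info.get(gene_tag)
            if isinstance(gene, tuple):
                gene = gene[0]
            gene = str(gene) if gene is not None else ""
            hgvs = info.get(hgvs_tag)
            if isinstance(hgvs, tuple):
                hgvs = hgvs[0]
            if hgvs is None:
                alt = rec.alts[0] if rec.alts else "."
                hgvs = f"{rec.chrom}:g.{rec.pos}{rec.ref}>{alt}"
            gt = rec.samples[sample].get("GT", ())
            alts = [a for a in gt if a is not None]
            if not alts or all(a == 0 for a in alts):
                continue
            if len(alts) == 1 and len(gt) == 1:
                zyg = Zygosity.HEMI
            elif all(a != 0 for a in alts):
                zyg = Zygosity.HOM
            else:
                zyg = Zygosity.HET
                if sex == "M" and rec.chrom.lstrip("chr") == "X":
                    logger.warning(
                        "anomalous diploid het call on chrX for male sample at "
                        "%s:%d; kept as het", rec.chrom, rec.pos,
                    )
            if cls in (AcmgClass.B, AcmgClass.LB):
                n_skipped += 1
                continue
            variants.append(ClassifiedVariant(gene=gene, hgvs_c=str(hgvs),
                                              acmg_class=cls, zygosity=zyg))
    if n_skipped:
        logger.info("skipped %d VCF records (no class tag or benign)", n_skipped)
    return variants


# ---------------------------------------------------------------------------
# Report writer
# ---------------------------------------------------------------------------

def write_reports(individuals: Sequence[Individual], panel, results,
                  out_dir: str | Path) -> dict[str, Path]:
    """Emit the three report tables plus a JSON summary.

    ``results`` is any object exposing ``diagnoses`` (DiagnosisResult list),
    ``arcs`` (ARCResult list), ``secondary_findings`` (SecondaryFinding list)
    and ``summary`` (JSON-serialisable mapping); see
    :func:`ecscreen.cli.run_pipeline`.  The three tables mirror the clinical
    reporting categories: diagnostic findings, at-risk couples, and carrier
    status + secondary findings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_gene = {g.symbol: g for g in panel}

    diag_rows = ["\t".join(("individual_id", "gene", "pattern", "diagnosed",
                            "penetrance_note", "phase_unconfirmed"))]
    for d in results.diagnoses:
        diag_rows.append("\t".join([
            d.individual_id, d.gene, d.pattern, str(d.diagnosed).lower(),
            str(d.penetrance_note).lower(), str(d.phase_unconfirmed).lower(),
        ]))
    diag_path = out_dir / "diagnostic.tsv"
    diag_path.write_text("\n".join(diag_rows) + "\n")

    arc_rows = ["\t".join(("couple_id", "genes", "rules", "female_classes",
                           "male_classes", "severity", "vus_involved"))]
    for a in results.arcs:
        arc_rows.append("\t".join([
            a.couple_id,
            ";".join(g.gene for g in a.at_risk_genes),
            ";".join(g.rule.value for g in a.at_risk_genes),
            ";".join(g.female_class.value if g.female_class else "-"
                     for g in a.at_risk_genes),
            ";".join(g.male_class.value if g.male_class else "-"
                     for g in a.at_risk_genes),
            a.severity.value if a.severity is not None else "unclassified",
            str(a.vus_involved).lower(),
        ]))
    arc_path = out_dir / "arc.tsv"
    arc_path.write_text("\n".join(arc_rows) + "\n")

    sf_keys = {(s.individual_id, s.gene, s.variant.hgvs_c)
               for s in results.secondary_findings}
    sf_listed = {(s.individual_id, s.gene, s.variant.hgvs_c): s.acmg_sf_listed
                 for s in results.secondary_findings}
    carrier_rows = ["\t".join(("individual_id", "gene", "hgvs_c", "acmg_class",
                               "zygosity", "secondary_finding", "acmg_sf_listed"))]
    for ind in individuals:
        for v in ind.variants:
            entry = by_gene.get(v.gene)
            if entry is None or not v.acmg_class.is_plp or v.phenotype_related:
                continue
            key = (ind.id, v.gene, v.hgvs_c)
            is_sf = key in sf_keys
            from .panel_model import Inheritance
            if entry.inheritance is Inheritance.AD and not is_sf:
                continue  # AD variants are reported only as SFs
            carrier_rows.append("\t".join([
                ind.id, v.gene, v.hgvs_c, v.acmg_class.value, v.zygosity.value,
                str(is_sf).lower(), str(sf_listed.get(key, False)).lower(),
            ]))
    carrier_path = out_dir / "carrier_sf.tsv"
    carrier_path.write_text("\n".join(carrier_rows) + "\n")

    summary_path = out_dir / "summary.json"
    summary_path.write_text(
        json.dumps(results.summary, indent=2, sort_keys=True) + "\n"
    )
    return {"diagnostic": diag_path, "arc": arc_path,
            "carrier_sf": carrier_path, "summary": summary_path}
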