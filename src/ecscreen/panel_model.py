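"""Domain model for an expanded-carrier-screening (ECS) gene panel.

An ECS panel is a list of disease genes, each with an inheritance mode
(autosomal recessive, X-linked, or autosomal dominant), a disease-severity
tier, a population carrier frequency used by the cohort simulator, and a
variant spectrum: the reportable alleles of the gene together with their ACMG
classification and their relative share of carried alleles.

The panel file dialect is tab-separated, one gene per row, with the variant
spectrum encoded as a semicolon-separated list of ``hgvs:class:rel_freq`` (an
optional fourth ``:transcript`` field may follow).  An equivalent JSON
representation is supported.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "EcsError",
    "ParseError",
    "ValidationError",
    "Inheritance",
    "Severity",
    "AcmgClass",
    "PredictorScores",
    "PanelVariant",
    "GenePanelEntry",
    "severity_rank",
    "load_panel",
    "write_panel",
    "load_severity_overrides",
    "apply_severity_overrides",
    "plp_spectrum_fraction",
]

REL_FREQ_TOL = 1e-9


class EcsError(Exception):
    """Base class for every error raised by this package."""


class ParseError(EcsError):
    """A file could not be parsed in its declared dialect."""


class ValidationError(EcsError):
    """Parsed or constructed content violates a domain invariant."""


class Inheritance(str, Enum):
    """Mendelian inheritance mode of a panel gene."""

    AR = "AR"
    XL = "XL"
    AD = "AD"


class Severity(str, Enum):
    """Disease-severity tier used to stratify at-risk-couple counselling.

    ``UNCLASSIFIED`` marks genes with no tier assignment; such genes are
    excluded from the decision analysis rather than silently tiered.
    """

    PROFOUND = "profound"
    SEVERE = "severe"
    MODERATE = "moderate"
    MILD = "mild"
    UNCLASSIFIED = "unclassified"


_SEVERITY_RANK: dict[Severity, int] = {
    Severity.MILD: 1,
    Severity.MODERATE: 2,
    Severity.SEVERE: 3,
    Severity.PROFOUND: 4,
}


def severity_rank(tier: Severity) -> int:
    """Strict total order over the four named tiers: profound > severe >
    moderate > mild.

    When a couple is at risk for several genes, the couple-level tier is the
    one with the higher rank.  ``UNCLASSIFIED`` has no rank; callers must
    exclude such genes or map them explicitly via a severity-override file.
    """
    tier = Severity(tier)
    if tier not in _SEVERITY_RANK:
        raise ValidationError(
            "severity tier 'unclassified' has no rank; supply a severity "
            "override for the gene or exclude it from the analysis"
        )
    return _SEVERITY_RANK[tier]


class AcmgClass(str, Enum):
    """ACMG variant classification label.

    Reportability is ordered P >= LP >= VUS > LB >= B.  P/LP are reportable
    carrier alleles; VUS participates only in the at-risk-couple rules that
    explicitly allow it; LB/B are dropped at ingestion.
    """

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"

    @property
    def reportability(self) -> int:
        return _REPORTABILITY[self]

    @property
    def is_plp(self) -> bool:
        return self in (AcmgClass.P, AcmgClass.LP)


_REPORTABILITY: dict[AcmgClass, int] = {
    AcmgClass.P: 4,
    AcmgClass.LP: 3,
    AcmgClass.VUS: 2,
    AcmgClass.LB: 1,
    AcmgClass.B: 0,
}


@dataclass(frozen=True)
class PredictorScores:
    """In-silico predictor scores attached to an observed variant.

    Fields are optional; absent tools simply do not vote in the consensus.
    Ranges: SIFT and PolyPhen-2 in [0, 1], PROVEAN in [-14, 14],
    MutationTaster one of A/D/N/P.
    """

    sift: float | None = None
    polyphen2: float | None = None
    provean: float | None = None
    mutationtaster: str | None = None

    def __post_init__(self) -> None:
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise ValidationError(f"SIFT score out of [0,1]: {self.sift}")
        if self.polyphen2 is not None and not 0.0 <= self.polyphen2 <= 1.0:
            raise ValidationError(f"PolyPhen-2 score out of [0,1]: {self.polyphen2}")
        if self.provean is not None and not -14.0 <= self.provean <= 14.0:
            raise ValidationError(f"PROVEAN score out of [-14,14]: {self.provean}")
        if self.mutationtaster is not None and self.mutationtaster not in "ADNP":
            raise ValidationError(
                f"MutationTaster call must be one of A/D/N/P: {self.mutationtaster!r}"
            )

    @property
    def n_available(self) -> int:
        return sum(
            x is not None
            for x in (self.sift, self.polyphen2, self.provean, self.mutationtaster)
        )


@dataclass(frozen=True)
class PanelVariant:
    """One reportable allele in a gene's variant spectrum.

    ``rel_freq`` is this allele's fraction of the gene's sampled carrier
    alleles; the fractions within a gene sum to one.  Only P/LP/VUS appear in
    a panel — benign labels exist only as observed-variant annotations and
    are filtered at ingestion.
    """

    hgvs_c: str
    default_class: AcmgClass
    rel_freq: float
    transcript: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "default_class", AcmgClass(self.default_class))
        if self.default_class in (AcmgClass.B, AcmgClass.LB):
            raise ValidationError(
                f"panel variant {self.hgvs_c}: benign classes are not reportable "
                "panel alleles"
            )
        if not 0.0 < self.rel_freq <= 1.0:
            raise ValidationError(
                f"panel variant {self.hgvs_c}: rel_freq must be in (0,1], "
                f"got {self.rel_freq}"
            )


@dataclass
class GenePanelEntry:
    """One screened gene: identity, inheritance, severity tier, simulation
    carrier frequency, and variant spectrum."""

    symbol: str
    omim_id: int
    disease: str
    inheritance: Inheritance
    severity: Severity = Severity.UNCLASSIFIED
    carrier_freq: float = 0.0
    variants: list[PanelVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inheritance = Inheritance(self.inheritance)
        self.severity = Severity(self.severity)
        if not self.symbol:
            raise ValidationError("gene symbol must be non-empty")
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ValidationError(
                f"{self.symbol}: carrier_freq must lie in [0,1], got {self.carrier_freq}"
            )
        if self.variants:
            total = sum(v.rel_freq for v in self.variants)
            if abs(total - 1.0) > REL_FREQ_TOL:
                raise ValidationError(
                    f"{self.symbol}: variant relative frequencies sum to {total!r}, "
                    "expected 1"
                )


# ---------------------------------------------------------------------------
# Panel readers / writers
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ("symbol", "omim_id", "disease", "inheritance", "severity",
                  "carrier_freq", "variants")
_REQUIRED_COLUMNS = ("symbol", "omim_id", "disease", "inheritance",
                     "carrier_freq", "variants")


def _parse_spectrum(cell: str, *, where: str) -> list[PanelVariant]:
    if not cell.strip():
        return []
    out: list[PanelVariant] = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        parts = token.split(":")
        if len(parts) not in (3, 4):
            raise ParseError(
                f"{where}: variant token {token!r} is not hgvs:class:rel_freq[:transcript]"
            )
        hgvs, cls, freq = parts[0], parts[1], parts[2]
        transcript = parts[3] if len(parts) == 4 else ""
        try:
            rel = float(freq)
        except ValueError as exc:
            raise ParseError(f"{where}: bad rel_freq in {token!r}") from exc
        try:
            out.append(PanelVariant(hgvs, AcmgClass(cls), rel, transcript))
        except ValueError as exc:
            raise ParseError(f"{where}: unknown ACMG class in {token!r}") from exc
    return out


def _format_spectrum(variants: Sequence[PanelVariant]) -> str:
    tokens = []
    for v in variants:
        tok = f"{v.hgvs_c}:{v.default_class.value}:{v.rel_freq!r}"
        if v.transcript:
            tok += f":{v.transcript}"
        tokens.append(tok)
    return ";".join(tokens)


def _entry_from_record(rec: Mapping[str, object], *, where: str) -> GenePanelEntry:
    try:
        variants = rec["variants"]
        if isinstance(variants, str):
            variants = _parse_spectrum(variants, where=where)
        else:
            variants = [
                PanelVariant(
                    str(v["hgvs_c"]),
                    AcmgClass(str(v["default_class"])),
                    float(v["rel_freq"]),
                    str(v.get("transcript", "")),
                )
                for v in variants  # type: ignore[union-attr]
            ]
        return GenePanelEntry(
            symbol=str(rec["symbol"]).strip(),
            omim_id=int(rec["omim_id"]),
            disease=str(rec["disease"]).strip(),
            inheritance=Inheritance(str(rec["inheritance"]).strip()),
            severity=Severity(str(rec.get("severity") or "unclassified").strip()),
            carrier_freq=float(rec["carrier_freq"]),
            variants=variants,
        )
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from exc
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"{where}: malformed panel record ({exc})") from exc


def load_panel(path: str | Path, format: str | None = None) -> list[GenePanelEntry]:
    """Read a gene panel from TSV or JSON and validate every invariant.

    ``format`` is inferred from the file suffix when omitted.  The severity
    column may be absent, in which case tiers default to ``unclassified``.
    Raises :class:`ParseError` naming the offending line, or
    :class:`ValidationError` for duplicate symbols / out-of-range values.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    entries: list[GenePanelEntry] = []
    if fmt == "json":
        records = json.loads(path.read_text())
        for i, rec in enumerate(records):
            entries.append(_entry_from_record(rec, where=f"{path.name} record {i}"))
    elif fmt == "tsv":
        lines = [
            (i + 1, ln)
            for i, ln in enumerate(path.read_text().splitlines())
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        if not lines:
            raise ParseError(f"{path.name}: empty panel file (no header)")
        header = [c.strip() for c in lines[0][1].split("\t")]
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path.name}: header lacks column(s) {missing}")
        for lineno, raw in lines[1:]:
            cells = raw.split("\t")
            if len(cells) < len(header):
                cells += [""] * (len(header) - len(cells))
            rec = dict(zip(header, cells))
            entries.append(_entry_from_record(rec, where=f"{path.name} line {lineno}"))
    else:
        raise ValueError(f"unknown panel format {fmt!r}")

    seen: set[str] = set()
    for e in entries:
        if e.symbol in seen:
            raise ValidationError(f"duplicate gene symbol in panel: {e.symbol}")
        seen.add(e.symbol)
    return entries


def write_panel(panel: Sequence[GenePanelEntry], path: str | Path,
                format: str | None = None) -> Path:
    """Write a panel in the TSV dialect or as JSON (inverse of load_panel)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        records = []
        for e in panel:
            rec = asdict(e)
            rec["inheritance"] = e.inheritance.value
            rec["severity"] = e.severity.value
            for v, pv in zip(rec["variants"], e.variants):
                v["default_class"] = pv.default_class.value
            records.append(rec)
        path.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        rows = ["\t".join(_PANEL_COLUMNS)]
        for e in panel:
            rows.append("\t".join([
                e.symbol, str(e.omim_id), e.disease, e.inheritance.value,
                e.severity.value, repr(e.carrier_freq), _format_spectrum(e.variants),
            ]))
        path.write_text("\n".join(rows) + "\n")
    else:
        raise ValueError(f"unknown panel format {fmt!r}")
    return path


def load_severity_overrides(path: str | Path) -> dict[str, Severity]:
    """Read a two-column TSV (symbol, tier) of severity-tier overrides."""
    out: dict[str, Severity] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cells = raw.split("\t")
        if len(cells) != 2:
            raise ParseError(f"severity overrides line {lineno}: expected 2 columns")
        symbol, tier = cells[0].strip(), cells[1].strip()
        if symbol.lower() == "symbol":
            continue
        try:
            out[symbol] = Severity(tier)
        except ValueError as exc:
            raise ParseError(
                f"severity overrides line {lineno}: unknown tier {tier!r}"
            ) from exc
    return out


def apply_severity_overrides(panel: Iterable[GenePanelEntry],
                             overrides: Mapping[str, Severity]) -> None:
    """Apply tier overrides in place."""
    for entry in panel:
        if entry.symbol in overrides:
            entry.severity = Severity(overrides[entry.symbol])


def plp_spectrum_fraction(entry: GenePanelEntry) -> float:
    """Fraction of a gene's spectrum that is P/LP by default class.

    This is the per-carried-allele probability of a reportable (non-VUS)
    label under the simulator with no VUS downgrading; genes without a
    spectrum contribute 1 (any carried allele counts).
    """
    if not entry.variants:
        return 1.0
    return sum(v.rel_freq for v in entry.variants if v.default_class.is_plp)
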