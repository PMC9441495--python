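# Methods

## Scope and data model

The package models the analysis layer of an expanded-carrier-screening (ECS)
programme. Sequencing, alignment, variant calling and ACMG evidence-code
classification are upstream and out of scope: the inputs are per-individual
variants that already carry an ACMG label (P, LP, VUS, LB, B), a gene panel
(inheritance mode, severity tier, carrier frequency, variant spectrum), and
a couples manifest (pairing, reason-for-screening subgroup, proband
segregation evidence, reproductive decision). Benign and likely-benign
records are dropped at ingestion — the analysis operates on P/LP plus VUS
only.

## Phenotype triage and diagnosis

A variant is *phenotype-related* when its gene's disease name shares at least
one informative token with one of the individual's phenotype terms, or when
an explicit gene→phenotype mapping entry matches (the bundled
`phenotype_map.tsv` supplies clinician-style synonyms such as deafness for
the *GJB2* hearing-loss entry). Generic tokens (`related`, `type`,
`syndrome`, `disease`, `disorder`) never match on their own. Real programmes
perform this mapping by clinician judgement; token overlap plus an
extensible mapping file is the reproducible stand-in, and its failure mode
(a synonym absent from both the disease name and the map) errs toward
keeping a variant in the carrier set.

Diagnosis requires a genotype consistent with the inheritance mode *and* a
phenotype match: homozygous P/LP for AR genes; two or more distinct
heterozygous P/LP variants in one AR gene are *potentially* biallelic (phase
is unknown from unphased calls) and flagged `phase_unconfirmed` rather than
silently diagnosed; any P/LP for AD genes; hemizygous P/LP for XL males.
A fitting genotype without the phenotype is recorded with a
`penetrance_note` — these observations feed penetrance estimates such as the
30% (6/20) penetrant fraction among homozygotes of the *GJB2* c.109G>A
hypomorph. Heterozygous XL carriage in a female is a carrier event, never a
diagnosis; X-linked dominant presentation is outside the default model.

## At-risk-couple rules

Per shared gene, exactly one of four rules can fire, matched highest class
first (a partner with both a P/LP and a VUS in a gene is matched through the
P/LP, so a both-P/LP pairing is never downgraded to P/LP-plus-VUS):

1. both partners P/LP in the same AR gene;
2. female partner P/LP in an XL gene (irrespective of the male — any son
   has a 50% risk);
3. one partner P/LP, the other a VUS of the same AR gene;
4. both partners VUS of the same AR gene.

Rules 3–4 require supporting evidence for every VUS involved: the gene is in
the couple's proband-evidence set (segregation confirmed in an affected
child), or the in-silico consensus calls the VUS deleterious. The consensus
is a strict majority over the available tools at the published cutoffs
(SIFT < 0.05; PolyPhen-2 ≥ 0.447, with ≥ 0.909 "probably damaging";
PROVEAN ≤ −2.5; MutationTaster A/D); ties and empty score sets are
indeterminate, which does **not** support an ARC call. How many predictors
must agree is not standardised anywhere we know of; the majority rule is
this package's documented choice, and the threshold constants are module
attributes for programmes that want a stricter panel.

The XL rule is restricted to female P/LP: the rule text for VUS speaks of
both partners sharing a gene, which has no natural XL reading, so a female
XL VUS never fires (design choice).

Diagnosed individuals' variants still participate in couple matching — a
couple whose genotypes satisfy a rule is at risk regardless of diagnostic
status. Triage instead controls the *carrier statistics*: phenotype-related
variants never count toward carrier numerators or secondary findings.

A couple at risk for several genes reports all of them; the couple-level
severity tier is the highest-ranked among them (profound > severe >
moderate > mild). Genes without a tier are `unclassified` and raise rather
than silently tiering — the severity-override TSV is the supported fix.

## Carrier-statistics conventions

* Reportable carrier variant: P/LP, AR or XL gene, not phenotype-related.
  AD-gene P/LP variants feed secondary findings only.
* The denominator of every carrier frequency is the **whole cohort**, both
  sexes, including XL genes. This is the only convention that reproduces the
  reference programme's printed XL rows (e.g. 40 *G6PD* carriers / 4,468 =
  0.90%) and it is how such programmes report.
* Homozygotes count once as gene carriers but contribute two alleles.
* "1 in N" for a variant is `round(n_individuals / allele_count)`, half away
  from zero; this reproduces all ten printed reference values.
* Display rounding (half away from zero): 2 dp for percentage frequencies
  and rates, 1 dp for the positive-carrier rate, 3 dp for the chi-square
  statistic. Internal values are never rounded.
* The reference programme's own summary states the positive rate variously
  as 94.4–94.9%; the count-derived value (4,242/4,468 = 94.94%, displayed
  94.9%) is what this package reports.
* Its printed subgroup ARC-rate column also disagrees with its pair counts
  for two subgroups (the birth-defect and patients rows appear swapped);
  rates here are always computed from counts (70/447 = 15.66%,
  13/127 = 10.24%).

## Decision analysis

ARCs collapse into the 2×2 table {profound/severe, moderate/mild} ×
{measures taken, no measures}. Couples lost to follow-up are pooled into the
no-measures column: the reference programme's 2×2 margins (71 + 148 = 219)
equal its three-way split (71 + 143 + 5) only under this pooling, which is
also substantively right — a couple lost to follow-up took no targeted
measure through the programme. The three-way split is reported separately.
The test is the Pearson chi-square **without** Yates continuity correction
(the only variant that reproduces the published 15.514 on (48, 58, 23, 90)),
df = 1, p from the χ² survival function; scipy's `chi2_contingency`
implements it, cross-checked in the tests against the closed form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) and a direct Σ(O−E)²/E.

## Synthetic cohort simulator

The simulator emulates the modelled programme's conditions:

* **Carriage.** Per individual and AR/AD gene, carrier status ~
  Bernoulli(carrier_freq), independent across genes and partners (random
  mating); XL genes are sampled as female heterozygous carriage only (male
  hemizygotes would present as patients; an option enables them). At most
  one carried variant per gene per individual — reference data report allele
  counts, not compound-het structure, so multi-variant burden arises across
  genes. Carried alleles are drawn from the gene's spectrum by relative
  frequency.
* **Classes and evidence.** A carried P/LP allele is downgraded to VUS with
  probability `vus_fraction` (default 0.05 — of the order implied by the
  reference programme's 7.8% VUS-involved ARC share; no per-allele rate is
  published). VUS records receive predictor scores, drawn from the
  deleterious region of every tool with probability
  `vus_deleterious_support` (default 0.5) and from the neutral region
  otherwise; each gene with any VUS enters the couple's proband-evidence set
  with probability 0.3.
* **Subgroups.** Couples are assigned to the six reason-for-screening
  subgroups at the reference programme's couple shares (39.3% recurrent
  miscarriage/stillborn, 26.3% infertility, 20.0% birth defect, 5.7%
  patients, 7.6% routine, 1.1% consanguineous). One partner of each
  patients-subgroup couple reports a phenotype drawn from the panel's
  disease names; the simulator does not target a particular diagnostic
  yield.
* **Consanguinity.** For consanguineous couples the male partner gains each
  AR gene the female carries — the same allele, identical by descent — with
  probability `consang_share_prob` (default 0.5, chosen so that under the
  bundled panel the subgroup's ARC rate is elevated to roughly the
  reference programme's 32% against a ~7% baseline).
* **Decisions.** Assigned post hoc, only to couples the rule engine calls
  at risk: lost to follow-up with probability 5/219, otherwise measures
  taken with probability 48/106 (profound/severe) or 23/113 (moderate/mild)
  — the reference uptake fractions.

Everything derives from one `numpy` generator seeded by the config, so equal
configs give byte-identical cohort files.

`expected_arc_rate` is the simulator's analytic validator: under
independence, 1 − Π over AR genes of (1 − (cf·q)²) · Π over XL genes of
(1 − cf·q), with q the P/LP share of the spectrum. It covers the P/LP
pathways only; with `vus_fraction = 0` and no consanguinity boost the
simulated rate converges to it (verified within 3 binomial SD at 25,000
couples), otherwise it is a documented approximation.

**What the simulator does not reproduce:** the full 4,158-gene frequency
spectrum (the bundled panel carries the ~19 printed genes, so simulated
cumulative carrier rates sit near 45% rather than ~95%, and the burden tail
stops early); linkage, de-novo mutation and population structure beyond the
consanguinity multiplier; compound heterozygotes; correlation between
subgroup and genotype (other than consanguinity and patient phenotypes).
Passing tests therefore validate the *analysis machinery* under the assumed
generative model, not the population-genetic realism of any particular
panel.

## Numerical and degenerate-input choices

* Spectrum relative frequencies must sum to 1 within 1e-9; subgroup weights
  likewise.
* Ties in the consensus vote are indeterminate, never deleterious.
* Empty cohorts raise for rate operations (no silent NaN); empty subgroups
  report NA in the subgroup-rate table.
* A zero marginal leaves the chi-square undefined and raises.
* A male diploid het call on chrX in VCF ingestion is kept as het but
  logged as anomalous; haploid non-reference calls map to hemizygous.
* Floats round-trip through the TSV dialects via `repr` (shortest exact
  representation), keeping write→read lossless and reruns byte-identical.

## Problem sizes used in the test and acceptance runs

Fixture recomputations run at the reference sizes (4,468 individuals, 2,234
couples, 219 ARCs) and complete in milliseconds. Stochastic validations use
25,000 simulated couples for parameter recovery and the analytic ARC-rate
check (3-binomial-SD criteria), 8,000 couples for the exact
Poisson-binomial burden comparison, and 1,000 random mini-cohorts for the
rule-engine/oracle equivalence — sizes at which the binomial error bars are
a few times tighter than the effects being checked.

## Known limitations

* Phenotype matching is lexical; unmapped synonyms leave a diagnostic
  variant in the carrier set.
* Phase is never inferred: potentially biallelic diagnoses are flagged, not
  resolved.
* The severity tiers bundled with the example panel are this package's
  reading of the four-tier counselling scale for those genes; programmes
  should supply their own override file.
* `expected_arc_rate` ignores VUS pathways and consanguinity by design.
* The decision model is two-outcome (+ lost); which measure a couple chose
  is not modelled.
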