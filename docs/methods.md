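# Methods

## Pipeline model and staging

`run_pipeline` applies, per case variant, a fixed evidence funnel:

1. **Identity match against gated knowledge.** Variants whose normalized
   identity equals a gated ClinVar P/LP record are reported as
   `clinvar_plp` and bypass de novo classification (including BS1 — the
   short-circuit is deliberate; an established interpretation is not
   re-litigated by a frequency filter).
2. **BS1 frequency exclusion**, evaluated for every remaining variant: a
   recorded control MAF strictly above `bs1_maf` excludes the variant.
3. **Predictive criteria** (PVS1, PS1, PM5, PM4, PP3), always evaluated.
4. **PM2 and PS4**, evaluated only for variants satisfying at least one
   predictive criterion. A variant with no predictive evidence is
   `not_evaluated`; its population status is never computed. This staging
   means a "PM2-only" profile cannot exist, and the synthetic generator
   rejects such plant requests as inconsistent.
5. **Combination rules**, applied verbatim as stated for this study:
   pathogenic = PVS1∧PS4 ∨ PS1∧PS4; likely pathogenic = PVS1∧PM2 ∨
   PS1∧PM2 ∨ PS4∧PM4 ∨ PS4∧PM5; else VUS if any criterion fired. These
   are narrower than the full Richards et al. combining calculus, which
   is intentionally not offered: the point of the package is to reproduce
   this operationalization exactly.

Placing BS1 ahead of the predictive gate is the one point where the
staging is genuinely open: the source text evaluates all three population
criteria behind the gate, but BS1 is an exclusion filter, and applying it
unconditionally makes "excluded because common" reportable for variants
with no predictive evidence while changing no P/LP call (BS1 beats every
pathogenic combination either way).

## Evidence semantics

- **Variant identity** is the trimmed `(contig, position, ref, alt)`
  tuple (shared suffix then prefix removed, 1-based coordinates). Full
  left-alignment through repeat context would require flanking reference
  sequence, which the pipeline's inputs do not carry; trimming is total,
  idempotent, and sufficient for the tabular inputs exchanged here. BED
  inputs are converted to 1-based inclusive intervals at the reader.
- **ClinVar gating** keeps records that are pathogenic or likely
  pathogenic, at review tier practice-guideline / expert-panel /
  multiple-submitters-without-conflicts, with at least one condition on
  the configured allowlist (exact match after case-folding and whitespace
  collapse; no ontology expansion). The free-text review-status dialects
  of real exports are mapped through a shipped alias table.
- **Index derivation.** PVS1's gene index and the PS1/PM5 amino-acid
  indices are built from `significance = pathogenic` records only; PM4's
  gene index uses both pathogenic and likely pathogenic, mirroring the
  wording of each criterion. Duplicate assertions collapse; multiplicity
  carries no weight. PS1 additionally requires that some asserting
  ClinVar variant differ from the case variant's genomic identity —
  the same nucleotide change is an identity match, not PS1.
- **Predictor votes.** REVEL votes pathogenic only if *all* of a
  variant's protein changes exceed 0.68 and benign if *any* is ≤ 0.32
  (the benign cutoff chosen for symmetry with the 95%-specificity
  pathogenic cutoff). CADD has only a pathogenic threshold (PHRED > 20);
  a low CADD is indeterminate, never benign. PolyPhen-2 HDIV and HVAR
  jointly form one predictor: deleterious if either model is damaging,
  benign if at least one model reports and neither is damaging. Absent
  predictors are indeterminate and contribute no vote either way.
- **PM4's repeat exclusion** attaches to in-frame indels only; stop-loss
  is exempt by default (`pm4_stoploss_repeat_exempt`, configurable),
  reading the criterion's repeat clause as qualifying indels.
- **"Recorded" vs zero count.** PM2 asks whether the variant is *present
  in the table* of each control cohort; a record with AC = 0 defeats PM2.
- **Unrecorded control sites in PS4.** AC = 0 with AN interpolated from
  the nearest recorded flank on each side within
  `interpolation_window_bp`, rounded to the nearest integer (Fisher
  margins must be integers). If the exact position carries a record for a
  different allele, that position's AN is used directly — the site was
  genotyped, so interpolation would discard information. If either flank
  is missing, the pair is skipped rather than defaulted (a median-AN
  fallback would fabricate a margin); a variant whose every pair is
  skipped cannot satisfy PS4.
- **Direction.** "Statistically enriched" requires p < `ps4_alpha` *and*
  a strict allele-frequency inequality, since a two-tailed p carries no
  direction. Enrichment in controls in any pair vetoes PS4. p-values
  below alpha/5 are starred separately in the output table but play no
  role in classification.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `revel_pathogenic` | 0.68 | REVEL score above which a change votes deleterious (95%-specificity operating point) |
| `revel_benign` | 0.32 | REVEL score at or below which a change votes benign |
| `cadd_pathogenic` | 20 | PHRED-scaled CADD cutoff (~top 0.1% of SNVs) |
| `bs1_maf` | 0.01 | MAF exclusion threshold, strict inequality |
| `ps4_alpha` | 0.05 | per-comparison significance level (no multiplicity correction, by design) |
| `interpolation_window_bp` | 150 | maximum flank distance for AN interpolation |
| `pp3_min_pathogenic_votes` | 2 | concordant deleterious predictions needed for PP3 |

All thresholds live in one `Thresholds` object (YAML-configurable through
the CLI); there are no hidden constants.

## What the synthetic data emulates

`plant_cohort` turns declarative `PlantSpec`s (criteria to make true)
into a full input set: a diploid case cohort with heterozygous carriers
(a case cohort of n fully genotyped subjects has AN = 2n at every site),
annotation rows, helper ClinVar records, and control panels of 9,626 and
9,770 subjects with site-to-site allele-number variation — coverage
varies in real panels, and constant AN would leave the interpolation
path unexercised. Extra case cohorts default to 290 (breast) and 209
(lung) subjects with the planted variants absent, so a singleton carrier
among 55 produces a PS4-scale contrast against ~19,000 control alleles
(p ≈ 0.006) while staying non-significant against a recorded control
frequency of 0.002. Control presence classes map onto the population
criteria: unrecorded-with-interpolable-flanks (PM2 and PS4),
unrecorded-uninterpolable (PM2 without PS4 — every pair is skipped),
recorded-with-AC-0 (PS4 without PM2), recorded-rare (AF 0.002; neither),
recorded-common (AF 0.05; BS1). Inconsistent combinations — PM2 with a
recorded variant, BS1 alongside PS4, a PS4-free gate-passing profile
with more than one carrier — are rejected at generation time.

The packaged study fixture (`paper_fixture`) instantiates the published
cohort's evidence structure at desk scale: the six ClinVar-recorded
variants, thirteen newly classifiable profiles with their genes,
consequences and carrier roster, plus VUS/excluded/evidence-free
fillers and a 55-patient metadata table whose categorical margins match
the cohort summary (52 never-smokers; 38/12/5 temporal split; EGFR 33
mutant + 12 wild-type over 45 tested adenocarcinomas). Three variants
keep their printed genomic coordinates; rsID-only variants receive
synthetic placeholder positions and carry the rsID as metadata. The
extracted per-row criterion checkmarks of the published table are
typographically ambiguous, so each row's criterion set was encoded to be
consistent with its printed classification and the accompanying
narrative (the splice/start-loss/stop-gain rows via PVS1, the TP53
missense via PS1, GPC3/MSH2/WRN via PM5, the in-frame indels via PM4,
all thirteen enriched in the discovery cohort).

**What passing these tests shows — and does not.** Recovery of planted
profiles demonstrates that the rule engine, gating, interpolation and
enrichment arithmetic compose correctly under the study's cohort sizes.
It does not validate upstream annotation, the in-silico predictors
themselves (scores are consumed, never computed), linkage or
site-frequency-spectrum realism (control sites are placed by design, not
drawn from a population model), or behaviour on WES-scale variant counts
— the source study's 33 genome-wide VUS, for instance, are not
reproducible from desk-scale inputs.

## Numerical choices and degenerate inputs

- Fisher exact p-values come from `scipy.stats.fisher_exact`
  (two-sided); the test suite cross-checks them against an independent
  exhaustive hypergeometric enumeration to 1e-9 on margins up to 500.
- Interpolated AN is rounded half-to-even by Python's `round`; on
  collinear flanks the result is exact within rounding.
- An AN of zero is an error for allele frequencies and Fisher margins;
  interpolation returning no value is an ordinary outcome, not an error.
- Readers reject malformed rows into explicit rejection records and
  continue; accepted + rejected always equals input rows. Missing
  required columns and unreadable VCFs are fatal.
- Unannotated case variants become rejection records, never silent drops.
- Multi-allelic VCF records are split per alt allele; missing genotypes
  are excluded from AN; a site with no called genotypes is skipped with
  a warning.
- Percentages over empty denominators are NaN, never exceptions; unknown
  metadata categories form their own bucket.

## Known limitations

- Trim-based normalization does not canonicalize indels across repeat
  context (needs reference sequence); inputs compared across tables must
  share a representation convention.
- PVS1 strength modulation (e.g. last-exon NMD escape), transcript-aware
  matching for PS1/PM5 (matching is by gene/residue/amino acids only),
  covariate-adjusted association, gene-burden testing and multiple-testing
  correction are out of scope.
- The ClinVar converter consumes the package's tabular format; a full
  ClinVar VCF importer is stubbed but not required by the pipeline.
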