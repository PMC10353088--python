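"""ClinVar-style evidence gating and the derived indices the criteria query.

Only records interpreted pathogenic or likely pathogenic at the three
accepted review tiers (practice guideline, expert panel, or multiple
submitters without conflicts), for at least one condition on the
configured allowlist, count as established evidence.  Everything the
predictive criteria need is precomputed here into small hash indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .variants import (
    Consequence,
    GenomicVariant,
    NULL_CONSEQUENCES,
    ProteinChange,
    normalize_variant,
)

__all__ = [
    "Significance",
    "ReviewStatus",
    "REVIEW_STATUS_ALIASES",
    "SIGNIFICANCE_ALIASES",
    "ClinVarRecord",
    "ClinVarKnowledge",
    "ConfigurationError",
    "normalize_condition",
    "gate_clinvar",
    "build_knowledge",
    "is_clinvar_recorded_plp",
]


class ConfigurationError(ValueError):
    """A run-level configuration problem (empty allowlist, missing cohort, ...)."""


class Significance(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    UNCERTAIN = "uncertain"
    OTHER = "other"


class ReviewStatus(str, Enum):
    PRACTICE_GUIDELINE = "practice_guideline"
    EXPERT_PANEL = "expert_panel"
    MULTIPLE_SUBMITTERS_NO_CONFLICT = "multiple_submitters_no_conflict"
    CONFLICTING_INTERPRETATIONS = "conflicting_interpretations"
    SINGLE_SUBMITTER_WITH_CRITERIA = "single_submitter_with_criteria"
    NO_ASSERTION_CRITERIA = "no_assertion_criteria"
    OTHER = "other"


#: Review tiers that count as established evidence.
ACCEPTED_REVIEW_STATUSES = frozenset(
    {
        ReviewStatus.PRACTICE_GUIDELINE,
        ReviewStatus.EXPERT_PANEL,
        ReviewStatus.MULTIPLE_SUBMITTERS_NO_CONFLICT,
    }
)

PLP_SIGNIFICANCES = frozenset({Significance.PATHOGENIC, Significance.LIKELY_PATHOGENIC})

# Mapping from the free-text dialects of real ClinVar exports to the enums.
# Applied after case-folding and comma/underscore-insensitive normalization.
REVIEW_STATUS_ALIASES: Mapping[str, ReviewStatus] = {
    "practice guideline": ReviewStatus.PRACTICE_GUIDELINE,
    "reviewed by expert panel": ReviewStatus.EXPERT_PANEL,
    "criteria provided multiple submitters no conflicts": (
        ReviewStatus.MULTIPLE_SUBMITTERS_NO_CONFLICT
    ),
    "criteria provided conflicting interpretations": (
        ReviewStatus.CONFLICTING_INTERPRETATIONS
    ),
    "criteria provided conflicting classifications": (
        ReviewStatus.CONFLICTING_INTERPRETATIONS
    ),
    "criteria provided single submitter": ReviewStatus.SINGLE_SUBMITTER_WITH_CRITERIA,
    "no assertion criteria provided": ReviewStatus.NO_ASSERTION_CRITERIA,
    "no assertion provided": ReviewStatus.NO_ASSERTION_CRITERIA,
}

SIGNIFICANCE_ALIASES: Mapping[str, Significance] = {
    "pathogenic": Significance.PATHOGENIC,
    "likely pathogenic": Significance.LIKELY_PATHOGENIC,
    "pathogenic/likely pathogenic": Significance.PATHOGENIC,
    "benign": Significance.BENIGN,
    "likely benign": Significance.LIKELY_BENIGN,
    "benign/likely benign": Significance.BENIGN,
    "uncertain significance": Significance.UNCERTAIN,
}


def _fold(text: str) -> str:
    return " ".join(text.replace("_", " ").replace(",", " ").split()).casefold()


def parse_review_status(text: str) -> ReviewStatus:
    """Map a ClinVar review-status string (either dialect) to the enum."""
    folded = _fold(text)
    if folded in REVIEW_STATUS_ALIASES:
        return REVIEW_STATUS_ALIASES[folded]
    try:
        return ReviewStatus(text.strip())
    except ValueError:
        return ReviewStatus.OTHER


def parse_significance(text: str) -> Significance:
    folded = _fold(text)
    if folded in SIGNIFICANCE_ALIASES:
        return SIGNIFICANCE_ALIASES[folded]
    try:
        return Significance(text.strip())
    except ValueError:
        return Significance.OTHER


def normalize_condition(name: str) -> str:
    """Case-fold and collapse whitespace; no ontology expansion."""
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class ClinVarRecord:
    variant: GenomicVariant
    gene: str
    significance: Significance
    review_status: ReviewStatus
    conditions: frozenset[str]
    consequence: Consequence
    protein_changes: tuple[ProteinChange, ...] = ()


@dataclass(frozen=True)
class ClinVarKnowledge:
    """Gated P/LP records plus the derived indices the criteria consult.

    ``aa_change_sources`` maps each pathogenic amino-acid change to the
    normalized genomic variants asserting it, so PS1 can require that the
    matching ClinVar variant be a *different* nucleotide change.
    """

    gated_plp: frozenset[ClinVarRecord]
    pathogenic_only: frozenset[ClinVarRecord]
    genes_with_pathogenic_null: frozenset[str]
    pathogenic_aa_changes: frozenset[tuple[str, int, str, str]]
    pathogenic_missense_residues: frozenset[tuple[str, int, str]]
    genes_with_any_plp: frozenset[str]
    gated_variant_ids: frozenset[GenomicVariant] = frozenset()
    aa_change_sources: Mapping[tuple[str, int, str, str], frozenset[GenomicVariant]] = (
        field(default_factory=dict)
    )

    @classmethod
    def empty(cls) -> "ClinVarKnowledge":
        return build_knowledge(frozenset())


def gate_clinvar(
    records: Iterable[ClinVarRecord], condition_allowlist: Iterable[str]
) -> frozenset[ClinVarRecord]:
    """Keep P/LP records at an accepted review tier for an allowlisted condition.

    A record asserted for both an allowlisted and an out-of-list condition
    is kept — at least one relevant condition suffices.
    """
    allow = {normalize_condition(c) for c in condition_allowlist}
    if not allow:
        raise ConfigurationError("condition allowlist is empty")
    kept = set()
    for rec in records:
        if rec.significance not in PLP_SIGNIFICANCES:
            continue
        if rec.review_status not in ACCEPTED_REVIEW_STATUSES:
            continue
        if not any(normalize_condition(c) in allow for c in rec.conditions):
            continue
        kept.add(rec)
    return frozenset(kept)


def build_knowledge(gated: Iterable[ClinVarRecord]) -> ClinVarKnowledge:
    """Materialize the criterion indices from an already-gated record set.

    Deterministic and order-independent: all indices are plain sets keyed
    by value; duplicate assertions of the same amino-acid change collapse
    (multiplicity carries no weight).
    """
    gated = frozenset(gated)
    pathogenic = frozenset(
        r for r in gated if r.significance is Significance.PATHOGENIC
    )

    genes_null = set()
    aa_sources: dict[tuple[str, int, str, str], set[GenomicVariant]] = {}
    residues = set()
    for rec in pathogenic:
        if rec.consequence in NULL_CONSEQUENCES:
            genes_null.add(rec.gene)
        for ch in rec.protein_changes:
            if ch.is_missense:
                key = (rec.gene, ch.residue_index, ch.ref_aa, ch.alt_aa)
                aa_sources.setdefault(key, set()).add(normalize_variant(rec.variant))
                residues.add((rec.gene, ch.residue_index, ch.ref_aa))

    return ClinVarKnowledge(
        gated_plp=gated,
        pathogenic_only=pathogenic,
        genes_with_pathogenic_null=frozenset(genes_null),
        pathogenic_aa_changes=frozenset(aa_sources),
        pathogenic_missense_residues=frozenset(residues),
        genes_with_any_plp=frozenset(r.gene for r in gated),
        gated_variant_ids=frozenset(normalize_variant(r.variant) for r in gated),
        aa_change_sources={k: frozenset(v) for k, v in aa_sources.items()},
    )


def is_clinvar_recorded_plp(v: GenomicVariant, k: ClinVarKnowledge) -> bool:
    """True iff ``v`` (normalized) matches a gated P/LP record's identity."""
    return normalize_variant(v) in k.gated_variant_ids
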