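"""The five computational/predictive pathogenicity criteria.

PVS1  predicted null variant in a gene with an established pathogenic null.
PS1   same amino-acid change as an established pathogenic variant, reached
      by a different nucleotide change.
PM5   novel missense at a residue with a different established pathogenic
      missense.
PM4   protein-length change: in-frame indel outside repeats, or stop-loss,
      in a gene with any established P/LP record.
PP3   concordant in-silico evidence: >= 2 deleterious predictions and no
      benign prediction across REVEL, CADD, SIFT, PolyPhen-2 and
      MutationTaster.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .clinvar import ClinVarKnowledge
from .variants import (
    Consequence,
    NULL_CONSEQUENCES,
    PredictionScores,
    MutationTasterCall,
    PolyPhenCall,
    SiftCall,
    Thresholds,
    VariantAnnotation,
    normalize_variant,
)

__all__ = [
    "Vote",
    "PredictiveEvidence",
    "PREDICTORS",
    "evaluate_pvs1",
    "evaluate_ps1",
    "evaluate_pm5",
    "evaluate_pm4",
    "predictor_votes",
    "evaluate_pp3",
    "evaluate_predictive",
]


class Vote(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    INDETERMINATE = "indeterminate"


#: Predictor names in reporting order.  PolyPhen-2 HDIV and HVAR jointly
#: constitute one predictor (deleterious if either model is damaging).
PREDICTORS = ("REVEL", "CADD", "SIFT", "PolyPhen-2", "MutationTaster")


@dataclass(frozen=True)
class PredictiveEvidence:
    pvs1: bool
    ps1: bool
    pm5: bool
    pm4: bool
    pp3: bool
    predictor_votes: Mapping[str, Vote]

    @property
    def any_criterion(self) -> bool:
        return self.pvs1 or self.ps1 or self.pm5 or self.pm4 or self.pp3


def evaluate_pvs1(ann: VariantAnnotation, k: ClinVarKnowledge) -> bool:
    """Null-class consequence in a gene holding an established pathogenic null."""
    return (
        ann.consequence in NULL_CONSEQUENCES
        and ann.gene in k.genes_with_pathogenic_null
    )


def evaluate_ps1(ann: VariantAnnotation, k: ClinVarKnowledge) -> bool:
    """Some missense change matches a pathogenic change exactly, while the
    genomic variant differs from every ClinVar variant asserting that change."""
    v = normalize_variant(ann.variant)
    for ch in ann.protein_changes:
        if not ch.is_missense:
            continue
        sources = k.aa_change_sources.get(
            (ch.gene, ch.residue_index, ch.ref_aa, ch.alt_aa)
        )
        if sources and any(src != v for src in sources):
            return True
    return False


def evaluate_pm5(ann: VariantAnnotation, k: ClinVarKnowledge) -> bool:
    """Some missense change hits a residue with a *different* pathogenic missense."""
    for ch in ann.protein_changes:
        if not ch.is_missense:
            continue
        if (ch.gene, ch.residue_index, ch.ref_aa) not in k.pathogenic_missense_residues:
            continue
        if (ch.gene, ch.residue_index, ch.ref_aa, ch.alt_aa) not in k.pathogenic_aa_changes:
            return True
    return False


def evaluate_pm4(
    ann: VariantAnnotation, k: ClinVarKnowledge, t: Thresholds = Thresholds()
) -> bool:
    """Protein-length-changing variant in a gene with any established P/LP.

    The repeat-region exclusion attaches to in-frame indels only; stop-loss
    is exempt by default (configurable through ``t.pm4_stoploss_repeat_exempt``).
    """
    if ann.gene not in k.genes_with_any_plp:
        return False
    if ann.consequence in (
        Consequence.NONFRAMESHIFT_INSERTION,
        Consequence.NONFRAMESHIFT_DELETION,
    ):
        return not ann.in_repeat_region
    if ann.consequence is Consequence.STOPLOSS:
        return t.pm4_stoploss_repeat_exempt or not ann.in_repeat_region
    return False


def predictor_votes(scores: PredictionScores, t: Thresholds) -> dict[str, Vote]:
    """One pathogenic/benign/indeterminate vote per predictor.

    REVEL votes pathogenic only when every protein change scores above the
    pathogenic cutoff (and at least one score exists); it votes benign when
    any change scores at or below the benign cutoff.  CADD has only a
    pathogenic threshold — a low CADD is indeterminate, never benign.
    Absent predictors are indeterminate.
    """
    votes: dict[str, Vote] = {}

    revel = scores.revel_scores()
    if revel and all(s > t.revel_pathogenic for s in revel):
        votes["REVEL"] = Vote.PATHOGENIC
    elif revel and any(s <= t.revel_benign for s in revel):
        votes["REVEL"] = Vote.BENIGN
    else:
        votes["REVEL"] = Vote.INDETERMINATE

    if scores.cadd_phred is not None and scores.cadd_phred > t.cadd_pathogenic:
        votes["CADD"] = Vote.PATHOGENIC
    else:
        votes["CADD"] = Vote.INDETERMINATE

    if scores.sift_call is SiftCall.DELETERIOUS:
        votes["SIFT"] = Vote.PATHOGENIC
    elif scores.sift_call is SiftCall.TOLERATED:
        votes["SIFT"] = Vote.BENIGN
    else:
        votes["SIFT"] = Vote.INDETERMINATE

    hdiv, hvar = scores.polyphen_hdiv_call, scores.polyphen_hvar_call
    if PolyPhenCall.DAMAGING in (hdiv, hvar):
        votes["PolyPhen-2"] = Vote.PATHOGENIC
    elif hdiv is not None or hvar is not None:
        votes["PolyPhen-2"] = Vote.BENIGN
    else:
        votes["PolyPhen-2"] = Vote.INDETERMINATE

    if scores.mutationtaster_call is MutationTasterCall.DELETERIOUS:
        votes["MutationTaster"] = Vote.PATHOGENIC
    elif scores.mutationtaster_call is MutationTasterCall.POLYMORPHISM:
        votes["MutationTaster"] = Vote.BENIGN
    else:
        votes["MutationTaster"] = Vote.INDETERMINATE

    return votes


def evaluate_pp3(scores: PredictionScores, t: Thresholds) -> bool:
    votes = predictor_votes(scores, t).values()
    n_path = sum(v is Vote.PATHOGENIC for v in votes)
    n_benign = sum(v is Vote.BENIGN for v in votes)
    return n_benign == 0 and n_path >= t.pp3_min_pathogenic_votes


def evaluate_predictive(
    ann: VariantAnnotation, k: ClinVarKnowledge, t: Thresholds
) -> PredictiveEvidence:
    """Evaluate all five criteria; a pure function of its inputs."""
    return PredictiveEvidence(
        pvs1=evaluate_pvs1(ann, k),
        ps1=evaluate_ps1(ann, k),
        pm5=evaluate_pm5(ann, k),
        pm4=evaluate_pm4(ann, k, t),
        pp3=evaluate_pp3(ann.scores, t),
        predictor_votes=predictor_votes(ann.scores, t),
    )
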