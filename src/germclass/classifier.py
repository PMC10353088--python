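"""Evidence combination, the staged pipeline, and patient/cohort summaries.

The combining rules are deliberately narrow: pathogenic requires
PVS1+PS4 or PS1+PS4; likely pathogenic requires PVS1+PM2, PS1+PM2,
PS4+PM4 or PS4+PM5.  A variant satisfying some criterion but no
combination is a VUS.  BS1 excludes a variant outright, and a variant
already recorded P/LP in the gated ClinVar knowledge bypasses de novo
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .clinvar import ClinVarKnowledge, is_clinvar_recorded_plp
from .population import (
    CohortSiteTable,
    PopulationEvidence,
    evaluate_bs1,
    evaluate_population,
)
from .predictive import PredictiveEvidence, evaluate_predictive
from .variants import GenomicVariant, Thresholds, VariantAnnotation, normalize_variant

__all__ = [
    "VariantClass",
    "CriterionProfile",
    "ClassificationResult",
    "PatientSummary",
    "PipelineResult",
    "RejectedVariant",
    "classify",
    "run_pipeline",
    "summarize_patients",
    "summarize_cohort",
    "PATHOGENIC_RULES",
    "LIKELY_PATHOGENIC_RULES",
]

logger = logging.getLogger(__name__)


class VariantClass(str, Enum):
    CLINVAR_PLP = "clinvar_plp"
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    EXCLUDED_BENIGN = "excluded_benign"
    NOT_EVALUATED = "not_evaluated"


#: Severity ordering used for reporting and the monotonicity property.
CLASS_ORDER = {
    VariantClass.NOT_EVALUATED: 0,
    VariantClass.VUS: 1,
    VariantClass.LIKELY_PATHOGENIC: 2,
    VariantClass.PATHOGENIC: 3,
}

PLP_CLASSES = frozenset(
    {VariantClass.CLINVAR_PLP, VariantClass.PATHOGENIC, VariantClass.LIKELY_PATHOGENIC}
)

PATHOGENIC_RULES = (("PVS1", "PS4"), ("PS1", "PS4"))
LIKELY_PATHOGENIC_RULES = (
    ("PVS1", "PM2"),
    ("PS1", "PM2"),
    ("PS4", "PM4"),
    ("PS4", "PM5"),
)

_EMPTY_POPULATION = PopulationEvidence(bs1=False, pm2=False, ps4=False)


@dataclass(frozen=True)
class CriterionProfile:
    predictive: PredictiveEvidence
    population: PopulationEvidence
    clinvar_recorded: bool = False

    def flags(self) -> dict[str, bool]:
        return {
            "PVS1": self.predictive.pvs1,
            "PS1": self.predictive.ps1,
            "PM5": self.predictive.pm5,
            "PM4": self.predictive.pm4,
            "PP3": self.predictive.pp3,
            "PM2": self.population.pm2,
            "PS4": self.population.ps4,
            "BS1": self.population.bs1,
        }


@dataclass(frozen=True)
class ClassificationResult:
    variant: GenomicVariant
    gene: str
    klass: VariantClass
    fired_rules: tuple[str, ...]
    profile: CriterionProfile

    @property
    def is_plp(self) -> bool:
        return self.klass in PLP_CLASSES

    @property
    def newly_classified(self) -> bool:
        return self.klass in (VariantClass.PATHOGENIC, VariantClass.LIKELY_PATHOGENIC)


def classify(
    profile: CriterionProfile,
    variant: Optional[GenomicVariant] = None,
    gene: str = "",
) -> ClassificationResult:
    """Map one criterion profile to exactly one class.

    Precedence: ClinVar-recorded P/LP, then BS1 exclusion, then the
    pathogenic combinations, then the likely-pathogenic combinations,
    then VUS if any criterion fired at all, else not evaluated.  Total
    and deterministic.
    """
    flags = profile.flags()
    if profile.clinvar_recorded:
        return ClassificationResult(
            variant, gene, VariantClass.CLINVAR_PLP, ("ClinVar",), profile
        )
    if flags["BS1"]:
        return ClassificationResult(
            variant, gene, VariantClass.EXCLUDED_BENIGN, ("BS1",), profile
        )
    fired = tuple(
        f"{a}+{b}" for a, b in PATHOGENIC_RULES if flags[a] and flags[b]
    )
    if fired:
        return ClassificationResult(variant, gene, VariantClass.PATHOGENIC, fired, profile)
    fired = tuple(
        f"{a}+{b}" for a, b in LIKELY_PATHOGENIC_RULES if flags[a] and flags[b]
    )
    if fired:
        return ClassificationResult(
            variant, gene, VariantClass.LIKELY_PATHOGENIC, fired, profile
        )
    if any(flags.values()):
        return ClassificationResult(variant, gene, VariantClass.VUS, (), profile)
    return ClassificationResult(variant, gene, VariantClass.NOT_EVALUATED, (), profile)


@dataclass(frozen=True)
class RejectedVariant:
    variant: GenomicVariant
    reason: str


@dataclass
class PipelineResult:
    results: list[ClassificationResult]
    rejections: list[RejectedVariant]
    stage_counts: dict[str, int]

    def by_class(self) -> dict[VariantClass, list[ClassificationResult]]:
        out: dict[VariantClass, list[ClassificationResult]] = {}
        for r in self.results:
            out.setdefault(r.klass, []).append(r)
        return out


def run_pipeline(
    case_cohort: CohortSiteTable,
    annotations: Mapping[GenomicVariant, VariantAnnotation],
    clinvar_knowledge: ClinVarKnowledge,
    control_tables: Sequence[CohortSiteTable],
    extra_case_cohorts: Sequence[CohortSiteTable] = (),
    thresholds: Thresholds = Thresholds(),
) -> PipelineResult:
    """Run the staged classification over every case variant.

    Stages mirror the study design funnel: ClinVar identity match first;
    then the BS1 frequency exclusion; then the five predictive criteria;
    PM2/PS4 only for variants passing the predictive gate.  Unannotated
    case variants become rejection records, never silent drops.
    """
    annotations = {normalize_variant(v): a for v, a in annotations.items()}
    case_tables = [case_cohort, *extra_case_cohorts]
    results: list[ClassificationResult] = []
    rejections: list[RejectedVariant] = []
    counts = {
        "input_variants": len(case_cohort.records),
        "rejected": 0,
        "clinvar_plp": 0,
        "bs1_excluded": 0,
        "predictive_gated": 0,
        "population_tested": 0,
    }

    for variant in sorted(case_cohort.records):
        ann = annotations.get(variant)
        if ann is None:
            logger.warning("case variant %s has no annotation; rejected", variant)
            rejections.append(RejectedVariant(variant, "no annotation row"))
            counts["rejected"] += 1
            continue

        if is_clinvar_recorded_plp(variant, clinvar_knowledge):
            counts["clinvar_plp"] += 1
            profile = CriterionProfile(
                predictive=evaluate_predictive(ann, clinvar_knowledge, thresholds),
                population=_EMPTY_POPULATION,
                clinvar_recorded=True,
            )
            results.append(classify(profile, variant, ann.gene))
            continue

        predictive = evaluate_predictive(ann, clinvar_knowledge, thresholds)

        if evaluate_bs1(variant, control_tables, thresholds):
            counts["bs1_excluded"] += 1
            population = PopulationEvidence(bs1=True, pm2=False, ps4=False)
        elif predictive.any_criterion:
            counts["predictive_gated"] += 1
            counts["population_tested"] += 1
            population = evaluate_population(
                variant, case_tables, control_tables, thresholds
            )
        else:
            population = _EMPTY_POPULATION

        profile = CriterionProfile(predictive=predictive, population=population)
        results.append(classify(profile, variant, ann.gene))

    for klass in VariantClass:
        counts[f"class_{klass.value}"] = sum(r.klass is klass for r in results)
    return PipelineResult(results=results, rejections=rejections, stage_counts=counts)


@dataclass
class PatientSummary:
    patient_id: str
    carried_plp: list[ClassificationResult] = field(default_factory=list)
    carried_vus: list[ClassificationResult] = field(default_factory=list)
    zygosity: dict[GenomicVariant, str] = field(default_factory=dict)

    @property
    def is_plp_carrier(self) -> bool:
        return bool(self.carried_plp)


def summarize_patients(
    results: Iterable[ClassificationResult],
    carriers: Mapping[GenomicVariant, Mapping[str, str]],
    cohort_size: int,
) -> tuple[list[PatientSummary], dict[str, float]]:
    """Roll classifications up to carriers.

    ``carriers`` maps each case variant to ``{patient_id: zygosity}`` for
    the patients carrying it ("het"/"hom").  Aggregates report carrier
    counts (and percentages over the cohort size) for any P/LP, for two or
    more P/LP, for newly classified P/LP only, for ClinVar-recorded only,
    and for VUS.
    """
    summaries: dict[str, PatientSummary] = {}
    for result in results:
        v = normalize_variant(result.variant)
        for patient_id, zygosity in carriers.get(v, {}).items():
            s = summaries.setdefault(patient_id, PatientSummary(patient_id))
            s.zygosity[v] = zygosity
            if result.is_plp:
                s.carried_plp.append(result)
            elif result.klass is VariantClass.VUS:
                s.carried_vus.append(result)

    ordered = [summaries[pid] for pid in sorted(summaries)]
    n_plp = sum(s.is_plp_carrier for s in ordered)
    n_multi = sum(len(s.carried_plp) >= 2 for s in ordered)
    n_new = sum(any(r.newly_classified for r in s.carried_plp) for s in ordered)
    n_clinvar = sum(
        any(r.klass is VariantClass.CLINVAR_PLP for r in s.carried_plp) for s in ordered
    )
    n_vus = sum(bool(s.carried_vus) for s in ordered)

    def pct(n: int) -> float:
        return round(100.0 * n / cohort_size, 1) if cohort_size else float("nan")

    aggregates = {
        "cohort_size": cohort_size,
        "plp_carriers": n_plp,
        "plp_carriers_pct": pct(n_plp),
        "multi_plp_carriers": n_multi,
        "new_plp_carriers": n_new,
        "new_plp_carriers_pct": pct(n_new),
        "clinvar_plp_carriers": n_clinvar,
        "clinvar_plp_carriers_pct": pct(n_clinvar),
        "vus_carriers": n_vus,
    }
    return ordered, aggregates


def summarize_cohort(
    metadata: pd.DataFrame,
    denominator_exclude: Optional[Mapping[str, Iterable[str]]] = None,
) -> pd.DataFrame:
    """Descriptive counts and percentages for categorical patient metadata.

    Every column except ``patient_id`` is summarized.  Missing values form
    their own ``<missing>`` bucket and are excluded from the percentage
    denominator; ``denominator_exclude`` lists further category values
    (per column) to drop from a column's denominator — e.g. "not_tested"
    when percentages are defined over tested cases.  A zero denominator
    yields NaN percentages, never a crash.
    """
    denominator_exclude = {
        col: {str(v) for v in vals}
        for col, vals in (denominator_exclude or {}).items()
    }
    rows = []
    for column in metadata.columns:
        if column == "patient_id":
            continue
        series = metadata[column].astype("object")
        counts = series.fillna("<missing>").astype(str).value_counts()
        excluded = denominator_exclude.get(column, set()) | {"<missing>"}
        denominator = int(sum(n for cat, n in counts.items() if cat not in excluded))
        for category, n in counts.items():
            in_denom = category not in excluded
            pct = round(100.0 * n / denominator, 1) if in_denom and denominator else float("nan")
            rows.append(
                {
                    "field": column,
                    "category": category,
                    "n": int(n),
                    "denominator": denominator if in_denom else None,
                    "pct": pct,
                }
            )
    return pd.DataFrame(rows, columns=["field", "category", "n", "denominator", "pct"])
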