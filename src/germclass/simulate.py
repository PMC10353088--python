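"""Synthetic cohorts with planted criterion profiles, and the packaged
desk-scale study fixture.

The generator builds, from a list of :class:`PlantSpec`, every input the
pipeline consumes: a diploid case cohort carrying heterozygous planted
variants, annotation rows, a gated-or-not ClinVar table, two control
site-frequency panels with deliberate recording gaps, extra case cohorts,
and a repeat mask — together with a truth table stating the criterion
flags and final class each planted variant must receive.  Defaults mirror
the study conditions: a 55-patient discovery cohort, extra case cohorts
of 290 (breast) and 209 (lung), and control panels of 9,626 and 9,770
subjects (allele numbers near 2n with site-to-site coverage variation,
since the allele-number interpolation is only exercised under
non-constant AN).

Profile consistency is enforced at generation time; an impossible spec
(e.g. PM2 with a commonly recorded variant) is rejected, never silently
emitted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    LIKELY_PATHOGENIC_RULES,
    PATHOGENIC_RULES,
    PipelineResult,
    VariantClass,
    run_pipeline,
)
from .clinvar import (
    ClinVarKnowledge,
    ClinVarRecord,
    ReviewStatus,
    Significance,
    build_knowledge,
    gate_clinvar,
)
from .population import CohortSiteTable
from .variants import (
    AA_ONE_LETTER,
    Consequence,
    DEL,
    FS,
    GenomicVariant,
    INS,
    MutationTasterCall,
    NULL_CONSEQUENCES,
    PredictionScores,
    ProteinChange,
    STOP,
    Thresholds,
    VariantAnnotation,
)

__all__ = [
    "ControlPresence",
    "PlantSpec",
    "PlantedCohort",
    "SpecError",
    "CRITERIA",
    "generate_control_panel",
    "plant_cohort",
    "random_consistent_specs",
    "paper_fixture",
]

CRITERIA = ("PVS1", "PS1", "PM5", "PM4", "PP3", "PM2", "PS4", "BS1")
PREDICTIVE_CRITERIA = frozenset({"PVS1", "PS1", "PM5", "PM4", "PP3"})

#: Study-scale defaults: case cohorts and control panel subject counts.
DEFAULT_COHORT_SIZE = 55
EXTRA_CASE_COHORTS = (("breast_290", 290), ("lung_209", 209))
CONTROL_COHORTS = (("gnomad_eas", 9626), ("sg10k", 9770))

#: Control allele frequencies the presence classes emulate: "rare" sits
#: well under the 1% BS1 line and produces no enrichment signal against a
#: singleton case carrier; "common" sits well above it.
RARE_CONTROL_AF = 0.002
COMMON_CONTROL_AF = 0.05
#: Flanking recorded sites for interpolable gaps sit inside the 150 bp
#: window; the uninterpolable gap has its downstream flank far outside it.
FLANK_IN_WINDOW = 60
FLANK_OUT_OF_WINDOW = 400

_DEFAULT_CONDITION = "hereditary cancer-predisposing syndrome"


class SpecError(ValueError):
    """A plant specification is internally inconsistent."""


class ControlPresence(str, Enum):
    UNRECORDED_INTERPOLABLE = "unrecorded_interpolable"
    UNRECORDED_UNINTERPOLABLE = "unrecorded_uninterpolable"
    RECORDED_ZERO = "recorded_zero"
    RECORDED_RARE = "recorded_rare"
    RECORDED_COMMON = "recorded_common"


@dataclass(frozen=True)
class PlantSpec:
    """One planted variant: the criteria to make true and how.

    Only ``target_profile``, ``gene``, ``consequence`` and
    ``control_presence`` are required; coordinates, residues, carriers and
    helper ClinVar records are assigned deterministically by the
    generator when not given.
    """

    target_profile: frozenset[str]
    gene: str
    consequence: Consequence
    control_presence: ControlPresence
    carrier_count: int = 1
    cohort_size: int = DEFAULT_COHORT_SIZE
    seed: Optional[int] = None
    # optional explicit detail (used by the packaged study fixture)
    variant: Optional[GenomicVariant] = None
    patients: tuple[str, ...] = ()
    rsid: Optional[str] = None
    residue_index: Optional[int] = None
    in_repeat: bool = False
    condition: str = _DEFAULT_CONDITION

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_profile", frozenset(self.target_profile))
        validate_spec(self)


def validate_spec(spec: PlantSpec) -> None:
    profile = spec.target_profile
    errors: list[str] = []
    unknown = profile - set(CRITERIA)
    if unknown:
        errors.append(f"unknown criteria {sorted(unknown)}")
        raise SpecError("; ".join(errors))

    if not 1 <= spec.carrier_count <= spec.cohort_size:
        errors.append("carrier_count must lie in [1, cohort_size]")
    if spec.patients and len(spec.patients) != spec.carrier_count:
        errors.append("explicit patient list must match carrier_count")

    # consequence compatibility
    if "PVS1" in profile:
        if spec.consequence not in NULL_CONSEQUENCES:
            errors.append("PVS1 requires a predicted-null consequence")
        if profile & {"PS1", "PM5", "PM4"}:
            errors.append("PVS1 is incompatible with PS1/PM5/PM4 on one variant")
    if profile & {"PS1", "PM5"}:
        if spec.consequence is not Consequence.NONSYNONYMOUS_SNV:
            errors.append("PS1/PM5 require a missense consequence")
        if "PM4" in profile:
            errors.append("PS1/PM5 are incompatible with PM4 on one variant")
    if "PM4" in profile:
        if spec.consequence not in (
            Consequence.NONFRAMESHIFT_INSERTION,
            Consequence.NONFRAMESHIFT_DELETION,
            Consequence.STOPLOSS,
        ):
            errors.append("PM4 requires an in-frame indel or stop-loss consequence")
        if spec.in_repeat and spec.consequence is not Consequence.STOPLOSS:
            errors.append("PM4 in-frame indel cannot sit in a repeat region")

    # population consistency
    gate_passes = bool(profile & PREDICTIVE_CRITERIA)
    if profile & {"PM2", "PS4"} and not gate_passes:
        errors.append("PM2/PS4 are only evaluated behind the predictive gate")
    if "BS1" in profile:
        if spec.control_presence is not ControlPresence.RECORDED_COMMON:
            errors.append("BS1 requires a commonly recorded control variant")
        if profile & {"PM2", "PS4"}:
            errors.append("BS1 excludes the variant before PM2/PS4 are tested")
    elif spec.control_presence is ControlPresence.RECORDED_COMMON:
        errors.append("a commonly recorded variant necessarily satisfies BS1")
    if "PM2" in profile:
        if spec.control_presence not in (
            ControlPresence.UNRECORDED_INTERPOLABLE,
            ControlPresence.UNRECORDED_UNINTERPOLABLE,
        ):
            errors.append("PM2 requires the variant to be unrecorded in all controls")
        if "PS4" in profile and spec.control_presence is not (
            ControlPresence.UNRECORDED_INTERPOLABLE
        ):
            errors.append("PM2+PS4 needs interpolable control allele numbers")
        if "PS4" not in profile and gate_passes and spec.control_presence is not (
            ControlPresence.UNRECORDED_UNINTERPOLABLE
        ):
            errors.append(
                "PM2 without PS4 needs uninterpolable controls, else the "
                "case-control contrast fires PS4"
            )
    else:
        if "PS4" in profile and spec.control_presence not in (
            ControlPresence.RECORDED_ZERO,
        ):
            errors.append("PS4 without PM2 needs a recorded-with-zero-count control")
        if gate_passes and "PS4" not in profile and "BS1" not in profile:
            if spec.control_presence not in (ControlPresence.RECORDED_RARE,):
                errors.append(
                    "a gate-passing variant without PM2/PS4/BS1 must be "
                    "recorded-rare in controls"
                )
            if spec.carrier_count != 1:
                errors.append(
                    "a gate-passing variant without PS4 must be a singleton, "
                    "or the contrast against rare controls turns significant"
                )
    if errors:
        raise SpecError(f"inconsistent spec for gene {spec.gene}: " + "; ".join(errors))


def expected_class(profile: Iterable[str]) -> VariantClass:
    """Class a (non-ClinVar-recorded) flag set must receive under the rules."""
    flags = set(profile)
    if "BS1" in flags:
        return VariantClass.EXCLUDED_BENIGN
    if any({a, b} <= flags for a, b in PATHOGENIC_RULES):
        return VariantClass.PATHOGENIC
    if any({a, b} <= flags for a, b in LIKELY_PATHOGENIC_RULES):
        return VariantClass.LIKELY_PATHOGENIC
    if flags:
        return VariantClass.VUS
    return VariantClass.NOT_EVALUATED


@dataclass(frozen=True)
class TruthRecord:
    variant: GenomicVariant
    gene: str
    flags: frozenset[str]
    expected_class: VariantClass
    patients: tuple[str, ...]
    clinvar_recorded: bool = False


@dataclass
class PlantedCohort:
    """Everything the pipeline consumes, plus the planted truth."""

    case_table: CohortSiteTable
    carriers: dict[GenomicVariant, dict[str, str]]
    annotations: dict[GenomicVariant, VariantAnnotation]
    clinvar_records: tuple[ClinVarRecord, ...]
    condition_allowlist: frozenset[str]
    controls: tuple[CohortSiteTable, ...]
    extra_cases: tuple[CohortSiteTable, ...]
    repeat_intervals: dict[str, list[tuple[int, int]]]
    truth: list[TruthRecord]
    patients: list[str]
    thresholds: Thresholds = field(default_factory=Thresholds)
    metadata: Optional[pd.DataFrame] = None

    def knowledge(self) -> ClinVarKnowledge:
        gated = gate_clinvar(self.clinvar_records, self.condition_allowlist)
        return build_knowledge(gated)

    def run(self, thresholds: Optional[Thresholds] = None) -> PipelineResult:
        return run_pipeline(
            self.case_table,
            self.annotations,
            self.knowledge(),
            list(self.controls),
            list(self.extra_cases),
            thresholds or self.thresholds,
        )

    def write_to(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all inputs in their on-disk formats (VCF/TSV/BED/text)."""
        from . import io as gio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "case_vcf": out / "case_cohort.vcf",
            "annotations": out / "annotations.tsv",
            "clinvar": out / "clinvar.tsv",
            "allowlist": out / "condition_allowlist.txt",
            "repeat_bed": out / "repeats.bed",
            "truth": out / "truth.tsv",
        }
        gio.write_case_vcf(
            paths["case_vcf"], self.patients, self.carriers, self.case_table
        )
        gio.write_annotation_tsv(paths["annotations"], self.annotations.values())
        gio.write_clinvar_table(paths["clinvar"], self.clinvar_records)
        paths["allowlist"].write_text(
            "".join(f"{c}\n" for c in sorted(self.condition_allowlist))
        )
        gio.write_repeat_bed(paths["repeat_bed"], self.repeat_intervals)
        for table in (*self.controls, *self.extra_cases):
            p = out / f"panel_{table.cohort_name}.tsv"
            gio.write_control_panel(p, table)
            paths[f"panel_{table.cohort_name}"] = p
        rows = [
            {
                "variant": str(t.variant),
                "gene": t.gene,
                "flags": "|".join(sorted(t.flags)) or ".",
                "expected_class": t.expected_class.value,
                "patients": "|".join(t.patients),
                "clinvar_recorded": int(t.clinvar_recorded),
            }
            for t in self.truth
        ]
        pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# control panels


def generate_control_panel(
    n_sites: int,
    region_length: int,
    an_mean: float,
    an_jitter: float,
    seed: int,
    contig: str = "chr1",
    cohort_name: str = "control",
) -> CohortSiteTable:
    """A standalone control panel with deliberate recording gaps.

    Sites are sorted and unique; AN is drawn around ``an_mean`` with
    site-to-site jitter (``an_jitter = 0`` gives constant AN).  The panel
    always contains one pair of recorded sites 100 bp apart (so the
    midpoint is an interpolable unrecorded position) and one empty
    stretch longer than twice the 150 bp window (so its midpoint is not).
    """
    if n_sites < 4 or region_length < 2000:
        raise ValueError("need n_sites >= 4 and region_length >= 2000")
    rng = np.random.default_rng(seed)
    gap_start, gap_end = region_length // 2, region_length // 2 + 400
    forced = [100, 200, gap_start - 1, gap_end + 1]
    positions: set[int] = set(forced)
    while len(positions) < n_sites:
        pos = int(rng.integers(1, region_length + 1))
        if gap_start <= pos <= gap_end or 99 <= pos <= 201:
            continue
        positions.add(pos)
    records = []
    for pos in sorted(positions):
        an = max(2, round(an_mean + rng.normal(0.0, 1.0) * an_jitter))
        ac = min(int(rng.poisson(1.0)), an)
        ref, alt = "A", "G"
        if ac == an:
            ac = an - 1
        records.append((GenomicVariant(contig, pos, ref, alt), ac, an))
    return CohortSiteTable(cohort_name, records)


# ---------------------------------------------------------------------------
# cohort planting

_BASES = "ACGT"


def _alleles_for(consequence: Consequence, rng: np.random.Generator) -> tuple[str, str]:
    if consequence in (
        Consequence.FRAMESHIFT_INSERTION,
    ):
        return "C", "CAT"
    if consequence is Consequence.NONFRAMESHIFT_INSERTION:
        return "C", "CAAG"
    if consequence is Consequence.FRAMESHIFT_DELETION:
        return "CAT", "C"
    if consequence is Consequence.NONFRAMESHIFT_DELETION:
        return "CAAG", "C"
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
    return ref, alt


def _protein_changes_for(
    spec: PlantSpec, rng: np.random.Generator, transcript: str = "NM_000001"
) -> tuple[tuple[ProteinChange, ...], list[tuple[str, ProteinChange]]]:
    """Case protein changes plus the helper ClinVar changes each implies.

    Returns ``(case_changes, [(kind, clinvar_change), ...])`` where kind is
    "exact" (PS1: same change) or "residue" (PM5: same residue, other alt).
    """
    aa = sorted(AA_ONE_LETTER)
    profile = spec.target_profile

    def pick_missense(residue: int) -> ProteinChange:
        ref_aa, alt_aa = rng.choice(aa, size=2, replace=False)
        return ProteinChange(spec.gene, transcript, residue, str(ref_aa), str(alt_aa))

    base_residue = spec.residue_index or int(rng.integers(2, 900))
    case_changes: list[ProteinChange] = []
    helpers: list[tuple[str, ProteinChange]] = []

    if spec.consequence is Consequence.NONSYNONYMOUS_SNV:
        if "PS1" in profile:
            change = pick_missense(base_residue)
            case_changes.append(change)
            helpers.append(("exact", change))
        if "PM5" in profile:
            residue = base_residue + (7 if "PS1" in profile else 0)
            change = pick_missense(residue)
            case_changes.append(
                replace(change, transcript="NM_000002" if "PS1" in profile else transcript)
            )
            other_alt = next(
                a for a in aa if a not in (change.ref_aa, change.alt_aa)
            )
            helpers.append(
                ("residue", replace(change, alt_aa=other_alt, transcript="NM_900001"))
            )
        if not case_changes:
            case_changes.append(pick_missense(base_residue))
    elif spec.consequence is Consequence.STOPGAIN:
        case_changes.append(
            ProteinChange(spec.gene, transcript, base_residue, "W", STOP)
        )
    elif spec.consequence is Consequence.STARTLOSS:
        case_changes.append(ProteinChange(spec.gene, transcript, 1, "M", "T"))
    elif spec.consequence in (
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.FRAMESHIFT_DELETION,
    ):
        case_changes.append(
            ProteinChange(spec.gene, transcript, base_residue, "T", FS)
        )
    elif spec.consequence is Consequence.NONFRAMESHIFT_DELETION:
        case_changes.append(
            ProteinChange(spec.gene, transcript, base_residue, "K", DEL)
        )
    elif spec.consequence is Consequence.NONFRAMESHIFT_INSERTION:
        case_changes.append(
            ProteinChange(spec.gene, transcript, base_residue, "K", INS)
        )
    # splice-site / synonymous / other: no protein change rows needed
    return tuple(case_changes), helpers


def _scores_for(
    spec: PlantSpec, case_changes: tuple[ProteinChange, ...]
) -> PredictionScores:
    if "PP3" not in spec.target_profile:
        return PredictionScores()
    if spec.consequence is Consequence.NONSYNONYMOUS_SNV and case_changes:
        return PredictionScores(
            revel_per_change=tuple((c, 0.90) for c in case_changes),
            cadd_phred=27.0,
        )
    # non-missense: REVEL/SIFT/PolyPhen do not apply; CADD + MutationTaster
    return PredictionScores(
        cadd_phred=27.0, mutationtaster_call=MutationTasterCall.DELETERIOUS
    )


def _helper_clinvar_records(
    spec: PlantSpec,
    case_variant: GenomicVariant,
    helpers: list[tuple[str, ProteinChange]],
    rng: np.random.Generator,
) -> list[ClinVarRecord]:
    """ClinVar records that justify the spec's predictive criteria."""
    records: list[ClinVarRecord] = []
    profile = spec.target_profile
    base = GenomicVariant(
        case_variant.contig, case_variant.position + 501, "G", "A"
    )
    common = dict(
        gene=spec.gene,
        review_status=ReviewStatus.MULTIPLE_SUBMITTERS_NO_CONFLICT,
        conditions=frozenset({spec.condition}),
    )
    if "PVS1" in profile:
        records.append(
            ClinVarRecord(
                variant=base,
                significance=Significance.PATHOGENIC,
                consequence=Consequence.STOPGAIN,
                protein_changes=(
                    ProteinChange(spec.gene, "NM_900000", 79, "W", STOP),
                ),
                **common,
            )
        )
    for offset, (kind, change) in enumerate(helpers):
        # a different nucleotide change: same codon +/- a base for "exact"
        pos = case_variant.position + (3 if kind == "exact" else 502 + offset)
        ref = "T" if case_variant.ref != "T" else "G"
        alt = "C" if case_variant.alt != "C" else "A"
        records.append(
            ClinVarRecord(
                variant=GenomicVariant(case_variant.contig, pos, ref, alt),
                significance=Significance.PATHOGENIC,
                consequence=Consequence.NONSYNONYMOUS_SNV,
                protein_changes=(change,),
                **common,
            )
        )
    if "PM4" in profile:
        # any established P/LP in the gene suffices; a likely-pathogenic
        # missense deliberately leaves the pathogenic-only indices untouched
        records.append(
            ClinVarRecord(
                variant=GenomicVariant(
                    case_variant.contig, case_variant.position + 601, "G", "C"
                ),
                significance=Significance.LIKELY_PATHOGENIC,
                consequence=Consequence.NONSYNONYMOUS_SNV,
                protein_changes=(
                    ProteinChange(spec.gene, "NM_900002", 23, "A", "V"),
                ),
                **common,
            )
        )
    return records


def plant_cohort(
    specs: Sequence[PlantSpec],
    seed: int,
    *,
    clinvar_recorded: Sequence[PlantSpec] = (),
    extra_clinvar: Sequence[ClinVarRecord] = (),
    extra_conditions: Iterable[str] = (),
    thresholds: Thresholds = Thresholds(),
) -> PlantedCohort:
    """Generate a full input set whose pipeline output is known by design.

    ``specs`` are classified de novo; ``clinvar_recorded`` specs instead
    receive a gated ClinVar record with their own identity, so the
    pipeline must short-circuit them to the ClinVar-recorded class.
    Identical seeds give identical cohorts.
    """
    all_specs = [*clinvar_recorded, *specs]
    if not all_specs:
        raise SpecError("no specs to plant")
    sizes = {s.cohort_size for s in all_specs}
    if len(sizes) != 1:
        raise SpecError(f"all specs must share one cohort_size, got {sorted(sizes)}")
    cohort_size = sizes.pop()
    rng = np.random.default_rng(seed)

    patients = sorted(
        {p for s in all_specs for p in s.patients}
    )
    filler = (f"S{i:04d}" for i in itertools.count(1))
    while len(patients) < cohort_size:
        pid = next(filler)
        if pid not in patients:
            patients.append(pid)
    patients = sorted(patients)
    if len(patients) > cohort_size:
        raise SpecError("more named patients than cohort_size")

    control_names = [name for name, _ in CONTROL_COHORTS]
    control_records: dict[str, list[tuple[GenomicVariant, int, int]]] = {
        name: [] for name in control_names
    }
    control_an = {name: 2 * n for name, n in CONTROL_COHORTS}

    case_records: list[tuple[GenomicVariant, int, int]] = []
    carriers: dict[GenomicVariant, dict[str, str]] = {}
    annotations: dict[GenomicVariant, VariantAnnotation] = {}
    clinvar_records: list[ClinVarRecord] = list(extra_clinvar)
    repeat_intervals: dict[str, list[tuple[int, int]]] = {}
    truth: list[TruthRecord] = []
    conditions = set(extra_conditions) | {s.condition for s in all_specs}

    # deterministic coordinate allocation per contig
    next_slot: dict[str, int] = {}

    def allocate(contig: str) -> int:
        slot = next_slot.get(contig, 0)
        next_slot[contig] = slot + 1
        return 1_000_000 + slot * 1_000

    for spec in all_specs:
        is_recorded_plp = spec in clinvar_recorded
        spec_rng = (
            np.random.default_rng(spec.seed) if spec.seed is not None else rng
        )
        if spec.variant is not None:
            variant = spec.variant
        else:
            contig = "chr1"
            ref, alt = _alleles_for(spec.consequence, spec_rng)
            variant = GenomicVariant(contig, allocate(contig), ref, alt)

        case_changes, helpers = _protein_changes_for(spec, spec_rng)
        scores = _scores_for(spec, case_changes)
        annotations[variant] = VariantAnnotation(
            variant=variant,
            gene=spec.gene,
            consequence=spec.consequence,
            protein_changes=case_changes,
            in_repeat_region=spec.in_repeat,
            scores=scores,
        )
        if spec.in_repeat:
            span = max(len(variant.ref), len(variant.alt))
            repeat_intervals.setdefault(variant.contig, []).append(
                (variant.position - 5, variant.position + span + 5)
            )

        # case cohort counts and carriers (all heterozygous)
        case_records.append((variant, spec.carrier_count, 2 * cohort_size))
        if spec.patients:
            chosen = list(spec.patients)
        else:
            chosen = list(
                spec_rng.choice(patients, size=spec.carrier_count, replace=False)
            )
        carriers[variant] = {str(p): "het" for p in chosen}

        # control panel structure
        for name in control_names:
            an = control_an[name]
            jitter = lambda: int(rng.integers(-300, 301))
            presence = spec.control_presence
            if is_recorded_plp:
                presence = ControlPresence.UNRECORDED_UNINTERPOLABLE
            if presence in (
                ControlPresence.RECORDED_ZERO,
                ControlPresence.RECORDED_RARE,
                ControlPresence.RECORDED_COMMON,
            ):
                site_an = an + jitter()
                af = {
                    ControlPresence.RECORDED_ZERO: 0.0,
                    ControlPresence.RECORDED_RARE: RARE_CONTROL_AF,
                    ControlPresence.RECORDED_COMMON: COMMON_CONTROL_AF,
                }[presence]
                control_records[name].append(
                    (variant, round(af * site_an), site_an)
                )
            else:
                up = FLANK_IN_WINDOW
                down = (
                    FLANK_IN_WINDOW
                    if presence is ControlPresence.UNRECORDED_INTERPOLABLE
                    else FLANK_OUT_OF_WINDOW
                )
                for delta in (-up, down):
                    pos = variant.position + delta
                    if pos < 1:
                        continue
                    site_an = an + jitter()
                    control_records[name].append(
                        (GenomicVariant(variant.contig, pos, "A", "G"),
                         min(3, site_an), site_an)
                    )

        # ClinVar evidence
        if is_recorded_plp:
            clinvar_records.append(
                ClinVarRecord(
                    variant=variant,
                    gene=spec.gene,
                    significance=Significance.PATHOGENIC,
                    review_status=ReviewStatus.MULTIPLE_SUBMITTERS_NO_CONFLICT,
                    conditions=frozenset({spec.condition}),
                    consequence=spec.consequence,
                    protein_changes=case_changes,
                )
            )
            truth.append(
                TruthRecord(
                    variant=variant,
                    gene=spec.gene,
                    flags=frozenset(),
                    expected_class=VariantClass.CLINVAR_PLP,
                    patients=tuple(str(p) for p in chosen),
                    clinvar_recorded=True,
                )
            )
        else:
            clinvar_records.extend(
                _helper_clinvar_records(spec, variant, helpers, spec_rng)
            )
            truth.append(
                TruthRecord(
                    variant=variant,
                    gene=spec.gene,
                    flags=spec.target_profile,
                    expected_class=expected_class(spec.target_profile),
                    patients=tuple(str(p) for p in chosen),
                )
            )

    controls = tuple(
        CohortSiteTable(name, control_records[name]) for name in control_names
    )
    extra_cases = tuple(
        CohortSiteTable(name, (), default_diploid_n=n) for name, n in EXTRA_CASE_COHORTS
    )
    case_table = CohortSiteTable(
        f"case_{cohort_size}", case_records, default_diploid_n=cohort_size
    )
    return PlantedCohort(
        case_table=case_table,
        carriers=carriers,
        annotations=annotations,
        clinvar_records=tuple(clinvar_records),
        condition_allowlist=frozenset(conditions),
        controls=controls,
        extra_cases=extra_cases,
        repeat_intervals=repeat_intervals,
        truth=truth,
        patients=patients,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# randomized consistent specs

#: (profile, control presence) templates covering every reachable class.
_TEMPLATES: tuple[tuple[frozenset[str], ControlPresence], ...] = tuple(
    (frozenset(profile), presence)
    for profile, presence in [
        ((), ControlPresence.RECORDED_RARE),
        ((), ControlPresence.UNRECORDED_UNINTERPOLABLE),
        (("BS1",), ControlPresence.RECORDED_COMMON),
        (("BS1", "PP3"), ControlPresence.RECORDED_COMMON),
        (("PVS1", "PM2", "PS4"), ControlPresence.UNRECORDED_INTERPOLABLE),
        (("PVS1", "PS4"), ControlPresence.RECORDED_ZERO),
        (("PVS1", "PM2"), ControlPresence.UNRECORDED_UNINTERPOLABLE),
        (("PVS1",), ControlPresence.RECORDED_RARE),
        (("PVS1", "PP3", "PM2", "PS4"), ControlPresence.UNRECORDED_INTERPOLABLE),
        (("PS1", "PM2", "PS4"), ControlPresence.UNRECORDED_INTERPOLABLE),
        (("PS1", "PS4"), ControlPresence.RECORDED_ZERO),
        (("PS1", "PM2"), ControlPresence.UNRECORDED_UNINTERPOLABLE),
        (("PS1", "PM5", "PM2", "PS4"), ControlPresence.UNRECORDED_INTERPOLABLE),
        (("PM5", "PS4"), ControlPresence.RECORDED_ZERO),
        (("PM5", "PM2", "PS4"), ControlPresence.UNRECORDED_INTERPOLABLE),
        (("PM5",), ControlPresence.RECORDED_RARE),
        (("PM5", "PP3", "PS4"), ControlPresence.RECORDED_ZERO),
        (("PM4", "PS4"), ControlPresence.RECORDED_ZERO),
        (("PM4", "PM2", "PS4"), ControlPresence.UNRECORDED_INTERPOLABLE),
        (("PM4",), ControlPresence.RECORDED_RARE),
        (("PM4", "PP3", "PS4"), ControlPresence.RECORDED_ZERO),
        (("PP3",), ControlPresence.RECORDED_RARE),
        (("PP3", "PM2", "PS4"), ControlPresence.UNRECORDED_INTERPOLABLE),
    ]
)


def _consequence_for(profile: frozenset[str], rng: np.random.Generator) -> Consequence:
    if "PVS1" in profile:
        return sorted(NULL_CONSEQUENCES)[int(rng.integers(0, len(NULL_CONSEQUENCES)))]
    if "PM4" in profile:
        return (
            Consequence.NONFRAMESHIFT_INSERTION,
            Consequence.NONFRAMESHIFT_DELETION,
            Consequence.STOPLOSS,
        )[int(rng.integers(0, 3))]
    if profile & {"PS1", "PM5"} or "PP3" in profile:
        return Consequence.NONSYNONYMOUS_SNV
    if "BS1" in profile:
        return Consequence.NONSYNONYMOUS_SNV
    return (Consequence.SYNONYMOUS, Consequence.OTHER)[int(rng.integers(0, 2))]


def random_consistent_specs(
    n: int, seed: int, cohort_size: int = DEFAULT_COHORT_SIZE
) -> list[PlantSpec]:
    """Draw ``n`` internally consistent PlantSpecs spanning the templates."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        profile, presence = _TEMPLATES[int(rng.integers(0, len(_TEMPLATES)))]
        gate_passes = bool(profile & PREDICTIVE_CRITERIA)
        if "PS4" in profile:
            carrier_count = int(rng.integers(1, 4))
        elif gate_passes and "BS1" not in profile:
            carrier_count = 1
        else:
            carrier_count = int(rng.integers(1, 3))
        specs.append(
            PlantSpec(
                target_profile=profile,
                gene=f"GENE{i:04d}",
                consequence=_consequence_for(profile, rng),
                control_presence=presence,
                carrier_count=carrier_count,
                cohort_size=cohort_size,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# the packaged desk-scale study fixture

# Synthetic placeholder coordinates are assigned to rsID-only variants
# (only three variants have printed genomic coordinates); identity within
# the fixture is positional and rsIDs are metadata.
_GENE_CONTIGS = {
    "FANCA": "chr16", "PALB2": "chr16", "WWOX": "chr16",
    "BRCA2": "chr13",
    "BRIP1": "chr17", "RAD51D": "chr17", "TP53": "chr17",
    "GATA2": "chr3",
    "ERCC6/PGBD3": "chr10", "PTEN": "chr10",
    "EXT2": "chr11", "KMT2A": "chr11",
    "GPC3": "chrX",
    "MSH2": "chr2",
    "WRN": "chr8",
    "FANCI": "chr15",
    "ATM": "chr11", "CHEK2": "chr22", "MUTYH": "chr1",
    "TERT": "chr5", "GREB1": "chr2",
}

_CANCER_CONDITIONS = frozenset(
    {
        "hereditary cancer-predisposing syndrome",
        "hereditary breast ovarian cancer syndrome",
        "malignant tumor of the esophagus",
        "acute myeloid leukemia susceptibility",
        "wilms tumor",
        "li-fraumeni syndrome",
        "lynch syndrome",
        "fanconi anemia",
    }
)

_INTERP = ControlPresence.UNRECORDED_INTERPOLABLE
_ZERO = ControlPresence.RECORDED_ZERO

# the six variants carried as established P/LP knowledge: patient, gene,
# rsid, consequence
_CLINVAR_SIX = [
    ("H3168", "FANCA", "rs2039260856", Consequence.STOPGAIN),
    ("H3168", "PALB2", "rs878855123", Consequence.STOPGAIN),
    ("H1641", "BRCA2", "rs1555283001", Consequence.STOPGAIN),
    ("H1362", "BRIP1", "rs775537066", Consequence.STOPGAIN),
    ("H1409", "RAD51D", "rs753862052", Consequence.FRAMESHIFT_INSERTION),
    ("H2590", "TP53", "rs587782144", Consequence.NONSYNONYMOUS_SNV),
]

# the thirteen newly classified variants: patient, gene, rsid or explicit
# coordinates, consequence, criterion profile, control presence
_NEW_THIRTEEN = [
    ("H3587", "EXT2", ("chr11", 44109284, "G", "C"), Consequence.SPLICE_SITE,
     ("PVS1", "PM2", "PS4"), _INTERP),
    ("H1026", "BRIP1", "rs1426528935", Consequence.FRAMESHIFT_DELETION,
     ("PVS1", "PM2", "PS4"), _INTERP),
    ("H3539", "FANCA", "rs755104393", Consequence.SPLICE_SITE,
     ("PVS1", "PM2", "PS4"), _INTERP),
    ("H4324", "WWOX", "rs758588684", Consequence.STARTLOSS,
     ("PVS1", "PM2", "PS4"), _INTERP),
    ("H2552", "GATA2", "rs1166272013", Consequence.SPLICE_SITE,
     ("PVS1", "PS4"), _ZERO),
    ("H3400", "ERCC6/PGBD3", "rs181055741", Consequence.STOPGAIN,
     ("PVS1", "PS4"), _ZERO),
    ("H4270", "TP53", "rs1019340046", Consequence.NONSYNONYMOUS_SNV,
     ("PS1", "PP3", "PM2", "PS4"), _INTERP),
    ("H1758", "GPC3", "rs1158430569", Consequence.NONSYNONYMOUS_SNV,
     ("PM5", "PM2", "PS4"), _INTERP),
    ("H4326", "MSH2", "rs768572053", Consequence.NONSYNONYMOUS_SNV,
     ("PM5", "PS4"), _ZERO),
    ("H3053", "WRN", "rs569405870", Consequence.NONSYNONYMOUS_SNV,
     ("PM5", "PM2", "PS4"), _INTERP),
    ("H4326", "PTEN", ("chr10", 87864072, "TCTA", "T"),
     Consequence.NONFRAMESHIFT_DELETION, ("PM4", "PM2", "PS4"), _INTERP),
    ("H2235", "FANCI", "rs747603151", Consequence.NONFRAMESHIFT_DELETION,
     ("PM4", "PS4"), _ZERO),
    ("H2420", "KMT2A", ("chr11", 118436698, "C", "CGCG"),
     Consequence.NONFRAMESHIFT_INSERTION, ("PM4", "PM2", "PS4"), _INTERP),
]

# evidence-bearing filler variants: patient, gene, consequence, profile,
# presence — three VUS, one frequency-excluded, one with no evidence
_FILLERS = [
    ("H9001", "ATM", Consequence.NONSYNONYMOUS_SNV, ("PP3",),
     ControlPresence.RECORDED_RARE),
    ("H9002", "CHEK2", Consequence.NONSYNONYMOUS_SNV, ("PP3",),
     ControlPresence.RECORDED_RARE),
    ("H9003", "MUTYH", Consequence.NONSYNONYMOUS_SNV, ("PP3",),
     ControlPresence.RECORDED_RARE),
    ("H9004", "TERT", Consequence.NONSYNONYMOUS_SNV, ("BS1", "PP3"),
     ControlPresence.RECORDED_COMMON),
    ("H9005", "GREB1", Consequence.SYNONYMOUS, (),
     ControlPresence.RECORDED_RARE),
]


_PLACEHOLDER_ALLELES = {
    Consequence.FRAMESHIFT_INSERTION: ("G", "GTA"),
    Consequence.FRAMESHIFT_DELETION: ("GTA", "G"),
    Consequence.NONFRAMESHIFT_INSERTION: ("G", "GAAA"),
    Consequence.NONFRAMESHIFT_DELETION: ("GAAA", "G"),
}


def _fixture_variant(
    gene: str, locator, consequence: Consequence, counters: dict[str, int]
) -> tuple[GenomicVariant, Optional[str]]:
    if isinstance(locator, tuple):
        contig, pos, ref, alt = locator
        return GenomicVariant(contig, pos, ref, alt), None
    contig = _GENE_CONTIGS[gene]
    k = counters.get(contig, 0)
    counters[contig] = k + 1
    ref, alt = _PLACEHOLDER_ALLELES.get(consequence, ("G", "A"))
    return GenomicVariant(contig, 5_000_000 + k * 10_000, ref, alt), locator


def _fixture_metadata(patients: Sequence[str]) -> pd.DataFrame:
    """55-patient metadata table matching the cohort's printed margins:
    52 never-smokers; 5/38/12 lung-first/breast-first/synchronous; EGFR
    (adenocarcinoma only): 33 mutant + 12 wild-type over 45 tested, 4
    untested, 6 non-adenocarcinoma."""
    smoking = {"H4326": "smoker"}
    temporal = {
        "H1409": "synchronous", "H2552": "synchronous", "H3400": "synchronous",
        "H3053": "synchronous", "H4326": "lung_first",
    }
    egfr = {
        "H3168": "mutant", "H1641": "mutant", "H2590": "mutant",
        "H1026": "mutant", "H3539": "mutant", "H3400": "mutant",
        "H1758": "mutant", "H2420": "mutant",
        "H1409": "wild_type", "H4324": "wild_type", "H2552": "wild_type",
        "H4326": "wild_type", "H3053": "wild_type", "H2235": "wild_type",
        "H1362": None, "H3587": None, "H4270": None,  # non-adenocarcinoma
    }
    fillers = [p for p in patients if p not in egfr]
    quotas = {
        "smoking": iter(["smoker", "smoker"]),
        "temporal_lung_first": 4,
        "temporal_synchronous": 8,
        "egfr_mutant": 25,
        "egfr_wild_type": 6,
        "egfr_not_tested": 4,
        "egfr_na": 3,
    }
    rows = []
    i_t, i_e = 0, 0
    for p in fillers:
        smoke = next(quotas["smoking"], "never")
        if i_t < quotas["temporal_lung_first"]:
            temp = "lung_first"
        elif i_t < quotas["temporal_lung_first"] + quotas["temporal_synchronous"]:
            temp = "synchronous"
        else:
            temp = "breast_first"
        i_t += 1
        if i_e < quotas["egfr_mutant"]:
            eg = "mutant"
        elif i_e < quotas["egfr_mutant"] + quotas["egfr_wild_type"]:
            eg = "wild_type"
        elif i_e < quotas["egfr_mutant"] + quotas["egfr_wild_type"] + quotas["egfr_not_tested"]:
            eg = "not_tested"
        else:
            eg = None
        i_e += 1
        smoking.setdefault(p, smoke)
        temporal.setdefault(p, temp)
        egfr.setdefault(p, eg)
    for p in patients:
        rows.append(
            {
                "patient_id": p,
                "smoking_status": smoking.get(p, "never"),
                "temporal_order": temporal.get(p, "breast_first"),
                "egfr_status": egfr.get(p),
            }
        )
    return pd.DataFrame(rows)


def paper_fixture(seed: int = 0) -> PlantedCohort:
    """The packaged desk-scale fixture: 6 ClinVar-recorded variants, 13
    newly classifiable criterion profiles, 5 evidence-bearing fillers, a
    Table-3-style carrier roster over 55 patients, and cohort metadata.

    rsID-only variants receive synthetic placeholder coordinates; only
    the three variants whose genomic coordinates are printed keep them.
    """
    counters: dict[str, int] = {}
    recorded_specs, new_specs = [], []
    residue_pool = itertools.count(100, 13)

    for patient, gene, rsid, consequence in _CLINVAR_SIX:
        variant, rs = _fixture_variant(gene, rsid, consequence, counters)
        recorded_specs.append(
            PlantSpec(
                target_profile=frozenset(),
                gene=gene,
                consequence=consequence,
                control_presence=ControlPresence.UNRECORDED_UNINTERPOLABLE,
                patients=(patient,),
                variant=variant,
                rsid=rs,
                residue_index=next(residue_pool),
            )
        )
    for patient, gene, locator, consequence, profile, presence in _NEW_THIRTEEN:
        variant, rs = _fixture_variant(gene, locator, consequence, counters)
        new_specs.append(
            PlantSpec(
                target_profile=frozenset(profile),
                gene=gene,
                consequence=consequence,
                control_presence=presence,
                patients=(patient,),
                variant=variant,
                rsid=rs,
                residue_index=next(residue_pool),
            )
        )
    for patient, gene, consequence, profile, presence in _FILLERS:
        variant, _ = _fixture_variant(gene, "synthetic", consequence, counters)
        new_specs.append(
            PlantSpec(
                target_profile=frozenset(profile),
                gene=gene,
                consequence=consequence,
                control_presence=presence,
                patients=(patient,),
                variant=variant,
                residue_index=next(residue_pool),
            )
        )

    # records that the evidence gate must drop
    dropped = [
        ClinVarRecord(
            variant=GenomicVariant("chr17", 6_400_000, "C", "T"),
            gene="TP53",
            significance=Significance.PATHOGENIC,
            review_status=ReviewStatus.SINGLE_SUBMITTER_WITH_CRITERIA,
            conditions=frozenset({"li-fraumeni syndrome"}),
            consequence=Consequence.NONSYNONYMOUS_SNV,
        ),
        ClinVarRecord(
            variant=GenomicVariant("chr13", 6_500_000, "G", "T"),
            gene="BRCA2",
            significance=Significance.PATHOGENIC,
            review_status=ReviewStatus.CONFLICTING_INTERPRETATIONS,
            conditions=frozenset({"hereditary breast ovarian cancer syndrome"}),
            consequence=Consequence.STOPGAIN,
        ),
    ]

    planted = plant_cohort(
        new_specs,
        seed=seed,
        clinvar_recorded=recorded_specs,
        extra_clinvar=dropped,
        extra_conditions=_CANCER_CONDITIONS,
    )
    # restore the H-series patient ids as the roster
    planted.metadata = _fixture_metadata(planted.patients)
    return planted
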