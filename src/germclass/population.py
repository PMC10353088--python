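"""Population-data criteria: BS1, PM2 and PS4.

Control cohorts are site-frequency tables keyed by normalized variant.
"Recorded" is presence of the variant in the table, which is deliberately
distinct from a zero allele count: a variant can be recorded with AC = 0
in a subpopulation slice while segregating elsewhere, whereas an
unrecorded variant was seen nowhere in the source database.

For the six pairwise Fisher tests, an unrecorded control variant enters
with AC = 0 and an allele number linearly interpolated from the nearest
recorded flanking sites within a window (150 bp by default).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import fisher_exact

from .clinvar import ConfigurationError
from .variants import GenomicVariant, Thresholds, normalize_variant

__all__ = [
    "CohortSiteTable",
    "Direction",
    "EnrichmentResult",
    "PopulationEvidence",
    "UNAVAILABLE",
    "allele_frequency",
    "minor_allele_frequency",
    "evaluate_bs1",
    "evaluate_pm2",
    "interpolate_allele_number",
    "fisher_two_tailed",
    "evaluate_ps4",
    "evaluate_population",
]

logger = logging.getLogger(__name__)

#: Sentinel returned when no flanking recorded site exists within the window.
UNAVAILABLE = None


class Direction(str, Enum):
    CASE_ENRICHED = "case_enriched"
    CONTROL_ENRICHED = "control_enriched"
    NONE = "none"


class CohortSiteTable:
    """Positionally indexed AC/AN records for one cohort.

    Parameters
    ----------
    cohort_name
        Label used in enrichment results.
    records
        Iterable of ``(variant, ac, an)``; variants are normalized on entry.
    default_diploid_n
        For case cohorts: number of fully genotyped subjects, so that a
        variant absent from the table still has AN = 2n and AC = 0.
    """

    def __init__(
        self,
        cohort_name: str,
        records: Iterable[tuple[GenomicVariant, int, int]] = (),
        default_diploid_n: Optional[int] = None,
    ) -> None:
        self.cohort_name = cohort_name
        self.default_diploid_n = default_diploid_n
        self.records: dict[GenomicVariant, tuple[int, int]] = {}
        for variant, ac, an in records:
            self.add(variant, ac, an)
        self._index: Optional[dict[str, tuple[list[int], list[int]]]] = None

    def add(self, variant: GenomicVariant, ac: int, an: int) -> None:
        if an <= 0:
            raise ValueError(f"allele number must be positive at {variant}")
        if not 0 <= ac <= an:
            raise ValueError(f"need 0 <= AC <= AN at {variant} (AC={ac}, AN={an})")
        self.records[normalize_variant(variant)] = (int(ac), int(an))
        self._index = None

    # -- queries ---------------------------------------------------------

    def is_recorded(self, v: GenomicVariant) -> bool:
        return normalize_variant(v) in self.records

    def lookup(self, v: GenomicVariant) -> Optional[tuple[int, int]]:
        return self.records.get(normalize_variant(v))

    def __len__(self) -> int:
        return len(self.records)

    def _position_index(self) -> dict[str, tuple[list[int], list[int]]]:
        """Per-contig sorted positions with a representative AN each."""
        if self._index is None:
            by_contig: dict[str, dict[int, int]] = {}
            for variant, (_, an) in self.records.items():
                # several alleles can share a site; they carry the same AN,
                # keep the max defensively
                sites = by_contig.setdefault(variant.contig, {})
                sites[variant.position] = max(sites.get(variant.position, 0), an)
            self._index = {
                contig: (sorted(sites), [sites[p] for p in sorted(sites)])
                for contig, sites in by_contig.items()
            }
        return self._index

    def an_at_position(self, contig: str, position: int) -> Optional[int]:
        positions, ans = self._position_index().get(contig, ([], []))
        i = bisect.bisect_left(positions, position)
        if i < len(positions) and positions[i] == position:
            return ans[i]
        return None

    def flanking_recorded(
        self, contig: str, position: int
    ) -> tuple[Optional[tuple[int, int]], Optional[tuple[int, int]]]:
        """Nearest recorded ``(pos, AN)`` strictly upstream and downstream."""
        positions, ans = self._position_index().get(contig, ([], []))
        i = bisect.bisect_left(positions, position)
        upstream = (positions[i - 1], ans[i - 1]) if i > 0 else None
        j = bisect.bisect_right(positions, position)
        downstream = (positions[j], ans[j]) if j < len(positions) else None
        return upstream, downstream


def allele_frequency(ac: int, an: int) -> float:
    if an <= 0:
        raise ValueError("allele frequency undefined for AN = 0")
    if not 0 <= ac <= an:
        raise ValueError(f"need 0 <= AC <= AN (AC={ac}, AN={an})")
    return ac / an


def minor_allele_frequency(ac: int, an: int) -> float:
    af = allele_frequency(ac, an)
    return min(af, 1.0 - af)


def evaluate_bs1(
    v: GenomicVariant, controls: Sequence[CohortSiteTable], t: Thresholds
) -> bool:
    """MAF strictly above the threshold in at least one control cohort."""
    if not controls:
        raise ConfigurationError("BS1 requires at least one control cohort")
    for table in controls:
        rec = table.lookup(v)
        if rec is not None and minor_allele_frequency(*rec) > t.bs1_maf:
            return True
    return False


def evaluate_pm2(v: GenomicVariant, controls: Sequence[CohortSiteTable]) -> bool:
    """Absent from the records of *every* control cohort.

    Recorded-with-AC-0 counts as recorded, hence PM2 false — stricter than
    a zero-allele-count test.
    """
    if not controls:
        raise ConfigurationError("PM2 requires control cohorts")
    if len(controls) == 1:
        logger.warning(
            "PM2 evaluated against a single control cohort (%s); the criterion "
            "is defined over two cohorts",
            controls[0].cohort_name,
        )
    return all(not table.is_recorded(v) for table in controls)


def interpolate_allele_number(
    contig: str,
    position: int,
    table: CohortSiteTable,
    t: Thresholds = Thresholds(),
) -> Optional[int]:
    """Linearly interpolate AN at an unrecorded position.

    Uses the nearest recorded sites strictly upstream and downstream, each
    within ``t.interpolation_window_bp``; returns ``UNAVAILABLE`` (None)
    when either flank is missing.  The result is rounded to the nearest
    integer so it can serve as a Fisher margin.
    """
    upstream, downstream = table.flanking_recorded(contig, position)
    w = t.interpolation_window_bp
    if upstream is None or position - upstream[0] > w:
        return UNAVAILABLE
    if downstream is None or downstream[0] - position > w:
        return UNAVAILABLE
    (u, an_u), (d, an_d) = upstream, downstream
    return round(an_u + (position - u) * (an_d - an_u) / (d - u))


def fisher_two_tailed(
    case_ac: int, case_an: int, ctrl_ac: int, ctrl_an: int
) -> tuple[float, Direction]:
    """Two-sided Fisher exact test on allele counts, plus a direction.

    The 2x2 table is ``[[case_ac, case_an - case_ac], [ctrl_ac,
    ctrl_an - ctrl_ac]]``.  Direction compares raw allele frequencies; a
    two-tailed p-value itself carries no direction.
    """
    if case_an <= 0 or ctrl_an <= 0:
        raise ValueError("Fisher test undefined for an empty margin (AN = 0)")
    if not (0 <= case_ac <= case_an and 0 <= ctrl_ac <= ctrl_an):
        raise ValueError("allele counts must satisfy 0 <= AC <= AN")
    table = [[case_ac, case_an - case_ac], [ctrl_ac, ctrl_an - ctrl_ac]]
    p = float(fisher_exact(table, alternative="two-sided").pvalue)
    case_af, ctrl_af = case_ac / case_an, ctrl_ac / ctrl_an
    if case_af > ctrl_af:
        direction = Direction.CASE_ENRICHED
    elif ctrl_af > case_af:
        direction = Direction.CONTROL_ENRICHED
    else:
        direction = Direction.NONE
    return p, direction


@dataclass(frozen=True)
class EnrichmentResult:
    case_cohort: str
    control_cohort: str
    p_value: float
    direction: Direction
    case_ac: int
    case_an: int
    control_ac: int
    control_an: int
    control_an_interpolated: bool


@dataclass(frozen=True)
class PopulationEvidence:
    bs1: bool
    pm2: bool
    ps4: bool
    comparisons: tuple[EnrichmentResult, ...] = ()

    @property
    def any_criterion(self) -> bool:
        return self.bs1 or self.pm2 or self.ps4


def _case_counts(v: GenomicVariant, table: CohortSiteTable) -> tuple[int, int]:
    rec = table.lookup(v)
    if rec is not None:
        return rec
    if table.default_diploid_n is None:
        raise ConfigurationError(
            f"case cohort {table.cohort_name!r} lacks {v} and has no cohort size "
            "to impute AC=0"
        )
    return 0, 2 * table.default_diploid_n


def _control_counts(
    v: GenomicVariant, table: CohortSiteTable, t: Thresholds
) -> Optional[tuple[int, int, bool]]:
    """(AC, AN, interpolated?) for a control cohort, or None if unavailable."""
    rec = table.lookup(v)
    if rec is not None:
        return rec[0], rec[1], False
    # unrecorded variant: AC = 0; AN from the genotyped position if another
    # allele is recorded there, else interpolated from flanking sites
    an = table.an_at_position(v.contig, v.position)
    if an is not None:
        return 0, an, False
    an = interpolate_allele_number(v.contig, v.position, table, t)
    if an is None or an <= 0:
        return None
    return 0, an, True


def evaluate_ps4(
    v: GenomicVariant,
    cases: Sequence[CohortSiteTable],
    controls: Sequence[CohortSiteTable],
    t: Thresholds,
) -> tuple[bool, tuple[EnrichmentResult, ...]]:
    """Case enrichment in >= 1 of the pairwise case-control comparisons,
    with no comparison significantly enriched in controls.

    Pairs whose control allele number cannot be established (unrecorded and
    uninterpolable) are skipped and yield no result.
    """
    if not cases:
        raise ConfigurationError("PS4 requires at least one case cohort")
    if not controls:
        raise ConfigurationError("PS4 requires control cohorts")
    v = normalize_variant(v)
    results = []
    for case in cases:
        case_ac, case_an = _case_counts(v, case)
        for control in controls:
            counts = _control_counts(v, control, t)
            if counts is None:
                continue
            ctrl_ac, ctrl_an, interpolated = counts
            p, direction = fisher_two_tailed(case_ac, case_an, ctrl_ac, ctrl_an)
            results.append(
                EnrichmentResult(
                    case_cohort=case.cohort_name,
                    control_cohort=control.cohort_name,
                    p_value=p,
                    direction=direction,
                    case_ac=case_ac,
                    case_an=case_an,
                    control_ac=ctrl_ac,
                    control_an=ctrl_an,
                    control_an_interpolated=interpolated,
                )
            )
    enriched_in_cases = any(
        r.p_value < t.ps4_alpha and r.direction is Direction.CASE_ENRICHED
        for r in results
    )
    enriched_in_controls = any(
        r.p_value < t.ps4_alpha and r.direction is Direction.CONTROL_ENRICHED
        for r in results
    )
    return enriched_in_cases and not enriched_in_controls, tuple(results)


def evaluate_population(
    v: GenomicVariant,
    cases: Sequence[CohortSiteTable],
    controls: Sequence[CohortSiteTable],
    t: Thresholds,
) -> PopulationEvidence:
    """Aggregate BS1, PM2 and PS4 with the pairwise comparisons.

    BS1 exclusion wins: a common variant is not tested for PM2/PS4.
    """
    bs1 = evaluate_bs1(v, controls, t)
    if bs1:
        return PopulationEvidence(bs1=True, pm2=False, ps4=False)
    pm2 = evaluate_pm2(v, controls)
    ps4, comparisons = evaluate_ps4(v, cases, controls, t)
    return PopulationEvidence(bs1=False, pm2=pm2, ps4=ps4, comparisons=comparisons)
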