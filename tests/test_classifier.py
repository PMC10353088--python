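"""Combination rules, pipeline staging, and patient/cohort summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from germclass import (
    ClinVarKnowledge,
    CohortSiteTable,
    Consequence,
    CriterionProfile,
    GenomicVariant,
    PopulationEvidence,
    PredictiveEvidence,
    Thresholds,
    VariantAnnotation,
    VariantClass,
    classify,
    run_pipeline,
    summarize_cohort,
    summarize_patients,
)
from germclass.classifier import CLASS_ORDER
from germclass.simulate import CRITERIA


def profile(flags=(), clinvar=False):
    flags = set(flags)
    return CriterionProfile(
        predictive=PredictiveEvidence(
            pvs1="PVS1" in flags,
            ps1="PS1" in flags,
            pm5="PM5" in flags,
            pm4="PM4" in flags,
            pp3="PP3" in flags,
            predictor_votes={},
        ),
        population=PopulationEvidence(
            bs1="BS1" in flags, pm2="PM2" in flags, ps4="PS4" in flags
        ),
        clinvar_recorded=clinvar,
    )


class TestClassify:
    @pytest.mark.parametrize(
        ("flags", "expected", "rule"),
        [
            ({"PVS1", "PM2", "PS4"}, VariantClass.PATHOGENIC, "PVS1+PS4"),
            ({"PS1", "PS4"}, VariantClass.PATHOGENIC, "PS1+PS4"),
            ({"PM5", "PS4"}, VariantClass.LIKELY_PATHOGENIC, "PS4+PM5"),
            ({"PVS1", "PM2"}, VariantClass.LIKELY_PATHOGENIC, "PVS1+PM2"),
            ({"PS1", "PM2"}, VariantClass.LIKELY_PATHOGENIC, "PS1+PM2"),
            ({"PS4", "PM4"}, VariantClass.LIKELY_PATHOGENIC, "PS4+PM4"),
            ({"PP3"}, VariantClass.VUS, None),
            ({"PM4"}, VariantClass.VUS, None),
            ({"BS1", "PVS1", "PS4"}, VariantClass.EXCLUDED_BENIGN, "BS1"),
            (set(), VariantClass.NOT_EVALUATED, None),
        ],
    )
    def test_rules(self, flags, expected, rule):
        result = classify(profile(flags))
        assert result.klass is expected
        if rule:
            assert rule in result.fired_rules

    def test_clinvar_recorded_short_circuits(self):
        result = classify(profile({"PVS1", "PS4", "BS1"}, clinvar=True))
        assert result.klass is VariantClass.CLINVAR_PLP
        assert result.fired_rules == ("ClinVar",)

    def test_total_and_deterministic(self):
        for bits in itertools.product([False, True], repeat=8):
            flags = {c for c, b in zip(CRITERIA, bits) if b}
            first = classify(profile(flags))
            second = classify(profile(flags))
            assert first.klass is second.klass
            assert first.fired_rules == second.fired_rules

    def test_severity_monotone_in_pathogenicity_criteria(self):
        """Adding a true pathogenicity criterion (never BS1) never lowers
        the class, over all profiles without BS1."""
        pathogenicity = [c for c in CRITERIA if c != "BS1"]
        for bits in itertools.product([False, True], repeat=7):
            flags = {c for c, b in zip(pathogenicity, bits) if b}
            base = classify(profile(flags)).klass
            for extra in pathogenicity:
                if extra in flags:
                    continue
                grown = classify(profile(flags | {extra})).klass
                assert CLASS_ORDER[grown] >= CLASS_ORDER[base], (flags, extra)


class TestPipelineStaging:
    def test_empty_cohort(self):
        out = run_pipeline(
            CohortSiteTable("case", (), default_diploid_n=10),
            {},
            ClinVarKnowledge.empty(),
            [CohortSiteTable("c1"), CohortSiteTable("c2")],
        )
        assert out.results == [] and out.rejections == []

    def test_unannotated_variant_is_rejected_not_dropped(self):
        v = GenomicVariant("chr1", 100, "G", "T")
        out = run_pipeline(
            CohortSiteTable("case", [(v, 1, 20)], default_diploid_n=10),
            {},
            ClinVarKnowledge.empty(),
            [CohortSiteTable("c1"), CohortSiteTable("c2")],
        )
        assert out.results == []
        assert len(out.rejections) == 1
        assert out.stage_counts["rejected"] == 1

    def test_gate_failed_variant_is_not_population_tested(self):
        v = GenomicVariant("chr1", 100, "G", "T")
        ann = VariantAnnotation(
            variant=v, gene="G", consequence=Consequence.SYNONYMOUS
        )
        # unrecorded in controls: would be PM2 if it were evaluated
        out = run_pipeline(
            CohortSiteTable("case", [(v, 1, 20)], default_diploid_n=10),
            {v: ann},
            ClinVarKnowledge.empty(),
            [CohortSiteTable("c1"), CohortSiteTable("c2")],
        )
        (result,) = out.results
        assert result.klass is VariantClass.NOT_EVALUATED
        assert not result.profile.population.pm2
        assert out.stage_counts["population_tested"] == 0


class TestPatientSummaries:
    def res(self, klass, pos):
        r = classify(
            profile(
                {
                    VariantClass.PATHOGENIC: {"PVS1", "PS4"},
                    VariantClass.VUS: {"PP3"},
                }[klass]
            ),
            variant=GenomicVariant("chr1", pos, "G", "T"),
            gene=f"G{pos}",
        )
        assert r.klass is klass
        return r

    def test_one_patient_p_and_vus(self):
        p = self.res(VariantClass.PATHOGENIC, 100)
        u = self.res(VariantClass.VUS, 200)
        carriers = {p.variant: {"A": "het"}, u.variant: {"A": "het"}}
        summaries, agg = summarize_patients([p, u], carriers, cohort_size=10)
        assert agg["plp_carriers"] == 1 and agg["vus_carriers"] == 1
        assert summaries[0].patient_id == "A"
        assert len(summaries[0].carried_plp) == 1

    def test_no_plp_no_carriers(self):
        u = self.res(VariantClass.VUS, 200)
        _, agg = summarize_patients([u], {u.variant: {"B": "het"}}, cohort_size=5)
        assert agg["plp_carriers"] == 0

    def test_multi_carrier_counted_once(self):
        p1 = self.res(VariantClass.PATHOGENIC, 100)
        p2 = self.res(VariantClass.PATHOGENIC, 300)
        carriers = {p1.variant: {"A": "het"}, p2.variant: {"A": "het", "B": "het"}}
        _, agg = summarize_patients([p1, p2], carriers, cohort_size=10)
        assert agg["plp_carriers"] == 2
        assert agg["multi_plp_carriers"] == 1


class TestCohortSummary:
    def test_percentages_over_custom_denominator(self):
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(6)],
                "status": ["mutant", "mutant", "mutant", "wild_type", "not_tested", None],
            }
        )
        out = summarize_cohort(df, {"status": {"not_tested"}})
        mutant = out[(out.field == "status") & (out.category == "mutant")].iloc[0]
        assert mutant.n == 3 and mutant.denominator == 4
        assert mutant.pct == 75.0
        excluded = out[(out.field == "status") & (out.category == "not_tested")].iloc[0]
        assert np.isnan(excluded.pct)

    def test_empty_metadata(self):
        out = summarize_cohort(pd.DataFrame({"patient_id": []}))
        assert out.empty

    def test_zero_denominator_yields_nan(self):
        df = pd.DataFrame({"patient_id": ["A"], "status": ["not_tested"]})
        out = summarize_cohort(df, {"status": {"not_tested"}})
        assert np.isnan(out.iloc[0].pct)
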