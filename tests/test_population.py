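"""Allele frequencies, interpolation, the Fisher test and BS1/PM2/PS4."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from germclass import (
    CohortSiteTable,
    Direction,
    GenomicVariant,
    Thresholds,
    allele_frequency,
    evaluate_bs1,
    evaluate_pm2,
    evaluate_population,
    evaluate_ps4,
    fisher_two_tailed,
    interpolate_allele_number,
    minor_allele_frequency,
)

T = Thresholds()


def v(pos=1000, ref="G", alt="T", contig="chr1"):
    return GenomicVariant(contig, pos, ref, alt)


def table(name, records, n=None):
    return CohortSiteTable(name, records, default_diploid_n=n)


class TestFrequencies:
    def test_af_and_maf(self):
        assert allele_frequency(500, 10000) == pytest.approx(0.05)
        assert minor_allele_frequency(500, 10000) == pytest.approx(0.05)
        assert minor_allele_frequency(9900, 10000) == pytest.approx(0.01)

    def test_zero_an_is_undefined(self):
        with pytest.raises(ValueError):
            allele_frequency(0, 0)


class TestBS1:
    def test_common_in_one_cohort_suffices(self):
        controls = [
            table("a", [(v(), 1000, 20000)]),  # MAF 5%
            table("b", []),
        ]
        assert evaluate_bs1(v(), controls, T)

    def test_exactly_one_percent_is_not_greater(self):
        controls = [
            table("a", [(v(), 200, 20000)]),
            table("b", [(v(), 100, 10000)]),
        ]
        assert not evaluate_bs1(v(), controls, T)

    def test_unrecorded_everywhere_is_false(self):
        assert not evaluate_bs1(v(), [table("a", []), table("b", [])], T)

    def test_major_allele_folding(self):
        # AF 99.5% folds to MAF 0.5% — below the threshold
        controls = [table("a", [(v(), 19900, 20000)])]
        assert not evaluate_bs1(v(), controls, T)


class TestPM2:
    def test_unrecorded_in_both(self):
        assert evaluate_pm2(v(), [table("a", []), table("b", [])])

    def test_recorded_with_zero_count_still_recorded(self):
        controls = [table("a", [(v(), 0, 20000)]), table("b", [])]
        assert not evaluate_pm2(v(), controls)

    def test_recorded_with_nonzero_count(self):
        controls = [table("a", []), table("b", [(v(), 3, 20000)])]
        assert not evaluate_pm2(v(), controls)


class TestInterpolation:
    def make(self, sites):
        return table("c", [(v(pos=p, ref="A", alt="G"), 1, an) for p, an in sites])

    @pytest.mark.parametrize(
        ("sites", "query", "expected"),
        [
            ([(950, 18000), (1050, 18000)], 1000, 18000),
            ([(100, 10000), (200, 12000)], 150, 11000),
            ([(100, 10000), (200, 12000)], 175, 11500),
            ([(849, 10000), (1050, 12000)], 1000, None),  # upstream 151 bp away
            ([(950, 10000)], 1000, None),  # no downstream flank
            ([(850, 10000), (1150, 12000)], 1000, 11000),  # exactly at window edge
        ],
    )
    def test_examples(self, sites, query, expected):
        got = interpolate_allele_number("chr1", query, self.make(sites), T)
        assert got == expected

    @given(
        u=st.integers(min_value=200, max_value=1000),
        du=st.integers(min_value=1, max_value=150),
        dd=st.integers(min_value=1, max_value=150),
        an_u=st.integers(min_value=100, max_value=30000),
        slope=st.integers(min_value=-50, max_value=50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_collinear_exactness(self, u, du, dd, an_u, slope):
        """With flanking ANs on an integer-slope line, the interpolated AN
        lies exactly on that line."""
        q, d = u + du, u + du + dd
        an_d = an_u + slope * (d - u)
        if an_d < 100:
            an_d, slope = an_u, 0
        got = interpolate_allele_number("chr1", q, self.make([(u, an_u), (d, an_d)]), T)
        assert got == round(an_u + slope * (q - u))


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    support = np.arange(max(0, n - (N - K)), min(n, K) + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    return float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())


class TestFisher:
    def test_identical_tables(self):
        p, direction = fisher_two_tailed(1, 110, 1, 110)
        assert p == pytest.approx(1.0)
        assert direction is Direction.NONE

    def test_direction_control_enriched(self):
        _, direction = fisher_two_tailed(0, 110, 500, 10000)
        assert direction is Direction.CONTROL_ENRICHED

    def test_matches_enumeration_on_singleton_contrast(self):
        p, direction = fisher_two_tailed(2, 110, 0, 19252)
        assert direction is Direction.CASE_ENRICHED
        assert p == pytest.approx(fisher_oracle(2, 108, 0, 19252), abs=1e-9)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(0, 0, 1, 10)

    @given(
        a=st.integers(0, 40), b=st.integers(0, 40),
        c=st.integers(0, 40), d=st.integers(0, 40),
    )
    @settings(max_examples=150, derandomize=True)
    def test_symmetry_under_row_swap(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p1, d1 = fisher_two_tailed(a, a + b, c, c + d)
        p2, d2 = fisher_two_tailed(c, c + d, a, a + b)
        assert p1 == pytest.approx(p2, rel=1e-12)
        flip = {
            Direction.CASE_ENRICHED: Direction.CONTROL_ENRICHED,
            Direction.CONTROL_ENRICHED: Direction.CASE_ENRICHED,
            Direction.NONE: Direction.NONE,
        }
        assert d2 is flip[d1]


class TestPS4:
    def setup_method(self):
        self.case = table("cases", [(v(), 2, 110)], n=55)
        self.extra = table("extra", [], n=290)

    def test_enriched_against_unrecorded_interpolable_control(self):
        control = self.make_control_with_flanks()
        ps4, results = evaluate_ps4(v(), [self.case, self.extra], [control], T)
        assert ps4
        enriched = [r for r in results if r.case_cohort == "cases"]
        assert enriched[0].control_an_interpolated
        assert enriched[0].control_ac == 0
        assert enriched[0].p_value < T.ps4_alpha

    def make_control_with_flanks(self):
        return table(
            "ctrl",
            [
                (v(pos=940, ref="A", alt="G"), 3, 19000),
                (v(pos=1060, ref="A", alt="G"), 3, 19400),
            ],
        )

    def test_control_enrichment_anywhere_excludes(self):
        # enriched in cases vs ctrl1, but significantly enriched in
        # controls vs ctrl2 -> PS4 must be false
        ctrl1 = self.make_control_with_flanks()
        ctrl2 = table("ctrl2", [(v(), 2000, 19000)])  # AF >> case AF
        ps4, results = evaluate_ps4(v(), [self.case], [ctrl1, ctrl2], T)
        assert any(
            r.direction is Direction.CONTROL_ENRICHED and r.p_value < T.ps4_alpha
            for r in results
        )
        assert not ps4

    def test_uninterpolable_pairs_are_skipped(self):
        control = table("ctrl", [(v(pos=400, ref="A", alt="G"), 3, 19000)])
        ps4, results = evaluate_ps4(v(), [self.case, self.extra], [control], T)
        assert not ps4
        assert results == ()

    def test_no_signal_when_frequencies_match(self):
        control = table("ctrl", [(v(), 350, 19250)])  # AF ~ case AF
        ps4, results = evaluate_ps4(v(), [self.case], [control], T)
        assert not ps4
        assert all(r.p_value >= T.ps4_alpha for r in results)

    def test_position_recorded_for_other_allele_uses_site_an(self):
        control = table("ctrl", [(v(alt="C"), 4, 19000)])  # same site, other alt
        ps4, results = evaluate_ps4(v(), [self.case], [control], T)
        assert results[0].control_an == 19000
        assert not results[0].control_an_interpolated
        assert ps4


class TestPopulationAggregate:
    def test_unrecorded_enriched_variant(self):
        case = table("cases", [(v(), 1, 110)], n=55)
        controls = [
            table(
                name,
                [
                    (v(pos=940, ref="A", alt="G"), 3, 19000),
                    (v(pos=1060, ref="A", alt="G"), 3, 19400),
                ],
            )
            for name in ("c1", "c2")
        ]
        ev = evaluate_population(v(), [case], controls, T)
        assert (ev.bs1, ev.pm2, ev.ps4) == (False, True, True)
        assert len(ev.comparisons) == 2

    def test_common_variant_short_circuits(self):
        case = table("cases", [(v(), 1, 110)], n=55)
        controls = [table("c1", [(v(), 1000, 20000)]), table("c2", [])]
        ev = evaluate_population(v(), [case], controls, T)
        assert ev.bs1 and not ev.pm2 and not ev.ps4
        assert ev.comparisons == ()

    def test_recorded_rare_no_enrichment(self):
        case = table("cases", [(v(), 1, 110)], n=55)
        controls = [
            table("c1", [(v(), 40, 19252)]),
            table("c2", [(v(), 40, 19540)]),
        ]
        ev = evaluate_population(v(), [case], controls, T)
        assert not ev.bs1 and not ev.pm2 and not ev.ps4

    def test_bs1_pm2_never_both(self):
        rng = np.random.default_rng(2)
        case = table("cases", [(v(), 1, 110)], n=55)
        for _ in range(100):
            recorded = rng.random() < 0.6
            ac = int(rng.integers(0, 5000)) if recorded else 0
            controls = [
                table("c1", [(v(), ac, 20000)] if recorded else []),
                table("c2", []),
            ]
            ev = evaluate_population(v(), [case], controls, T)
            assert not (ev.bs1 and ev.pm2)

    def test_growing_control_an_never_flips_to_control_enriched(self):
        """With control AC fixed, adding genotyped alleles only lowers the
        control frequency."""
        case = table("cases", [(v(), 2, 110)], n=55)
        previous = None
        for an in (5000, 10000, 20000, 40000):
            controls = [table("c1", [(v(), 3, an)])]
            _, results = evaluate_ps4(v(), [case], controls, T)
            assert results[0].direction is not Direction.CONTROL_ENRICHED
            if previous is not None:
                assert results[0].control_an > previous
            previous = results[0].control_an
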