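"""The five computational/predictive criteria and their vote logic."""

import numpy as np
import pytest

from germclass import (
    Consequence,
    GenomicVariant,
    PredictionScores,
    ProteinChange,
    Thresholds,
    VariantAnnotation,
    Vote,
    evaluate_pm4,
    evaluate_pm5,
    evaluate_pp3,
    evaluate_predictive,
    evaluate_ps1,
    evaluate_pvs1,
    predictor_votes,
)
from germclass.variants import (
    AA_ONE_LETTER,
    MutationTasterCall,
    PolyPhenCall,
    SiftCall,
)

T = Thresholds()


def ann(
    gene="G1",
    consequence=Consequence.STOPGAIN,
    changes=(),
    in_repeat=False,
    scores=PredictionScores(),
    position=1000,
):
    return VariantAnnotation(
        variant=GenomicVariant("chr1", position, "G", "T"),
        gene=gene,
        consequence=consequence,
        protein_changes=tuple(changes),
        in_repeat_region=in_repeat,
        scores=scores,
    )


def missense(gene, residue, ref_aa, alt_aa, transcript="NM_1"):
    return ProteinChange(gene, transcript, residue, ref_aa, alt_aa)


class TestPVS1:
    def test_null_in_null_gene(self, small_knowledge):
        assert evaluate_pvs1(ann("G1", Consequence.STOPGAIN), small_knowledge)
        assert evaluate_pvs1(ann("G1", Consequence.SPLICE_SITE), small_knowledge)

    def test_missense_in_null_gene_fails(self, small_knowledge):
        assert not evaluate_pvs1(
            ann("G1", Consequence.NONSYNONYMOUS_SNV), small_knowledge
        )

    def test_null_in_missense_only_gene_fails(self, small_knowledge):
        # G2 has only a pathogenic missense on record
        assert not evaluate_pvs1(ann("G2", Consequence.SPLICE_SITE), small_knowledge)


class TestPS1PM5:
    def test_same_change_different_nucleotide_is_ps1(self, small_knowledge):
        a = ann(
            "G2",
            Consequence.NONSYNONYMOUS_SNV,
            changes=[missense("G2", 175, "R", "H")],
            position=999,  # different site than the ClinVar record at 600
        )
        assert evaluate_ps1(a, small_knowledge)
        assert not evaluate_pm5(a, small_knowledge)

    def test_same_nucleotide_change_is_not_ps1(self, small_knowledge):
        a = VariantAnnotation(
            variant=GenomicVariant("chr1", 600, "G", "A"),  # the record itself
            gene="G2",
            consequence=Consequence.NONSYNONYMOUS_SNV,
            protein_changes=(missense("G2", 175, "R", "H"),),
        )
        assert not evaluate_ps1(a, small_knowledge)

    def test_different_alt_residue_is_pm5_not_ps1(self, small_knowledge):
        a = ann("G2", Consequence.NONSYNONYMOUS_SNV, changes=[missense("G2", 175, "R", "L")])
        assert evaluate_pm5(a, small_knowledge)
        assert not evaluate_ps1(a, small_knowledge)

    def test_unknown_residue_is_neither(self, small_knowledge):
        a = ann("G2", Consequence.NONSYNONYMOUS_SNV, changes=[missense("G2", 99, "K", "E")])
        assert not evaluate_ps1(a, small_knowledge)
        assert not evaluate_pm5(a, small_knowledge)

    def test_no_protein_changes_is_neither(self, small_knowledge):
        a = ann("G2", Consequence.SPLICE_SITE)
        assert not evaluate_ps1(a, small_knowledge)
        assert not evaluate_pm5(a, small_knowledge)

    def test_single_change_never_both(self, small_knowledge):
        """One protein change cannot justify PS1 and PM5 simultaneously."""
        rng = np.random.default_rng(11)
        aa = sorted(AA_ONE_LETTER)
        for _ in range(300):
            ref_aa, alt_aa = rng.choice(aa, size=2, replace=False)
            a = ann(
                "G2",
                Consequence.NONSYNONYMOUS_SNV,
                changes=[missense("G2", int(rng.integers(170, 180)), str(ref_aa), str(alt_aa))],
            )
            assert not (evaluate_ps1(a, small_knowledge) and evaluate_pm5(a, small_knowledge))


class TestPM4:
    @pytest.mark.parametrize(
        ("gene", "consequence", "in_repeat", "expected"),
        [
            ("G3", Consequence.NONFRAMESHIFT_DELETION, False, True),
            ("G3", Consequence.NONFRAMESHIFT_INSERTION, True, False),
            ("G3", Consequence.STOPLOSS, True, True),  # repeat clause is indel-only
            ("G3", Consequence.STOPLOSS, False, True),
            ("G3", Consequence.FRAMESHIFT_DELETION, False, False),
            ("NOPE", Consequence.NONFRAMESHIFT_DELETION, False, False),
        ],
    )
    def test_rules(self, small_knowledge, gene, consequence, in_repeat, expected):
        a = ann(gene, consequence, in_repeat=in_repeat)
        assert evaluate_pm4(a, small_knowledge, T) is expected

    def test_stoploss_repeat_exemption_is_configurable(self, small_knowledge):
        strict = Thresholds(pm4_stoploss_repeat_exempt=False)
        a = ann("G3", Consequence.STOPLOSS, in_repeat=True)
        assert not evaluate_pm4(a, small_knowledge, strict)


def change(i):
    return ProteinChange("G", f"NM_{i}", 10 + i, "A", "V")


class TestVotes:
    def test_revel_requires_all_changes_pathogenic(self):
        scores = PredictionScores(
            revel_per_change=((change(1), 0.80), (change(2), 0.91))
        )
        assert predictor_votes(scores, T)["REVEL"] is Vote.PATHOGENIC

    def test_revel_any_low_change_is_benign(self):
        scores = PredictionScores(
            revel_per_change=((change(1), 0.80), (change(2), 0.30))
        )
        assert predictor_votes(scores, T)["REVEL"] is Vote.BENIGN

    def test_revel_middle_is_indeterminate(self):
        scores = PredictionScores(revel_per_change=((change(1), 0.5),))
        assert predictor_votes(scores, T)["REVEL"] is Vote.INDETERMINATE

    def test_all_absent_all_indeterminate(self):
        votes = predictor_votes(PredictionScores(), T)
        assert set(votes.values()) == {Vote.INDETERMINATE}

    def test_cadd_low_is_indeterminate_not_benign(self):
        votes = predictor_votes(PredictionScores(cadd_phred=3.0), T)
        assert votes["CADD"] is Vote.INDETERMINATE

    def test_polyphen_either_model_damaging_counts(self):
        votes = predictor_votes(
            PredictionScores(
                polyphen_hdiv_call=PolyPhenCall.BENIGN,
                polyphen_hvar_call=PolyPhenCall.DAMAGING,
            ),
            T,
        )
        assert votes["PolyPhen-2"] is Vote.PATHOGENIC
        votes = predictor_votes(
            PredictionScores(polyphen_hdiv_call=PolyPhenCall.BENIGN), T
        )
        assert votes["PolyPhen-2"] is Vote.BENIGN


class TestPP3:
    def test_two_pathogenic_votes_suffice(self):
        scores = PredictionScores(
            revel_per_change=((change(1), 0.9),), cadd_phred=30.0
        )
        assert evaluate_pp3(scores, T)

    def test_any_benign_vote_blocks(self):
        scores = PredictionScores(
            cadd_phred=30.0,
            sift_call=SiftCall.DELETERIOUS,
            mutationtaster_call=MutationTasterCall.DELETERIOUS,
            polyphen_hdiv_call=PolyPhenCall.BENIGN,
        )
        assert not evaluate_pp3(scores, T)

    def test_one_vote_is_not_enough(self):
        assert not evaluate_pp3(PredictionScores(cadd_phred=30.0), T)

    def test_monotone_in_pathogenic_and_benign_votes(self):
        """Adding a deleterious call never un-fires PP3; adding a benign
        call never fires it."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            base = PredictionScores(
                cadd_phred=float(rng.uniform(0, 40)),
                sift_call=None,
                mutationtaster_call=(
                    MutationTasterCall.DELETERIOUS if rng.random() < 0.5 else None
                ),
                polyphen_hdiv_call=(
                    PolyPhenCall.DAMAGING if rng.random() < 0.5 else None
                ),
            )
            before = evaluate_pp3(base, T)
            more_path = PredictionScores(
                revel_per_change=base.revel_per_change,
                cadd_phred=base.cadd_phred,
                sift_call=SiftCall.DELETERIOUS,
                mutationtaster_call=base.mutationtaster_call,
                polyphen_hdiv_call=base.polyphen_hdiv_call,
            )
            more_benign = PredictionScores(
                revel_per_change=base.revel_per_change,
                cadd_phred=base.cadd_phred,
                sift_call=SiftCall.TOLERATED,
                mutationtaster_call=base.mutationtaster_call,
                polyphen_hdiv_call=base.polyphen_hdiv_call,
            )
            if before:
                assert evaluate_pp3(more_path, T)
            assert not evaluate_pp3(more_benign, T)


def test_aggregate_matches_straight_line_oracle(small_knowledge):
    """evaluate_predictive equals an independently coded conjunction of the
    five criteria over randomized annotations."""
    from germclass.variants import NULL_CONSEQUENCES
    from germclass.predictive import predictor_votes as votes_fn

    rng = np.random.default_rng(23)
    genes = ["G1", "G2", "G3", "XX"]
    consequences = list(Consequence)
    aa = sorted(AA_ONE_LETTER)
    for i in range(1000):
        gene = genes[rng.integers(0, len(genes))]
        cons = consequences[rng.integers(0, len(consequences))]
        changes = []
        if rng.random() < 0.7:
            ref_aa, alt_aa = (str(a) for a in rng.choice(aa, size=2, replace=False))
            changes.append(
                ProteinChange(gene, "NM_1", int(rng.integers(170, 180)), ref_aa, alt_aa)
            )
        scores = PredictionScores(
            revel_per_change=tuple(
                (c, float(rng.uniform(0, 1))) for c in changes if rng.random() < 0.5
            ),
            cadd_phred=float(rng.uniform(0, 40)) if rng.random() < 0.5 else None,
            sift_call=SiftCall.DELETERIOUS if rng.random() < 0.3 else None,
            mutationtaster_call=(
                MutationTasterCall.POLYMORPHISM if rng.random() < 0.3 else None
            ),
        )
        a = VariantAnnotation(
            variant=GenomicVariant("chr1", int(rng.integers(1, 10_000)), "G", "T"),
            gene=gene,
            consequence=cons,
            protein_changes=tuple(changes),
            in_repeat_region=bool(rng.random() < 0.3),
            scores=scores,
        )
        got = evaluate_predictive(a, small_knowledge, T)

        # straight-line re-derivation
        exp_pvs1 = cons in NULL_CONSEQUENCES and gene in small_knowledge.genes_with_pathogenic_null
        exp_ps1 = any(
            c.is_missense
            and any(
                src != a.variant
                for src in small_knowledge.aa_change_sources.get(
                    (c.gene, c.residue_index, c.ref_aa, c.alt_aa), ()
                )
            )
            for c in changes
        )
        exp_pm5 = any(
            c.is_missense
            and (c.gene, c.residue_index, c.ref_aa)
            in small_knowledge.pathogenic_missense_residues
            and (c.gene, c.residue_index, c.ref_aa, c.alt_aa)
            not in small_knowledge.pathogenic_aa_changes
            for c in changes
        )
        exp_pm4 = gene in small_knowledge.genes_with_any_plp and (
            (
                cons
                in (
                    Consequence.NONFRAMESHIFT_INSERTION,
                    Consequence.NONFRAMESHIFT_DELETION,
                )
                and not a.in_repeat_region
            )
            or cons is Consequence.STOPLOSS
        )
        vts = list(votes_fn(scores, T).values())
        exp_pp3 = (
            sum(v is Vote.BENIGN for v in vts) == 0
            and sum(v is Vote.PATHOGENIC for v in vts) >= 2
        )
        assert (got.pvs1, got.ps1, got.pm5, got.pm4, got.pp3) == (
            exp_pvs1, exp_ps1, exp_pm5, exp_pm4, exp_pp3,
        ), f"iteration {i}"
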