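import pytest

from germclass import (
    ClinVarRecord,
    Consequence,
    GenomicVariant,
    ProteinChange,
    ReviewStatus,
    Significance,
    Thresholds,
    build_knowledge,
    paper_fixture,
)


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


def make_record(
    gene="G1",
    position=500,
    significance=Significance.PATHOGENIC,
    review_status=ReviewStatus.MULTIPLE_SUBMITTERS_NO_CONFLICT,
    consequence=Consequence.STOPGAIN,
    protein_changes=(),
    conditions=frozenset({"hereditary cancer-predisposing syndrome"}),
    contig="chr1",
    ref="G",
    alt="A",
):
    return ClinVarRecord(
        variant=GenomicVariant(contig, position, ref, alt),
        gene=gene,
        significance=significance,
        review_status=review_status,
        conditions=conditions,
        consequence=consequence,
        protein_changes=tuple(protein_changes),
    )


@pytest.fixture(scope="session")
def small_knowledge():
    """G1: pathogenic stopgain; G2: pathogenic missense R175H at chr1:600;
    G3: likely-pathogenic missense (counts for PM4 only)."""
    records = [
        make_record(gene="G1", position=500, consequence=Consequence.STOPGAIN),
        make_record(
            gene="G2",
            position=600,
            consequence=Consequence.NONSYNONYMOUS_SNV,
            protein_changes=(ProteinChange("G2", "NM_2", 175, "R", "H"),),
        ),
        make_record(
            gene="G3",
            position=700,
            significance=Significance.LIKELY_PATHOGENIC,
            consequence=Consequence.NONSYNONYMOUS_SNV,
            protein_changes=(ProteinChange("G3", "NM_3", 40, "A", "T"),),
        ),
    ]
    return build_knowledge(frozenset(records))


@pytest.fixture(scope="session")
def paper():
    return paper_fixture(seed=1)


@pytest.fixture(scope="session")
def paper_run(paper):
    return paper.run()
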