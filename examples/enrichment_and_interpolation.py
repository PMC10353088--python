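"""Case-control enrichment on a singleton carrier, with allele-number
interpolation at an unrecorded control site.

A variant seen once among 55 diploid patients (1 of 110 alleles) but
absent from a ~9,600-subject control cohort is already significantly
enriched by a two-tailed Fisher exact test — this is the contrast that
powers the PS4 criterion for rare variants.  When the control site was
never recorded, its allele number is linearly interpolated from the
nearest recorded sites within 150 bp.
"""

from germclass import (
    CohortSiteTable,
    GenomicVariant,
    Thresholds,
    fisher_two_tailed,
    interpolate_allele_number,
)

t = Thresholds()

# flanking recorded sites 60 bp either side of the unrecorded position
control = CohortSiteTable(
    "gnomad_eas",
    [
        (GenomicVariant("chr1", 940, "A", "G"), 3, 19000),
        (GenomicVariant("chr1", 1060, "A", "G"), 3, 19400),
    ],
)
an = interpolate_allele_number("chr1", 1000, control, t)
print(f"interpolated control AN at chr1:1000 = {an}")

p, direction = fisher_two_tailed(1, 110, 0, an)
print(f"1/110 case alleles vs 0/{an} control alleles: p = {p:.4f} ({direction.value})")
print(f"significant at alpha {t.ps4_alpha}: {p < t.ps4_alpha}")

# out of the 150 bp window, no interpolation is possible
sparse = CohortSiteTable("sparse", [(GenomicVariant("chr1", 700, "A", "G"), 3, 19000)])
print("AN with no flank within 150 bp:", interpolate_allele_number("chr1", 1000, sparse, t))
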