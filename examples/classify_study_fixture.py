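"""Classify the packaged desk-scale study fixture and summarize carriers.

The fixture encodes a 55-patient dual breast-and-lung-cancer cohort:
6 variants already recorded pathogenic/likely pathogenic at accepted
ClinVar review tiers, 13 variants with planted criterion profiles that
the combining rules must call pathogenic or likely pathogenic, and a few
variants of uncertain significance / excluded / evidence-free fillers.
"""

from collections import Counter

from germclass import paper_fixture, summarize_patients

fixture = paper_fixture(seed=1)
pipeline = fixture.run()

counts = Counter(r.klass.value for r in pipeline.results)
plp = [r for r in pipeline.results if r.is_plp]
print("classes:", dict(sorted(counts.items())))
print(f"P/LP variants: {len(plp)} across {len({r.gene for r in plp})} genes")

summaries, agg = summarize_patients(pipeline.results, fixture.carriers, 55)
print(
    f"carriers: {agg['plp_carriers']}/55 patients ({agg['plp_carriers_pct']}%), "
    f"{agg['multi_plp_carriers']} carrying two variants, "
    f"{agg['new_plp_carriers']} with newly classified variants"
)
# Per-variant provenance: which rule combination fired for each new call.
for r in sorted(plp, key=lambda r: (r.klass.value, r.gene)):
    if r.newly_classified:
        print(f"  {r.gene:12s} {r.klass.value:18s} via {','.join(r.fired_rules)}")
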