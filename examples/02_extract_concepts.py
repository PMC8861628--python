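"""Extract knowledge-graph concepts from a patient record.

Shows the three extraction routes on hand-written content: the ATC
hierarchy ancestors of a drug code, the contraindication relation reached
through a drug's UMLS CUI, and the medical-domain DBpedia subjects of
entities annotated in French free text (including an abbreviated surface
form).
"""

from kgemr import (annotate_text, atc_ancestors, dbpedia_candidate_subjects,
                   generate_kg_fixture, ndfrt_pairs)

fixture = generate_kg_fixture()

print("ATC ancestors of C01DA38 (tenitramine), levels 1-3:")
for atom in atc_ancestors("C01DA38", fixture.graphs["ATC"], levels={1, 2, 3}):
    print(f"  level {atom.depth}: {atom.label}")

print("\nNDF-RT contraindications of C10AA05 (atorvastatin):")
for atom in ndfrt_pairs("C10AA05", fixture.graphs["ATC"],
                        fixture.graphs["NDFRT"], properties=["CI_with"]):
    print(f"  {atom.property} -> {atom.label}")

text = "insuf cardiaque décompensée - rupture de kyste"
print(f"\nfree text: {text!r}")
mentions = annotate_text(text, fixture)
for m in mentions:
    print(f"  mention {m.surface!r} -> {m.entity}")
print("medical-domain subjects (both constraints):")
for atom in dbpedia_candidate_subjects(mentions, fixture):
    print(f"  {atom.feature_name}")

# 'insuf' expands to 'insuffisance' through the abbreviation dictionary
# before matching; each subject passed both the seed-category constraint
# (skos:broader chain) and the typed-equivalent constraint (owl:sameAs).
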