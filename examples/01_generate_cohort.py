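"""Generate a small synthetic EMR cohort with planted concept effects.

Builds a miniature knowledge fixture (drug/diagnosis hierarchies plus a
DBpedia-like category graph), then draws a balanced cohort whose
hospitalization labels depend on five planted "signal" concepts injected
into the free text through synonym surface forms.
"""

from kgemr import CohortConfig, FixtureSpec, generate_cohort, \
    generate_kg_fixture

fixture = generate_kg_fixture(FixtureSpec(seed=0))
config = CohortConfig(n_hospitalized=60, n_not_hospitalized=60, seed=0)
cohort, truth = generate_cohort(config, fixture)

n_hosp = sum(r.hospitalized for r in cohort)
print(f"patients: {len(cohort)} ({n_hosp} hospitalized)")
print(f"planted signal concepts (log-odds weights): ")
for iri, w in truth.signal_concepts.items():
    print(f"  {iri}  weight={w}")
first = cohort[0]
print(f"\nexample patient {first.patient_id} "
      f"(hospitalized={first.hospitalized}, "
      f"index={first.hospitalization_index}):")
print("  observations of visit 0:",
      first.consultations[0].field_texts["observations"][:70], "...")
print("  ATC codes of visit 0:", first.consultations[0].atc_codes)

# Each weight is the planted log-odds contribution of that concept to the
# hospitalization label; downstream stages must rediscover these concepts
# from text alone.
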