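"""Cohort-level summaries on the bundled example cohort.

Recomputes the descriptive numbers for a 10-patient meningioma
grade-progression cohort from its baseline and variant tables, then shows a
feature-recurrence table and landscape matrix on a synthetic cohort.
"""

from mencna import (SimulationConfig, count_mutation_recurrence,
                    landscape_matrix, load_example_cohort,
                    recurrence_by_feature, simulate_cohort,
                    summarize_demographics)
from mencna.pipeline import process_cohort

patients, variants = load_example_cohort()
demo = summarize_demographics(patients)
print(f"{demo['n_patients']} patients; mean age {demo['mean_age']:.1f} "
      f"(range {demo['min_age']}-{demo['max_age']}); "
      f"{100 * demo['radiation_fraction']:.0f}% irradiated")
print(f"initial WHO grade counts: {demo['initial_grade_counts']}; "
      f"{demo['progressed_to_grade3']} progressed to Grade 3")

rec = count_mutation_recurrence(variants, n_patients=10)
print("\nmost recurrently mutated genes:")
print(rec.head(5).to_string(index=False))

# CNA recurrence stratified by NF2 status, on a synthetic cohort
bundle = simulate_cohort(SimulationConfig(
    n_patients=6, tumours_per_patient=2, n_genes=120, n_snp_loci=3000,
    baseline_depth=500.0, seed=19, high_cna_fraction=0.5))
results = process_cohort(bundle)
calls = {sid: r.segments for sid, r in results.segmentation.items()}
nf2 = dict(zip(bundle.patients["patient_id"], bundle.patients["nf2_mutant"]))
table = recurrence_by_feature(calls, bundle.sample_map(), nf2)
print("\nCNA feature recurrence (percentages over patients per stratum):")
print(table.head(8).to_string(index=False))

mat = landscape_matrix(results.kept_variants, calls, bundle.sample_map())
print(f"\nlandscape matrix: {mat.shape[0]} samples x {mat.shape[1]} features "
      f"({(mat != '').to_numpy().sum()} non-empty cells)")
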