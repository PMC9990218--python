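"""Generate a synthetic multi-tumour meningioma-like cohort with known truth.

Builds a 523-gene autosomal panel with 13,294 SNP loci, then simulates 10
patients (4 high-CNA "NF2-like", 6 quiet), 3 tumours each, at purity 0.8.
Prints the patient classes and the injected truth events for one patient.
"""

from mencna import SimulationConfig, simulate_cohort

config = SimulationConfig(n_patients=10, tumours_per_patient=3, seed=1)
bundle = simulate_cohort(config)

print(bundle.patients.to_string(index=False))
print(f"\n{len(bundle.samples)} tumour samples; panel: "
      f"{bundle.panel.n_genes} genes, {bundle.panel.n_snp_loci} SNP loci")

first_high = bundle.patients.loc[bundle.patients["cna_class"] == "high",
                                 "patient_id"].iloc[0]
sample = next(s for s in bundle.samples if s.patient_id == first_high)
print(f"\ninjected events for {first_high} (shared by all their tumours):")
for ev in sample.truth_events:
    print(f"  {ev.event_type:<11} {ev.chrom}{ev.arm}  allele state "
          f"({ev.n_a},{ev.n_b})")
# Each event names the copy state the simulator applied; e.g. LOSS 22q with
# state (1,0) is a one-copy deletion of the arm carrying NF2.
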