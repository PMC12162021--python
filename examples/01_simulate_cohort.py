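"""Generate a synthetic primary-care cohort and inspect its latent truth.

The generator emulates the record structure the switching analysis needs:
prescription streams, diagnosis codes, baseline covariates with polygenic
scores, and kinship pairs, plus a truth table of every latent draw.
"""

from rxswitch import SimulationConfig, generate_cohort

cohort = generate_cohort(SimulationConfig(n_participants=2000), seed=42)

print(cohort.prescriptions.head(8).to_string(index=False))
print(f"\nprescription rows: {len(cohort.prescriptions)}")
print(f"diagnosis rows:    {len(cohort.diagnoses)}")
print(f"latent switchers:  {(cohort.truth['latent_status'] == 'SWITCHER').sum()} "
      f"of {len(cohort.truth)} (target prevalence 0.13)")

# The truth table records what each participant *is*; the phenotyper must
# recover it from the prescription stream alone.
print("\ntruth columns:", ", ".join(cohort.truth.columns))
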