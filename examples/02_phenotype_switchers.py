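"""Classify a cohort into SSRI switchers / nonswitchers / unclassified.

A switcher has a prescription of a different antidepressant 5-95 days after
the first issue of an index SSRI, with that SSRI issued at most 3 times in
total, at most twice before and at most twice after the switch. A
nonswitcher has at least 3 issues of some SSRI and no valid switch event.
"""

from rxswitch import SimulationConfig, audit_synthetic, build_cohort, generate_cohort, phenotype_cohort

cohort = generate_cohort(SimulationConfig(n_participants=5000), seed=11)
memberships = build_cohort(cohort.diagnoses, set(cohort.prescriptions["participant_id"]))
pheno, counts = phenotype_cohort(cohort.prescriptions, memberships)

print(counts.pivot(index="stratum", columns="status", values="n"))

classified = pheno[pheno["status"] != "UNCLASSIFIED"]
prev = (classified["status"] == "SWITCHER").mean()
print(f"\nrecovered switch prevalence: {100 * prev:.1f}%  (generator target 13%)")

audit = audit_synthetic(cohort.truth, pheno)
print(f"agreement with latent truth: {100 * audit.accuracy:.1f}%")
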