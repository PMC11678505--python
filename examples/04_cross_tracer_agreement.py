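"""Cross-tracer agreement: does resolution recovery increase correlation with
a reference tracer?

Uses the synthetic two-tracer cohort harness: a shared latent amyloid burden
is observed cleanly by a reference tracer, while the test tracer suffers a
subject-varying partial volume effect (thin cortex -> stronger attenuation)
plus noise.  Anatomy-informed recovery divides out the per-subject
attenuation.  Pearson correlations with the reference and Steiger's test for
the two dependent correlations quantify the improvement.
"""

from petrr.stats import (
    DependentCorr,
    pearson_r,
    steiger_test,
    synthetic_crosstracer_cohort,
)

cohort = synthetic_crosstracer_cohort(n=150, seed=42)
ref = cohort["reference"]

r_deg = pearson_r(cohort["degraded"], ref)
r_rec = pearson_r(cohort["recovered"], ref)
r_pair = pearson_r(cohort["degraded"], cohort["recovered"])
z, p = steiger_test(DependentCorr(r13=r_rec, r23=r_deg, r12=r_pair, n=len(ref)))

print(f"r(degraded,  reference) = {r_deg:.4f}")
print(f"r(recovered, reference) = {r_rec:.4f}")
print(f"Steiger z = {z:.2f}, two-tailed p = {p:.2e}")
print("-> removing the subject-specific partial-volume attenuation raises\n"
      "   agreement with the reference tracer; Steiger's test judges whether\n"
      "   the two dependent correlations differ significantly")
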