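"""Longitudinal power and trial sample size from summary statistics.

Takes published summary rows (mean and SD of the annualized amyloid
accumulation rate in SUVR/year for n = 167 participants, quantified with
three analysis pipelines) and computes the one-tailed t-test of accumulation
and the per-arm sample size of a hypothetical anti-amyloid trial (25% rate
reduction, 80% power, two-tailed alpha 0.05).
"""

from petrr.stats import RateSummary, one_sample_t, sample_size_per_arm

rows = [
    ("uncorrected", 0.0278, 0.0664),
    ("RL-recovered", 0.0377, 0.0807),
    ("LDM-recovered", 0.0459, 0.0881),
]

print(f"{'pipeline':14s} {'t':>6s} {'p (one-tailed)':>15s} {'n per arm':>10s}")
for name, mean, sd in rows:
    summary = RateSummary(mean, sd, n=167, interval_years=2.0)
    t, df, p = one_sample_t(summary=summary)
    n_arm = sample_size_per_arm(summary)
    print(f"{name:14s} {t:6.2f} {p:15.2e} {n_arm:10d}")
print(
    "-> a smaller p and a smaller per-arm n mean more power to detect\n"
    "   amyloid accumulation; resolution recovery increases both"
)
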