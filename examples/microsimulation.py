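"""Microsimulation check: patient-level simulation versus rollback.

Simulates 200,000 individual patients per arm through the same event
logic as the cohort tree and compares the cohort means with the analytic
expectation — a brute-force validation of the tree structure and its
probability wiring.
"""
from nsclc_cea import build_arm, default_parameters, rollback, simulate_cohort

p = default_parameters()

for strategy, seed in (("NAC", 1), ("AC", 2)):
    expected_cost, expected_qaly = rollback(build_arm(strategy, p))
    cohort = simulate_cohort(strategy, p, n=200_000, seed=seed, return_records=False)
    z_cost = (cohort.mean_cost - expected_cost) / cohort.se_cost
    z_qaly = (cohort.mean_qaly - expected_qaly) / cohort.se_qaly
    print(f"{strategy}:")
    print(f"  rollback:  cost {expected_cost:,.2f} RMB, {expected_qaly:.4f} QALYs")
    print(
        f"  microsim:  cost {cohort.mean_cost:,.2f} (SE {cohort.se_cost:.2f}, z={z_cost:+.2f}), "
        f"{cohort.mean_qaly:.4f} QALYs (SE {cohort.se_qaly:.5f}, z={z_qaly:+.2f})"
    )

print()
print(
    "Both z-scores sitting within a few units of zero means the simulated\n"
    "patient flow reproduces the analytic tree: the probabilities, path\n"
    "payoffs and event wiring agree."
)
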