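"""Base case: roll back both treatment arms and compare them.

Builds the NAC and AC decision trees at the published base-case inputs
(post-treatment utility at its calibrated value 0.98), prints each
arm's expected cost and QALYs, the per-path audit table, and the
incremental comparison.
"""
from nsclc_cea import (
    CALIBRATED_U_POST,
    compare,
    cost_effective_at,
    default_parameters,
    evaluate_base_case,
    set_value,
)

p = set_value(default_parameters(), "utilities.u_post_treatment", CALIBRATED_U_POST)
nac, ac = evaluate_base_case(p)

print("Per-path audit (NAC arm):")
print(nac.to_frame().to_string(index=False, float_format=lambda x: f"{x:,.4f}"))
print()
print(f"AC : expected cost {ac.expected_cost:,.2f} RMB, {ac.expected_qaly:.4f} QALYs")
print(f"NAC: expected cost {nac.expected_cost:,.2f} RMB, {nac.expected_qaly:.4f} QALYs")

cea = compare(nac, ac, p.wtp_threshold)
print()
print(f"Increment (NAC - AC): {cea.delta_cost:,.2f} RMB, {cea.delta_qaly:.4f} QALYs")
print(f"ICER: {cea.icer:,.1f} RMB/QALY ({cea.dominance})")
print(f"Cost-effective strategy at WTP {p.wtp_threshold:,.0f} RMB/QALY: {cost_effective_at(cea)}")
print()
print(
    "A positive cost increment and a negative QALY increment mean adjuvant\n"
    "chemotherapy is cheaper AND more effective here: it dominates, and the\n"
    "negative ICER is only meaningful together with that dominance label."
)
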