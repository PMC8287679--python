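# Methods

## Model structure and assumptions

The model is a one-shot decision tree (no Markov cycles, no half-cycle
correction) comparing two strategies for resectable cT2-4N0-1 NSCLC
over the initial treatment phase plus a single overall-survival (OS)
horizon:

* **AC** — surgery, then four chemotherapy cycles;
* **NAC** — two chemotherapy cycles, surgery, two more cycles.

Each arm resolves a three-way postoperative outcome (no grade ≥3
complication / grade ≥3 complication with recovery / postoperative
death) and, for survivors, a whole-course grade ≥3 chemotherapy adverse
event (AE) drawn once per patient. That gives five leaves per arm. The
decision node is compared, never optimized over: both arms are rolled
back and the choice is made by the incremental layer (ICER, dominance,
net monetary benefit), mirroring how such analyses are reported.

Assumptions inherited from the source data: both arms share the same OS
(9.1 years) and utility schedule; every patient initiates surgery and
chemotherapy; chemotherapy itself is never fatal; progression/recurrence
costs and outcomes are outside the horizon; 30- and 90-day mortality are
folded into the postoperative-death branch.

## Parameters

All inputs live in one `ParameterSet` (flat-key YAML serializable,
shipped in `data/base_case.yaml`):

| group | parameters (defaults) | units |
|---|---|---|
| probabilities, per arm | no-complication / complication / death: 0.82/0.14/0.04 (NAC), 0.91/0.07/0.02 (AC); AE: 0.15 (NAC), 0.38 (AC) | — |
| costs, per arm | surgery base 2,351.96 / 2,367.82; additional procedures 1,854.46 / 2,513.65; imaging 6,036 / 3,568; shared: hospitalization 96,462 (with ≥3 complication) / 66,800 (without), chemotherapy course 30,946.5, AE treatment 3,679.8 | 2020 RMB |
| utilities × time frames | surgery+chemo 0.81 × 4.87 mo; AE 0.45 × 0.73 mo (additional); complication 0.63 × 0.50 mo (additional); surgery alone 0.77 × 0.53 mo; chemo alone 1.00 × 0.21 mo; death 0 | — × months |
| horizon / decision | OS 9.1 y per arm; WTP ¥35,446/QALY; source cohort n = 92; discount rate 0 | |

`discount_rate` (annual, applied to the post-treatment QALY stream;
costs are upfront) defaults to 0 because the analysis has a single
survival figure as horizon and the source analysis does not discount;
it is exposed for completeness.

Two published statements conflict and are resolved as follows: the
tabulated complication utility (0.63) is used even though the prose
also says 0.45 for both AEs and complications (the table is the more
specific source), and the anomalous "chemotherapy alone" utility of
1.00 is retained as printed.

## Cost and QALY accrual

Survivor path cost = surgery base + additional procedures + arm-specific
imaging + hospitalization (with/without-complication rate) + full
chemotherapy course + AE treatment if an AE occurred. Survivor path
QALY = [4.87 mo × 0.81 + (0.73 mo × 0.45 if AE) + (0.50 mo × 0.63 if
complication) + (OS − treatment months) × u_post] / 12.

**Death-path conventions** (the tables do not specify them; all are
explicit `StructuralConventions` toggles logged in every run manifest):

* hospitalization billed at the **without-complication** rate. Rationale:
  postoperative deaths are rapid and accrue short stays; decisively, this
  convention reproduces the published arm totals (see below) while the
  with-complication alternative overshoots the NAC arm by ~1%;
* chemotherapy: NAC deaths accrue **half** the course (the two
  pre-operative cycles were delivered), AC deaths **none** (death
  precedes all chemotherapy);
* no AE cost or disutility on death paths;
* QALY before death: NAC deaths accrue two chemo-alone segments
  (2 × 0.21 mo at 1.00) plus a surgery-alone segment (0.53 mo at 0.77);
  AC deaths the surgery-alone segment only. This is < 0.07 QALY.

With these conventions the rollback gives AC ¥109,023.74 and NAC
¥112,052.56 — within ¥25 and ¥13 of the published ¥108,999.73 and
¥112,064.63 — and an incremental cost of ¥3,028.82 vs the published
¥3,064.90.

## The post-treatment utility and a known inconsistency

The utility applying from the end of treatment to the OS horizon,
`u_post_treatment`, is not tabulated in the source (its prose says only
that the utility six months after initial treatment "remained
unchanged"). It ships as an explicit parameter, default 1.0. The
published arm QALYs (AC 8.66, NAC 8.56) are reproduced at the
**calibrated value 0.98** (`CALIBRATED_U_POST`), which the reporting
layer uses and states; at the calibrated value the model gives AC 8.6597
and NAC 8.4911.

Those published *levels* are, however, arithmetically inconsistent with
the published *increment* of −0.10 QALYs (ICER −31,615/QALY implies
−0.097): with death paths truncating the 9.1-year OS, the 2-point
difference in death probability alone costs NAC ≈ 0.17 QALYs, and no
value of a shared u_post can yield −0.10 while keeping the levels near
8.6 (matching −0.10 alone would need u_post ≈ 0.56, i.e. arm QALYs
near 5). Conversely, letting death paths keep accruing survival time
flips the increment positive. This package sides with the levels and
the stated accrual rules; consequently its QALY increment is −0.169,
and the two downstream quantities that the published analysis derived
from its −0.10 increment land elsewhere:

* the OS threshold at which NAC becomes cost-effective at ¥35,446/QALY
  is **0.270 years** here vs 0.19 years published (0.19 is recovered
  exactly if one inserts ΔQ = −0.10 into the same NMB algebra);
* the survival scenario OS 9.22 vs 8.98 years yields an ICER of
  ¥50,830/QALY here — still above the threshold — vs ¥22,560 published.

The acceptance suite asserts the published values for these two
quantities and therefore documents the discrepancy as failing checks
rather than adjusting the model to hit them.

## One-way sensitivity and threshold analysis

Parameters are varied to 0.8× and 1.2× base (probabilities and
utilities clipped to [0, 1]); varying a complication-outcome probability
renormalizes the no-complication branch so the chance node stays a
distribution. The tornado metric is the swing in the NMB difference at
the WTP threshold — the ICER is reported alongside but not used for
ordering because its sign flips when ΔQ crosses zero. Parameter
identity matches the PSA: cost rows published as a single figure for
both arms (hospitalization, chemotherapy course, AE treatment) vary
jointly; arm-specific rows (surgery, additional procedures, imaging),
event probabilities and OS vary per arm. OS of either arm dominates the
tornado by ~25× over the largest non-OS parameter.

The threshold analysis holds AC's OS at base, sets
`os_nac = os_ac + δ`, verifies the NMB difference is monotone in δ on a
coarse grid (guaranteed for u_post > 0), and finds the crossing by
Brent's method on [0, 2] years to 1e-6; a 10,000-point grid scan serves
as the test oracle.

## Probabilistic sensitivity analysis

Distribution assignment per parameter kind: gamma for costs, time
frames and OS (mean = base, SD = 10% of base, i.e. shape 100, scale
base/100); triangular for utilities (mode = base, support ±0.05 clipped
to [0, 1] — including u_post_treatment); per-arm Dirichlet over the
three postoperative outcomes with concentrations 92 × base; per-arm
Beta(92p, 92(1−p)) for AE probabilities (e.g. AC: Beta(34.96, 57.04)).
Draws are batched per distribution in a fixed order from one seeded
`numpy` PCG64 generator, so (seed, n, specs) fully determine the
result. Sampled hospitalization rates are not constrained to preserve
the with ≥ without ordering (violated in ~0.6% of draws; immaterial to
the summaries).

OS is sampled **independently per arm by default**; the
`os_correlated` switch instead draws one mean-1 gamma multiplier
applied to both arms. The switch is decisive and both settings are
reported: with 10,000 draws at the calibrated u_post,

* independent OS: P(AC cost-effective at ¥35,446) ≈ 58%, AC strictly
  dominant in ≈ 53% of draws — the ΔOS noise (SD ≈ 1.3 y) swamps the
  −0.17 QALY increment;
* correlated OS: AC dominant in ≈ 76%, cost-effective in ≈ 90%.

The published figures (AC "dominant in 68.9%" but "cost-effective" in
54.4%) are mutually inconsistent under any single sampling scheme —
strict dominance implies cost-effectiveness at every threshold, so the
dominant share can never exceed the cost-effective share. They are
consistent with this model's two *different* settings: the
cost-effective probability matches under independent OS, the dominance
share under correlated OS; the package reports each under that setting
and makes no attempt to force both from one run.

The CEAC tabulates P(AC has the weakly higher NMB) on a WTP grid of 0
to 150,000 in steps of 1,000, always including ¥35,446 exactly. Ties go
to AC as the reference comparator (relevant only for degenerate
point-mass draws).

## Microsimulation oracle

`simulate_cohort` pushes individual patients through the same event
logic (categorical postoperative outcome, Bernoulli AE for survivors)
and prices them with the same path payoff functions — by construction it
tests the tree *structure and probability wiring*, not an independent
payoff derivation; an independent hand-computed payoff table for all
ten paths lives in the test suite as the second check. At n = 200,000
per arm the cohort means agree with the rollback within 3 standard
errors (SE ≈ ¥25 for cost, ≈ 0.004 QALY). The generator emulates only
what the cohort model contains: no per-patient survival heterogeneity,
no correlation between complication and AE risk, no partial
chemotherapy courses — so agreement validates the implementation, not
the model's fidelity to real patients.

## Numerical choices and problem sizes

Chance-node probability sums are enforced to 1e-9; rollback and path
enumeration agree to 1e-9 by test; currency is carried at full printed
precision with no intermediate rounding. Default problem sizes — 10,000
PSA draws, 200,000 microsimulation patients per arm, a 10,000-point
grid for the threshold oracle — were chosen so Monte Carlo error is
negligible relative to every tolerance used (binomial SE ≤ 0.5
percentage points on PSA shares) while the full pipeline completes in
well under a minute; the reduced sizes used in a few smoke tests are
flagged `reduced_run` in their output.

## Known limitations

* The published QALY increment (and the two results derived from it)
  cannot be reproduced jointly with the published QALY levels; see
  above.
* Death-path cost accrual is a calibrated structural convention, not a
  documented fact; alternatives are one toggle away and logged.
* Single-course AE resolution (no per-cycle granularity), no
  progression phase, no discounted costs, two-strategy frontier only.
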