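"""The NAC/AC tree: per-path payoffs, structure, and rollback behaviour.

The expected payoffs below are written as literal arithmetic over the
published inputs (an independent hand derivation), so they cross-check
the accrual rules rather than re-running them.
"""
import pytest

from nsclc_cea.metrics import compare
from nsclc_cea.model import (
    PathDescriptor,
    StructuralConventions,
    all_paths,
    build_arm,
    evaluate_arm,
    evaluate_base_case,
    path_cost,
    path_qaly,
)
from nsclc_cea.params import set_value
from nsclc_cea.tree import chance, enumerate_paths, rollback

# hand-summed path costs (2020 RMB); death paths billed the
# without-complication hospitalization rate, NAC deaths half the chemo
# course, AC deaths none
HAND_COSTS = {
    ("NAC", "none", "none"): 2351.96 + 1854.46 + 66800 + 30946.5 + 6036,
    ("NAC", "none", "ge3"): 2351.96 + 1854.46 + 66800 + 30946.5 + 6036 + 3679.8,
    ("NAC", "ge3_recovered", "none"): 2351.96 + 1854.46 + 96462 + 30946.5 + 6036,
    ("NAC", "ge3_recovered", "ge3"): 2351.96 + 1854.46 + 96462 + 30946.5 + 6036 + 3679.8,
    ("NAC", "death", "none"): 2351.96 + 1854.46 + 66800 + 0.5 * 30946.5 + 6036,
    ("AC", "none", "none"): 2367.82 + 2513.65 + 66800 + 30946.5 + 3568,
    ("AC", "none", "ge3"): 2367.82 + 2513.65 + 66800 + 30946.5 + 3568 + 3679.8,
    ("AC", "ge3_recovered", "none"): 2367.82 + 2513.65 + 96462 + 30946.5 + 3568,
    ("AC", "ge3_recovered", "ge3"): 2367.82 + 2513.65 + 96462 + 30946.5 + 3568 + 3679.8,
    ("AC", "death", "none"): 2367.82 + 2513.65 + 66800 + 3568,
}

# hand-accrued QALYs at u_post_treatment = 1.0 and OS 9.1 years
# (= 109.2 months); survivors spend 4.87 mo at 0.81 plus any event
# extensions, then the OS remainder at 1.0; deaths accrue only the
# pre-death treatment segments
_OS = 9.1 * 12
HAND_QALYS = {
    ("NAC", "none", "none"): (4.87 * 0.81 + (_OS - 4.87)) / 12,
    ("NAC", "none", "ge3"): (4.87 * 0.81 + 0.73 * 0.45 + (_OS - 4.87 - 0.73)) / 12,
    ("NAC", "ge3_recovered", "none"): (4.87 * 0.81 + 0.5 * 0.63 + (_OS - 4.87 - 0.5)) / 12,
    ("NAC", "ge3_recovered", "ge3"): (
        4.87 * 0.81 + 0.73 * 0.45 + 0.5 * 0.63 + (_OS - 4.87 - 0.73 - 0.5)
    ) / 12,
    ("NAC", "death", "none"): (2 * 0.21 * 1.0 + 0.53 * 0.77) / 12,
    ("AC", "death", "none"): (0.53 * 0.77) / 12,
}
# survivor QALYs are arm-independent when both arms share OS
for _comp in ("none", "ge3_recovered"):
    for _ae in ("none", "ge3"):
        HAND_QALYS[("AC", _comp, _ae)] = HAND_QALYS[("NAC", _comp, _ae)]


@pytest.mark.parametrize("key", sorted(HAND_COSTS))
def test_path_cost_matches_hand_sum(base, key):
    strategy, comp, ae = key
    d = PathDescriptor(strategy, comp, ae)
    assert path_cost(d, base) == pytest.approx(HAND_COSTS[key], abs=1e-9)


@pytest.mark.parametrize("key", sorted(HAND_QALYS))
def test_path_qaly_matches_hand_accrual(base, key):
    strategy, comp, ae = key
    d = PathDescriptor(strategy, comp, ae)
    assert path_qaly(d, base) == pytest.approx(HAND_QALYS[key], abs=1e-12)


def test_uncomplicated_ac_survivor_qaly_value(base):
    d = PathDescriptor("AC", "none", "none")
    assert path_qaly(d, base) == pytest.approx((4.87 * 0.81 + (109.2 - 4.87) * 1.0) / 12, abs=1e-9)
    assert path_qaly(d, base) == pytest.approx(9.0229, abs=1e-4)


def test_zeroed_costs_give_zero_path_cost(base):
    p = base
    for key in (
        "surgery_base",
        "surgery_additional",
        "hosp_with_complication",
        "hosp_without_complication",
        "chemo_full_course",
        "imaging",
        "ae_treatment",
    ):
        p = set_value(p, f"nac.{key}", 0.0)
    for d in all_paths("NAC"):
        assert path_cost(d, p) == 0.0


def test_zeroed_time_frames_give_zero_death_qaly(base):
    p = base
    for key in ("t_surgery_alone", "t_chemo_alone"):
        p = set_value(p, f"utilities.{key}", 0.0)
    for strategy in ("NAC", "AC"):
        assert path_qaly(PathDescriptor(strategy, "death", "none"), p) == 0.0


def test_ae_lowers_qaly_by_the_utility_gap(base):
    # AE adds 0.73 months at utility 0.45 and displaces post-treatment
    # time, so the QALY penalty is 0.73 * (u_post - 0.45) / 12
    for u_post in (0.6, 0.98, 1.0):
        p = set_value(base, "utilities.u_post_treatment", u_post)
        with_ae = path_qaly(PathDescriptor("AC", "none", "ge3"), p)
        without = path_qaly(PathDescriptor("AC", "none", "none"), p)
        assert without - with_ae == pytest.approx(0.73 * (u_post - 0.45) / 12, abs=1e-12)
        assert with_ae < without


def test_os_shorter_than_treatment_raises(base):
    p = set_value(base, "os_nac_years", 0.3)  # 3.6 months < 4.87-month treatment
    with pytest.raises(ValueError, match="survival"):
        path_qaly(PathDescriptor("NAC", "none", "none"), p)


def test_death_path_rejects_ae_flag():
    with pytest.raises(ValueError, match="death"):
        PathDescriptor("NAC", "death", "ge3")


def test_arm_has_five_paths_with_table_probabilities(base):
    paths = enumerate_paths(build_arm("AC", base))
    assert len(paths) == 5
    by_label = {p.leaf_label: p.probability for p in paths}
    assert by_label["AC:no_complication/no_ae"] == pytest.approx(0.91 * 0.62)
    assert by_label["AC:no_complication/ae"] == pytest.approx(0.91 * 0.38)
    assert by_label["AC:complication/no_ae"] == pytest.approx(0.07 * 0.62)
    assert by_label["AC:complication/ae"] == pytest.approx(0.07 * 0.38)
    assert by_label["AC:death"] == pytest.approx(0.02)
    assert sum(by_label.values()) == pytest.approx(1.0, abs=1e-12)

    nac_paths = enumerate_paths(build_arm("NAC", base))
    assert len(nac_paths) == 5
    assert sum(p.probability for p in nac_paths) == pytest.approx(1.0, abs=1e-12)


def test_event_flags_identify_paths(base):
    flags = {p.leaf_label: p.event_flags for p in enumerate_paths(build_arm("NAC", base))}
    assert flags["NAC:death"] == frozenset({"death"})
    assert flags["NAC:complication/ae"] == frozenset({"complication", "ae"})
    assert flags["NAC:no_complication/no_ae"] == frozenset()


def test_degenerate_probabilities_leave_single_effective_path(base):
    p = base
    p = set_value(p, "nac.p_no_complication", 1.0)
    p = set_value(p, "nac.p_complication_ge3", 0.0)
    p = set_value(p, "nac.p_postop_death", 0.0)
    p = set_value(p, "nac.p_ae_ge3", 0.0)
    paths = [q for q in enumerate_paths(build_arm("NAC", p)) if q.probability > 0]
    assert len(paths) == 1
    assert paths[0].leaf_label == "NAC:no_complication/no_ae"


def test_rollback_equals_path_sum_for_both_arms(base):
    for strategy in ("NAC", "AC"):
        root = build_arm(strategy, base)
        ec, eq = rollback(root)
        paths = enumerate_paths(root)
        assert ec == pytest.approx(sum(p.probability * p.cost for p in paths), abs=1e-9)
        assert eq == pytest.approx(sum(p.probability * p.qaly for p in paths), abs=1e-12)


def test_rollback_invariant_under_sibling_reordering(base):
    root = build_arm("NAC", base)
    reordered = chance(root.label, [(b.probability, b.child) for b in reversed(root.branches)])
    assert rollback(reordered) == pytest.approx(rollback(root))


def test_identical_arms_give_identical_results(base):
    p = base
    for key in ("p_no_complication", "p_complication_ge3", "p_postop_death", "p_ae_ge3"):
        p = set_value(p, f"nac.{key}", getattr(base.ac, key))
    for key in (
        "surgery_base",
        "surgery_additional",
        "hosp_with_complication",
        "hosp_without_complication",
        "chemo_full_course",
        "imaging",
        "ae_treatment",
    ):
        p = set_value(p, f"nac.{key}", getattr(base.ac, key))
    # neutralize the strategy-specific death-path accrual (NAC deaths
    # carry two pre-operative chemo cycles of cost and QALY)
    p = set_value(p, "utilities.t_chemo_alone", 0.0)
    conv = StructuralConventions(nac_death_chemo_fraction=0.0)
    nac, ac = evaluate_base_case(p, conv)
    assert nac.expected_cost == pytest.approx(ac.expected_cost, abs=1e-9)
    assert nac.expected_qaly == pytest.approx(ac.expected_qaly, abs=1e-12)


def test_cost_gap_reduces_to_ae_term_when_drivers_equalized(base):
    # equalize probabilities, arm-specific costs and the death-path chemo
    # convention; the remaining cost difference is exactly the AE term
    p = base
    for key in ("p_no_complication", "p_complication_ge3", "p_postop_death"):
        p = set_value(p, f"nac.{key}", getattr(base.ac, key))
    for key in ("surgery_base", "surgery_additional", "imaging"):
        p = set_value(p, f"nac.{key}", getattr(base.ac, key))
    conv = StructuralConventions(nac_death_chemo_fraction=0.0)
    nac, ac = evaluate_base_case(p, conv)
    survivors = 1.0 - base.ac.p_postop_death
    expected = survivors * (base.nac.p_ae_ge3 - base.ac.p_ae_ge3) * 3679.8
    assert nac.expected_cost - ac.expected_cost == pytest.approx(expected, abs=1e-9)
    assert nac.expected_cost < ac.expected_cost  # NAC has fewer AEs


def test_expected_qaly_monotone_in_u_post_and_os(base):
    q_prev = {"NAC": -1.0, "AC": -1.0}
    for u_post in (0.90, 0.95, 1.0):
        p = set_value(base, "utilities.u_post_treatment", u_post)
        for strategy in ("NAC", "AC"):
            q = evaluate_arm(strategy, p).expected_qaly
            assert q > q_prev[strategy]
            q_prev[strategy] = q
    q_prev = {"NAC": -1.0, "AC": -1.0}
    for os in (8.0, 9.1, 10.0):
        p = set_value(set_value(base, "os_nac_years", os), "os_ac_years", os)
        for strategy in ("NAC", "AC"):
            q = evaluate_arm(strategy, p).expected_qaly
            assert q > q_prev[strategy]
            q_prev[strategy] = q


def test_death_hospitalization_convention_toggle(base):
    cheap = evaluate_arm("NAC", base, StructuralConventions("without_complication"))
    dear = evaluate_arm("NAC", base, StructuralConventions("with_complication"))
    assert dear.expected_cost - cheap.expected_cost == pytest.approx(
        base.nac.p_postop_death * (96462 - 66800), abs=1e-9
    )


def test_partial_treatment_initiation_rejected(base):
    p = set_value(base, "nac.p_receive_surgery", 0.9)
    with pytest.raises(ValueError, match="initiation"):
        build_arm("NAC", p)


def test_discounting_reduces_qalys_only_through_post_phase(base):
    import dataclasses

    discounted = dataclasses.replace(base, discount_rate=0.03)
    for strategy in ("NAC", "AC"):
        assert (
            evaluate_arm(strategy, discounted).expected_qaly
            < evaluate_arm(strategy, base).expected_qaly
        )
        # costs are all upfront and unaffected
        assert evaluate_arm(strategy, discounted).expected_cost == pytest.approx(
            evaluate_arm(strategy, base).expected_cost
        )
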