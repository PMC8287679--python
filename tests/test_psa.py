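"""PSA distributions, sampling moments, determinism, CEAC behaviour."""
import numpy as np
import pytest

from nsclc_cea.model import evaluate_base_case
from nsclc_cea.params import set_value
from nsclc_cea.psa import (
    build_distributions,
    default_wtp_grid,
    point_mass_specs,
    run_psa,
    sample_parameters,
    _draw,
)


def _spec(specs, target):
    matches = [s for s in specs if s.target == target]
    assert len(matches) == 1, target
    return matches[0]


def test_families_follow_parameter_kind(base):
    specs = build_distributions(base)
    chemo = _spec(specs, "chemo_full_course")
    assert chemo.family == "gamma"
    assert chemo.hyperparameters["mean"] == pytest.approx(30946.5)
    assert chemo.hyperparameters["sd"] == pytest.approx(3094.65)
    assert chemo.hyperparameters["shape"] == 100.0
    # the shared cost writes to both arms
    assert set(chemo.paths) == {"nac.chemo_full_course", "ac.chemo_full_course"}

    u = _spec(specs, "u_surgery_chemo")
    assert u.family == "triangular"
    assert (u.hyperparameters["left"], u.hyperparameters["mode"], u.hyperparameters["right"]) == (
        pytest.approx(0.76),
        0.81,
        pytest.approx(0.86),
    )

    ae = _spec(specs, "ac.p_ae_ge3")
    assert ae.family == "beta"
    assert ae.hyperparameters["alpha"] == pytest.approx(92 * 0.38)  # 34.96
    assert ae.hyperparameters["beta"] == pytest.approx(92 * 0.62)  # 57.04

    dirich = _spec(specs, "nac.complication_outcome")
    assert dirich.family == "dirichlet"
    assert dirich.hyperparameters["alpha"] == (
        pytest.approx(92 * 0.82),
        pytest.approx(92 * 0.14),
        pytest.approx(92 * 0.04),
    )


def test_utility_support_clips_at_one(base):
    specs = build_distributions(base)
    u = _spec(specs, "u_chemo_alone")
    assert u.hyperparameters["right"] == 1.0
    assert u.hyperparameters["left"] == pytest.approx(0.95)


def test_os_sampling_independent_vs_correlated(base):
    independent = build_distributions(base, os_correlated=False)
    assert _spec(independent, "os_nac_years").family == "gamma"
    assert _spec(independent, "os_ac_years").family == "gamma"
    correlated = build_distributions(base, os_correlated=True)
    assert not [s for s in correlated if s.target in ("os_nac_years", "os_ac_years")]
    common = _spec(correlated, "os_common")
    assert common.family == "scaled_gamma"
    assert common.paths == ("os_nac_years", "os_ac_years")
    # one multiplier scales both arms: sampled OS values stay equal
    rng = np.random.default_rng(0)
    draws = _draw(common, rng, 1000)
    assert np.allclose(draws[:, 0], draws[:, 1])
    assert draws[:, 0].mean() == pytest.approx(9.1, rel=0.02)


def test_zero_cost_base_becomes_point_mass(base):
    p = set_value(base, "nac.ae_treatment", 0.0)
    p = set_value(p, "ac.ae_treatment", 0.0)
    with pytest.warns(UserWarning, match="point mass"):
        specs = build_distributions(p)
    assert _spec(specs, "ae_treatment").family == "point"


def test_sample_moments_match_distribution_moments(base):
    """Law-of-large-numbers check on every family at n = 50,000."""
    n = 50_000
    rng = np.random.default_rng(2024)
    for spec in build_distributions(base):
        draws = _draw(spec, rng, n)
        h = spec.hyperparameters
        if spec.family == "gamma":
            se = h["sd"] / np.sqrt(n)
            assert abs(draws.mean() - h["mean"]) < 3 * se
            assert abs(draws.mean() - h["mean"]) < 0.01 * h["mean"]
            assert draws.std() == pytest.approx(h["sd"], rel=0.05)
        elif spec.family == "beta":
            mean = h["alpha"] / (h["alpha"] + h["beta"])
            se = draws.std() / np.sqrt(n)
            assert abs(draws.mean() - mean) < 3 * se
        elif spec.family == "dirichlet":
            total = sum(h["alpha"])
            for j, a in enumerate(h["alpha"]):
                assert abs(draws[:, j].mean() - a / total) < 0.01
        elif spec.family == "triangular":
            mean = (h["left"] + h["mode"] + h["right"]) / 3
            se = draws.std() / np.sqrt(n)
            assert abs(draws.mean() - mean) < 3 * se


def test_sample_parameters_returns_coherent_set(base):
    specs = build_distributions(base)
    rng = np.random.default_rng(7)
    p = sample_parameters(specs, rng, base)
    for arm in (p.nac, p.ac):
        pr = arm.probabilities
        assert pr.p_no_complication + pr.p_complication_ge3 + pr.p_postop_death == pytest.approx(
            1.0, abs=1e-12
        )
        assert 0 <= pr.p_ae_ge3 <= 1
    assert p.nac.chemo_full_course == p.ac.chemo_full_course  # shared draw
    assert p.nac.imaging != base.nac.imaging  # arm-specific draw moved


def test_same_seed_reproduces_draws(base):
    a = run_psa(base, n=200, seed=42)
    b = run_psa(base, n=200, seed=42)
    assert np.array_equal(a.delta_cost, b.delta_cost)
    assert np.array_equal(a.delta_qaly, b.delta_qaly)
    assert np.array_equal(a.ceac_p_ac, b.ceac_p_ac)
    c = run_psa(base, n=200, seed=43)
    assert not np.array_equal(a.delta_cost, c.delta_cost)


def test_point_masses_collapse_to_base_case(calibrated):
    nac, ac = evaluate_base_case(calibrated)
    dc0 = nac.expected_cost - ac.expected_cost
    dq0 = nac.expected_qaly - ac.expected_qaly
    result = run_psa(calibrated, n=50, seed=1, specs=point_mass_specs(calibrated))
    assert np.allclose(result.delta_cost, dc0, atol=1e-9)
    assert np.allclose(result.delta_qaly, dq0, atol=1e-12)
    assert result.fraction_ac_dominant == 1.0
    # the CEAC is then the base-case decision: a 0/1 step at the ICER
    assert set(np.unique(result.ceac_p_ac)) <= {0.0, 1.0}


def test_single_draw_gives_step_functions(base):
    result = run_psa(base, n=1, seed=3)
    assert result.fraction_ac_dominant in (0.0, 1.0)
    assert set(np.unique(result.ceac_p_ac)) <= {0.0, 1.0}
    assert result.quadrant_fractions()["ac_dominant"] in (0.0, 1.0)


def test_ceac_at_zero_wtp_counts_cost_sign(base):
    result = run_psa(base, n=400, seed=11)
    expected = float(np.mean(result.delta_cost > 0))
    assert result.ceac_p_ac[result.ceac_wtp == 0.0][0] == pytest.approx(expected)


def test_quadrant_fractions_partition(base):
    result = run_psa(base, n=400, seed=5)
    fractions = result.quadrant_fractions()
    assert sum(fractions.values()) == pytest.approx(1.0)
    assert fractions["ac_dominant"] == result.fraction_ac_dominant


def test_wtp_grid_includes_threshold_exactly(base):
    grid = default_wtp_grid(base)
    assert 35446.0 in grid
    assert grid[0] == 0.0 and grid[-1] == 150000.0


def test_invalid_draw_count_rejected(base):
    with pytest.raises(ValueError, match="n must be"):
        run_psa(base, n=0, seed=1)
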