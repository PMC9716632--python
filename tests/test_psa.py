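"""Monte-Carlo PSA: sampling conventions, reproducibility, CE plane, CEAC."""

import numpy as np
import pytest
import scipy.stats

from woundcea import (
    DistributionSpec,
    Family,
    ce_plane,
    ceac,
    distribution_mean,
    moment_match_gamma,
    rollback,
    run_psa,
    sample_parameter,
)
from woundcea.synthetic import degenerate_scenario

N_BIG = 100_000


@pytest.mark.parametrize(
    "family, params, expected",
    [
        (Family.GAMMA, (0.0477, 400), 19.08),
        (Family.GAMMA, (0.0616, 400), 24.64),
        (Family.BINOMIAL, (8, 0.18), 1.44),
        (Family.BINOMIAL, (8, 0.23), 1.84),
        (Family.BETA, (2.03, 1.2960), 0.6103),  # 2.03 / 3.326
        (Family.BETA, (1.82, 1.4323), 0.5596),  # 1.82 / 3.2523
        (Family.FIXED, (12.1667,), 12.1667),
    ],
)
def test_distribution_mean(family, params, expected):
    assert distribution_mean(DistributionSpec(family=family, params=params)) == pytest.approx(
        expected, abs=5e-5
    )


def test_fixed_distribution_is_point_mass():
    spec = DistributionSpec(family=Family.FIXED, params=(12.1667,))
    rng = np.random.default_rng(0)
    assert all(sample_parameter(spec, rng) == 12.1667 for _ in range(10))


@pytest.mark.parametrize(
    "family, params",
    [
        (Family.GAMMA, (0.0477, 400)),
        (Family.GAMMA, (0.5264, 23.112994)),
        (Family.BINOMIAL, (8, 0.18)),
        (Family.BINOMIAL, (8, 0.23)),
        (Family.BETA, (2.03, 1.2960)),
        (Family.BETA, (1.82, 1.4323)),
    ],
)
def test_sample_mean_recovers_analytic_mean(family, params):
    """|empirical mean − analytic mean| < 3.29 SE at n = 1e5 (seeded)."""
    spec = DistributionSpec(family=family, params=params)
    rng = np.random.default_rng(42)
    draws = np.array([sample_parameter(spec, rng) for _ in range(1000)])
    # vectorised path for the bulk, scalar path spot-checked above
    from woundcea.psa import _sample

    draws = np.concatenate([draws, np.asarray(_sample(spec, rng, N_BIG - 1000), dtype=float)])
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - distribution_mean(spec)) < 3.29 * se


def test_binomial_support_is_integer_bounded():
    spec = DistributionSpec(family=Family.BINOMIAL, params=(8, 0.23))
    rng = np.random.default_rng(7)
    draws = [sample_parameter(spec, rng) for _ in range(2000)]
    assert all(d == int(d) and 0 <= d <= 8 for d in draws)


@pytest.mark.parametrize(
    "family, params, frozen",
    [
        (Family.GAMMA, (0.0477, 400), scipy.stats.gamma(a=400, scale=0.0477)),
        (Family.BETA, (2.03, 1.2960), scipy.stats.beta(2.03, 1.2960)),
    ],
)
def test_sampling_parameterisation_against_scipy(family, params, frozen):
    """KS goodness-of-fit of our draws against the independent scipy CDF
    pins down the (scale, shape) reading of the gamma parameters."""
    spec = DistributionSpec(family=family, params=params)
    from woundcea.psa import _sample

    draws = _sample(spec, np.random.default_rng(3), 20_000)
    assert scipy.stats.kstest(draws, frozen.cdf).pvalue > 1e-3


@pytest.mark.parametrize(
    "mean, theta, expected_shape",
    [
        (12.1667, 0.5264, 23.113),
        (19.08, 0.0477, 400.0),
        (3.5, 3.5, 1.0),
    ],
)
def test_moment_match_gamma(mean, theta, expected_shape):
    spec = moment_match_gamma(mean, theta)
    assert spec.family is Family.GAMMA
    assert spec.params[0] == theta
    assert spec.params[1] == pytest.approx(expected_shape, abs=5e-4)
    assert distribution_mean(spec) == pytest.approx(mean)


@pytest.mark.parametrize("mean, theta", [(0, 1), (-1, 1), (1, 0), (1, -2)])
def test_moment_match_gamma_rejects_nonpositive(mean, theta):
    with pytest.raises(ValueError):
        moment_match_gamma(mean, theta)


def test_run_psa_shape_and_reproducibility(paper_scenario):
    a = run_psa(paper_scenario, n_iterations=500, seed=11)
    b = run_psa(paper_scenario, n_iterations=500, seed=11)
    c = run_psa(paper_scenario, n_iterations=500, seed=12)
    assert len(a.frame) == 500
    assert a.frame.equals(b.frame)
    assert not a.frame.equals(c.frame)
    assert a.ceac().to_frame().equals(b.ceac().to_frame())


def test_run_psa_rejects_zero_iterations(paper_scenario):
    with pytest.raises(ValueError):
        run_psa(paper_scenario, n_iterations=0, seed=1)


def test_all_fixed_scenario_degenerates_to_base_case(paper_scenario_fixed):
    psa = run_psa(paper_scenario_fixed, n_iterations=50, seed=5)
    base_i, base_c = rollback(paper_scenario_fixed)
    assert np.allclose(psa.frame["cost_intervention"], base_i.cost)
    assert np.allclose(psa.frame["cost_comparator"], base_c.cost)
    assert np.allclose(psa.frame["effect_intervention"], base_i.effect)
    pts = ce_plane(psa)
    assert np.allclose(pts["delta_cost"], -133.2480)
    assert np.allclose(pts["delta_effect"], 0.0106)


def test_iteration_objects_carry_draws_and_valuations(paper_scenario):
    psa = run_psa(paper_scenario, n_iterations=10, seed=2)
    its = psa.iterations
    assert len(its) == 10
    horizon = paper_scenario.horizon_weeks
    for it in its:
        assert set(it.draws) == set(paper_scenario.parameter_map())
        assert 0.0 <= it.draws["HA.healing_rate"] <= 1.0
        assert it.draws["Silver.units_per_week"] in range(0, 9)
        expected = horizon * it.draws["HA.units_per_week"] * (
            it.draws["HA.unit_price"] + it.draws["change_tariff"]
        )
        assert it.intervention_cost == pytest.approx(expected)


def test_psa_mean_cost_matches_independence_factorisation(paper_scenario):
    """E[cost] = 12 · E[U] · (E[P] + E[tariff]) with the moment-matched tariff."""
    psa = run_psa(paper_scenario, n_iterations=N_BIG, seed=99)
    cost = psa.frame["cost_intervention"].to_numpy()
    analytic = 12 * 1.44 * (19.08 + 12.1667)
    se = cost.std(ddof=1) / np.sqrt(len(cost))
    assert abs(cost.mean() - analytic) < 3.29 * se


def test_shared_tariff_draw_feeds_both_arms(paper_scenario):
    psa = run_psa(paper_scenario, n_iterations=200, seed=8)
    f = psa.frame
    # reconstruct the tariff from each arm's cost identity; both must agree
    mask = (f["HA.units_per_week"] > 0) & (f["Silver.units_per_week"] > 0)
    t_i = f["cost_intervention"] / (12 * f["HA.units_per_week"]) - f["HA.unit_price"]
    t_c = f["cost_comparator"] / (12 * f["Silver.units_per_week"]) - f["Silver.unit_price"]
    assert np.allclose(t_i[mask], t_c[mask])
    assert np.allclose(t_i[mask], f["change_tariff"][mask])


def test_ce_plane_antisymmetric_under_arm_swap(paper_scenario):
    """Re-evaluating the swapped scenario on the *same* sampled inputs negates
    every cost-effectiveness-plane point."""
    import json

    from woundcea import incremental_analysis, load_scenario, write_scenario

    doc = json.loads(write_scenario(paper_scenario))
    doc["strategies"] = doc["strategies"][::-1]
    swapped = load_scenario(json.dumps(doc))
    psa = run_psa(paper_scenario, 50, seed=21)
    fwd = ce_plane(psa)
    for i, it in enumerate(psa.iterations):
        rev = incremental_analysis(*rollback(swapped, it.draws))
        assert rev.delta_cost == pytest.approx(-fwd["delta_cost"].iloc[i])
        assert rev.delta_effect == pytest.approx(-fwd["delta_effect"].iloc[i])


def test_ceac_probabilities_complementary(paper_scenario):
    curve = ceac(run_psa(paper_scenario, 2000, seed=4))
    for p in curve.points:
        assert p.probability_intervention + p.probability_comparator == pytest.approx(1.0)
        assert 0.0 <= p.probability_intervention <= 1.0


def test_ceac_point_mass_oracle():
    """With point-mass scenarios the CEAC equals the deterministic NMB indicator."""
    dominant = run_psa(degenerate_scenario(700, 0.6, 900, 0.5), 100, seed=1)
    dominated = run_psa(degenerate_scenario(900, 0.5, 700, 0.6), 100, seed=1)
    tied = run_psa(degenerate_scenario(800, 0.55, 800, 0.55), 100, seed=1)
    for curve, expected in ((ceac(dominant), 1.0), (ceac(dominated), 0.0), (ceac(tied), 0.5)):
        assert all(p.probability_intervention == expected for p in curve.points)


def test_ceac_monotone_when_delta_effect_nonnegative():
    """If every iteration has ΔE >= 0, the intervention's CEAC cannot decrease in λ."""
    import json

    from woundcea import builtin_paper_scenario, load_scenario, write_scenario

    doc = json.loads(write_scenario(builtin_paper_scenario()))
    doc["strategies"][0]["healing_rate"]["dist"] = {"family": "fixed", "params": [0.6068]}
    doc["strategies"][1]["healing_rate"]["dist"] = {"family": "fixed", "params": [0.5962]}
    scenario = load_scenario(json.dumps(doc))
    curve = ceac(run_psa(scenario, 3000, seed=6))
    probs = [p.probability_intervention for p in curve.points]
    assert all(b >= a for a, b in zip(probs, probs[1:]))


def test_ceac_grid_validation(paper_scenario):
    psa = run_psa(paper_scenario, 10, seed=1)
    with pytest.raises(ValueError):
        ceac(psa, [])
    with pytest.raises(ValueError):
        ceac(psa, [-100.0])
    with pytest.raises(KeyError):
        ceac(psa, [0.0, 100.0]).at(55.0)
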