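import numpy as np
import pytest

from ssediff import (
    FIXTURES,
    GeoSSEParams,
    enumerate_range_states,
    integrate_frequency_ode,
    sample_equal_thirds_rates,
    solve_rates_for_frequencies,
    solve_stationary_2region,
    split_key,
    stationary_by_eigen,
    stationary_by_ode,
    time_to_stationarity,
    verify_rates_for_frequencies,
)
from ssediff.stationary import reduced_affine_system

from .conftest import random_geosse_params


def load(name):
    space, params, init, run = FIXTURES[name].load()
    return space, params, init


class TestBenchmarkStationaries:
    """Cross-method stationary frequencies on the two 2-region benchmarks."""

    def test_benchmark1_ode(self):
        space, params, _ = load("two_region_benchmark1")
        pi = stationary_by_ode(params, space)
        assert pi == pytest.approx([0.057, 0.506, 0.437], abs=2e-3)

    def test_benchmark1_closed_form(self):
        _, params, _ = load("two_region_benchmark1")
        sol = solve_stationary_2region(params)
        assert sol.pi_hat == pytest.approx([0.057, 0.506, 0.437], abs=2e-3)
        # the closed-form ratio constants reproduce the fixed point
        assert sol.numA / sol.denomA == pytest.approx(sol.pi_hat[0], rel=1e-12)
        assert sol.lambda1 < sol.lambda2 < 0

    def test_benchmark2_widespread_dominates(self):
        space, params, _ = load("two_region_benchmark2")
        pi = stationary_by_ode(params, space)
        assert pi[2] == pytest.approx(0.8008, abs=5e-3)
        sol = solve_stationary_2region(params)
        assert sol.pi_hat == pytest.approx(pi, abs=1e-9)

    def test_benchmark1_eigen_method(self):
        space, params, _ = load("two_region_benchmark1")
        pi = stationary_by_eigen(params, space)
        assert pi[0] == pytest.approx(0.055, abs=3e-3)
        assert pi == pytest.approx([0.055, 0.490, 0.455], abs=3e-3)

    def test_eigen_and_ode_agree_closely(self):
        # the two routes answer slightly different questions when net growth
        # is nonzero; on these benchmarks they differ by < 0.02 per state
        for name in ("two_region_benchmark1", "two_region_benchmark2"):
            space, params, _ = load(name)
            a = stationary_by_eigen(params, space)
            b = stationary_by_ode(params, space)
            assert np.max(np.abs(a - b)) < 0.02

    def test_single_state_system(self):
        space = enumerate_range_states(["A"])
        p = GeoSSEParams(w={"A": 0.1}, e={"A": 0.05}, d={}, b={})
        assert stationary_by_eigen(p, space) == pytest.approx([1.0])


class TestClosedFormVsODE:
    def test_trajectories_match_on_random_rates(self, space2):
        rng = np.random.default_rng(314)
        times = np.linspace(0.0, 50.0, 201)
        for _ in range(50):
            p = random_geosse_params(space2, rng, low=1e-3, high=1.0)
            pi0 = rng.dirichlet(np.ones(3))
            sol = solve_stationary_2region(p, pi0)
            closed = sol.trajectory(times).values
            ode = integrate_frequency_ode(p, space2, pi0, 50.0, 201).values
            # scale-aware: growing modes can leave the simplex and blow up
            err = np.abs(closed - ode) / np.maximum(1.0, np.abs(closed))
            assert np.max(err) < 1e-7

    def test_fixed_point_has_zero_drift(self, space2):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_geosse_params(space2, rng, low=1e-3, high=1.0)
            sol = solve_stationary_2region(p)
            J, c = reduced_affine_system(p, space2)
            assert np.max(np.abs(J @ sol.K + c)) < 1e-8

    def test_starting_at_the_fixed_point_stays_there(self, space2):
        _, params, _ = load("two_region_benchmark1")
        sol = solve_stationary_2region(params)
        sol2 = solve_stationary_2region(params, sol.pi_hat)
        assert abs(sol2.C1) < 1e-12 and abs(sol2.C2) < 1e-12
        traj = sol2.trajectory(np.linspace(0, 100, 50))
        assert np.max(np.abs(traj.values - sol.pi_hat)) < 1e-9

    def test_symmetric_rates_symmetric_dynamics(self, space2):
        p = GeoSSEParams(
            w={"A": 0.05, "B": 0.05},
            e={"A": 0.02, "B": 0.02},
            d={("A", "B"): 0.03, ("B", "A"): 0.03},
            b={split_key("A", "B"): 0.01},
        )
        traj = integrate_frequency_ode(
            p, enumerate_range_states(["A", "B"]), [0.4, 0.4, 0.2], 50.0, 100
        )
        assert np.max(np.abs(traj.values[:, 0] - traj.values[:, 1])) < 1e-10

    def test_requires_two_regions(self, space3):
        rng = np.random.default_rng(1)
        p = random_geosse_params(space3, rng)
        with pytest.raises(ValueError):
            solve_stationary_2region(p)


class TestRateSolving:
    def test_equal_thirds_solution_verifies(self, space2):
        target = np.full(3, 1 / 3)
        sol = solve_rates_for_frequencies(target, space2, seed=11)
        assert sol.feasible
        assert np.max(np.abs(sol.residuals)) < 1e-8
        assert all(
            v > 0
            for m in (sol.params.w, sol.params.e, sol.params.d, sol.params.b)
            for v in m.values()
        )

    def test_round_trip_recovers_target(self, space2):
        target = np.full(3, 1 / 3)
        sol = solve_rates_for_frequencies(target, space2, seed=23)
        terminal = stationary_by_ode(sol.params, space2)
        assert terminal == pytest.approx(target, abs=1e-6)

    def test_asymmetric_target(self, space2):
        target = np.array([0.057, 0.506, 0.437])
        sol = solve_rates_for_frequencies(target, space2, seed=3)
        assert sol.feasible
        terminal = stationary_by_ode(sol.params, space2)
        assert terminal == pytest.approx(target, abs=1e-6)
        # flux ordering follows the frequency ordering
        f = dict(zip(space2.labels(), sol.flux))
        assert f["B"] > f["AB"] > f["A"]

    def test_many_to_one_mapping(self, space2):
        # distinct rate sets — one from each closed-form family plus a
        # solver vertex — share the same stationary frequencies
        target = np.full(3, 1 / 3)
        params_list = [
            sample_equal_thirds_rates(1, seed=0),
            sample_equal_thirds_rates(2, seed=0),
            solve_rates_for_frequencies(target, space2, seed=101).params,
        ]

        def vec(p):
            return np.array(
                list(p.w.values())
                + list(p.e.values())
                + list(p.d.values())
                + list(p.b.values())
            )

        vecs = [vec(p) for p in params_list]
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                assert np.linalg.norm(vecs[i] - vecs[j]) > 0.05
        pis = [stationary_by_ode(p, space2) for p in params_list]
        for pi in pis[1:]:
            assert pi == pytest.approx(pis[0], abs=1e-6)

    def test_fixed_rates_are_respected(self, space2):
        sol = solve_rates_for_frequencies(
            np.full(3, 1 / 3), space2, fixed={"d:B>A": 0.25}, seed=4
        )
        assert sol.feasible
        assert sol.params.d[("B", "A")] == pytest.approx(0.25)

    def test_verifier_on_exact_family_member(self, space2):
        # family-1 member: frees (bBA, dAB, dBA, eB) = (.004, .015, .173, .008)
        bBA, dAB, dBA, eB = 0.004, 0.015, 0.173, 0.008
        wA = 0.5 * (-2 * bBA + 2 * dAB + dBA - 2 * eB)
        wB = 0.5 * (2 * eB - dAB)
        eA = dAB + dBA - bBA - eB
        assert wA == pytest.approx(0.0895)
        assert eA == pytest.approx(0.176)
        p = GeoSSEParams(
            w={"A": wA, "B": wB},
            e={"A": eA, "B": eB},
            d={("A", "B"): dAB, ("B", "A"): dBA},
            b={split_key("A", "B"): bBA},
        )
        res = verify_rates_for_frequencies(p, np.full(3, 1 / 3), space2)
        assert res.feasible
        assert np.max(np.abs(res.residuals)) < 1e-12

    @pytest.mark.parametrize("family", [1, 2])
    def test_family_samples_converge_to_equal_thirds(self, family, space2):
        for seed in range(3):
            p = sample_equal_thirds_rates(family, seed=seed)
            terminal = stationary_by_ode(p, space2)
            assert terminal == pytest.approx(np.full(3, 1 / 3), abs=1e-6)

    def test_family_constraints_hold(self):
        rng_seeds = range(5)
        for seed in rng_seeds:
            p1 = sample_equal_thirds_rates(1, seed=seed)
            dAB, eB = p1.d[("A", "B")], p1.e["B"]
            bBA = p1.b[split_key("A", "B")]
            assert eB < dAB < 2 * eB and 0 < bBA <= dAB - eB
            p2 = sample_equal_thirds_rates(2, seed=seed)
            dAB, eB = p2.d[("A", "B")], p2.e["B"]
            bBA, dBA = p2.b[split_key("A", "B")], p2.d[("B", "A")]
            assert 0 < dAB <= eB and dBA > 2 * (bBA - dAB + eB)

    def test_infeasible_target_reports_failure(self, space2):
        with pytest.raises(ValueError):
            solve_rates_for_frequencies(
                np.array([1.0, 0.0, 0.0]), space2, seed=1
            )


class TestMixingTimes:
    def test_family1_panel(self, space2):
        _, params, init = load("equal_thirds_f1_b")
        mt = time_to_stationarity(
            params, space2, init["pi0"], 250.0, 1000, 1e-9
        )
        # two grid steps of slack absorbs the 3-decimal rounding of the
        # published rates
        tol = 0.501
        assert abs(mt.times["A"] - 76.827) <= tol
        assert abs(mt.times["B"] - 75.576) <= tol
        assert abs(mt.times["AB"] - 70.320) <= tol

    def test_family2_panel(self, space2):
        _, params, init = load("equal_thirds_f2_a")
        mt = time_to_stationarity(params, space2, init["pi0"], 60.0, 1000, 1e-9)
        tol = 0.121
        assert abs(mt.times["A"] - 53.153) <= tol
        assert abs(mt.times["B"] - 51.952) <= tol
        assert abs(mt.times["AB"] - 48.048) <= tol

    def test_start_at_stationarity_hits_first_grid_point(self, space2):
        _, params, _ = load("two_region_benchmark1")
        sol = solve_stationary_2region(params)
        mt = time_to_stationarity(params, space2, sol.pi_hat, 10.0, 100, 1e-9)
        assert all(t == pytest.approx(mt.dt) for t in mt.times.values())

    def test_huge_epsilon_met_immediately(self, space2):
        _, params, init = load("equal_thirds_f1_a")
        mt = time_to_stationarity(params, space2, init["pi0"], 250.0, 1000, 10.0)
        assert all(t == pytest.approx(mt.dt) for t in mt.times.values())

    def test_criterion_never_met_reported_as_none(self, space2):
        _, params, init = load("equal_thirds_f1_a")
        mt = time_to_stationarity(params, space2, init["pi0"], 1.0, 50, 1e-12)
        assert all(t is None for t in mt.times.values())

    def test_three_region_round_trip_and_mixing(self, space3):
        # solver-built three-region rates hold their target stationary and
        # the (ODE-evaluated) mixing criterion is met for every state
        target = np.array([0.25, 0.2, 0.15, 0.12, 0.11, 0.08, 0.09])
        sol = solve_rates_for_frequencies(target, space3, seed=2)
        assert sol.feasible
        pi0 = np.full(7, 1 / 7)
        assert stationary_by_ode(
            sol.params, space3, pi0=pi0
        ) == pytest.approx(target, abs=1e-6)
        mt = time_to_stationarity(sol.params, space3, pi0, 400.0, 500, 1e-7)
        assert all(t is not None for t in mt.times.values())
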