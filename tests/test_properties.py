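"""Property tests of the model invariants, quantified over random inputs."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from trigame.game_model import (
    AS_PRINTED,
    TABLE2_CONSISTENT,
    StrategyState,
    check_payoff_replicator_consistency,
    expected_utilities,
    replicator_field,
    replicator_rate_enterprise,
    replicator_rate_government,
    replicator_rate_institution,
)
from trigame.simulator import SimulationSettings, detect_convergence, integrate
from trigame.stability import (
    CORNER_ORDER,
    classify_pure_equilibria,
    critical_reputation_loss,
    jacobian,
    midpoint_region_proportions,
    regulation_thresholds,
)
from trigame.scenarios import random_parameters

from conftest import random_parameter_sets
from test_stability import finite_difference_jacobian

PARAM_SETS = random_parameter_sets(100)

proportions = st.floats(0.0, 1.0, allow_nan=False, allow_subnormal=False)
interior = st.floats(0.01, 0.99, allow_nan=False, allow_subnormal=False)
seeds = st.integers(0, 10_000)


class TestFixedPoints:
    def test_all_corners_fixed_for_random_parameters(self):
        for params in PARAM_SETS:
            for corner in CORNER_ORDER:
                state = StrategyState(*corner)
                for variant in (AS_PRINTED, TABLE2_CONSISTENT):
                    assert replicator_field(params, state, variant) == (0.0, 0.0, 0.0)

    def test_jacobian_diagonal_at_corners_for_random_parameters(self):
        for params in PARAM_SETS:
            for corner in CORNER_ORDER:
                J = jacobian(params, StrategyState(*corner))
                assert np.all(J - np.diag(np.diag(J)) == 0.0)


class TestRateIdentities:
    @hyp_settings(max_examples=60, deadline=None)
    @given(seed=seeds, x=interior, y=interior, z=interior)
    def test_rate_equals_share_weighted_utility_gap(self, seed, x, y, z):
        params = random_parameters(seed)
        state = StrategyState(x, y, z)
        u_gov = expected_utilities(params, state, "government")
        u_inst = expected_utilities(params, state, "institution")
        r_gov = replicator_rate_government(params, state)
        r_inst = replicator_rate_institution(params, state)
        assert r_gov == pytest.approx(
            x * (1 - x) * (u_gov.u_adopt - u_gov.u_decline), rel=1e-12, abs=1e-12
        )
        assert r_inst == pytest.approx(
            z * (1 - z) * (u_inst.u_adopt - u_inst.u_decline), rel=1e-12, abs=1e-12
        )

    @hyp_settings(max_examples=60, deadline=None)
    @given(seed=seeds, x=proportions, y=proportions, z=proportions)
    def test_enterprise_variant_residual_closed_form(self, seed, x, y, z):
        params = random_parameters(seed)
        state = StrategyState(x, y, z)
        diff = replicator_rate_enterprise(
            params, state, AS_PRINTED
        ) - replicator_rate_enterprise(params, state, TABLE2_CONSISTENT)
        expected = y * (1 - y) * (1 - z) * params.P * params.q
        assert diff == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @hyp_settings(max_examples=40, deadline=None)
    @given(seed=seeds, x=interior, y=interior, z=interior)
    def test_payoff_consistency_residuals(self, seed, x, y, z):
        params = random_parameters(seed)
        state = StrategyState(x, y, z)
        for rec in check_payoff_replicator_consistency(params, [state]):
            if rec.player == "enterprise":
                expected = y * (1 - y) * (1 - z) * params.P * params.q
                assert rec.residual == pytest.approx(expected, rel=1e-9, abs=1e-12)
            else:
                assert rec.residual == pytest.approx(0.0, abs=1e-12)

    @hyp_settings(max_examples=40, deadline=None)
    @given(seed=seeds, x=proportions, y=proportions, z=proportions)
    def test_rates_linear_in_q(self, seed, x, y, z):
        params = random_parameters(seed)
        doubled = params.replace(q=2.0 * params.q)
        state = StrategyState(x, y, z)
        f1 = replicator_field(params, state)
        f2 = replicator_field(doubled, state)
        # exact doubling, up to underflow at subnormal magnitudes
        assert f2 == pytest.approx(
            tuple(2.0 * v for v in f1), rel=1e-12, abs=1e-300
        )


class TestJacobianOracle:
    def test_matches_finite_differences_random(self, rng):
        for params in PARAM_SETS[:30]:
            state = StrategyState(*rng.uniform(0.1, 0.9, 3))
            for variant in (AS_PRINTED, TABLE2_CONSISTENT):
                J = jacobian(params, state, variant)
                J_fd = finite_difference_jacobian(params, state, variant)
                assert np.allclose(J, J_fd, rtol=1e-6, atol=1e-6)


class TestThresholdProperties:
    def test_midpoint_identities_exact(self):
        for params in PARAM_SETS:
            try:
                regions = midpoint_region_proportions(params)
            except ZeroDivisionError:
                continue
            thr = regulation_thresholds(params, y=0.5, z=0.5)
            assert regions.v11 == thr.lambda_z
            assert regions.v12 == thr.lambda_y

    def test_thresholds_monotone_in_opponent_shares(self):
        grid = np.linspace(0.0, 1.0, 6)
        for params in PARAM_SETS[:40]:
            lam_y = [regulation_thresholds(params, 0.3, z).lambda_y for z in grid]
            lam_z = [regulation_thresholds(params, y, 0.3).lambda_z for y in grid]
            assert np.all(np.diff(lam_y) <= 1e-12)
            assert np.all(np.diff(lam_z) <= 1e-12)

    def test_rate_factors_monotone_in_supporters(self):
        # producer incentive grows with regulation and consumer shares,
        # consumer incentive grows with regulation and producer shares
        from trigame.game_model import enterprise_rate_factor, institution_rate_factor

        grid = np.linspace(0.0, 1.0, 6)
        for params in PARAM_SETS[:40]:
            ent_x = [enterprise_rate_factor(params, x, 0.3) for x in grid]
            inst_x = [institution_rate_factor(params, x, 0.3) for x in grid]
            inst_y = [institution_rate_factor(params, 0.3, y) for y in grid]
            assert np.all(np.diff(ent_x) >= -1e-12)
            assert np.all(np.diff(inst_x) >= -1e-12)
            assert np.all(np.diff(inst_y) >= -1e-12)
            if params.alpha * params.P >= params.f2:
                ent_z = [enterprise_rate_factor(params, 0.3, z) for z in grid]
                assert np.all(np.diff(ent_z) >= -1e-12)

    @hyp_settings(max_examples=60, deadline=None)
    @given(seed=seeds, prop=proportions, margin=st.floats(1e-6, 5.0))
    def test_dominant_reputation_loss_pushes_threshold_past_one(
        self, seed, prop, margin
    ):
        params = random_parameters(seed)
        # engineer H just above the critical loss and check the threshold claim
        for mode in ("given_y", "given_z"):
            crit = critical_reputation_loss(params, mode, prop)
            boosted = params.replace(H=max(crit, 0.0) + margin)
            if mode == "given_y":
                thr = regulation_thresholds(boosted, y=prop, z=0.0)
                assert thr.lambda_z > 1.0
            else:
                thr = regulation_thresholds(boosted, y=0.0, z=prop)
                assert thr.lambda_y > 1.0


class TestTrajectoryProperties:
    def test_states_contained_for_random_parameters(self, rng):
        for params in PARAM_SETS:
            start = StrategyState(*rng.uniform(0.01, 0.99, 3))
            traj = integrate(params, start, SimulationSettings(t_final=5.0))
            assert np.all(traj.states >= 0.0) and np.all(traj.states <= 1.0)

    def test_corner_persistence_for_random_parameters(self):
        for params in PARAM_SETS[:25]:
            for corner in CORNER_ORDER:
                traj = integrate(params, StrategyState(*corner),
                                 SimulationSettings(t_final=1.0, dt=0.25))
                assert np.all(traj.states == np.asarray(corner, dtype=float))

    @pytest.mark.parametrize("variant", [AS_PRINTED, TABLE2_CONSISTENT])
    def test_random_starts_reach_the_unique_stable_corner(self, baseline, variant, rng):
        records = classify_pure_equilibria(baseline, variant)
        stable = [r.corner for r in records if r.is_stable()]
        assert stable == [StrategyState(0, 1, 1)]
        # long horizon: the slowest contraction rate toward the corner is 0.45
        settings = SimulationSettings(t_final=80.0, variant=variant)
        for _ in range(20):
            start = StrategyState(*rng.uniform(0.05, 0.95, 3))
            traj = integrate(baseline, start, settings)
            assert detect_convergence(traj, tol=0.01, dwell=20) == stable[0]

    def test_integrators_agree_after_convergence(self, baseline):
        # at t = 15 the run is still ~0.035 from the corner and forward Euler
        # carries a visible O(dt) error; after convergence the methods agree
        start = StrategyState(0.1, 0.1, 0.1)
        euler = integrate(baseline, start, SimulationSettings(t_final=40.0))
        rk4 = integrate(
            baseline, start, SimulationSettings(t_final=40.0, dt=0.005, method="rk4")
        )
        assert np.max(np.abs(euler.states[-1] - rk4.states[-1])) < 1e-4

    def test_step_halving_stable_after_convergence(self, baseline):
        start = StrategyState(0.1, 0.1, 0.1)
        a = integrate(baseline, start, SimulationSettings(t_final=40.0, dt=0.05))
        b = integrate(baseline, start, SimulationSettings(t_final=40.0, dt=0.025))
        assert np.max(np.abs(a.states[-1] - b.states[-1])) < 1e-4
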