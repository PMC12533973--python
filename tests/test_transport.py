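"""Embolus dynamics: response time, force inventory, wall collisions and
trajectory integration against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from embotrace import hemodynamics as hemo
from embotrace import transport as tp

from conftest import straight_tube_network


class TestMomentumResponse:
    def test_default_response_time(self, fluid):
        tau = tp.momentum_response_time(tp.EmbolusProperties(), fluid)
        assert tau == pytest.approx(0.004, rel=0.01)

    def test_diameter_and_viscosity_scaling(self, fluid):
        tau = tp.momentum_response_time(tp.EmbolusProperties(), fluid)
        half_d = tp.momentum_response_time(
            tp.EmbolusProperties(diameter_um=250.0), fluid
        )
        assert half_d == pytest.approx(tau / 4.0)
        thick = hemo.FluidProperties(viscosity_cp=8.0)
        assert tp.momentum_response_time(
            tp.EmbolusProperties(), thick
        ) == pytest.approx(tau / 2.0)

    @pytest.mark.parametrize(
        "tau, period, expected",
        [(0.004, 0.83, 0.00482), (0.83, 0.83, 1.0), (0.002, 1.0, 0.002)],
    )
    def test_stokes_number(self, tau, period, expected):
        assert tp.stokes_number(tau, period) == pytest.approx(expected, rel=0.01)


class TestForceInventory:
    def test_equilibrium_gives_zero_acceleration(self, tube_field, fluid):
        x = np.array([0.0, 0.0, 50.0])
        u = tube_field.velocity(x, 0.0, "tube")
        state = tp.EmbolusState(position=x, velocity=u, time=0.0,
                                current_segment="tube")
        comp = tp.hydrodynamic_acceleration(
            state, tube_field, tp.EmbolusProperties(), fluid, components=True
        )
        # on the axis of a steady straight tube: no slip, no gradient forcing
        assert np.linalg.norm(comp["total"]) < 1e-6

    def test_zero_shear_gives_zero_lift(self, tube_field, fluid):
        x = np.array([0.0, 0.0, 50.0])  # axis: vorticity vanishes
        state = tp.EmbolusState(position=x, velocity=np.zeros(3), time=0.0,
                                current_segment="tube")
        comp = tp.hydrodynamic_acceleration(
            state, tube_field, tp.EmbolusProperties(), fluid, components=True
        )
        assert np.linalg.norm(comp["lift"]) == 0.0

    def test_zero_slip_gives_zero_shear_lift(self, tube_field, fluid):
        x = np.array([0.0, 1.5, 50.0])
        u = tube_field.velocity(x, 0.0, "tube")
        state = tp.EmbolusState(position=x, velocity=u, time=0.0,
                                current_segment="tube")
        comp = tp.hydrodynamic_acceleration(
            state, tube_field, tp.EmbolusProperties(wall_lift_coefficient=0.0),
            fluid, components=True,
        )
        assert np.linalg.norm(comp["lift"]) < 1e-9

    def test_lagging_particle_lift_points_away_from_wall(self, tube_field, fluid):
        """Near-wall shear with a lagging particle: Saffman lift is directed
        toward the channel core, matching the slip x vorticity product."""
        x = np.array([0.0, 2.5, 50.0])  # near the y = 3 wall
        state = tp.EmbolusState(position=x, velocity=np.zeros(3), time=0.0,
                                current_segment="tube")
        props = tp.EmbolusProperties(wall_lift_coefficient=0.0)
        comp = tp.hydrodynamic_acceleration(state, tube_field, fluid=fluid,
                                            props=props, components=True)
        # inward = -y here
        assert comp["lift"][1] < 0.0
        # direction agrees with the Saffman cross product slip x omega
        smp = tube_field.sample(x, 0.0, "tube")
        G = smp["gradient"]
        omega = np.array([G[2, 1] - G[1, 2], G[0, 2] - G[2, 0], G[1, 0] - G[0, 1]])
        expected = np.cross(smp["velocity"], omega)
        cos = np.dot(comp["lift"], expected) / (
            np.linalg.norm(comp["lift"]) * np.linalg.norm(expected)
        )
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_out_of_lumen_query_rejected(self, tube_field, fluid):
        state = tp.EmbolusState(position=np.array([0.0, 5.0, 50.0]),
                                velocity=np.zeros(3), time=0.0,
                                current_segment="tube")
        with pytest.raises(ValueError, match="lumen"):
            tp.hydrodynamic_acceleration(state, tube_field,
                                         tp.EmbolusProperties(), fluid)


class TestExponentialRelaxation:
    def _efold(self, props, fluid, tube_field):
        """Euler-integrate a particle released at rest on the axis and
        measure the e-folding time of its velocity error."""
        x = np.array([0.0, 0.0, 20.0])
        u0 = tube_field.velocity(x, 0.0, "tube")
        v = np.zeros(3)
        dt = 5.0e-5
        t = 0.0
        errs, times = [], []
        state = tp.EmbolusState(position=x.copy(), velocity=v, time=t,
                                current_segment="tube")
        for _ in range(400):
            acc = tp.hydrodynamic_acceleration(state, tube_field, props, fluid)
            state.velocity = state.velocity + acc * dt
            state.position = state.position + state.velocity * dt
            state.time += dt
            errs.append(np.linalg.norm(
                tube_field.velocity(state.position, state.time, "tube")
                - state.velocity))
            times.append(state.time)
        errs = np.array(errs)
        times = np.array(times)
        mask = errs > 1e-3 * np.linalg.norm(u0)
        slope = np.polyfit(times[mask], np.log(errs[mask]), 1)[0]
        return -1.0 / slope

    def test_efolding_matches_bare_stokes_time(self, tube_field, fluid):
        """Without added mass the velocity error decays on the bare response
        time rho_p d^2 / (18 mu) to within 1%."""
        props = tp.EmbolusProperties(added_mass_coefficient=0.0, lift=False)
        tau = tp.momentum_response_time(props, fluid)
        assert self._efold(props, fluid, tube_field) == pytest.approx(tau, rel=0.01)

    def test_added_mass_slows_relaxation(self, tube_field, fluid):
        props = tp.EmbolusProperties(lift=False)
        tau = tp.momentum_response_time(props, fluid)
        tau_eff = tau * (props.rho_p + 0.5 * fluid.rho) / props.rho_p
        assert self._efold(props, fluid, tube_field) == pytest.approx(
            tau_eff, rel=0.01
        )


class TestWallCollision:
    def test_dry_limit_recovers_e0(self, fluid):
        props = tp.EmbolusProperties()
        assert tp.effective_restitution(1.0e9, props, fluid) == pytest.approx(
            props.restitution_dry, rel=1e-4
        )

    def test_slow_impacts_fully_damped(self, fluid):
        props = tp.EmbolusProperties()
        # impact Stokes number at the critical threshold
        v_crit = props.critical_impact_stokes * 9 * fluid.mu / (
            props.rho_p * props.d_mm
        )
        assert tp.effective_restitution(0.5 * v_crit, props, fluid) == 0.0
        state = tp.EmbolusState(position=np.zeros(3),
                                velocity=np.array([10.0, 0.5 * v_crit, 0.0]),
                                time=0.0)
        out = tp.resolve_wall_collision(state, [0.0, 1.0, 0.0],
                                        props, fluid)
        # normal component removed, tangential preserved: deposition slide
        assert out.velocity[1] == pytest.approx(0.0)
        assert out.velocity[0] == pytest.approx(10.0)

    def test_grazing_contact_is_noop_with_warning(self, fluid):
        state = tp.EmbolusState(position=np.zeros(3),
                                velocity=np.array([5.0, -1.0, 0.0]), time=0.0)
        with pytest.warns(UserWarning):
            out = tp.resolve_wall_collision(state, [0.0, 1.0, 0.0],
                                            tp.EmbolusProperties(), fluid)
        np.testing.assert_array_equal(out.velocity, state.velocity)

    @settings(max_examples=50, deadline=None)
    @given(v_n=st.floats(1.0, 5000.0), v_t=st.floats(-2000.0, 2000.0))
    def test_collision_dissipates_energy(self, v_n, v_t):
        fluid = hemo.FluidProperties()
        props = tp.EmbolusProperties()
        state = tp.EmbolusState(position=np.zeros(3),
                                velocity=np.array([v_t, v_n, 0.0]), time=0.0)
        out = tp.resolve_wall_collision(state, [0.0, 1.0, 0.0], props, fluid)
        assert np.dot(out.velocity, out.velocity) <= np.dot(
            state.velocity, state.velocity
        ) + 1e-9
        # restitution never exceeds the dry coefficient
        assert abs(out.velocity[1]) <= props.restitution_dry * v_n + 1e-9


class TestTrajectoryIntegration:
    def test_straight_tube_transit_time(self, tube_field, fluid):
        rec = tp.advance_and_integrate(
            [0.0, 0.0, 2.0], 0.0, tube_field, tp.EmbolusProperties(), fluid,
            tp.IntegrationPolicy(base_cycles=3),
        )
        assert rec.status == "exited"
        assert rec.exit_outlet == "tube_out"
        v_center = 2.0 * 10.0e3 / (np.pi * 9.0)
        assert rec.exit_time == pytest.approx(98.0 / v_center, rel=0.02)

    def test_release_outside_lumen_rejected(self, tube_field, fluid):
        with pytest.raises(ValueError):
            tp.advance_and_integrate([0.0, 2.9, 2.0], 0.0, tube_field,
                                     tp.EmbolusProperties(), fluid)

    def test_exhausted_horizon_is_unresolved(self, tube_network, fluid):
        slow = hemo.CardiacWaveform(mean_flow=0.3,
                                    shape=lambda ph: np.ones_like(ph))
        res = hemo.OutletResistanceSet(resistances={"tube_out": 1.0})
        sol = hemo.solve_unsteady(tube_network, slow, res, fluid)
        field = hemo.segment_velocity_field(sol, tube_network, fluid)
        rec = tp.advance_and_integrate(
            [0.0, 2.7, 5.0], 0.0, field, tp.EmbolusProperties(), fluid,
            tp.IntegrationPolicy(base_cycles=1, extension_cycles=0),
        )
        assert rec.status == "unresolved"
        assert rec.exit_outlet is None

    def test_tracer_limit_matches_pathline_oracle(self, fluid):
        """Neutrally buoyant drag-only particle follows the pathline computed
        by high-order integration of u to within 0.5% of the path length."""
        net = straight_tube_network(radius=3.0, length=160.0)
        wave = hemo.CardiacWaveform(mean_flow=6.0)  # pulsatile
        res = hemo.OutletResistanceSet(resistances={"tube_out": 1.0})
        sol = hemo.solve_unsteady(net, wave, res, fluid)
        field = hemo.segment_velocity_field(sol, net, fluid)
        x0 = np.array([0.0, 1.2, 5.0])
        T = wave.period

        def rhs(t, x):
            return field.velocity(x, t, "tube")

        oracle = solve_ivp(rhs, (0.0, T), x0, rtol=1e-9, atol=1e-10,
                           dense_output=True)
        props = tp.EmbolusProperties(density_g_cc=fluid.density_g_cc,
                                     lift=False, added_mass_coefficient=0.0)
        x = x0.copy()
        v = field.velocity(x, 0.0, "tube").copy()
        dt = 5.0e-5
        state = tp.EmbolusState(position=x, velocity=v, time=0.0,
                                current_segment="tube")
        n_steps = int(round(T / dt))
        for _ in range(n_steps):
            acc = tp.hydrodynamic_acceleration(state, field, props, fluid)
            state.velocity = state.velocity + acc * dt
            state.position = state.position + state.velocity * dt
            state.time += dt
        path_len = np.abs(oracle.y[2, -1] - x0[2])
        err = np.linalg.norm(state.position - oracle.y[:, -1])
        assert err < 0.005 * path_len

    def test_batch_equals_per_particle_integration(self, tube_field, fluid):
        """Particles are independent: batch results are identical to
        integrating each trajectory on its own (order independence)."""
        rng = np.random.default_rng(3)
        n = 8
        pos = np.column_stack([
            rng.uniform(-1.5, 1.5, n), rng.uniform(-1.5, 1.5, n),
            np.full(n, 5.0),
        ])
        t0s = rng.uniform(0.0, 0.83, n)
        vels = np.array([tube_field.velocity(p, t, "tube")
                         for p, t in zip(pos, t0s)])
        props = tp.EmbolusProperties()
        pol = tp.IntegrationPolicy(base_cycles=2)
        batch, _ = tp.integrate_batch(tube_field, pos, vels, t0s, props, fluid,
                                      pol, segments=["tube"] * n)
        for i in range(n):
            single, _ = tp.integrate_batch(
                tube_field, pos[i:i + 1], vels[i:i + 1], t0s[i:i + 1],
                props, fluid, pol, segments=["tube"],
            )
            assert single[0].exit_outlet == batch[i].exit_outlet
            assert single[0].exit_time == batch[i].exit_time
            assert single[0].collision_count == batch[i].collision_count

    def test_field_is_immutable_under_integration(self, tube_field, fluid):
        """One-way coupling at the API level: integrating particles can never
        modify the velocity field arrays."""
        with pytest.raises((ValueError, RuntimeError)):
            tube_field._a["Q"][0, 0] = 999.0
        before = tube_field._a["Q"].copy()
        tp.advance_and_integrate([0.0, 0.0, 2.0], 0.0, tube_field,
                                 tp.EmbolusProperties(), fluid,
                                 tp.IntegrationPolicy(base_cycles=1))
        np.testing.assert_array_equal(before, tube_field._a["Q"])


class TestStepSizeRobustness:
    def test_halving_dt_preserves_destination_distribution(self, baseline,
                                                           baseline_field,
                                                           fluid):
        """Halving the Euler step leaves the outlet destination distribution
        unchanged within sampling noise.

        Individual near-wall trajectories decorrelate through the siphon's
        secondary-flow mixing (chaotic advection), so robustness is asserted
        at the distribution level: the total variation distance between the
        outlet histograms at dt and dt/2 stays small.
        """
        from collections import Counter

        from embotrace import runner

        n = 150
        samples = runner.sample_release(
            "left_carotid", baseline, baseline_field, n,
            tp.EmbolusProperties().radius_mm, seed=11,
        )
        pos = np.array([s.position for s in samples])
        t0s = np.array([s.release_time for s in samples])
        segs = [s.segment for s in samples]
        vels = np.array([baseline_field.velocity(p, t, segment_hint=sg)
                         for p, t, sg in zip(pos, t0s, segs)])
        props = tp.EmbolusProperties()
        hists = {}
        for dt in (5.0e-5, 2.5e-5):
            recs, _ = tp.integrate_batch(
                baseline_field, pos, vels, t0s, props, fluid,
                tp.IntegrationPolicy(dt=dt, base_cycles=5, extension_cycles=0),
                segments=segs,
            )
            hists[dt] = Counter(r.exit_outlet for r in recs)
        keys = set(hists[5.0e-5]) | set(hists[2.5e-5])
        tv = 0.5 * sum(
            abs(hists[5.0e-5][k] - hists[2.5e-5][k]) for k in keys
        ) / n
        assert tv <= 0.12
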