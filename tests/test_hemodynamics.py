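"""Network hemodynamics: scalar formulas, resistance tuning, pulsatile
solve, velocity reconstruction and communicator flow maps."""

import numpy as np
import pytest

from embotrace import hemodynamics as hemo
from embotrace import vasculature as vas

from conftest import straight_tube_network, y_network


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "sys_p, dia_p, expected",
        [(120.0, 80.0, 93.33), (100.0, 100.0, 100.0), (90.0, 60.0, 70.0)],
    )
    def test_mean_arterial_pressure(self, sys_p, dia_p, expected):
        assert hemo.mean_arterial_pressure(sys_p, dia_p) == pytest.approx(
            expected, abs=0.005
        )

    def test_map_rejects_inverted_pressures(self):
        with pytest.raises(ValueError):
            hemo.mean_arterial_pressure(80.0, 120.0)

    @pytest.mark.parametrize(
        "map_mmhg, co, expected",
        [(93.33, 79.0, 1.1814), (93.33, 93.33, 1.0)],
    )
    def test_total_arterial_resistance(self, map_mmhg, co, expected):
        assert hemo.total_arterial_resistance(map_mmhg, co) == pytest.approx(
            expected, rel=1e-4
        )

    def test_tar_homogeneity(self):
        assert hemo.total_arterial_resistance(93.33, 158.0) == pytest.approx(
            hemo.total_arterial_resistance(93.33, 79.0) / 2.0
        )


class TestWaveform:
    def test_cycle_average_equals_cardiac_output(self, waveform):
        t = np.linspace(0.0, waveform.period, 20000, endpoint=False)
        assert np.mean(waveform.flow(t)) == pytest.approx(79.0, rel=1e-3)

    def test_periodicity(self, waveform):
        t = np.linspace(0.0, waveform.period, 100, endpoint=False)
        np.testing.assert_allclose(
            waveform.flow(t), waveform.flow(t + waveform.period), rtol=1e-12
        )


class TestTargets:
    def test_descending_aorta_default_fraction(self, baseline):
        tg = hemo.target_flow_splits(baseline)
        assert tg.fractions["descending_aorta"] == pytest.approx(0.65)

    def test_fractions_sum_to_one(self, baseline):
        tg = hemo.target_flow_splits(baseline)
        assert sum(tg.fractions.values()) == pytest.approx(1.0)

    def test_residual_split_proportional_to_area(self, baseline):
        tg = hemo.target_flow_splits(baseline)
        # subclavian outlet radius 4.0 mm vs ECA outlet radius 1.8 mm
        ratio = tg.fractions["l_subclavian"] / tg.fractions["l_eca"]
        assert ratio == pytest.approx((4.0 / 1.8) ** 2, rel=1e-6)

    def test_overcommitted_fractions_rejected(self, baseline):
        with pytest.raises(vas.ConfigurationError):
            hemo.target_flow_splits(baseline, {"descending_aorta_fraction": 0.99})


class TestResistanceTuning:
    def test_outlet_fractions_hit_targets(self, baseline, waveform, fluid,
                                          tuned_resistances, baseline_solution):
        tg = hemo.target_flow_splits(baseline)
        means = baseline_solution.outlet_cycle_means()
        co = waveform.mean_flow
        for outlet, frac in tg.fractions.items():
            assert means[outlet] / co == pytest.approx(frac, rel=0.01)

    def test_symmetric_outlets_get_equal_resistance(self, tuned_resistances):
        r = tuned_resistances.resistances
        assert r["l_mca"] == pytest.approx(r["r_mca"], rel=0.01)
        assert r["l_subclavian"] == pytest.approx(r["r_subclavian"], rel=0.01)

    def test_inlet_pressure_matches_map(self, baseline, waveform, fluid,
                                        tuned_resistances):
        _, p, _ = hemo.steady_solve(baseline, waveform.mean_flow,
                                    tuned_resistances, fluid)
        assert p[baseline.inlet] == pytest.approx(93.33, rel=0.01)

    def test_raising_a_target_lowers_its_resistance(self, baseline, waveform, fluid):
        tg_lo = hemo.target_flow_splits(baseline)
        cer = dict(hemo.DEFAULT_CEREBRAL_FRACTIONS)
        cer["l_mca"] += 0.01
        cer["r_mca"] -= 0.01
        tg_hi = hemo.target_flow_splits(baseline, {"cerebral_fractions": cer})
        r_lo = hemo.tune_outlet_resistances(baseline, tg_lo, waveform, fluid)
        r_hi = hemo.tune_outlet_resistances(baseline, tg_hi, waveform, fluid)
        assert r_hi.resistances["l_mca"] < r_lo.resistances["l_mca"]


class TestUnsteadySolve:
    def test_single_tube_is_ohmic(self, fluid):
        net = straight_tube_network(radius=3.0, length=100.0)
        res = hemo.OutletResistanceSet(resistances={"tube_out": 2.0})
        wave = hemo.CardiacWaveform(mean_flow=10.0,
                                    shape=lambda ph: np.ones_like(ph))
        sol = hemo.solve_unsteady(net, wave, res, fluid)
        # Poiseuille segment resistance: 8 mu L / (pi r^4) ~ 0.094 mmHg.s/mL
        r_seg = 8 * fluid.mu * 100.0 / (np.pi * 3.0**4) * 1e3 / hemo.MMHG_TO_G_MM_S2
        p_in = sol.node_pressure["inlet"][0]
        assert p_in == pytest.approx(10.0 * (r_seg + 2.0), rel=1e-9)
        assert r_seg * 10.0 == pytest.approx(0.94, abs=0.01)

    def test_two_identical_branches_split_evenly(self, fluid, waveform):
        net = y_network()
        res = hemo.OutletResistanceSet(resistances={"left_out": 3.0, "right_out": 3.0})
        sol = hemo.solve_unsteady(net, waveform, res, fluid)
        np.testing.assert_allclose(
            sol.segment_flow["left"], sol.segment_flow["right"], rtol=1e-12
        )

    def test_mass_conservation(self, baseline_solution, waveform):
        assert baseline_solution.mass_residual < 1e-9 * waveform.mean_flow

    def test_occluded_segment_carries_no_flow(self, baseline, waveform,
                                              tuned_resistances, fluid):
        net = vas.build_model_network(baseline, vas.ModelSpec(100.0, 50.0))
        sol = hemo.solve_unsteady(net, waveform, tuned_resistances, fluid)
        assert np.all(sol.segment_flow["l_internal_carotid"] == 0.0)

    def test_disconnected_outlet_raises(self, fluid, waveform):
        net = straight_tube_network()
        net.outlets["ghost"] = "nowhere"
        res = hemo.OutletResistanceSet(resistances={"tube_out": 1.0, "ghost": 1.0})
        with pytest.raises(vas.ConfigurationError, match="nowhere"):
            hemo.solve_unsteady(net, waveform, res, fluid)

    def test_inlet_flow_follows_waveform(self, baseline_solution, waveform):
        q_root = baseline_solution.segment_flow["aortic_root"]
        np.testing.assert_allclose(
            q_root, waveform.flow(baseline_solution.times), rtol=1e-9
        )

    def test_outlet_fractions_stable_across_stenosis_models(
        self, baseline, waveform, tuned_resistances, fluid, baseline_solution
    ):
        """Fixed outlet resistances keep outlet flow fractions nearly
        constant while stenosis reroutes the cervical supply."""
        base_means = baseline_solution.outlet_cycle_means()
        net = vas.build_model_network(baseline, vas.ModelSpec(40.0, 85.0))
        sol = hemo.solve_unsteady(net, waveform, tuned_resistances, fluid)
        means = sol.outlet_cycle_means()
        for outlet in base_means:
            assert means[outlet] == pytest.approx(base_means[outlet], rel=0.15)
        # ... while the right ICA supply collapses and collaterals take over
        assert sol.cycle_mean("r_internal_carotid") < 0.3 * (
            baseline_solution.cycle_mean("r_internal_carotid")
        )

    def test_monotone_cervical_recruitment(self, baseline, waveform,
                                           tuned_resistances, fluid):
        """Sweeping left severity at fixed right severity, the left ICA share
        of total cerebral blood flow is non-increasing and the compensating
        share non-decreasing."""
        lica, comp = [], []
        for sev in (0.0, 50.0, 70.0, 85.0):
            net = baseline if sev == 0 else vas.build_model_network(
                baseline, vas.ModelSpec(sev, 10.0)
            )
            sol = hemo.solve_unsteady(net, waveform, tuned_resistances, fluid)
            cm = hemo.communicator_flow_map(sol, net)
            lica.append(cm["lica_fraction_tcbf"])
            comp.append(cm["rica_fraction_tcbf"] + cm["ba_fraction_tcbf"])
        assert all(a >= b - 1e-9 for a, b in zip(lica, lica[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(comp, comp[1:]))


class TestVelocityField:
    def test_centerline_velocity_twice_mean(self, tube_field):
        u = tube_field.velocity([0.0, 0.0, 50.0], 0.0)
        v_mean = 10.0e3 / (np.pi * 3.0**2)
        assert u[2] == pytest.approx(2.0 * v_mean, rel=1e-6)

    def test_no_slip_at_wall(self, tube_field):
        u = tube_field.velocity([0.0, 2.999999, 50.0], 0.0)
        assert np.linalg.norm(u) < 1e-2

    def test_flux_quadrature_matches_segment_flow(self, tube_field):
        flux = hemo.cross_section_flux(tube_field, "tube", 50.0, 0.0)
        assert flux == pytest.approx(10.0, rel=1e-3)

    def test_inlet_cycle_average_is_cardiac_output(self, baseline_field):
        q = hemo.cycle_average_flux(baseline_field, "aortic_root", 2.0, n_time=16)
        assert q == pytest.approx(79.0, rel=0.01)

    def test_stenosis_throat_velocity_amplification(self, baseline, waveform,
                                                    tuned_resistances, fluid):
        """At equal flow, throat centerline velocity scales like the inverse
        throat area, i.e. about 1/(1-s)^2."""
        net = vas.build_model_network(baseline, vas.ModelSpec(85.0, 0.0))
        sol = hemo.solve_unsteady(net, waveform, tuned_resistances, fluid)
        field = hemo.segment_velocity_field(sol, net, fluid)
        seg = net.segments["l_internal_carotid"]
        i_throat = int(np.argmin(seg.radii))
        s_throat = float(seg.arclengths[i_throat])
        s_ref = 55.0  # outside the taper and both junction blend zones
        c_t, t_t, r_t = field.section_frame("l_internal_carotid", s_throat)
        c_r, t_r, r_r = field.section_frame("l_internal_carotid", s_ref)
        t = 0.1
        w_t = np.dot(field.velocity(c_t, t, "l_internal_carotid"), t_t)
        w_r = np.dot(field.velocity(c_r, t, "l_internal_carotid"), t_r)
        assert w_t / w_r == pytest.approx((r_r / r_t) ** 2, rel=0.05)

    def test_taper_field_divergence_integral(self, baseline, waveform,
                                             tuned_resistances, fluid):
        """Net flux imbalance over a sub-volume of the stenosis taper stays
        below 1% of the throughflow."""
        net = vas.build_model_network(baseline, vas.ModelSpec(50.0, 0.0))
        sol = hemo.solve_unsteady(net, waveform, tuned_resistances, fluid)
        field = hemo.segment_velocity_field(sol, net, fluid)
        q_in = hemo.cross_section_flux(field, "l_internal_carotid", 12.0, 0.2)
        q_out = hemo.cross_section_flux(field, "l_internal_carotid", 22.0, 0.2)
        q_ref = sol.segment_flow["l_internal_carotid"][
            int(0.2 / (sol.times[1] - sol.times[0]))
        ]
        assert abs(q_out - q_in) < 0.01 * abs(q_ref)

    def test_out_of_domain_flagged(self, tube_field):
        smp = tube_field.sample([0.0, 10.0, 50.0], 0.0, "tube")
        assert smp["out_of_domain"]


class TestCommunicatorFlowMap:
    def test_symmetric_network_zero_acoa(self, fluid, waveform):
        sym = vas.build_baseline_network({"symmetric_arch": True})
        tg = hemo.target_flow_splits(sym)
        res = hemo.tune_outlet_resistances(sym, tg, waveform, fluid)
        net = vas.build_model_network(sym, vas.ModelSpec(50.0, 50.0))
        sol = hemo.solve_unsteady(net, waveform, res, fluid)
        cm = hemo.communicator_flow_map(sol, net)
        assert abs(cm["acoa"]) < 1e-6 * 79.0 * 60.0

    def test_acoa_directed_toward_severe_side_and_grows(self, baseline, waveform,
                                                        tuned_resistances, fluid):
        mags = []
        for sev in (50.0, 70.0, 85.0):
            net = vas.build_model_network(baseline, vas.ModelSpec(sev, 10.0))
            sol = hemo.solve_unsteady(net, waveform, tuned_resistances, fluid)
            cm = hemo.communicator_flow_map(sol, net)
            # positive = right -> left: toward the severely stenosed left side
            assert cm["acoa"] > 0
            mags.append(cm["acoa"])
        assert mags == sorted(mags)

    def test_cervical_fractions_sum_to_one(self, baseline_solution, baseline):
        cm = hemo.communicator_flow_map(baseline_solution, baseline)
        total = (cm["lica_fraction_tcbf"] + cm["rica_fraction_tcbf"]
                 + cm["ba_fraction_tcbf"])
        assert total == pytest.approx(1.0, rel=1e-9)
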