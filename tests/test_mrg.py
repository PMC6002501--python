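import numpy as np
import pytest

from stimfem.mrg import (MRG_GEOMETRY_TABLE, MembraneParameters,
                         StimulusWaveform, build_fiber, resting_state,
                         simulate, steady_gates)
from stimfem.postprocess import sample_axon_path


@pytest.fixture(scope="module")
def params():
    return MembraneParameters()


class TestFiberGeometry:
    def test_node_count_follows_internodal_spacing(self):
        # 20 mm at the published 500 um internode: 41 nodes, odd
        f = build_fiber(5.7)
        assert f.n_nodes == int(20000 // 500) + 1 == 41
        assert f.n_nodes % 2 == 1

    @pytest.mark.parametrize("d", [2.0, 5.7, 10.0])
    def test_compartments_tile_fiber_exactly_with_center_node(self, d):
        f = build_fiber(d)
        assert f.length.sum() == pytest.approx(20000.0, abs=1e-9)
        assert f.n_nodes % 2 == 1
        x = f.compartment_x_mm()
        center = f.node_indices()[f.n_nodes // 2]
        assert x[center] == pytest.approx(0.0, abs=1e-9)

    def test_internode_composition(self):
        f = build_fiber(5.7)
        # node, MYSA, FLUT, 6x STIN, FLUT, MYSA per internode
        kinds = f.kind[:12]
        assert list(kinds) == [0, 1, 2, 3, 3, 3, 3, 3, 3, 2, 1, 0]

    def test_builds_are_deterministic(self):
        a, b = build_fiber(10.0), build_fiber(10.0)
        np.testing.assert_array_equal(a.length, b.length)
        np.testing.assert_array_equal(a.kind, b.kind)

    def test_unsupported_diameter_and_short_fiber_rejected(self):
        with pytest.raises(ValueError, match="diameter"):
            build_fiber(6.5)
        with pytest.raises(ValueError, match="internodal"):
            build_fiber(10.0, length_mm=2.0)

    def test_small_diameter_entry_is_flagged_extrapolated(self):
        assert build_fiber(2.0).extrapolated
        assert not build_fiber(5.7).extrapolated

    def test_yaml_summary(self):
        text = build_fiber(5.7).to_yaml()
        assert "internodal_length_um: 500" in text


class TestMembraneDynamics:
    def test_gates_at_rest_are_interior_probabilities(self, params):
        m, h, p, s = steady_gates(np.array(-80.0))
        for g in (m, h, p, s):
            assert 0.0 < float(g) < 1.0

    def test_resting_state_is_stationary_for_ten_ms(self, params):
        f = build_fiber(5.7)
        rs = resting_state(f, params)
        res = simulate(f, params, np.zeros(f.n_compartments),
                       StimulusWaveform(), 0.0, duration_ms=10.0,
                       initial_state=rs)
        assert not res.activated
        drift = np.abs(res.sentinel_vm - res.sentinel_vm[0]).max()
        assert drift < 1.0   # mV

    def test_zero_amplitude_never_activates(self, params, gold_solution):
        f = build_fiber(10.0)
        ve = sample_axon_path(gold_solution, 0.75,
                              f.compartment_x_mm()).potentials
        res = simulate(f, params, ve, StimulusWaveform(), 0.0,
                       initial_state=resting_state(f, params))
        assert not res.activated

    def test_strong_cathodic_pulse_reaches_both_sentinels(self, params,
                                                          gold_solution):
        f = build_fiber(5.7)
        ve = sample_axon_path(gold_solution, 0.05,
                              f.compartment_x_mm()).potentials
        rs = resting_state(f, params)
        res = simulate(f, params, ve, StimulusWaveform(), 2000.0,
                       initial_state=rs, record=True)
        assert res.activated
        # the propagating spike reaches the sentinel on each side
        assert res.sentinel_vm[:, 0].max() > 0.0
        assert res.sentinel_vm[:, 1].max() > 0.0
        # gating variables stay within [0, 1] throughout strong stimulation
        for g in res.final_state["gates"]:
            assert np.all(g >= 0.0) and np.all(g <= 1.0)

    def test_activation_monotone_in_amplitude_around_threshold(
            self, params, gold_solution, gold_report):
        from stimfem.threshold import find_threshold
        f = build_fiber(5.7)
        ve = sample_axon_path(gold_solution, 0.75,
                              f.compartment_x_mm()).potentials
        rs = resting_state(f, params)
        T0 = gold_report.thresholds_uA[(5.7, 0.75)]
        T = find_threshold(f, params, ve, initial_state=rs,
                           bracket=(T0 * 0.7, T0 * 1.4)).threshold_uA
        for amp in (T - 5, T - 1):
            assert not simulate(f, params, ve, StimulusWaveform(), amp,
                                initial_state=rs).activated
        for amp in (T, T + 1, T + 5, T + 60):
            assert simulate(f, params, ve, StimulusWaveform(), amp,
                            initial_state=rs).activated

    def test_threshold_stable_under_time_step_refinement(
            self, params, gold_solution, gold_report):
        from stimfem.threshold import SearchSettings, find_threshold
        f = build_fiber(5.7)
        ve = sample_axon_path(gold_solution, 0.75,
                              f.compartment_x_mm()).potentials
        rs = resting_state(f, params)
        T0 = gold_report.thresholds_uA[(5.7, 0.75)]
        base = find_threshold(f, params, ve, initial_state=rs,
                              bracket=(T0 * 0.7, T0 * 1.4)).threshold_uA
        fine = find_threshold(f, params, ve,
                              settings=SearchSettings(dt_us=1.0,
                                                      dt_after_us=5.0),
                              initial_state=rs,
                              bracket=(base * 0.8, base * 1.25))
        assert abs(fine.threshold_uA - base) <= 1.0

    def test_waveform_is_charge_balanced_cathodic_first(self):
        w = StimulusWaveform()
        t = np.linspace(0.0005, 0.5, 2000)
        s = w.scale(t)
        assert s[0] == -1.0                        # cathodic phase first
        assert abs(np.trapezoid(s, t)) < 1e-3      # zero net charge
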