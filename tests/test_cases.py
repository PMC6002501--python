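import numpy as np
import pytest

from stimfem.cases import (CaseSpec, FiberBank, ModelContext,
                           field_for_case, load_case_table, percent_errors,
                           error_stats, run_case, verify_threshold_identity)
from stimfem.postprocess import sample_axon_path


@pytest.fixture(scope="module")
def tiny_ctx():
    return ModelContext(resolution="tiny")


class TestCaseTables:
    @pytest.mark.parametrize("figure,count", [("fig2", 28), ("fig3", 20),
                                              ("fig4", 8)])
    def test_tables_load_with_expected_case_counts(self, figure, count):
        specs = load_case_table(figure)
        assert len(specs) == count
        assert sum(s.gold_standard for s in specs) in (1, 2)

    def test_commercial_solver_anomalies_are_flagged_not_modelled(self):
        fig2 = {s.case_id: s for s in load_case_table("fig2")}
        assert fig2["16"].known_solver_artifact
        assert fig2["16"].source_model == "ep"
        fig3 = {s.case_id: s for s in load_case_table("fig3")}
        assert fig3["19"].known_solver_artifact
        assert fig3["20"].known_solver_artifact

    def test_point_source_without_contact_domain_is_invalid(self):
        with pytest.raises(ValueError, match="conductive contact"):
            CaseSpec(case_id="x", source_model="pcs",
                     contact_model="no_thin_domain")


class TestErrorStatistics:
    def test_gold_standard_against_itself_is_zero_error(self, gold_report,
                                                        coarse_ctx,
                                                        fiber_bank):
        errors = percent_errors(gold_report.thresholds_uA,
                                gold_report.thresholds_uA)
        mean, sd, mx = error_stats(errors)
        assert (mean, sd, mx) == (0.0, 0.0, 0.0)
        # and the definitional certificate holds on the solved field
        sol = field_for_case(CaseSpec(case_id="gold"), coarse_ctx)
        ok = verify_threshold_identity(sol, fiber_bank,
                                       gold_report.thresholds_uA)
        assert all(ok.values())

    def test_thresholds_ordered_by_diameter_and_distance(self, gold_report):
        T = gold_report.thresholds_uA
        for d in (2.0, 5.7, 10.0):
            assert T[(d, 0.05)] < T[(d, 0.75)] < T[(d, 2.0)]
        for z in (0.05, 0.75, 2.0):
            assert T[(10.0, z)] < T[(5.7, z)] < T[(2.0, z)]


class TestSuperpositionMechanics:
    def test_monopolar_pattern_superposition_equals_direct_solve(
            self, tiny_ctx):
        spec_a = CaseSpec(case_id="a", superposition_mode="none",
                          current_pattern=(1.0, 0.0))
        spec_b = CaseSpec(case_id="b",
                          superposition_mode="superposition_A_floating",
                          current_pattern=(1.0, 0.0))
        va = field_for_case(spec_a, tiny_ctx).V
        vb = field_for_case(spec_b, tiny_ctx).V
        np.testing.assert_allclose(vb, va, rtol=1e-9, atol=1e-12)

    def test_superposition_A_matches_simultaneous_but_B_does_not(
            self, tiny_ctx):
        sim = field_for_case(CaseSpec(
            case_id="sim", superposition_mode="simultaneous",
            current_pattern=(1.0, -1.0)), tiny_ctx)
        supA = field_for_case(CaseSpec(
            case_id="supA", superposition_mode="superposition_A_floating",
            current_pattern=(1.0, -1.0)), tiny_ctx)
        supB = field_for_case(CaseSpec(
            case_id="supB", superposition_mode="superposition_B_grounded",
            current_pattern=(1.0, -1.0)), tiny_ctx)
        x = np.linspace(-9, 9, 61)
        for z in (0.05, 0.75):
            a = sample_axon_path(sim, z, x).potentials
            b = sample_axon_path(supA, z, x).potentials
            c = sample_axon_path(supB, z, x).potentials
            scale = np.abs(a).max()
            assert np.abs(b - a).max() / scale < 1e-3
            assert np.abs(c - a).max() / scale > 0.02

    def test_ep_simultaneous_bipolar_misdelivers_current(self, tiny_ctx):
        """With both contacts at calibrated voltages, each contact's field
        shifts the other's delivered current away from +/-1 mA."""
        spec = CaseSpec(case_id="ep_sim", source_model="ep",
                        superposition_mode="simultaneous",
                        current_pattern=(1.0, -1.0))
        from stimfem.fem import symmetry_factor
        sol = field_for_case(spec, tiny_ctx)
        op = sol.operator
        fac = symmetry_factor(sol.mesh)
        delivered = []
        for k in (0, 1):
            dofs = op.facet_set_dofs(f"contact_{k}_exposed")
            delivered.append(float(sol.residual[dofs].sum()) * 1e3 * fac)
        # net current nearly balances (x antisymmetry, up to solver
        # tolerance) while each contact individually misses its target
        assert delivered[0] + delivered[1] == pytest.approx(0.0, abs=5e-3)
        assert abs(abs(delivered[0]) - 1.0) > 0.01


class TestMultipolar:
    def test_2x2_superposition_A_equals_simultaneous(self, tiny_ctx):
        for pattern in [(1.0, -1.0, 1.0, -1.0), (1.0, 1.0, 1.0, 1.0)]:
            sim = field_for_case(CaseSpec(
                case_id="m_sim", figure="fig4",
                superposition_mode="simultaneous",
                current_pattern=pattern), tiny_ctx)
            sup = field_for_case(CaseSpec(
                case_id="m_sup", figure="fig4",
                superposition_mode="superposition_A_floating",
                current_pattern=pattern), tiny_ctx)
            x = np.linspace(-9, 9, 61)
            for z in (0.05, 0.75):
                a = sample_axon_path(sim, z, x).potentials
                b = sample_axon_path(sup, z, x).potentials
                assert np.abs(b - a).max() / np.abs(a).max() < 1e-3
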