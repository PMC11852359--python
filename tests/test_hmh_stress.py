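"""HMH equivalent stress, stress recovery and the component summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cytomech.geometry import REGION_CORTEX, REGION_ECM, REGION_NUCLEUS, build_box_mesh
from cytomech.materials import MaterialSpec
from cytomech.assembly import FEModel
from cytomech.solver import IncrementRecord, SolverConfig, SystemState, solve_linear_pressure
from cytomech.stress import (
    StressField,
    compare_scenarios,
    compute_hmh,
    recover_stress_field,
    summarize_component_stress,
)


def voigt(sx=0.0, sy=0.0, sz=0.0, txy=0.0, tyz=0.0, tzx=0.0):
    return np.array([[sx, txy, tzx], [txy, sy, tyz], [tzx, tyz, sz]])


class TestHmh:
    def test_uniaxial(self):
        assert compute_hmh(voigt(sx=5.0)) == pytest.approx(5.0, abs=1e-12)

    def test_hydrostatic_is_zero(self):
        assert compute_hmh(voigt(sx=3.0, sy=3.0, sz=3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear(self):
        assert compute_hmh(voigt(txy=1.0)) == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_plane_stress_input_promoted(self):
        s2 = np.array([[5.0, 0.0], [0.0, 0.0]])
        assert compute_hmh(s2) == pytest.approx(5.0, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        S = A + A.T
        R = Rotation.random(random_state=int(seed % (2**31))).as_matrix()
        assert compute_hmh(R @ S @ R.T) == pytest.approx(compute_hmh(S), rel=1e-10)

    @given(st.integers(0, 2**32 - 1), st.floats(-1e3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_absolute_homogeneity(self, seed, lam):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        S = A + A.T
        assert compute_hmh(lam * S) == pytest.approx(abs(lam) * compute_hmh(S), rel=1e-10, abs=1e-12)


class TestRecovery:
    def test_zero_state_all_zero_field(self, single_mesh):
        mats = MaterialSpec.defaults("stiff").with_prestress(0.0)
        model = FEModel(single_mesh, mats, 0.0)
        state = SystemState(
            displacements=np.zeros((single_mesh.n_nodes, 3)),
            prestress_scale=0.0,
            load_scale=0.0,
            record=IncrementRecord(step=1, increment=1, converged=True, prestress_scale=0, load_scale=0),
        )
        field = recover_stress_field(model, state)
        assert np.allclose(field.tet_stress, 0) and np.allclose(field.tri_stress, 0)
        # machine-epsilon strains are amplified by the GPa fibre moduli
        assert np.allclose(field.bar_s11, 0, atol=1e-5)

    def test_unconverged_state_refused(self, single_mesh):
        mats = MaterialSpec.defaults("stiff")
        model = FEModel(single_mesh, mats, 6.0)
        bad = SystemState(
            displacements=np.zeros((single_mesh.n_nodes, 3)),
            prestress_scale=1.0,
            load_scale=1.0,
            record=IncrementRecord(step=2, increment=8, converged=False, prestress_scale=1, load_scale=1),
        )
        with pytest.raises(ValueError):
            recover_stress_field(model, bad)

    def test_confined_compression_hmh_uniform(self):
        mesh = build_box_mesh([[0, 0, 0], [40e-6] * 3], (3, 4, 3))
        mats = MaterialSpec.defaults("stiff")
        model = FEModel(mesh, mats, 6.0)
        state = solve_linear_pressure(mesh, mats, 6.0, model=model)
        field = recover_stress_field(model, state)
        nu = mats.ecm.poisson_ratio
        expect = 6.0 * (1 - 2 * nu) / (1 - nu)
        assert np.allclose(field.tet_hmh, expect, rtol=1e-6)

    def test_in_cell_prestressed_tendons_tensile_bars_compressive(self, solved_single):
        """After the prestress step (no pressure yet) the embedded
        cytoskeleton carries tension in tendons and compression in bars."""
        data = solved_single["stiff"]
        prestress_end = data["history"][1]  # last prestress increment
        assert prestress_end.load_scale == 0.0
        field = recover_stress_field(data["model"], prestress_end)
        mesh = data["model"].mesh
        from cytomech.geometry import REGION_ACTIN_TENDON, REGION_MICROTUBULE_BAR

        tendon = field.bar_s11[mesh.bar_tags == REGION_ACTIN_TENDON]
        bar = field.bar_s11[mesh.bar_tags == REGION_MICROTUBULE_BAR]
        assert np.all(tendon > 0)
        assert np.all(bar < 0)


class TestSummary:
    def test_all_zero_field_zero_summary(self, single_mesh):
        field = StressField(
            mesh=single_mesh,
            tet_stress=np.zeros((len(single_mesh.tets), 3, 3)),
            tri_stress=np.zeros((len(single_mesh.tris), 2, 2)),
            bar_s11=np.zeros(len(single_mesh.bars)),
            displacements=np.zeros((single_mesh.n_nodes, 3)),
        )
        s = summarize_component_stress(field, single_mesh)
        assert all(v == 0.0 for v in s.max_hmh.values())
        assert s.s11_max == 0.0 and s.s11_min == 0.0

    def test_spiked_element_located_in_right_component(self, single_mesh):
        tet_stress = np.zeros((len(single_mesh.tets), 3, 3))
        nucleus_ids = np.where(single_mesh.tet_tags == REGION_NUCLEUS)[0]
        tet_stress[nucleus_ids[3]] = np.diag([123.0, 0, 0])
        field = StressField(
            mesh=single_mesh,
            tet_stress=tet_stress,
            tri_stress=np.zeros((len(single_mesh.tris), 2, 2)),
            bar_s11=np.zeros(len(single_mesh.bars)),
            displacements=np.zeros((single_mesh.n_nodes, 3)),
        )
        s = summarize_component_stress(field, single_mesh)
        assert s.max_hmh["nucleus"] == pytest.approx(123.0)
        assert s.max_hmh["ecm"] == 0.0 and s.max_hmh["cytoplasm"] == 0.0

    def test_maxima_match_brute_force_scan(self, solved_single):
        """Summary maxima equal an independent per-element linear scan."""
        for variant in ("stiff", "soft"):
            data = solved_single[variant]
            field, mesh = data["field"], data["model"].mesh
            s = data["summary"]
            # brute force over solids
            best = {}
            for i, tag in enumerate(mesh.tet_tags):
                h = compute_hmh(field.tet_stress[i])
                name = {0: "ecm", 1: "cytoplasm", 2: "nucleus"}[int(tag)]
                best[name] = max(best.get(name, -np.inf), h)
            for i, tag in enumerate(mesh.tri_tags):
                h = compute_hmh(field.tri_stress[i])
                name = {3: "cortex", 4: "nuclear_membrane"}[int(tag)]
                best[name] = max(best.get(name, -np.inf), h)
            for name, val in best.items():
                assert s.max_hmh[name] == pytest.approx(val, rel=1e-12)
            assert s.s11_max == pytest.approx(max(field.bar_s11), rel=1e-12)
            assert s.s11_min == pytest.approx(min(field.bar_s11), rel=1e-12)


class TestCompare:
    def test_identical_summaries_tie_with_unit_ratios(self, solved_single):
        import copy

        a = solved_single["stiff"]["summary"]
        b = copy.deepcopy(a)
        b.ecm_variant = "soft"
        b.scenario_id = "single-soft"
        report = compare_scenarios([a, b])
        for check in report.checks:
            assert check.ratio == pytest.approx(1.0)
            assert check.holds is None  # ties assert nothing

    def test_single_cell_orderings(self, solved_single):
        report = compare_scenarios(
            [solved_single["stiff"]["summary"], solved_single["soft"]["summary"]]
        )
        by_name = {c.name: c for c in report.checks}
        assert by_name["ecm_max_hmh_stiff_gt_soft[single]"].holds
        assert by_name["cortex_max_hmh_soft_gt_stiff[single]"].holds
        assert by_name["max_displacement_soft_gt_stiff[single]"].holds

    def test_mismatched_layout_pair_refused(self, solved_single):
        import copy

        a = solved_single["stiff"]["summary"]
        b = copy.deepcopy(solved_single["soft"]["summary"])
        del b.max_hmh["cortex"]
        with pytest.raises(ValueError):
            compare_scenarios([a, b])

    def test_duplicate_scenarios_refused(self, solved_single):
        a = solved_single["stiff"]["summary"]
        with pytest.raises(ValueError):
            compare_scenarios([a, a])
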