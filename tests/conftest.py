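import numpy as np
import pytest

from cytomech.assembly import FEModel
from cytomech.geometry import CellSpec, SceneSpec, build_scene
from cytomech.materials import MaterialSpec
from cytomech.solver import SolverConfig, run_two_step_solution
from cytomech.stress import recover_stress_field, summarize_component_stress

BOX_SIDE = 40e-6


def make_single_scene(n_surface=4, n_ecm_layers=3, pressure=6.0, **cell_kwargs):
    spec = CellSpec(
        center=np.full(3, BOX_SIDE / 2),
        mesh_resolution=2.5e-6,
        n_surface=n_surface,
        n_ecm_layers=n_ecm_layers,
        **cell_kwargs,
    )
    return SceneSpec(
        cells=[spec],
        ecm_box=[[0.0, 0.0, 0.0], [BOX_SIDE] * 3],
        pressure=pressure,
    )


@pytest.fixture(scope="session")
def single_mesh():
    """Coarse single-cell-in-box mesh shared across the suite."""
    return build_scene(make_single_scene())


@pytest.fixture(scope="session")
def solved_single(single_mesh):
    """Solved coarse single-cell scenarios, stiff and soft ECM.

    Returns variant -> dict(model, history, field, summary).
    """
    out = {}
    for variant in ("stiff", "soft"):
        materials = MaterialSpec.defaults(variant)
        model = FEModel(single_mesh, materials, 6.0)
        history = run_two_step_solution(
            single_mesh, materials, 6.0, SolverConfig(), model=model, check_mesh=False
        )
        field = recover_stress_field(model, history[-1])
        summary = summarize_component_stress(
            field,
            single_mesh,
            scenario_id=f"single-{variant}",
            layout="single",
            ecm_variant=variant,
        )
        out[variant] = {
            "model": model,
            "history": history,
            "field": field,
            "summary": summary,
        }
    return out
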