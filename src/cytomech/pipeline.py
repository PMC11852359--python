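"""Scenario orchestration: the {single cell, cell group} x {stiff, soft ECM}
matrix, stress summaries, ordering report and file exports."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .assembly import FEModel
from .config import RunConfig, config_hash, dump_config
from .geometry import (
    AffineTransform,
    CellSpec,
    Mesh,
    SceneSpec,
    build_scene,
    default_group_cells,
    validate_mesh,
)
from .solver import NonConvergenceError, run_two_step_solution
from .stress import (
    ComparisonReport,
    StressField,
    StressSummary,
    compare_scenarios,
    recover_stress_field,
    summarize_component_stress,
)
from .vtkio import default_field_arrays, write_vtu

__all__ = [
    "ScenarioResult",
    "MatrixResult",
    "build_scenario_scene",
    "run_scenario",
    "run_scenario_matrix",
    "export_report",
    "read_summary_tables",
    "LAYOUTS",
    "VARIANTS",
]

LAYOUTS = ("single", "group")
VARIANTS = ("stiff", "soft")

_LAYOUT_LABEL = {"single": "1 cell", "group": "18 cells"}

TABLE_FILES = {
    "ecm": "max_hmh_ecm.csv",
    "cortex": "max_hmh_cortex.csv",
    "cytoplasm": "max_hmh_cytoplasm.csv",
    "nuclear_membrane": "max_hmh_nuclear_membrane.csv",
    "nucleus": "max_hmh_nucleus.csv",
}
UNIAXIAL_FILE = "uniaxial_extremes.csv"
ORDERINGS_FILE = "orderings.csv"
REPORT_FILE = "report.txt"


@dataclass
class ScenarioResult:
    scenario_id: str
    layout: str
    ecm_variant: str
    mesh: Mesh
    summary: StressSummary
    field: StressField
    iterations: list  # Newton iterations per increment
    config_digest: str


@dataclass
class MatrixResult:
    results: dict  # (layout, variant) -> ScenarioResult
    report: Optional[ComparisonReport]
    incomplete: dict = field(default_factory=dict)  # (layout, variant) -> reason

    @property
    def complete(self) -> bool:
        return not self.incomplete


def _cell_spec(config: RunConfig, center, layout: str) -> CellSpec:
    sc = config.scene
    transform = (
        AffineTransform.oblate(sc.oblate_squash)
        if sc.oblate_squash is not None
        else AffineTransform.identity()
    )
    if layout == "single":
        n_surface, n_ecm = sc.single_n_surface, sc.single_n_ecm_layers
        n_nuc = n_cyt = None
    else:
        n_surface, n_ecm = sc.group_n_surface, sc.group_n_ecm_layers
        n_nuc, n_cyt = sc.group_n_nucleus_layers, sc.group_n_cytoplasm_layers
    return CellSpec(
        center=center,
        cell_radius=sc.cell_radius_m,
        nucleus_radius=sc.nucleus_radius_m,
        mesh_resolution=sc.mesh_resolution_m,
        shape_transform=transform,
        attachment=sc.attachment,
        n_surface=n_surface,
        n_nucleus_layers=n_nuc,
        n_cytoplasm_layers=n_cyt,
        n_ecm_layers=n_ecm,
    )


def build_scenario_scene(config: RunConfig, layout: str, ecm_variant: str = "stiff") -> SceneSpec:
    """Scene description for one matrix corner (geometry identical across
    ECM variants: only the modulus differs)."""
    sc = config.scene
    if layout == "single":
        side = sc.single_box_side_m
        center = np.full(3, side / 2.0)
        cells = [_cell_spec(config, center, layout)]
        box = np.array([[0.0, 0.0, 0.0], [side, side, side]])
        scene = SceneSpec(cells=cells, ecm_box=box, pressure=sc.pressure_pa, ecm_variant=ecm_variant)
    elif layout == "group":
        template = default_group_cells(
            nx=sc.group_nx,
            ny=sc.group_ny,
            nz=sc.group_nz,
            spacing=sc.group_spacing_m,
            cell_radius=sc.cell_radius_m,
            nucleus_radius=sc.nucleus_radius_m,
            mesh_resolution=sc.mesh_resolution_m,
        )
        cells = [_cell_spec(config, c.center, layout) for c in template.cells]
        scene = SceneSpec(
            cells=cells, ecm_box=template.ecm_box, pressure=sc.pressure_pa, ecm_variant=ecm_variant
        )
    else:
        raise ValueError(f"unknown layout '{layout}'")
    return scene


def run_scenario(
    config: RunConfig,
    layout: str,
    ecm_variant: str,
    mesh: Optional[Mesh] = None,
    log=None,
) -> ScenarioResult:
    """Mesh (or reuse a mesh), solve the two-step schedule, recover stresses
    and summarize one scenario."""
    if mesh is None:
        mesh = build_scene(build_scenario_scene(config, layout, ecm_variant))
        report = validate_mesh(mesh)
        if not report.passed:
            raise RuntimeError("generated mesh failed validation:\n" + str(report))
    materials = config.materials.to_material_spec(ecm_variant)
    model = FEModel(mesh, materials, config.scene.pressure_pa)
    history = run_two_step_solution(
        mesh,
        materials,
        config.scene.pressure_pa,
        config.solver.to_solver_config(),
        model=model,
        check_mesh=False,
        log=log,
    )
    state = history[-1]
    field_ = recover_stress_field(model, state)
    scenario_id = f"{layout}-{ecm_variant}"
    summary = summarize_component_stress(
        field_, mesh, scenario_id=scenario_id, layout=layout, ecm_variant=ecm_variant
    )
    return ScenarioResult(
        scenario_id=scenario_id,
        layout=layout,
        ecm_variant=ecm_variant,
        mesh=mesh,
        summary=summary,
        field=field_,
        iterations=[h.record.iterations for h in history],
        config_digest=config_hash(config),
    )


def run_scenario_matrix(config: RunConfig, out_dir=None, log_stream=None) -> MatrixResult:
    """Run the full 2x2 matrix and the ordering comparison.

    Within each layout the stiff and soft runs share one mesh, so the pair
    differs only in ECM modulus.  A non-convergent scenario is recorded as
    incomplete instead of fabricating orderings.
    """
    results = {}
    incomplete = {}
    log = log_stream or io.StringIO()
    log.write("run configuration (resolved):\n" + dump_config(config) + "\n")
    for layout in LAYOUTS:
        scene = build_scenario_scene(config, layout)
        mesh = build_scene(scene)
        report = validate_mesh(mesh)
        log.write(
            f"[{layout}] mesh: {mesh.n_nodes} nodes, counts {mesh.element_counts()}, "
            f"validation {'pass' if report.passed else 'FAIL'}\n"
        )
        if not report.passed:
            raise RuntimeError("generated mesh failed validation:\n" + str(report))
        for variant in VARIANTS:
            log.write(f"[{layout}-{variant}] solving\n")
            try:
                res = run_scenario(config, layout, variant, mesh=mesh, log=log)
            except NonConvergenceError as exc:
                incomplete[(layout, variant)] = str(exc)
                log.write(f"[{layout}-{variant}] INCOMPLETE: {exc}\n")
                continue
            results[(layout, variant)] = res
            log.write(
                f"[{layout}-{variant}] done; iterations {res.iterations}; "
                f"max HMH {res.summary.max_hmh}\n"
            )
    report = None
    if len(results) >= 2:
        report = compare_scenarios([r.summary for r in results.values()])
    matrix = MatrixResult(results=results, report=report, incomplete=incomplete)
    if out_dir is not None:
        export_report(matrix, out_dir, config=config, log_text=log.getvalue())
    return matrix


def _summary_tables(summaries):
    by_key = {(s.layout, s.ecm_variant): s for s in summaries}
    layouts = [l for l in LAYOUTS if any(k[0] == l for k in by_key)]
    tables = {}
    for comp, fname in TABLE_FILES.items():
        rows = []
        for layout in layouts:
            row = {"case": _LAYOUT_LABEL.get(layout, layout)}
            for variant in VARIANTS:
                s = by_key.get((layout, variant))
                row[f"{variant}_ecm_pa"] = s.max_hmh.get(comp) if s else None
            rows.append(row)
        tables[fname] = pd.DataFrame(rows)
    rows = []
    for layout in layouts:
        row = {"case": _LAYOUT_LABEL.get(layout, layout)}
        for variant in VARIANTS:
            s = by_key.get((layout, variant))
            row[f"{variant}_s11_max_pa"] = s.s11_max if s else None
            row[f"{variant}_s11_min_pa"] = s.s11_min if s else None
        rows.append(row)
    tables[UNIAXIAL_FILE] = pd.DataFrame(rows)
    return tables


def export_report(
    matrix: MatrixResult,
    out_dir,
    formats=("csv", "txt", "vtu"),
    config: Optional[RunConfig] = None,
    log_text: str = "",
):
    """Write summary CSV tables, the ordering report and VTU fields.

    Raises on an empty result set; a partially complete matrix is exported
    with explicit ``incomplete`` markers.
    """
    if not matrix.results:
        raise ValueError("nothing to export: no completed scenarios")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    summaries = [r.summary for r in matrix.results.values()]
    if "csv" in formats:
        for fname, df in _summary_tables(summaries).items():
            p = out / fname
            df.to_csv(p, index=False, float_format=None)
            written.append(p)
        if matrix.report is not None:
            p = out / ORDERINGS_FILE
            pd.DataFrame(matrix.report.as_rows()).to_csv(p, index=False)
            written.append(p)

    if "txt" in formats:
        lines = ["scenario comparison report", "=" * 60]
        if config is not None:
            lines.append(f"config hash: {config_hash(config)}")
        if matrix.incomplete:
            lines.append("STATUS: INCOMPLETE")
            for key, reason in matrix.incomplete.items():
                lines.append(f"  incomplete {key[0]}-{key[1]}: {reason}")
        else:
            lines.append("STATUS: complete")
        for res in matrix.results.values():
            s = res.summary
            lines.append(f"\n[{s.scenario_id}]")
            for comp, val in sorted(s.max_hmh.items()):
                lines.append(f"  max HMH {comp:18s} {val:.6e} Pa")
            if s.s11_max is not None:
                lines.append(f"  S11 max {s.s11_max:.6e} Pa, S11 min {s.s11_min:.6e} Pa")
            lines.append(f"  max displacement {s.max_displacement:.6e} m")
            if s.cortex_hmh_ratio is not None:
                lines.append(f"  cortex HMH max/min ratio {s.cortex_hmh_ratio:.3f}")
        if matrix.report is not None:
            lines.append("\nordering checks:")
            for c in matrix.report.checks:
                status = {True: "ok", False: "VIOLATED", None: "tie"}[c.holds]
                lines.append(
                    f"  [{status:8s}] {c.name}: {c.greater} / {c.lesser} = {c.ratio:.4g}"
                )
        if log_text:
            lines.append("\nsolver log:")
            lines.append(log_text)
        p = out / REPORT_FILE
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    if "vtu" in formats:
        for res in matrix.results.values():
            arrays = default_field_arrays(res.mesh, res.field)
            p = out / f"{res.scenario_id}.vtu"
            write_vtu(
                res.mesh,
                arrays,
                p,
                point_data={"displacement": res.field.displacements},
            )
            written.append(p)
    return written


def read_summary_tables(out_dir) -> dict:
    """Re-read the exported CSV summary tables (round-trip counterpart)."""
    out = Path(out_dir)
    tables = {}
    for fname in list(TABLE_FILES.values()) + [UNIAXIAL_FILE]:
        p = out / fname
        if p.exists():
            tables[fname] = pd.read_csv(p)
    return tables
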