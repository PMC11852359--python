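"""Stress recovery and reduction.

Huber-Mises-Hencky (HMH, von Mises) equivalent stress, per-component field
extraction at element centroids, per-component maxima summaries (the
headline comparisons are per-component maximum HMH stress and the uniaxial
cytoskeleton extremes), and the stiff-vs-soft / single-vs-group ordering
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assembly import FEModel
from .geometry import (
    Mesh,
    REGION_ACTIN_TENDON,
    REGION_CORTEX,
    REGION_CYTOPLASM,
    REGION_ECM,
    REGION_MICROTUBULE_BAR,
    REGION_NAMES,
    REGION_NUCLEAR_MEMBRANE,
    REGION_NUCLEUS,
)
from .solver import SystemState

__all__ = [
    "compute_hmh",
    "StressField",
    "StressSummary",
    "OrderingCheck",
    "ComparisonReport",
    "recover_stress_field",
    "summarize_component_stress",
    "compare_scenarios",
    "SOLID_COMPONENTS",
    "MEMBRANE_COMPONENTS",
    "CELL_COMPONENTS",
]

SOLID_COMPONENTS = (REGION_ECM, REGION_CYTOPLASM, REGION_NUCLEUS)
MEMBRANE_COMPONENTS = (REGION_CORTEX, REGION_NUCLEAR_MEMBRANE)
#: components belonging to the cell (soft-ECM maxima exceed stiff-ECM ones)
CELL_COMPONENTS = ("cortex", "cytoplasm", "nucleus", "nuclear_membrane")


def compute_hmh(stress_tensor) -> np.ndarray:
    """HMH (von Mises) equivalent stress of symmetric stress tensors.

    Accepts a single 3x3 (or 2x2 plane-stress) tensor or a batch (..., d, d);
    plane-stress input is promoted with zero out-of-plane components.
    ``sqrt(0.5*[(sx-sy)^2+(sy-sz)^2+(sz-sx)^2] + 3*(txy^2+tyz^2+tzx^2))``.
    """
    S = np.asarray(stress_tensor, dtype=float)
    if S.shape[-2:] == (2, 2):
        Z = np.zeros(S.shape[:-2] + (3, 3))
        Z[..., :2, :2] = S
        S = Z
    if S.shape[-2:] != (3, 3):
        raise ValueError("expected (...,3,3) or (...,2,2) stress tensors")
    sx, sy, sz = S[..., 0, 0], S[..., 1, 1], S[..., 2, 2]
    txy, tyz, tzx = S[..., 0, 1], S[..., 1, 2], S[..., 2, 0]
    val = 0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2) + 3.0 * (
        txy**2 + tyz**2 + tzx**2
    )
    return np.sqrt(np.maximum(val, 0.0))


@dataclass
class StressField:
    """Element-centroid stresses of one converged state (constant-strain
    elements make the centroid value exact)."""

    mesh: Mesh
    tet_stress: np.ndarray  # (Nt, 3, 3) Cauchy
    tri_stress: np.ndarray  # (Ntri, 2, 2) plane stress, element frame
    bar_s11: np.ndarray  # (Nb,) uniaxial, tension positive
    displacements: np.ndarray  # (N, 3)

    @property
    def tet_hmh(self) -> np.ndarray:
        return compute_hmh(self.tet_stress)

    @property
    def tri_hmh(self) -> np.ndarray:
        return compute_hmh(self.tri_stress)


def recover_stress_field(model: FEModel, state: SystemState) -> StressField:
    """Element stresses from a converged state; refuses unconverged input."""
    if not state.converged:
        raise ValueError("refusing stress recovery from an unconverged state")
    nonlinear = True
    # Small-strain verification states are tagged by their record: a linear
    # solve stores exactly one residual evaluation.
    if state.record.step == 2 and state.record.increment == 1 and len(state.record.residuals) == 1:
        nonlinear = False
    tet_s, tri_s, bar_s = model.element_stresses(
        state.displacements.ravel(), state.prestress_scale, nonlinear=nonlinear
    )
    return StressField(
        mesh=model.mesh,
        tet_stress=tet_s,
        tri_stress=tri_s,
        bar_s11=bar_s,
        displacements=state.displacements,
    )


@dataclass
class StressSummary:
    """Per-component maxima of one scenario (the tables' row analogue)."""

    scenario_id: str
    layout: str  # "single" | "group" (or any matching key)
    ecm_variant: str  # "stiff" | "soft"
    max_hmh: dict  # component name -> float Pa (absent components omitted)
    s11_max: Optional[float]  # tendon/bar uniaxial extremes, Pa
    s11_min: Optional[float]
    cortex_hmh_ratio: Optional[float]  # max/min over cortex elements
    max_displacement: float  # m
    per_cell_max_hmh: dict = field(default_factory=dict)  # name -> {cell_id: max}

    def component(self, name: str) -> float:
        if name not in self.max_hmh:
            raise KeyError(f"component '{name}' absent from summary {self.scenario_id}")
        return self.max_hmh[name]


def summarize_component_stress(
    field_: StressField,
    mesh: Optional[Mesh] = None,
    scenario_id: str = "",
    layout: str = "single",
    ecm_variant: str = "stiff",
) -> StressSummary:
    """Exact per-component maxima (brute-force equivalent) of a stress field."""
    mesh = mesh or field_.mesh
    tet_h = field_.tet_hmh
    tri_h = field_.tri_hmh
    max_hmh = {}
    per_cell = {}
    for tag in SOLID_COMPONENTS:
        sel = mesh.tet_tags == tag
        if np.any(sel):
            name = REGION_NAMES[tag]
            max_hmh[name] = float(tet_h[sel].max())
            if tag != REGION_ECM:
                per_cell[name] = {
                    int(c): float(tet_h[sel & (mesh.tet_cell_ids == c)].max())
                    for c in np.unique(mesh.tet_cell_ids[sel])
                }
    for tag in MEMBRANE_COMPONENTS:
        sel = mesh.tri_tags == tag
        if np.any(sel):
            name = REGION_NAMES[tag]
            max_hmh[name] = float(tri_h[sel].max())
            per_cell[name] = {
                int(c): float(tri_h[sel & (mesh.tri_cell_ids == c)].max())
                for c in np.unique(mesh.tri_cell_ids[sel])
            }

    if len(field_.bar_s11):
        s11_max = float(field_.bar_s11.max())
        s11_min = float(field_.bar_s11.min())
    else:
        s11_max = s11_min = None

    cortex_sel = mesh.tri_tags == REGION_CORTEX
    ratio = None
    if np.any(cortex_sel):
        lo = float(tri_h[cortex_sel].min())
        hi = float(tri_h[cortex_sel].max())
        ratio = hi / lo if lo > 0 else np.inf

    return StressSummary(
        scenario_id=scenario_id,
        layout=layout,
        ecm_variant=ecm_variant,
        max_hmh=max_hmh,
        s11_max=s11_max,
        s11_min=s11_min,
        cortex_hmh_ratio=ratio,
        max_displacement=float(np.max(np.linalg.norm(field_.displacements, axis=1)))
        if len(field_.displacements)
        else 0.0,
        per_cell_max_hmh=per_cell,
    )


@dataclass
class OrderingCheck:
    name: str
    greater: str  # scenario id expected larger
    lesser: str
    ratio: float  # value(greater) / value(lesser)
    holds: Optional[bool]  # None when the two values tie (nothing asserted)


@dataclass
class ComparisonReport:
    summaries: list
    checks: list

    def passed(self) -> bool:
        return all(c.holds for c in self.checks if c.holds is not None)

    def as_rows(self):
        return [
            {
                "check": c.name,
                "greater": c.greater,
                "lesser": c.lesser,
                "ratio": c.ratio,
                "holds": c.holds,
            }
            for c in self.checks
        ]


def _ordering(name, big: StressSummary, small: StressSummary, value) -> OrderingCheck:
    hi, lo = value(big), value(small)
    if lo == 0 and hi == 0:
        ratio, holds = 1.0, None
    else:
        ratio = hi / lo if lo != 0 else np.inf
        holds = None if np.isclose(hi, lo, rtol=1e-12) else bool(hi > lo)
    return OrderingCheck(name, big.scenario_id, small.scenario_id, float(ratio), holds)


def compare_scenarios(summaries) -> ComparisonReport:
    """Pairwise ordering checks over the stiff/soft x single/group matrix.

    (a) every cell component's max HMH: soft > stiff within each layout;
    (b) ECM max HMH: stiff > soft within each layout;
    (c) ECM max HMH: group > single within each ECM variant;
    (d) cytoskeleton |S11| extremes and max displacement: soft > stiff.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    by_key = {}
    for s in summaries:
        key = (s.layout, s.ecm_variant)
        if key in by_key:
            raise ValueError(f"duplicate scenario for layout/variant {key}")
        by_key[key] = s

    layouts = sorted({s.layout for s in summaries})
    variants = sorted({s.ecm_variant for s in summaries})
    checks = []

    for layout in layouts:
        stiff = by_key.get((layout, "stiff"))
        soft = by_key.get((layout, "soft"))
        if stiff is None or soft is None:
            continue
        if set(stiff.max_hmh) != set(soft.max_hmh):
            raise ValueError(f"mismatched layouts for '{layout}' stiff/soft pair")
        for comp in CELL_COMPONENTS:
            if comp in soft.max_hmh:
                checks.append(
                    _ordering(
                        f"{comp}_max_hmh_soft_gt_stiff[{layout}]",
                        soft,
                        stiff,
                        lambda s, c=comp: s.max_hmh[c],
                    )
                )
        if "ecm" in stiff.max_hmh:
            checks.append(
                _ordering(
                    f"ecm_max_hmh_stiff_gt_soft[{layout}]",
                    stiff,
                    soft,
                    lambda s: s.max_hmh["ecm"],
                )
            )
        if soft.s11_max is not None:
            checks.append(
                _ordering(
                    f"abs_s11_extreme_soft_gt_stiff[{layout}]",
                    soft,
                    stiff,
                    lambda s: max(abs(s.s11_max), abs(s.s11_min)),
                )
            )
        checks.append(
            _ordering(
                f"max_displacement_soft_gt_stiff[{layout}]",
                soft,
                stiff,
                lambda s: s.max_displacement,
            )
        )

    if "single" in layouts and "group" in layouts:
        for variant in variants:
            single = by_key.get(("single", variant))
            group = by_key.get(("group", variant))
            if single is None or group is None:
                continue
            if "ecm" in single.max_hmh and "ecm" in group.max_hmh:
                checks.append(
                    _ordering(
                        f"ecm_max_hmh_group_gt_single[{variant}]",
                        group,
                        single,
                        lambda s: s.max_hmh["ecm"],
                    )
                )

    return ComparisonReport(summaries=list(summaries), checks=checks)
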