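"""Global assembly: element groups, sparse tangent/internal-force assembly,
consistent pressure loads and roller boundary conditions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import elements as el
from .geometry import (
    Mesh,
    REGION_ACTIN_TENDON,
    REGION_CORTEX,
    REGION_CYTOPLASM,
    REGION_ECM,
    REGION_MICROTUBULE_BAR,
    REGION_NUCLEAR_MEMBRANE,
    REGION_NUCLEUS,
    triangle_areas,
)
from .materials import MaterialSpec

__all__ = ["FEModel", "build_load_and_constraints", "BoundaryError"]


class BoundaryError(ValueError):
    pass


def build_load_and_constraints(mesh: Mesh, pressure: float):
    """Consistent nodal loads for top-face pressure and roller constraints.

    The pressure is a dead load on the undeformed top face, acting along -z;
    each top-face triangle contributes p*area/3 to each of its nodes.  Side
    faces are constrained in their (axis-aligned) normal direction only and
    the bottom face in z; tangential sliding is free.  Nodes on edges or
    corners accumulate every applicable normal constraint.
    """
    required = {"top", "bottom", "x-", "x+", "y-", "y+"}
    missing = required - set(mesh.boundary_faces)
    if missing:
        raise BoundaryError(f"mesh boundary faces untagged: {sorted(missing)}")

    n = mesh.n_nodes
    load = np.zeros((n, 3))
    top = mesh.boundary_faces["top"]
    areas = triangle_areas(mesh.nodes, top)
    for tri, a in zip(top, areas):
        load[tri, 2] -= pressure * a / 3.0

    fixed = set()
    normal_dof = {"x-": 0, "x+": 0, "y-": 1, "y+": 1, "bottom": 2}
    for tag, dof in normal_dof.items():
        for node in np.unique(mesh.boundary_faces[tag]):
            fixed.add(3 * int(node) + dof)
    return load.ravel(), np.array(sorted(fixed), dtype=int)


@dataclass
class _TetGroup:
    conn: np.ndarray
    gradN: np.ndarray
    vol: np.ndarray
    lam: float
    mu: float
    dof_idx: np.ndarray  # (Ne, 12)


@dataclass
class _TriGroup:
    conn: np.ndarray
    gradN2: np.ndarray
    area: np.ndarray
    F0: np.ndarray
    lam_bar: float
    mu: float
    thickness: float
    dof_idx: np.ndarray  # (Ne, 9)


@dataclass
class _BarGroup:
    conn: np.ndarray
    L0: np.ndarray
    dir0: np.ndarray
    EA: np.ndarray
    area: np.ndarray
    prestress_force: float
    dof_idx: np.ndarray  # (Ne, 6)


def _dof_idx(conn: np.ndarray) -> np.ndarray:
    return (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(len(conn), -1)


class FEModel:
    """A meshed scenario ready for assembly.

    Groups elements by region tag, precomputes reference quantities, and
    exposes ``assemble`` (tangent + internal force) and ``element_stresses``.
    """

    def __init__(self, mesh: Mesh, materials: MaterialSpec, pressure: float = 0.0):
        self.mesh = mesh
        self.materials = materials
        self.pressure = float(pressure)
        self.n_dof = 3 * mesh.n_nodes

        solid_mats = {
            REGION_ECM: materials.ecm,
            REGION_CYTOPLASM: materials.cytoplasm,
            REGION_NUCLEUS: materials.nucleus,
        }
        self.tet_groups = {}
        for tag, mat in solid_mats.items():
            sel = mesh.tet_tags == tag
            if not np.any(sel):
                continue
            conn = mesh.tets[sel]
            gradN, vol = el.tet_precompute(mesh.nodes, conn)
            lam, mu = mat.lame
            self.tet_groups[tag] = _TetGroup(conn, gradN, vol, lam, mu, _dof_idx(conn))

        membrane_mats = {
            REGION_CORTEX: materials.cortex,
            REGION_NUCLEAR_MEMBRANE: materials.nuclear_membrane,
        }
        self.tri_groups = {}
        for tag, mat in membrane_mats.items():
            sel = mesh.tri_tags == tag
            if not np.any(sel):
                continue
            conn = mesh.tris[sel]
            gradN2, area, F0 = el.tri_precompute(mesh.nodes, conn)
            lam_bar, mu = mat.plane_stress_lame
            self.tri_groups[tag] = _TriGroup(
                conn, gradN2, area, F0, lam_bar, mu, mat.thickness, _dof_idx(conn)
            )

        truss_mats = {
            REGION_MICROTUBULE_BAR: materials.microtubule_bar,
            REGION_ACTIN_TENDON: materials.actin_tendon,
        }
        self.bar_groups = {}
        for tag, mat in truss_mats.items():
            sel = mesh.bar_tags == tag
            if not np.any(sel):
                continue
            conn = mesh.bars[sel]
            L0, dir0 = el.truss_precompute(mesh.nodes, conn)
            ne = len(conn)
            self.bar_groups[tag] = _BarGroup(
                conn,
                L0,
                dir0,
                np.full(ne, mat.young_modulus * mat.cross_section_area),
                np.full(ne, mat.cross_section_area),
                mat.prestress_force,
                _dof_idx(conn),
            )

        if mesh.box is not None:
            self.external_load, self.fixed_dofs = build_load_and_constraints(mesh, self.pressure)
        else:
            self.external_load = np.zeros(self.n_dof)
            self.fixed_dofs = np.zeros(0, dtype=int)
        free = np.ones(self.n_dof, dtype=bool)
        free[self.fixed_dofs] = False
        self.free_dofs = np.where(free)[0]

        # Precompute the global sparsity pattern and the triplet-to-CSR slot
        # map so repeated assemblies reduce to one vectorized accumulation.
        rows_parts, cols_parts = [], []
        for groups in (self.tet_groups, self.tri_groups, self.bar_groups):
            for g in groups.values():
                nd = g.dof_idx.shape[1]
                rows_parts.append(np.repeat(g.dof_idx, nd, axis=1).ravel())
                cols_parts.append(np.tile(g.dof_idx, (1, nd)).ravel())
        if rows_parts:
            rows = np.concatenate(rows_parts)
            cols = np.concatenate(cols_parts)
            order = np.lexsort((cols, rows))
            r_s, c_s = rows[order], cols[order]
            new_slot = np.empty(len(order), dtype=bool)
            new_slot[0] = True
            new_slot[1:] = (r_s[1:] != r_s[:-1]) | (c_s[1:] != c_s[:-1])
            slot_of_sorted = np.cumsum(new_slot) - 1
            self._triplet_slot = np.empty(len(order), dtype=np.int64)
            self._triplet_slot[order] = slot_of_sorted
            uniq_rows = r_s[new_slot]
            self._csr_indices = c_s[new_slot]
            self._csr_indptr = np.searchsorted(uniq_rows, np.arange(self.n_dof + 1))
            self._nnz = int(new_slot.sum())
        else:
            self._triplet_slot = None

        # Magnitude of the fully ramped prestress loading, used as the
        # residual reference in the load-free prestress step.
        p_forces = [
            abs(g.prestress_force) for g in self.bar_groups.values() if g.prestress_force
        ]
        self.prestress_force_norm = float(
            np.sqrt(
                sum(
                    len(g.conn) * g.prestress_force**2
                    for g in self.bar_groups.values()
                    if g.prestress_force
                )
            )
        ) if p_forces else 0.0

    # ------------------------------------------------------------- assembly

    def assemble(self, U: np.ndarray, prestress_scale: float, nonlinear: bool = True):
        """Tangent stiffness (CSR) and internal force at displacement U."""
        U3 = U.reshape(-1, 3)
        f_int = np.zeros(self.n_dof)
        vals = []

        def scatter(K, f, dof_idx):
            np.add.at(f_int, dof_idx.ravel(), f.reshape(len(dof_idx), -1).ravel())
            vals.append(K.ravel())

        for g in self.tet_groups.values():
            K, f, _, J = el.tet_batch(
                g.gradN, g.vol, U3[g.conn], g.lam, g.mu, nonlinear=nonlinear
            )
            if nonlinear and np.any(J <= 0):
                raise ElementInversion("tetrahedral element inverted")
            scatter(K, f, g.dof_idx)

        for g in self.tri_groups.values():
            K, f, _ = el.tri_batch(
                g.gradN2, g.area, g.F0, U3[g.conn], g.lam_bar, g.mu, g.thickness,
                nonlinear=nonlinear,
            )
            scatter(K, f, g.dof_idx)

        for g in self.bar_groups.values():
            d = (
                self.mesh.nodes[g.conn[:, 1]] + U3[g.conn[:, 1]]
                - self.mesh.nodes[g.conn[:, 0]] - U3[g.conn[:, 0]]
            )
            s0 = prestress_scale * g.prestress_force / g.EA  # rest-length prestress strain
            K, f, _ = el.truss_batch(
                g.L0, g.dir0, d, g.EA, g.area, s0, nonlinear=nonlinear
            )
            scatter(K, f, g.dof_idx)

        data = np.zeros(self._nnz)
        np.add.at(data, self._triplet_slot, np.concatenate(vals))
        K = sp.csr_matrix(
            (data, self._csr_indices, self._csr_indptr),
            shape=(self.n_dof, self.n_dof),
        )
        return K, f_int

    def internal_force(self, U: np.ndarray, prestress_scale: float, nonlinear: bool = True):
        U3 = U.reshape(-1, 3)
        f_int = np.zeros(self.n_dof)
        for g in self.tet_groups.values():
            _, f, _, _ = el.tet_batch(
                g.gradN, g.vol, U3[g.conn], g.lam, g.mu, nonlinear=nonlinear, stiffness=False
            )
            np.add.at(f_int, g.dof_idx.ravel(), f.reshape(len(g.conn), -1).ravel())
        for g in self.tri_groups.values():
            _, f, _ = el.tri_batch(
                g.gradN2, g.area, g.F0, U3[g.conn], g.lam_bar, g.mu, g.thickness,
                nonlinear=nonlinear, stiffness=False,
            )
            np.add.at(f_int, g.dof_idx.ravel(), f.reshape(len(g.conn), -1).ravel())
        for g in self.bar_groups.values():
            d = (
                self.mesh.nodes[g.conn[:, 1]] + U3[g.conn[:, 1]]
                - self.mesh.nodes[g.conn[:, 0]] - U3[g.conn[:, 0]]
            )
            s0 = prestress_scale * g.prestress_force / g.EA  # rest-length prestress strain
            _, f, _ = el.truss_batch(
                g.L0, g.dir0, d, g.EA, g.area, s0, nonlinear=nonlinear, stiffness=False
            )
            np.add.at(f_int, g.dof_idx.ravel(), f.reshape(len(g.conn), -1).ravel())
        return f_int

    # ------------------------------------------------------ stress recovery

    def element_stresses(self, U: np.ndarray, prestress_scale: float, nonlinear: bool = True):
        """Per-element stresses at displacement U, in mesh element order.

        Returns (tet_cauchy (Nt,3,3), tri_plane (Ntri,2,2), bar_s11 (Nb,)).
        """
        U3 = U.reshape(-1, 3)
        tet_s = np.zeros((len(self.mesh.tets), 3, 3))
        for tag, g in self.tet_groups.items():
            sel = self.mesh.tet_tags == tag
            _, _, cauchy, _ = el.tet_batch(
                g.gradN, g.vol, U3[g.conn], g.lam, g.mu, nonlinear=nonlinear, stiffness=False
            )
            tet_s[sel] = cauchy
        tri_s = np.zeros((len(self.mesh.tris), 2, 2))
        for tag, g in self.tri_groups.items():
            sel = self.mesh.tri_tags == tag
            _, _, sigma2 = el.tri_batch(
                g.gradN2, g.area, g.F0, U3[g.conn], g.lam_bar, g.mu, g.thickness,
                nonlinear=nonlinear, stiffness=False,
            )
            tri_s[sel] = sigma2
        bar_s = np.zeros(len(self.mesh.bars))
        for tag, g in self.bar_groups.items():
            sel = self.mesh.bar_tags == tag
            d = (
                self.mesh.nodes[g.conn[:, 1]] + U3[g.conn[:, 1]]
                - self.mesh.nodes[g.conn[:, 0]] - U3[g.conn[:, 0]]
            )
            s0 = prestress_scale * g.prestress_force / g.EA  # rest-length prestress strain
            _, _, s11 = el.truss_batch(
                g.L0, g.dir0, d, g.EA, g.area, s0, nonlinear=nonlinear, stiffness=False
            )
            bar_s[sel] = s11
        return tet_s, tri_s, bar_s

    def reaction_forces(self, U: np.ndarray, prestress_scale: float, load_scale: float, nonlinear: bool = True):
        """Reactions (internal minus applied external) at constrained dofs."""
        r = self.internal_force(U, prestress_scale, nonlinear) - load_scale * self.external_load
        out = np.zeros(self.n_dof)
        out[self.fixed_dofs] = r[self.fixed_dofs]
        return out


class ElementInversion(RuntimeError):
    pass
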