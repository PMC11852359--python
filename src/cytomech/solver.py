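"""Two-step incremental Newton-Raphson solution.

Step 1 ramps the tendon prestress (a rest-length shortening, no external
pressure), step 2 ramps the top-face pressure on top of the prestressed
state.  Each
increment is solved by full Newton iteration on the geometrically nonlinear
residual; the tangent carries the geometric (initial-stress) stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .assembly import ElementInversion, FEModel
from .geometry import Mesh, validate_mesh
from .materials import MaterialSpec

__all__ = [
    "SolverConfig",
    "SystemState",
    "IncrementRecord",
    "NonConvergenceError",
    "run_two_step_solution",
    "solve_linear_pressure",
]


@dataclass(frozen=True)
class SolverConfig:
    n_prestress_increments: int = 2
    n_load_increments: int = 6
    residual_tolerance: float = 1e-8  # relative force norm
    #: absolute residual floor (N): load-free increments converge once the
    #: residual is numerical noise; far below any physical force scale here
    #: (nodal forces are ~1e-12 N)
    absolute_tolerance: float = 1e-18
    max_newton_iterations: int = 20
    geometric_nonlinearity: bool = True

    def __post_init__(self):
        if self.n_prestress_increments < 1 or self.n_load_increments < 1:
            raise ValueError("increment counts must be >= 1")
        if not self.residual_tolerance > 0:
            raise ValueError("residual tolerance must be positive")


@dataclass
class IncrementRecord:
    step: int  # 1 = prestress, 2 = pressure
    increment: int  # global increment index (1-based)
    prestress_scale: float
    load_scale: float
    residuals: list = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return max(len(self.residuals) - 1, 0)


@dataclass
class SystemState:
    """Converged state at the end of one increment."""

    displacements: np.ndarray  # (N, 3) m
    prestress_scale: float
    load_scale: float
    record: IncrementRecord

    @property
    def converged(self) -> bool:
        return self.record.converged

    @property
    def max_displacement(self) -> float:
        return float(np.max(np.linalg.norm(self.displacements, axis=1)))


class NonConvergenceError(RuntimeError):
    def __init__(self, step, increment, residuals, reason=""):
        self.step = step
        self.increment = increment
        self.residuals = residuals
        msg = f"Newton did not converge in step {step}, increment {increment}"
        if reason:
            msg += f" ({reason})"
        msg += f"; residual trace: {['%.3e' % r for r in residuals]}"
        super().__init__(msg)


def _schedule(config: SolverConfig):
    sched = []
    for k in range(1, config.n_prestress_increments + 1):
        sched.append((1, k / config.n_prestress_increments, 0.0))
    for k in range(1, config.n_load_increments + 1):
        sched.append((2, 1.0, k / config.n_load_increments))
    return sched


def run_two_step_solution(
    mesh: Mesh,
    materials: MaterialSpec,
    pressure: float,
    config: SolverConfig = SolverConfig(),
    model: FEModel | None = None,
    check_mesh: bool = True,
    log=None,
) -> list:
    """Run the full prestress-then-pressure schedule; return the state history.

    Raises :class:`NonConvergenceError` (with the increment id and residual
    trace) if any increment fails to converge.
    """
    if model is None:
        model = FEModel(mesh, materials, pressure)
    if check_mesh:
        report = validate_mesh(mesh)
        if not report.passed:
            raise ValueError("mesh validation failed:\n" + str(report))

    nonlinear = config.geometric_nonlinearity
    U = np.zeros(model.n_dof)
    free = model.free_dofs
    load_norm = float(np.linalg.norm(model.external_load[free]))
    history = []

    for inc, (step, ps, ls) in enumerate(_schedule(config), start=1):
        rec = IncrementRecord(step=step, increment=inc, prestress_scale=ps, load_scale=ls)
        ref = max(ls * load_norm, ps * model.prestress_force_norm, 1e-30)
        # The factorized tangent is reused across iterations of an increment
        # (refactorized when the residual contraction stalls): per-increment
        # configuration changes are small, so the quasi-Newton iteration
        # converges to the same state at a fraction of the factorization cost.
        lu = None
        prev_res = np.inf
        for it in range(config.max_newton_iterations + 1):
            try:
                if lu is None:
                    K, f_int = model.assemble(U, ps, nonlinear=nonlinear)
                    lu = spla.splu(K[free][:, free].tocsc())
                else:
                    f_int = model.internal_force(U, ps, nonlinear=nonlinear)
            except ElementInversion as exc:
                raise NonConvergenceError(step, inc, rec.residuals, str(exc))
            R = f_int - ls * model.external_load
            res = float(np.linalg.norm(R[free]))
            rec.residuals.append(res)
            if not np.isfinite(res):
                raise NonConvergenceError(step, inc, rec.residuals, "non-finite residual")
            if res <= max(config.residual_tolerance * ref, config.absolute_tolerance):
                rec.converged = True
                break
            if it == config.max_newton_iterations:
                break
            if res > 0.3 * prev_res:  # stalled: rebuild the tangent
                K, f_int2 = model.assemble(U, ps, nonlinear=nonlinear)
                lu = spla.splu(K[free][:, free].tocsc())
            prev_res = res
            U[free] += lu.solve(-R[free])
        if log is not None:
            log.write(
                f"increment {inc} (step {step}, prestress {ps:.3f}, load {ls:.3f}): "
                f"{rec.iterations} iterations, residuals "
                + " ".join("%.3e" % r for r in rec.residuals)
                + "\n"
            )
        if not rec.converged:
            raise NonConvergenceError(step, inc, rec.residuals)
        history.append(
            SystemState(
                displacements=U.reshape(-1, 3).copy(),
                prestress_scale=ps,
                load_scale=ls,
                record=rec,
            )
        )
    return history


def relax_free_tensegrity(
    graph,
    materials: MaterialSpec,
    n_increments: int = 8,
    tol: float = 1e-10,
    max_iter: int = 60,
):
    """Relax a free-standing tensegrity to self-stressed equilibrium.

    Tendon prestress (a ramped rest-length shortening, parameterized by the
    equivalent force ``materials.actin_tendon.prestress_force``) drives the
    free network into its self-stressed state: equal tendon tensions, strut
    compressions about sqrt(6) times larger.  The 6-strut tensegrity has one
    internal mechanism, stabilized by the geometric stiffness of the
    prestressed tendons; a small diagonal damping keeps the early
    (prestress-free) tangent solvable, and rigid-body modes are removed by a
    load-free penalty.

    Returns (node positions at equilibrium (12,3), bar_s11 (6,), tendon_s11
    (24,), residual_norm).
    """
    from . import elements as el

    X0 = np.asarray(graph.node_positions, dtype=float)
    n = len(X0)
    conn = np.vstack([graph.bars, graph.tendons]).astype(int)
    nb = len(graph.bars)
    bar_mat, ten_mat = materials.microtubule_bar, materials.actin_tendon
    EA = np.concatenate(
        [
            np.full(nb, bar_mat.young_modulus * bar_mat.cross_section_area),
            np.full(len(graph.tendons), ten_mat.young_modulus * ten_mat.cross_section_area),
        ]
    )
    area = np.concatenate(
        [
            np.full(nb, bar_mat.cross_section_area),
            np.full(len(graph.tendons), ten_mat.cross_section_area),
        ]
    )
    L0, dir0 = el.truss_precompute(X0, conn)
    dof_idx = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(len(conn), -1)

    # Rigid-body modes are removed by a symmetric penalty instead of node
    # pinning: internal truss forces (central, pairwise) are exactly
    # orthogonal to translations and rotations, so the penalty never carries
    # load at equilibrium and cannot bias the self-stressed state the way a
    # support that blocks one member could.
    centroid = X0.mean(axis=0)
    rigid = []
    for k in range(3):
        m = np.zeros((n, 3))
        m[:, k] = 1.0
        rigid.append(m.ravel())
    for axis in np.eye(3):
        m = np.cross(np.broadcast_to(axis, (n, 3)), X0 - centroid)
        rigid.append(m.ravel())
    Rm = np.linalg.qr(np.array(rigid).T)[0]  # (3n, 6) orthonormal

    free = np.arange(3 * n)
    U = np.zeros(3 * n)
    res = np.inf
    ref = max(abs(ten_mat.prestress_force) * np.sqrt(len(graph.tendons) * 2.0), 1e-30)
    for inc in range(1, n_increments + 1):
        scale = inc / n_increments
        s0 = np.concatenate(
            [
                np.zeros(nb),
                np.full(
                    len(graph.tendons),
                    scale
                    * ten_mat.prestress_force
                    / (ten_mat.young_modulus * ten_mat.cross_section_area),
                ),
            ]
        )
        for it in range(max_iter):
            U3 = U.reshape(-1, 3)
            d = X0[conn[:, 1]] + U3[conn[:, 1]] - X0[conn[:, 0]] - U3[conn[:, 0]]
            K_e, f_e, s11 = el.truss_batch(L0, dir0, d, EA, area, s0)
            f_int = np.zeros(3 * n)
            np.add.at(f_int, dof_idx.ravel(), f_e.reshape(len(conn), -1).ravel())
            res = float(np.linalg.norm(f_int[free]))
            if res <= tol * ref:
                break
            rows = np.repeat(dof_idx, 6, axis=1).ravel()
            cols = np.tile(dof_idx, (1, 6)).ravel()
            import scipy.sparse as sp

            K = sp.coo_matrix((K_e.ravel(), (rows, cols)), shape=(3 * n, 3 * n)).toarray()
            scale_k = float(np.abs(np.diag(K)).max())
            K += scale_k * (Rm @ Rm.T)  # rigid-mode penalty
            K += 1e-8 * scale_k * np.eye(3 * n)  # mechanism damping
            U += np.linalg.solve(K, -f_int)
            U -= Rm @ (Rm.T @ U)  # keep the drift-free representative
        else:
            raise NonConvergenceError(0, inc, [res], "free tensegrity relaxation")
    U3 = U.reshape(-1, 3)
    d = X0[conn[:, 1]] + U3[conn[:, 1]] - X0[conn[:, 0]] - U3[conn[:, 0]]
    _, _, s11 = el.truss_batch(L0, dir0, d, EA, area, s0, stiffness=False)
    return X0 + U3, s11[:nb], s11[nb:], res


def solve_linear_pressure(
    mesh: Mesh, materials: MaterialSpec, pressure: float, model: FEModel | None = None
) -> SystemState:
    """One-shot small-strain linear solve under pressure (no prestress).

    Used for linear verification problems (patch tests, linear-regime
    consistency); equivalent to a single Newton iteration from zero with
    linear kinematics.
    """
    if model is None:
        model = FEModel(mesh, materials, pressure)
    U = np.zeros(model.n_dof)
    free = model.free_dofs
    K, f_int = model.assemble(U, prestress_scale=0.0, nonlinear=False)
    R = f_int - model.external_load
    Kff = K[free][:, free].tocsc()
    U[free] = spla.spsolve(Kff, -R[free])
    rec = IncrementRecord(step=2, increment=1, prestress_scale=0.0, load_scale=1.0)
    res = model.internal_force(U, 0.0, nonlinear=False) - model.external_load
    rec.residuals = [float(np.linalg.norm(res[free]))]
    rec.converged = True
    return SystemState(
        displacements=U.reshape(-1, 3), prestress_scale=0.0, load_scale=1.0, record=rec
    )
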