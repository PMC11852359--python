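"""Element library: vectorized total-Lagrangian 4-node tetrahedra, 3-node
membrane triangles (plane stress, no bending) and 2-node truss members with
optional force-controlled prestress.

Kinematics follow the incremental Green-Lagrange split dE = de + deta, with
`de` the linear (symmetric-gradient) part and `deta` the quadratic part in
the displacement-derivative increments.  All batch routines operate on whole
element groups at once and return the internal force vector, the consistent
tangent (material + geometric/initial-stress part), and recovered stresses.
A small-strain mode (``nonlinear=False``) drops `deta` and the geometric
stiffness, which is used for linear verification solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StrainIncrement",
    "compute_strain_increment",
    "tet_precompute",
    "tet_batch",
    "tri_precompute",
    "tri_batch",
    "truss_precompute",
    "truss_batch",
    "ElementError",
]

_I3 = np.eye(3)
_I2 = np.eye(2)


class ElementError(ValueError):
    pass


@dataclass(frozen=True)
class StrainIncrement:
    """Green-Lagrange strain increment split into linear and quadratic parts.

    ``de`` is the symmetric part of the displacement-gradient increment
    (the linear operator acting on the increment vector) and ``deta`` is
    one half of the gradient-transpose times gradient (the quadratic form in
    the displacement-derivative increments).  ``dE = de + deta`` exactly.
    """

    de: np.ndarray
    deta: np.ndarray

    @property
    def dE(self) -> np.ndarray:
        return self.de + self.deta


def compute_strain_increment(displacement_gradient_increment) -> StrainIncrement:
    """Strain increment from a 3x3 displacement-gradient increment du_i/dx_j."""
    G = np.asarray(displacement_gradient_increment, dtype=float).reshape(3, 3)
    if not np.all(np.isfinite(G)):
        raise ElementError("displacement gradient increment must be finite")
    de = 0.5 * (G + G.T)
    deta = 0.5 * (G.T @ G)
    return StrainIncrement(de=de, deta=deta)


# ----------------------------------------------------------------- tetrahedra


def tet_precompute(nodes: np.ndarray, conn: np.ndarray):
    """Reference shape-function gradients (Ne,4,3) and volumes (Ne,)."""
    p = nodes[conn]
    d = p[:, 1:] - p[:, 0:1]  # (Ne,3,3) edge matrix rows
    vol = np.linalg.det(d) / 6.0
    if np.any(vol <= 0):
        raise ElementError("non-positive tet volume in reference mesh")
    dinv = np.linalg.inv(d)  # (Ne,3,3)
    # grad N_a = rows of [ -sum ; dinv^T ]
    g = np.transpose(dinv, (0, 2, 1))  # (Ne,3,3): row a-1 is grad N_a (a=1..3)
    gradN = np.empty((len(conn), 4, 3))
    gradN[:, 1:, :] = g
    gradN[:, 0, :] = -g.sum(axis=1)
    return gradN, vol


def tet_batch(gradN, vol, ue, lam, mu, nonlinear=True, stiffness=True):
    """Internal force, tangent and stress for a batch of St.V-K tetrahedra.

    Returns (K (Ne,12,12) or None, f (Ne,4,3), cauchy (Ne,3,3), J (Ne,)).
    """
    H = np.einsum("eai,eaj->eij", ue, gradN)
    if nonlinear:
        F = _I3 + H
        E = 0.5 * (H + np.swapaxes(H, 1, 2) + np.einsum("eki,ekj->eij", H, H))
    else:
        F = np.broadcast_to(_I3, H.shape)
        E = 0.5 * (H + np.swapaxes(H, 1, 2))
    trE = np.trace(E, axis1=1, axis2=2)
    S = lam * trE[:, None, None] * _I3 + 2.0 * mu * E
    P = np.einsum("eij,ejk->eik", F, S) if nonlinear else S
    f = np.einsum("e,eij,eaj->eai", vol, P, gradN)

    J = np.linalg.det(F) if nonlinear else np.ones(len(vol))
    if nonlinear:
        FS = np.einsum("eij,ejk->eik", F, S)
        cauchy = np.einsum("e,eik,elk->eil", 1.0 / J, FS, F)
    else:
        cauchy = S

    K = None
    if stiffness:
        FN = np.einsum("eim,eam->eai", F, gradN)
        AB = np.einsum("eaj,ebj->eab", gradN, gradN)
        FFt = np.einsum("eim,ekm->eik", F, F)
        K = lam * np.einsum("eai,ebk->eaibk", FN, FN)
        K += mu * np.einsum("eab,eik->eaibk", AB, FFt)
        K += mu * np.einsum("ebi,eak->eaibk", FN, FN)
        if nonlinear:
            G = np.einsum("eaj,ejl,ebl->eab", gradN, S, gradN)
            K += np.einsum("eab,ik->eaibk", G, _I3)
        K = (vol[:, None, None] * K.reshape(len(vol), 12, 12)).copy()
    return K, f, cauchy, J


# ------------------------------------------------------------------ membranes


def tri_precompute(nodes: np.ndarray, conn: np.ndarray):
    """Local 2D shape gradients, reference areas and tangent maps.

    Returns (gradN2 (Ne,3,2), area (Ne,), F0 (Ne,3,2)) where F0 maps local
    reference 2D coordinates into 3-space (its columns are the element frame).
    """
    p = nodes[conn]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    nrm = np.cross(d1, d2)
    area2 = np.linalg.norm(nrm, axis=1)
    if np.any(area2 <= 0):
        raise ElementError("zero-area membrane triangle")
    e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    e2 = np.cross(nrm, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    # 2D reference coordinates of the three nodes
    q1 = np.stack([np.einsum("ei,ei->e", d1, e1), np.einsum("ei,ei->e", d1, e2)], axis=1)
    q2 = np.stack([np.einsum("ei,ei->e", d2, e1), np.einsum("ei,ei->e", d2, e2)], axis=1)
    Dm = np.stack([q1, q2], axis=2)  # (Ne,2,2) columns are edges
    Dm_inv = np.linalg.inv(Dm)
    dNdxi = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    gradN2 = np.einsum("ak,ekJ->eaJ", dNdxi, Dm_inv)
    F0 = np.stack([e1, e2], axis=2)  # (Ne,3,2)
    return gradN2, 0.5 * area2, F0


def tri_batch(gradN2, area, F0, ue, lam_bar, mu, thickness, nonlinear=True, stiffness=True):
    """Internal force, tangent and plane stress for St.V-K membranes.

    Returns (K (Ne,9,9) or None, f (Ne,3,3), sigma2 (Ne,2,2) Cauchy plane
    stress in the deformed element frame).
    """
    Fu = np.einsum("eai,eaJ->eiJ", ue, gradN2)
    if nonlinear:
        F = F0 + Fu
        C = np.einsum("eiJ,eiL->eJL", F, F)
        E2 = 0.5 * (C - _I2)
    else:
        F = F0
        E2 = 0.5 * (
            np.einsum("eiJ,eiL->eJL", F0, Fu) + np.einsum("eiJ,eiL->eLJ", F0, Fu)
        )
    trE = np.trace(E2, axis1=1, axis2=2)
    S2 = lam_bar * trE[:, None, None] * _I2 + 2.0 * mu * E2
    coeff = thickness * area
    f = np.einsum("e,eiJ,eaJ->eai", coeff, np.einsum("eiJ,eJL->eiL", F, S2), gradN2)

    # Cauchy plane stress in the deformed local frame.
    a1 = F[:, :, 0]
    nvec = np.cross(F[:, :, 0], F[:, :, 1])
    eh1 = a1 / np.linalg.norm(a1, axis=1, keepdims=True)
    eh2 = np.cross(nvec, eh1)
    eh2 /= np.linalg.norm(eh2, axis=1, keepdims=True)
    R = np.stack([eh1, eh2], axis=1)  # (Ne,2,3)
    F2 = np.einsum("eki,eiJ->ekJ", R, F)  # (Ne,2,2)
    detF2 = np.linalg.det(F2)
    sigma2 = np.einsum("e,ekJ,eJL,emL->ekm", 1.0 / detF2, F2, S2, F2)

    K = None
    if stiffness:
        FN = np.einsum("eiM,eaM->eai", F, gradN2)
        AB = np.einsum("eaJ,ebJ->eab", gradN2, gradN2)
        FFt = np.einsum("eiM,ekM->eik", F, F)
        K = lam_bar * np.einsum("eai,ebk->eaibk", FN, FN)
        K += mu * np.einsum("eab,eik->eaibk", AB, FFt)
        K += mu * np.einsum("ebi,eak->eaibk", FN, FN)
        if nonlinear:
            G = np.einsum("eaJ,eJL,ebL->eab", gradN2, S2, gradN2)
            K += np.einsum("eab,ik->eaibk", G, _I3)
        K = (coeff[:, None, None] * K.reshape(len(area), 9, 9)).copy()
    return K, f, sigma2


# -------------------------------------------------------------------- trusses


def truss_precompute(nodes: np.ndarray, conn: np.ndarray):
    """Reference lengths and unit directions."""
    d0 = nodes[conn[:, 1]] - nodes[conn[:, 0]]
    L0 = np.linalg.norm(d0, axis=1)
    if np.any(L0 <= 0):
        raise ElementError("zero-length truss member")
    return L0, d0 / L0[:, None]


def truss_batch(L0, dir0, x0_diff_plus_u, EA, area, prestress_strain, nonlinear=True, stiffness=True):
    """Internal force, tangent and uniaxial stress of prestressed trusses.

    ``x0_diff_plus_u`` is the current end-to-end vector (Ne,3).
    Prestress is rest-length controlled: ``prestress_strain`` is the (already
    ramped) imposed shortening of the natural length as a strain, so a member
    held at its reference length carries tension EA*prestress_strain.  This
    reproduces the self-stressed equilibrium of a free tensegrity (tendons
    tensile, bars compressive); a constant-force prestress would instead let
    a free network contract and shed its own tension.

    Returns (K (Ne,6,6) or None, f (Ne,2,3), s11 (Ne,)).
    """
    d = x0_diff_plus_u
    if nonlinear:
        l2 = np.einsum("ei,ei->e", d, d)
        epsG = (l2 - L0**2) / (2.0 * L0**2)
        s11 = (EA / area) * (epsG + prestress_strain)
        f2 = (area * s11 / L0)[:, None] * d  # A*L0*S * d(epsG)/du2
    else:
        eps = np.einsum("ei,ei->e", dir0, d - L0[:, None] * dir0) / L0
        s11 = (EA / area) * (eps + prestress_strain)
        f2 = (area * s11)[:, None] * dir0
    f = np.stack([-f2, f2], axis=1)

    K = None
    if stiffness:
        if nonlinear:
            kmat = (EA / L0**3)[:, None, None] * np.einsum("ei,ej->eij", d, d)
            kgeo = (area * s11 / L0)[:, None, None] * _I3
            kb = kmat + kgeo
        else:
            kb = (EA / L0)[:, None, None] * np.einsum("ei,ej->eij", dir0, dir0)
        K = np.empty((len(L0), 6, 6))
        K[:, :3, :3] = kb
        K[:, 3:, 3:] = kb
        K[:, :3, 3:] = -kb
        K[:, 3:, :3] = -kb
    return K, f, s11
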