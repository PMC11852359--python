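"""Synthetic geometry: tensegrity cytoskeletons, cell assemblies, and
cell-in-ECM scenes meshed as one conforming multi-region tetrahedral mesh.

The mesher is fully structured (cubed-sphere shells radiating from the cell
centre out to an axis-aligned sub-box), which makes every build deterministic
and makes the cortex / nuclear-membrane interfaces conforming by
construction: interface triangles are literal faces shared between the solid
regions on either side, with no duplicated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "MeshingError",
    "AffineTransform",
    "TensegrityGraph",
    "CellSpec",
    "SceneSpec",
    "Mesh",
    "ValidationReport",
    "build_icosahedron_tensegrity",
    "build_cell_assembly",
    "build_scene",
    "validate_mesh",
    "build_box_mesh",
    "default_group_cells",
    "REGION_NAMES",
    "REGION_ECM",
    "REGION_CYTOPLASM",
    "REGION_NUCLEUS",
    "REGION_CORTEX",
    "REGION_NUCLEAR_MEMBRANE",
    "REGION_MICROTUBULE_BAR",
    "REGION_ACTIN_TENDON",
]


class GeometryError(ValueError):
    """Invalid geometric input (singular transform, overlapping cells...)."""


class MeshingError(RuntimeError):
    """The requested discretization cannot produce a valid mesh."""


# Region tag codes shared by the whole package (also written to VTU output).
REGION_ECM = 0
REGION_CYTOPLASM = 1
REGION_NUCLEUS = 2
REGION_CORTEX = 3
REGION_NUCLEAR_MEMBRANE = 4
REGION_MICROTUBULE_BAR = 5
REGION_ACTIN_TENDON = 6

REGION_NAMES = {
    REGION_ECM: "ecm",
    REGION_CYTOPLASM: "cytoplasm",
    REGION_NUCLEUS: "nucleus",
    REGION_CORTEX: "cortex",
    REGION_NUCLEAR_MEMBRANE: "nuclear_membrane",
    REGION_MICROTUBULE_BAR: "microtubule_bar",
    REGION_ACTIN_TENDON: "actin_tendon",
}

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

# Node-pool quantum (m).  Mesh feature sizes are ~1e-7 m, so rounding shared
# coordinates to 1e-12 m merges last-ulp duplicates without ever merging
# distinct nodes.
_QUANTUM = 1e-12


@dataclass(frozen=True)
class AffineTransform:
    """Affine shape transform applied about the cell centre: x -> M p + b."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float).reshape(3, 3))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(3))

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.offset

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform()

    @staticmethod
    def oblate(squash: float = 0.6) -> "AffineTransform":
        """Oblate squash along z: a simple stand-in for a flattened cell."""
        if squash <= 0:
            raise GeometryError("oblate squash factor must be positive")
        return AffineTransform(np.diag([1.0, 1.0, float(squash)]))


@dataclass
class TensegrityGraph:
    """The classic 6-strut tensegrity on the 12 icosahedron vertices.

    Bars (compression struts, the microtubule analogue) are six
    vertex-disjoint edges; the remaining 24 icosahedron edges are the
    prestressed tendons (the actin analogue).
    """

    node_positions: np.ndarray  # (12, 3) m
    bars: np.ndarray  # (6, 2) node indices
    tendons: np.ndarray  # (24, 2) node indices

    def edge_set(self) -> set:
        edges = set()
        for conn in (self.bars, self.tendons):
            for a, b in conn:
                edges.add(tuple(sorted((int(a), int(b)))))
        return edges


def _tensegrity_vertices(ratio: float = 2.0) -> np.ndarray:
    """Unit-sphere vertices of the 6-strut icosahedral tensegrity.

    The 12 vertices are three mutually perpendicular rectangles, cyclic
    permutations of (0, ±ratio, ±1) (normalized).  ``ratio = 2`` is the
    self-equilibrated configuration of the strut/tendon network (equal
    tendon tensions balance the strut compressions exactly); the *regular*
    icosahedron (ratio = golden ratio) admits no self-stress state, so the
    equilibrium form is the natural reference shape for a prestressed
    cytoskeleton.
    """
    p = float(ratio)
    base = []
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            base.append((0.0, s1 * p, s2))
            base.append((s2, 0.0, s1 * p))
            base.append((s1 * p, s2, 0.0))
    verts = np.array(base)
    return verts / np.linalg.norm(verts[0])


def build_icosahedron_tensegrity(
    radius: float,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    shape_transform: Optional[AffineTransform] = None,
) -> TensegrityGraph:
    """Build the 6-bar / 24-tendon tensegrity on icosahedral vertices.

    The graph is built on the self-equilibrated icosahedral configuration of
    the requested radius (all 12 vertices on the sphere), then mapped by
    ``shape_transform`` about ``center``.  Bars are the six long rectangle
    sides (vertex-disjoint); each vertex is tied by four tendons to the two
    other rectangles.
    """
    if radius <= 0:
        raise GeometryError("tensegrity radius must be positive")
    transform = shape_transform or AffineTransform.identity()
    if abs(transform.determinant) < 1e-14:
        raise GeometryError("shape transform is singular")
    unit = _tensegrity_vertices()
    verts = unit * float(radius)

    d2 = np.sum((unit[:, None, :] - unit[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # Bars: within-rectangle pairs across the long side -- the unique pair
    # of vertices sharing the same zero coordinate and short coordinate.
    bars = []
    for i in range(12):
        for j in range(i + 1, 12):
            diff = np.abs(unit[i] - unit[j])
            if np.sum(diff > 1e-12) == 1 and abs(unit[i] @ unit[j]) < max(d2[i, j], 1):
                # exactly one differing coordinate: long side (length 2p) or
                # short side (2q); keep the long one
                if diff.max() > 1.2 * np.linalg.norm(unit[0]):
                    bars.append((i, j))
    bars = np.array(sorted(bars), dtype=int)
    assert bars.shape == (6, 2), "bar detection failed"
    # Tendons: the common nearest-neighbour distance *between* rectangles.
    cross = d2.copy()
    for i in range(12):
        for j in range(12):
            if i != j and np.sum(np.abs(unit[i] - unit[j]) > 1e-12) == 1:
                cross[i, j] = np.inf  # same-rectangle pair, never a tendon
    t_len2 = cross.min()
    ii, jj = np.where(cross < t_len2 * (1 + 1e-9))
    tendons = np.array(sorted({(min(i, j), max(i, j)) for i, j in zip(ii, jj)}), dtype=int)
    assert tendons.shape == (24, 2), "tendon detection failed"

    positions = np.asarray(center, dtype=float) + transform.apply(verts)
    return TensegrityGraph(node_positions=positions, bars=bars, tendons=tendons)


@dataclass
class CellSpec:
    """One cell: nested nucleus/cytoplasm spheres plus a tensegrity skeleton."""

    center: np.ndarray
    cell_radius: float = 10e-6
    nucleus_radius: float = 5e-6
    shape_transform: AffineTransform = field(default_factory=AffineTransform.identity)
    mesh_resolution: float = 2.5e-6
    #: cytoskeleton attachment surface: "cortex" (default) or "nuclear_membrane"
    attachment: str = "cortex"
    # Optional explicit discretization overrides (surface grid per cube-face
    # edge and radial layer counts); derived from mesh_resolution when None.
    n_surface: Optional[int] = None
    n_nucleus_layers: Optional[int] = None
    n_cytoplasm_layers: Optional[int] = None
    n_ecm_layers: Optional[int] = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not (0 < self.nucleus_radius < self.cell_radius):
            raise GeometryError("require 0 < nucleus_radius < cell_radius")
        if self.shape_transform.determinant <= 0:
            raise GeometryError("shape transform must have positive determinant")
        if self.attachment not in ("cortex", "nuclear_membrane"):
            raise GeometryError("attachment must be 'cortex' or 'nuclear_membrane'")

    @property
    def bounding_radius(self) -> float:
        """Radius of a sphere containing the transformed cell."""
        s = np.linalg.svd(self.shape_transform.matrix, compute_uv=False)[0]
        return float(self.cell_radius * s + np.linalg.norm(self.shape_transform.offset))

    def discretization(self, ecm_clearance: Optional[float] = None):
        res = float(self.mesh_resolution)
        if res > self.nucleus_radius / 2.0 + 1e-15:
            raise MeshingError(
                "mesh_resolution %.3g m too coarse to resolve the nucleus "
                "(need >= 2 elements across nucleus radius %.3g m)"
                % (res, self.nucleus_radius)
            )
        # A cube-face edge spans a quarter arc (~1.57 R); n = 2R/res keeps the
        # surface element edge below the requested resolution.
        n = self.n_surface or max(4, int(np.ceil(2.0 * self.cell_radius / res)))
        n_nuc = self.n_nucleus_layers or max(2, int(round(self.nucleus_radius / res)))
        n_cyt = self.n_cytoplasm_layers or max(
            2, int(round((self.cell_radius - self.nucleus_radius) / res))
        )
        if ecm_clearance is None:
            n_ecm = 0
        else:
            n_ecm = self.n_ecm_layers or max(2, int(round(ecm_clearance / res)))
        return n, n_nuc, n_cyt, n_ecm


@dataclass
class SceneSpec:
    """Cells embedded in an axis-aligned ECM box under top-face pressure."""

    cells: list
    ecm_box: np.ndarray  # (2, 3) [[xmin, ymin, zmin], [xmax, ymax, zmax]]
    pressure: float = 6.0
    ecm_variant: str = "stiff"

    def __post_init__(self):
        self.ecm_box = np.asarray(self.ecm_box, dtype=float).reshape(2, 3)
        if np.any(self.ecm_box[1] <= self.ecm_box[0]):
            raise GeometryError("ecm_box extents must satisfy max > min")
        if self.ecm_variant not in ("stiff", "soft"):
            raise GeometryError("ecm_variant must be 'stiff' or 'soft'")
        if not self.cells:
            raise GeometryError("scene needs at least one cell")

    def validate(self):
        """Check cell/box clearance and pairwise non-overlap."""
        for idx, cell in enumerate(self.cells):
            r = cell.bounding_radius
            clearance = cell.mesh_resolution
            lo = self.ecm_box[0] + r + clearance
            hi = self.ecm_box[1] - r - clearance
            if np.any(cell.center < lo) or np.any(cell.center > hi):
                raise GeometryError(
                    f"cell {idx} violates the box clearance (>= one element edge)"
                )
        for i in range(len(self.cells)):
            for j in range(i + 1, len(self.cells)):
                ci, cj = self.cells[i], self.cells[j]
                gap = np.linalg.norm(ci.center - cj.center)
                if gap <= ci.bounding_radius + cj.bounding_radius:
                    raise GeometryError(f"cells {i} and {j} overlap")


@dataclass
class Mesh:
    """Multi-region unstructured mesh shared by all cell components and ECM."""

    nodes: np.ndarray  # (N, 3) m
    tets: np.ndarray  # (Nt, 4)
    tet_tags: np.ndarray  # (Nt,) region codes
    tet_cell_ids: np.ndarray  # (Nt,) owning cell, -1 for ECM
    tris: np.ndarray  # (Ntri, 3)
    tri_tags: np.ndarray
    tri_cell_ids: np.ndarray
    bars: np.ndarray  # (Nb, 2)
    bar_tags: np.ndarray
    bar_cell_ids: np.ndarray
    boundary_faces: dict  # tag -> (Nf, 3) triangles; tags: top, bottom, x-, x+, y-, y+
    box: Optional[np.ndarray] = None  # (2, 3) extents when the mesh is a boxed scene

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets) + len(self.tris) + len(self.bars)

    def side_face_tags(self):
        return [t for t in ("x-", "x+", "y-", "y+") if t in self.boundary_faces]

    def element_counts(self) -> dict:
        counts = {}
        for tags, label in ((self.tet_tags, "tets"), (self.tri_tags, "tris"), (self.bar_tags, "bars")):
            for code in np.unique(tags):
                counts[REGION_NAMES[int(code)]] = int(np.sum(tags == code))
        return counts


class _NodePool:
    """Coordinate-keyed global node registry (deterministic insertion order)."""

    def __init__(self):
        self._index = {}
        self._coords = []

    def add(self, xyz) -> int:
        key = tuple(int(round(c / _QUANTUM)) for c in xyz)
        idx = self._index.get(key)
        if idx is None:
            idx = len(self._coords)
            self._index[key] = idx
            self._coords.append(tuple(float(c) for c in xyz))
        return idx

    def add_many(self, pts: np.ndarray) -> np.ndarray:
        return np.array([self.add(p) for p in np.asarray(pts, dtype=float)], dtype=int)

    def coords(self) -> np.ndarray:
        return np.array(self._coords, dtype=float).reshape(-1, 3)


def _cube_surface_parametrization(n: int):
    """Grid points and quads of the surface of the [0, n]^3 integer cube.

    Returns (points (P,3) int grid coords, quads (Q,4) point indices,
    quad_face (Q,) face codes 0..5 with code = 2*axis + (0 for min side)).
    """
    index = {}
    points = []

    def pid(ijk):
        idx = index.get(ijk)
        if idx is None:
            idx = len(points)
            index[ijk] = idx
            points.append(ijk)
        return idx

    quads = []
    quad_face = []
    for axis in range(3):
        u_axis, v_axis = (axis + 1) % 3, (axis + 2) % 3
        for side in (0, 1):
            w = 0 if side == 0 else n
            for u in range(n):
                for v in range(n):
                    corners = []
                    for du, dv in ((0, 0), (1, 0), (1, 1), (0, 1)):
                        ijk = [0, 0, 0]
                        ijk[axis] = w
                        ijk[u_axis] = u + du
                        ijk[v_axis] = v + dv
                        corners.append(pid(tuple(ijk)))
                    quads.append(corners)
                    quad_face.append(2 * axis + side)
    return (
        np.array(points, dtype=int),
        np.array(quads, dtype=int),
        np.array(quad_face, dtype=int),
    )


def _split_prism(a, b, order_key):
    """Split prism (bottom tri a, top tri b) into 3 tets whose quad-face
    diagonals all pass through the minimum-order vertex of each quad.

    ``order_key(node_id)`` must be a strict total order shared by neighbouring
    prisms; using it guarantees identical diagonals on shared quad faces,
    hence a conforming tetrahedralization.
    """
    a = list(a)
    b = list(b)
    verts = a + b
    m = min(range(6), key=lambda i: order_key(verts[i]))
    if m >= 3:  # flip the prism so the minimum vertex is on the bottom
        a, b = [b[0], b[2], b[1]], [a[0], a[2], a[1]]
        m = {0: 0, 1: 2, 2: 1}[m - 3]
    a = a[m:] + a[:m]
    b = b[m:] + b[:m]
    # Now a[0] is the global minimum; diagonals a0-b1 and a0-b2 are forced.
    q1 = (a[1], a[2], b[2], b[1])
    if min(order_key(a[1]), order_key(b[2])) < min(order_key(a[2]), order_key(b[1])):
        tets = [
            (a[0], b[0], b[1], b[2]),
            (a[0], a[1], a[2], b[2]),
            (a[0], a[1], b[2], b[1]),
        ]
    else:
        tets = [
            (a[0], b[0], b[1], b[2]),
            (a[0], a[1], a[2], b[1]),
            (a[0], a[2], b[2], b[1]),
        ]
    return tets


def _orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two nodes of any negatively oriented tet."""
    tets = np.asarray(tets, dtype=int).copy()
    p = nodes[tets]
    vol = np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    return (
        np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        / 6.0
    )


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


class _SceneBuilder:
    def __init__(self):
        self.pool = _NodePool()
        self.tets = []
        self.tet_tags = []
        self.tet_cells = []
        self.tris = []
        self.tri_tags = []
        self.tri_cells = []
        self.bars = []
        self.bar_tags = []
        self.bar_cells = []
        self.boundary = {k: [] for k in ("top", "bottom", "x-", "x+", "y-", "y+")}

    def add_cell(self, spec: CellSpec, cell_id: int, sub_box: Optional[np.ndarray], scene_box: Optional[np.ndarray]):
        """Mesh one cell (and, if sub_box is given, its surrounding ECM)."""
        with_ecm = sub_box is not None
        if with_ecm:
            sub_box = np.asarray(sub_box, dtype=float).reshape(2, 3)
            half = 0.5 * (sub_box[1] - sub_box[0])
            box_center = 0.5 * (sub_box[0] + sub_box[1])
            clearance = float(np.min(half) - spec.bounding_radius)
            if clearance <= 0:
                raise GeometryError(f"cell {cell_id} does not fit in its ECM sub-box")
        else:
            clearance = None
        n, n_nuc, n_cyt, n_ecm = spec.discretization(clearance)

        grid_pts, quads, quad_face = _cube_surface_parametrization(n)
        param = 2.0 * grid_pts / n - 1.0  # points on the [-1,1]^3 cube surface
        dirs = param / np.linalg.norm(param, axis=1, keepdims=True)

        def sphere_shell(radius):
            local = radius * dirs
            return spec.center + spec.shape_transform.apply(local)

        # Radial ladder of shells, innermost first.
        shells = []  # list of (node-id array, region of the layer *below* it)
        center_id = self.pool.add(spec.center + spec.shape_transform.offset)
        for i in range(1, n_nuc + 1):
            r = spec.nucleus_radius * i / n_nuc
            shells.append((self.pool.add_many(sphere_shell(r)), REGION_NUCLEUS))
        nucleus_surface_ids = shells[-1][0]
        for i in range(1, n_cyt + 1):
            r = spec.nucleus_radius + (spec.cell_radius - spec.nucleus_radius) * i / n_cyt
            shells.append((self.pool.add_many(sphere_shell(r)), REGION_CYTOPLASM))
        cortex_surface_ids = shells[-1][0]
        cortex_pos = sphere_shell(spec.cell_radius)
        if with_ecm:
            box_pos = box_center + param * half
            for i in range(1, n_ecm + 1):
                t = i / n_ecm
                shells.append((self.pool.add_many((1 - t) * cortex_pos + t * box_pos), REGION_ECM))
            outer_ids = shells[-1][0]
        else:
            outer_ids = cortex_surface_ids

        # Parameter-space quad diagonals fixed by the outer-shell node ids.
        # Adjacent sub-boxes share those ids on common faces, so the split of
        # the shared box face (and hence the tet faces on it) is identical on
        # both sides.
        quad_ids_outer = outer_ids[quads]
        diag_at_0 = np.zeros(len(quads), dtype=bool)
        for q in range(len(quads)):
            k = int(np.argmin(quad_ids_outer[q]))
            diag_at_0[q] = k in (0, 2)

        def shell_tris(ids):
            tris = []
            qi = ids[quads]
            for q in range(len(quads)):
                c = qi[q]
                if diag_at_0[q]:
                    tris.append((c[0], c[1], c[2]))
                    tris.append((c[0], c[2], c[3]))
                else:
                    tris.append((c[0], c[1], c[3]))
                    tris.append((c[1], c[2], c[3]))
            return np.array(tris, dtype=int)

        order_key = int  # global node ids are the total order

        # Centre fan into the innermost shell.
        first = shells[0][0]
        for t0, t1, t2 in shell_tris(first):
            self.tets.append((center_id, t0, t1, t2))
            self.tet_tags.append(REGION_NUCLEUS)
            self.tet_cells.append(cell_id)

        # Prism layers between consecutive shells.
        prev_ids = first
        for ids, region in shells[1:]:
            tris_lo = shell_tris(prev_ids)
            tris_hi = shell_tris(ids)
            for tlo, thi in zip(tris_lo, tris_hi):
                for tet in _split_prism(tlo, thi, order_key):
                    self.tets.append(tet)
                    self.tet_tags.append(region)
                    self.tet_cells.append(-1 if region == REGION_ECM else cell_id)
            prev_ids = ids

        # Interface membranes.
        for t in shell_tris(nucleus_surface_ids):
            self.tris.append(tuple(t))
            self.tri_tags.append(REGION_NUCLEAR_MEMBRANE)
            self.tri_cells.append(cell_id)
        for t in shell_tris(cortex_surface_ids):
            self.tris.append(tuple(t))
            self.tri_tags.append(REGION_CORTEX)
            self.tri_cells.append(cell_id)

        # Scene boundary faces: outer-shell triangles on faces of the scene box.
        if with_ecm and scene_box is not None:
            face_tags = {}
            for axis, names in enumerate((("x-", "x+"), ("y-", "y+"), ("bottom", "top"))):
                for side in (0, 1):
                    if np.isclose(sub_box[side, axis], scene_box[side, axis], atol=_QUANTUM):
                        face_tags[2 * axis + side] = names[side]
            qi = outer_ids[quads]
            for q in range(len(quads)):
                tag = face_tags.get(int(quad_face[q]))
                if tag is None:
                    continue
                c = qi[q]
                if diag_at_0[q]:
                    faces = ((c[0], c[1], c[2]), (c[0], c[2], c[3]))
                else:
                    faces = ((c[0], c[1], c[3]), (c[1], c[2], c[3]))
                for f in faces:
                    self.boundary[tag].append(tuple(int(x) for x in f))

        # Cytoskeleton: icosahedron tensegrity snapped onto membrane nodes.
        graph = build_icosahedron_tensegrity(
            spec.cell_radius if spec.attachment == "cortex" else spec.nucleus_radius,
            spec.center,
            spec.shape_transform,
        )
        surface_ids = cortex_surface_ids if spec.attachment == "cortex" else nucleus_surface_ids
        coords = self.pool.coords()
        surface_xyz = coords[surface_ids]
        snapped = []
        for p in graph.node_positions:
            k = int(np.argmin(np.sum((surface_xyz - p) ** 2, axis=1)))
            snapped.append(int(surface_ids[k]))
        if len(set(snapped)) != 12:
            raise MeshingError(
                "surface mesh too coarse: distinct tensegrity nodes snapped to "
                "the same membrane node"
            )
        for i, j in graph.bars:
            self.bars.append((snapped[i], snapped[j]))
            self.bar_tags.append(REGION_MICROTUBULE_BAR)
            self.bar_cells.append(cell_id)
        for i, j in graph.tendons:
            self.bars.append((snapped[i], snapped[j]))
            self.bar_tags.append(REGION_ACTIN_TENDON)
            self.bar_cells.append(cell_id)

    def finish(self, box: Optional[np.ndarray]) -> Mesh:
        nodes = self.pool.coords()
        tets = _orient_tets(nodes, np.array(self.tets, dtype=int).reshape(-1, 4))
        boundary = {
            k: np.array(v, dtype=int).reshape(-1, 3)
            for k, v in self.boundary.items()
            if v
        }
        return Mesh(
            nodes=nodes,
            tets=tets,
            tet_tags=np.array(self.tet_tags, dtype=int),
            tet_cell_ids=np.array(self.tet_cells, dtype=int),
            tris=np.array(self.tris, dtype=int).reshape(-1, 3),
            tri_tags=np.array(self.tri_tags, dtype=int),
            tri_cell_ids=np.array(self.tri_cells, dtype=int),
            bars=np.array(self.bars, dtype=int).reshape(-1, 2),
            bar_tags=np.array(self.bar_tags, dtype=int),
            bar_cell_ids=np.array(self.bar_cells, dtype=int),
            boundary_faces=boundary,
            box=box,
        )


def build_cell_assembly(spec: CellSpec) -> Mesh:
    """Mesh a single free cell: nucleus and cytoplasm solids, nuclear-membrane
    and cortex triangles, and the attached tensegrity cytoskeleton (no ECM)."""
    builder = _SceneBuilder()
    builder.add_cell(spec, cell_id=0, sub_box=None, scene_box=None)
    return builder.finish(box=None)


def _grid_partition(centers: np.ndarray, box: np.ndarray):
    """Axis-aligned sub-box per cell: the tensor grid split at midpoints
    between adjacent distinct centre coordinates."""
    cuts = []
    for axis in range(3):
        vals = np.unique(np.round(centers[:, axis] / _QUANTUM)) * _QUANTUM
        mids = 0.5 * (vals[:-1] + vals[1:])
        cuts.append(np.concatenate(([box[0, axis]], mids, [box[1, axis]])))
    sub_boxes = []
    for c in centers:
        lo, hi = [], []
        for axis in range(3):
            edges = cuts[axis]
            k = int(np.searchsorted(edges, c[axis]) - 1)
            k = min(max(k, 0), len(edges) - 2)
            lo.append(edges[k])
            hi.append(edges[k + 1])
        sub_boxes.append(np.array([lo, hi]))
    return sub_boxes


def build_scene(spec: SceneSpec) -> Mesh:
    """Mesh a full scene: cells plus conforming ECM filling the box.

    Cells must sit on a (possibly degenerate) rectilinear grid; each gets an
    axis-aligned ECM sub-box, and identical surface grids on shared sub-box
    faces make the assembled mesh conforming.
    """
    spec.validate()
    centers = np.array([c.center for c in spec.cells])
    sub_boxes = _grid_partition(centers, spec.ecm_box)
    builder = _SceneBuilder()
    for cell_id, (cell, sub_box) in enumerate(zip(spec.cells, sub_boxes)):
        builder.add_cell(cell, cell_id, sub_box, spec.ecm_box)
    return builder.finish(box=spec.ecm_box.copy())


def default_group_cells(
    nx: int = 3,
    ny: int = 3,
    nz: int = 2,
    spacing: float = 25e-6,
    cell_radius: float = 10e-6,
    nucleus_radius: float = 5e-6,
    mesh_resolution: float = 2.5e-6,
    shape_transform: Optional[AffineTransform] = None,
    **cell_kwargs,
) -> SceneSpec:
    """The multicellular layout: two horizontal 3-by-3 layers on a regular
    grid (18 cells by default), each cell in a spacing-sized ECM cube."""
    cells = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                center = (np.array([i, j, k]) + 0.5) * spacing
                cells.append(
                    CellSpec(
                        center=center,
                        cell_radius=cell_radius,
                        nucleus_radius=nucleus_radius,
                        mesh_resolution=mesh_resolution,
                        shape_transform=shape_transform or AffineTransform.identity(),
                        **cell_kwargs,
                    )
                )
    box = np.array([[0.0, 0.0, 0.0], [nx * spacing, ny * spacing, nz * spacing]])
    return SceneSpec(cells=cells, ecm_box=box, ecm_variant="stiff")


def build_box_mesh(extents, divisions) -> Mesh:
    """Homogeneous ECM block (no cells): structured grid with the Freudenthal
    6-tet split, boundary faces tagged.  Used for patch tests."""
    extents = np.asarray(extents, dtype=float).reshape(2, 3)
    nx, ny, nz = (int(d) for d in divisions)
    xs = [np.linspace(extents[0, a], extents[1, a], n + 1) for a, n in enumerate((nx, ny, nz))]
    X, Y, Z = np.meshgrid(xs[0], xs[1], xs[2], indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Freudenthal/Kuhn subdivision: conforming across the whole grid.
    kuhn = [
        (0, 1, 3, 7),
        (0, 1, 5, 7),
        (0, 2, 3, 7),
        (0, 2, 6, 7),
        (0, 4, 5, 7),
        (0, 4, 6, 7),
    ]
    corner_offsets = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = [nid(i + di, j + dj, k + dk) for di, dj, dk in corner_offsets]
                for tet in kuhn:
                    tets.append([ids[c] for c in tet])
    tets = _orient_tets(nodes, np.array(tets, dtype=int))

    boundary = {k: [] for k in ("x-", "x+", "y-", "y+", "bottom", "top")}
    face_names = {(0, 0): "x-", (0, 1): "x+", (1, 0): "y-", (1, 1): "y+", (2, 0): "bottom", (2, 1): "top"}
    # Surface faces of boundary tets: faces whose nodes all lie on a box plane.
    face_count = {}
    for t in tets:
        for f in ((t[0], t[1], t[2]), (t[0], t[1], t[3]), (t[0], t[2], t[3]), (t[1], t[2], t[3])):
            key = tuple(sorted(int(x) for x in f))
            face_count[key] = face_count.get(key, 0) + 1
    for f, cnt in face_count.items():
        if cnt != 1:
            continue
        pts = nodes[list(f)]
        for axis in range(3):
            for side in (0, 1):
                if np.allclose(pts[:, axis], extents[side, axis], atol=_QUANTUM):
                    boundary[face_names[(axis, side)]].append(f)
    boundary = {k: np.array(v, dtype=int).reshape(-1, 3) for k, v in boundary.items()}
    n_t = len(tets)
    return Mesh(
        nodes=nodes,
        tets=tets,
        tet_tags=np.full(n_t, REGION_ECM, dtype=int),
        tet_cell_ids=np.full(n_t, -1, dtype=int),
        tris=np.zeros((0, 3), dtype=int),
        tri_tags=np.zeros(0, dtype=int),
        tri_cell_ids=np.zeros(0, dtype=int),
        bars=np.zeros((0, 2), dtype=int),
        bar_tags=np.zeros(0, dtype=int),
        bar_cell_ids=np.zeros(0, dtype=int),
        boundary_faces=boundary,
        box=extents.copy(),
    )


@dataclass
class ValidationReport:
    passed: bool
    checks: list  # (name, ok, detail)

    def failures(self):
        return [(n, d) for n, ok, d in self.checks if not ok]

    def __str__(self):
        lines = [f"mesh validation: {'PASS' if self.passed else 'FAIL'}"]
        for name, ok, detail in self.checks:
            lines.append(f"  [{'ok' if ok else 'FAIL'}] {name}" + (f": {detail}" if detail else ""))
        return "\n".join(lines)


def validate_mesh(mesh: Mesh, min_quality: float = 1e-3) -> ValidationReport:
    """Check all mesh invariants; report-only (never raises).

    Checks: positive tet orientation, element quality, orphan nodes,
    interface conformity of cortex / nuclear-membrane triangles (shared faces
    between the correct solid regions, no duplicated interface nodes),
    cytoskeleton attachment by shared node, and boundary-face sanity.
    """
    checks = []

    vols = tet_volumes(mesh.nodes, mesh.tets)
    bad = np.where(vols <= 0)[0]
    checks.append(
        ("positive tet orientation", len(bad) == 0, f"inverted tets: {bad.tolist()[:10]}" if len(bad) else "")
    )

    # Quality: normalized volume vs mean edge length cubed (regular tet ~0.118).
    p = mesh.nodes[mesh.tets]
    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    el = np.mean(
        np.stack([np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in edges]), axis=0
    )
    quality = np.abs(vols) / np.maximum(el**3, 1e-300)
    bad_q = np.where(quality < min_quality)[0]
    checks.append(
        (
            "tet quality",
            len(bad_q) == 0,
            f"{len(bad_q)} tets below quality {min_quality}; worst ids {bad_q.tolist()[:10]}"
            if len(bad_q)
            else f"min quality {quality.min():.4f}" if len(quality) else "",
        )
    )

    used = np.zeros(mesh.n_nodes, dtype=bool)
    for conn in (mesh.tets, mesh.tris, mesh.bars):
        if len(conn):
            used[conn.ravel()] = True
    orphans = np.where(~used)[0]
    checks.append(("no orphan nodes", len(orphans) == 0, f"orphans: {orphans.tolist()[:10]}" if len(orphans) else ""))

    dup_key = {}
    dup = 0
    for i, xyz in enumerate(mesh.nodes):
        key = tuple(int(round(c / _QUANTUM)) for c in xyz)
        if key in dup_key:
            dup += 1
        dup_key[key] = i
    checks.append(("no duplicated nodes", dup == 0, f"{dup} coincident node pairs" if dup else ""))

    # Face adjacency: face (sorted nodes) -> list of (tet id, region tag).
    face_map = {}
    for t, (tet, tag) in enumerate(zip(mesh.tets, mesh.tet_tags)):
        for f in ((tet[0], tet[1], tet[2]), (tet[0], tet[1], tet[3]), (tet[0], tet[2], tet[3]), (tet[1], tet[2], tet[3])):
            face_map.setdefault(tuple(sorted(int(x) for x in f)), []).append((t, int(tag)))

    expected = {
        REGION_CORTEX: {REGION_CYTOPLASM, REGION_ECM},
        REGION_NUCLEAR_MEMBRANE: {REGION_NUCLEUS, REGION_CYTOPLASM},
    }
    bad_ifc = []
    has_ecm = bool(np.any(mesh.tet_tags == REGION_ECM))
    for i, (tri, tag) in enumerate(zip(mesh.tris, mesh.tri_tags)):
        key = tuple(sorted(int(x) for x in tri))
        owners = face_map.get(key, [])
        regions = {r for _, r in owners}
        want = expected[int(tag)]
        if int(tag) == REGION_CORTEX and not has_ecm:
            want = {REGION_CYTOPLASM}  # free cell assembly: no ECM side
        if regions != want or len(owners) != len(want):
            bad_ifc.append(i)
    checks.append(
        (
            "interface conformity (cortex / nuclear membrane)",
            len(bad_ifc) == 0,
            f"non-conforming interface tris: {bad_ifc[:10]}" if bad_ifc else "",
        )
    )

    # Internal solid faces shared by exactly <= 2 tets.
    over = [f for f, owners in face_map.items() if len(owners) > 2]
    checks.append(("solid face sharing <= 2", len(over) == 0, f"{len(over)} overshared faces" if over else ""))

    membrane_nodes = set(mesh.tris.ravel().tolist()) if len(mesh.tris) else set()
    loose = [i for i, bar in enumerate(mesh.bars) if not (int(bar[0]) in membrane_nodes and int(bar[1]) in membrane_nodes)]
    checks.append(
        (
            "cytoskeleton attached by shared membrane nodes",
            len(loose) == 0,
            f"detached members: {loose[:10]}" if loose else "",
        )
    )

    bad_bnd = []
    for tag, faces in mesh.boundary_faces.items():
        for f in faces:
            key = tuple(sorted(int(x) for x in f))
            owners = face_map.get(key, [])
            if len(owners) != 1:
                bad_bnd.append((tag, key))
    checks.append(
        ("boundary faces are single-tet surface faces", len(bad_bnd) == 0, f"{len(bad_bnd)} bad boundary faces" if bad_bnd else "")
    )

    passed = all(ok for _, ok, _ in checks)
    return ValidationReport(passed=passed, checks=checks)
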