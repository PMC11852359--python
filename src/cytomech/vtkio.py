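"""VTU (VTK XML unstructured grid) export and a minimal reader.

The writer emits plain ASCII XML with mixed cells (tetrahedra, triangles,
lines), region tags and cell ids as cell data, stress channels (HMH, decimal
log of HMH, uniaxial S11) and nodal displacements.  The reader parses the
same format back for round-trip verification and is intentionally
independent of the writer's internals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Mesh

__all__ = ["write_vtu", "read_vtu", "VtuError", "default_field_arrays"]

_VTK_TET = 10
_VTK_TRI = 5
_VTK_LINE = 3


class VtuError(ValueError):
    pass


def _fmt(arr, ncomp):
    arr = np.asarray(arr)
    flat = arr.reshape(-1)
    if np.issubdtype(arr.dtype, np.integer):
        return " ".join(str(int(v)) for v in flat)
    return " ".join(repr(float(v)) for v in flat)


def default_field_arrays(mesh: Mesh, field=None, log10_floor: float = 1e-12) -> dict:
    """Standard per-element channels: region tag, cell id, HMH, log10 HMH, S11."""
    n_cells = len(mesh.tets) + len(mesh.tris) + len(mesh.bars)
    arrays = {
        "region": np.concatenate([mesh.tet_tags, mesh.tri_tags, mesh.bar_tags]).astype(np.int64)
        if n_cells
        else np.zeros(0, dtype=np.int64),
        "cell_id": np.concatenate(
            [mesh.tet_cell_ids, mesh.tri_cell_ids, mesh.bar_cell_ids]
        ).astype(np.int64)
        if n_cells
        else np.zeros(0, dtype=np.int64),
    }
    if field is not None:
        hmh = np.concatenate(
            [field.tet_hmh, field.tri_hmh, np.abs(field.bar_s11)]
        )
        s11 = np.concatenate(
            [np.zeros(len(mesh.tets)), np.zeros(len(mesh.tris)), field.bar_s11]
        )
        arrays["hmh"] = hmh
        arrays["log10_hmh"] = np.log10(np.maximum(hmh, log10_floor))
        arrays["s11"] = s11
    return arrays


def write_vtu(mesh: Mesh, fields: dict, path, point_data: dict | None = None) -> Path:
    """Write the mesh and per-element data arrays to an ASCII .vtu file.

    ``fields`` maps array names to per-element arrays over the concatenated
    (tets, tris, bars) cell order; ``point_data`` maps names to per-node
    arrays (scalars or 3-vectors).  Mismatched lengths are refused.
    """
    path = Path(path)
    n_cells = len(mesh.tets) + len(mesh.tris) + len(mesh.bars)
    for name, arr in fields.items():
        if len(np.asarray(arr)) != n_cells:
            raise VtuError(
                f"cell array '{name}' has length {len(arr)}, expected {n_cells}"
            )
    point_data = point_data or {}
    for name, arr in point_data.items():
        if len(np.asarray(arr)) != mesh.n_nodes:
            raise VtuError(
                f"point array '{name}' has length {len(arr)}, expected {mesh.n_nodes}"
            )

    conn_parts, offsets, types = [], [], []
    off = 0
    for block, vtk_type in ((mesh.tets, _VTK_TET), (mesh.tris, _VTK_TRI), (mesh.bars, _VTK_LINE)):
        for row in block:
            conn_parts.extend(int(v) for v in row)
            off += len(row)
            offsets.append(off)
            types.append(vtk_type)

    lines = []
    w = lines.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w("  <UnstructuredGrid>")
    w(f'    <Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{n_cells}">')
    w("      <Points>")
    w('        <DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    w("          " + _fmt(mesh.nodes, 3))
    w("        </DataArray>")
    w("      </Points>")
    w("      <Cells>")
    w('        <DataArray type="Int64" Name="connectivity" format="ascii">')
    w("          " + " ".join(str(v) for v in conn_parts))
    w("        </DataArray>")
    w('        <DataArray type="Int64" Name="offsets" format="ascii">')
    w("          " + " ".join(str(v) for v in offsets))
    w("        </DataArray>")
    w('        <DataArray type="UInt8" Name="types" format="ascii">')
    w("          " + " ".join(str(v) for v in types))
    w("        </DataArray>")
    w("      </Cells>")
    w("      <CellData>")
    for name, arr in fields.items():
        arr = np.asarray(arr)
        dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        w(f'        <DataArray type="{dtype}" Name="{name}" format="ascii">')
        w("          " + _fmt(arr, 1))
        w("        </DataArray>")
    w("      </CellData>")
    w("      <PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        w(
            f'        <DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">'
        )
        w("          " + _fmt(arr, ncomp))
        w("        </DataArray>")
    w("      </PointData>")
    w("    </Piece>")
    w("  </UnstructuredGrid>")
    w("</VTKFile>")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtu(path):
    """Parse an ASCII .vtu back into (points, cells, cell_data, point_data).

    ``cells`` is a list of (vtk_type, node_tuple).  Uses an XML parser, not
    the writer's own string templates, so a write/read round trip is a real
    consistency check.
    """
    try:
        from lxml import etree
    except ImportError:  # pragma: no cover - lxml is a test dependency
        import xml.etree.ElementTree as etree  # type: ignore

    tree = etree.parse(str(path))
    root = tree.getroot()
    piece = root.find(".//{*}Piece") if hasattr(root, "find") else None
    if piece is None:
        piece = root.find(".//Piece")
    if piece is None:
        raise VtuError(f"no <Piece> element in {path}")

    def grab(parent, name=None):
        out = {}
        for da in parent.iter():
            if not str(da.tag).endswith("DataArray"):
                continue
            nm = da.get("Name") or "__points__"
            text = (da.text or "").split()
            if da.get("type") in ("Int64", "Int32", "UInt8"):
                vals = np.array([int(v) for v in text], dtype=np.int64)
            else:
                vals = np.array([float(v) for v in text])
            ncomp = int(da.get("NumberOfComponents") or 1)
            if ncomp > 1:
                vals = vals.reshape(-1, ncomp)
            out[nm] = vals
        return out

    def child(tag):
        for c in piece:
            if str(c.tag).endswith(tag):
                return c
        raise VtuError(f"missing <{tag}> in {path}")

    points = grab(child("Points"))["__points__"].reshape(-1, 3)
    cells_raw = grab(child("Cells"))
    conn = cells_raw["connectivity"]
    offsets = cells_raw["offsets"]
    types = cells_raw["types"]
    cells = []
    start = 0
    for t, end in zip(types, offsets):
        cells.append((int(t), tuple(int(v) for v in conn[start:end])))
        start = int(end)
    cell_data = grab(child("CellData"))
    point_data = grab(child("PointData"))
    return points, cells, cell_data, point_data
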