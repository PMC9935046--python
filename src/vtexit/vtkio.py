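"""Plain-text VTK XML (.vtu) export/import for tetrahedral meshes.

Writes ASCII UnstructuredGrid files carrying the mesh, per-node data
(surface labels, UVC coordinates, activation times) and per-element
data (fiber vectors, conduction multipliers); reads back meshes written
by this module or other tools emitting ASCII tet .vtu files.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Optional

import numpy as np

from .geometry import VentricularMesh

__all__ = ["write_vtu", "read_vtu", "mesh_point_data"]

_VTK_TETRA = 10


def _data_array(name: str, arr: np.ndarray) -> str:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        dtype, fmt = "Int64", "%d"
    else:
        dtype, fmt = "Float64", "%.17g"
    comps = arr.shape[1] if arr.ndim == 2 else 1
    body = "\n".join(" ".join(fmt % v for v in np.atleast_1d(row)) for row in arr)
    ncomp = f' NumberOfComponents="{comps}"' if comps > 1 else ""
    return f'<DataArray type="{dtype}" Name="{name}"{ncomp} format="ascii">\n{body}\n</DataArray>'


def mesh_point_data(mesh: VentricularMesh) -> dict:
    """Standard per-node label arrays for export."""
    n = mesh.n_nodes
    labels = {
        "endocardium": np.zeros(n, dtype=np.int64),
        "epicardium": np.zeros(n, dtype=np.int64),
        "base": np.zeros(n, dtype=np.int64),
        "apex_node": np.zeros(n, dtype=np.int64),
    }
    labels["endocardium"][mesh.endo_nodes] = 1
    labels["epicardium"][mesh.epi_nodes] = 1
    labels["base"][mesh.base_nodes] = 1
    labels["apex_node"][mesh.apex_node] = 1
    return labels


def write_vtu(
    mesh: VentricularMesh,
    path,
    point_data: Optional[dict] = None,
    cell_data: Optional[dict] = None,
    include_labels: bool = True,
) -> None:
    pdata = dict(mesh_point_data(mesh)) if include_labels else {}
    pdata.update(point_data or {})
    cdata = dict(cell_data or {})
    if mesh.fiber_dirs is not None and "fibers" not in cdata:
        cdata["fibers"] = mesh.fiber_dirs
    n, m = mesh.n_nodes, mesh.n_elements
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        _data_array("Points", mesh.nodes),
        "</Points>",
        "<Cells>",
        _data_array("connectivity", mesh.elements.ravel()),
        _data_array("offsets", 4 * np.arange(1, m + 1)),
        _data_array("types", np.full(m, _VTK_TETRA)),
        "</Cells>",
    ]
    if pdata:
        parts.append("<PointData>")
        parts.extend(_data_array(k, v) for k, v in pdata.items())
        parts.append("</PointData>")
    if cdata:
        parts.append("<CellData>")
        parts.extend(_data_array(k, v) for k, v in cdata.items())
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def _parse_array(el) -> np.ndarray:
    dtype = float if el.attrib.get("type", "Float64").startswith("Float") else np.int64
    vals = np.array((el.text or "").split(), dtype=float).astype(dtype)
    comps = int(el.attrib.get("NumberOfComponents", 1))
    return vals.reshape(-1, comps) if comps > 1 else vals


def read_vtu(path, anatomy_id: str = "imported") -> tuple[VentricularMesh, dict, dict]:
    """Read an ASCII tet .vtu; returns (mesh, point_data, cell_data).

    Surface labels are reconstructed from the standard label arrays when
    present; otherwise the mesh is returned with empty labels (the
    caller must label it before UVC computation).
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    arrays = {el.attrib["Name"]: el for el in piece.iter("DataArray")}
    nodes = _parse_array(arrays["Points"])
    conn = _parse_array(arrays["connectivity"]).astype(np.int64)
    types = _parse_array(arrays["types"])
    if not np.all(types == _VTK_TETRA):
        raise ValueError("only tetrahedral .vtu files are supported")
    elements = conn.reshape(-1, 4)
    pdata, cdata = {}, {}
    for section, out in (("PointData", pdata), ("CellData", cdata)):
        sec = piece.find(section)
        if sec is not None:
            for el in sec.iter("DataArray"):
                out[el.attrib["Name"]] = _parse_array(el)

    def _idx(name):
        return np.flatnonzero(pdata[name]) if name in pdata else np.array([], dtype=int)

    apex = _idx("apex_node")
    fibers = cdata.get("fibers")
    mesh = VentricularMesh(
        nodes=nodes,
        elements=elements,
        endo_nodes=_idx("endocardium"),
        epi_nodes=_idx("epicardium"),
        base_nodes=_idx("base"),
        apex_node=int(apex[0]) if apex.size else 0,
        septal_ref_dir=np.array([1.0, 0.0, 0.0]),
        anatomy_id=anatomy_id,
        fiber_dirs=np.asarray(fibers, dtype=float) if fibers is not None else None,
    )
    return mesh, pdata, cdata
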