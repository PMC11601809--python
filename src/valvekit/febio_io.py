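"""FEBio input-deck export and standard mesh file I/O.

The ``.feb`` writer emits a paper-faithful FEBio 4.0 deck (generalized-
alpha dynamic analysis, Lee–Sacks shells, linear-truss chordae, pressure
ramp load curve, pinned annulus/papillary node sets, contact section) so
the configuration can be run in FEBio externally. Deck units: mm/N/MPa.

Mesh I/O covers ASCII VTK XML (.vtu/.vtp), STL, OBJ and PLY without
external dependencies; valve feature labels travel in named point-data
arrays plus a JSON sidecar (``<path>.meta.json``).
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET

import numpy as np

from .chordae_gen import ChordaeSet
from .closure_solver import KPA_TO_MPA as _KPA
from .closure_solver import MMHG_TO_MPA, SimulationConfig
from .mechanics import MaterialParams
from .valve_geometry import ValveModel

__all__ = ["write_feb", "parse_feb", "write_mesh", "read_mesh",
           "write_chordae_vtp", "read_chordae_vtp", "FEB_SPEC_VERSION"]

# pinned FEBio dialect names (single mapping table)
FEB_SPEC_VERSION = "4.0"
FEB_MAT_LEE_SACKS = "isotropic Lee-Sacks"
FEB_MAT_TRUSS = "linear truss"
FEB_CONTACT_TYPE = "contact potential"
FEB_SOLVER = "generalized-alpha"

_F = "{:.17g}".format


def _fmt(v) -> str:
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return _F(float(v))


# ---------------------------------------------------------------------------
# FEBio deck
# ---------------------------------------------------------------------------


def write_feb(model: ValveModel, chordae: ChordaeSet | None, mat: MaterialParams,
              config: SimulationConfig, path) -> None:
    """Write a FEBio 4.0 XML input deck. Deterministic bytes for fixed inputs."""
    if model.quads.shape[1] != 4:
        raise ValueError("unsupported element type: only quad4 shells are exported")
    root = ET.Element("febio_spec", version=FEB_SPEC_VERSION)
    ET.SubElement(root, "Module", type="solid")

    control = ET.SubElement(root, "Control")
    ET.SubElement(control, "analysis").text = "DYNAMIC"
    n_steps = max(int(round(config.ramp_time / config.dt_max)), 1)
    ET.SubElement(control, "time_steps").text = str(n_steps)
    ET.SubElement(control, "step_size").text = _fmt(config.ramp_time / n_steps)
    stepper = ET.SubElement(control, "time_stepper", type="default")
    ET.SubElement(stepper, "dtmin").text = _fmt(config.dt_min)
    ET.SubElement(stepper, "dtmax").text = _fmt(config.dt_max)
    solver = ET.SubElement(control, "solver", type="solid")
    ET.SubElement(solver, "integration").text = FEB_SOLVER
    ET.SubElement(solver, "mass_damping").text = _fmt(config.damping_c)

    mats = ET.SubElement(root, "Material")
    m1 = ET.SubElement(mats, "material", id="1", name="leaflet", type=FEB_MAT_LEE_SACKS)
    ET.SubElement(m1, "density").text = _fmt(mat.tissue_density)
    ET.SubElement(m1, "c0").text = _fmt(mat.c0 * _KPA)
    ET.SubElement(m1, "c1").text = _fmt(mat.c1 * _KPA)
    ET.SubElement(m1, "c2").text = _fmt(mat.c2)
    ET.SubElement(m1, "k").text = _fmt(mat.bulk_modulus * _KPA)
    has_truss = chordae is not None and chordae.n_segments > 0
    if has_truss:
        m2 = ET.SubElement(mats, "material", id="2", name="chordae", type=FEB_MAT_TRUSS)
        ET.SubElement(m2, "density").text = _fmt(mat.tissue_density)
        ET.SubElement(m2, "E").text = _fmt(mat.truss_modulus)

    mesh = ET.SubElement(root, "Mesh")
    nodes_el = ET.SubElement(mesh, "Nodes", name="all")
    allx = chordae.all_nodes(model.nodes) if chordae is not None else model.nodes
    for i, p in enumerate(allx, start=1):
        ET.SubElement(nodes_el, "node", id=str(i)).text = ",".join(_F(c) for c in p)

    shells = ET.SubElement(mesh, "Elements", type="quad4", name="leaflets")
    for k, q in enumerate(model.quads, start=1):
        ET.SubElement(shells, "elem", id=str(k)).text = ",".join(str(int(i) + 1) for i in q)
    if has_truss:
        trusses = ET.SubElement(mesh, "Elements", type="line2", name="chordae")
        for k, s in enumerate(chordae.segments, start=len(model.quads) + 1):
            ET.SubElement(trusses, "elem", id=str(k)).text = ",".join(str(int(i) + 1) for i in s)

    ann = ET.SubElement(mesh, "NodeSet", name="annulus")
    ann.text = ",".join(str(int(i) + 1) for i in model.annulus_nodes)
    if has_truss:
        pm = ET.SubElement(mesh, "NodeSet", name="papillary")
        pm.text = ",".join(str(int(i) + 1) for i in chordae.papillary_node_index)

    surf = ET.SubElement(mesh, "Surface", name="ventricular")
    for k, q in enumerate(model.quads, start=1):
        ET.SubElement(surf, "quad4", id=str(k)).text = ",".join(str(int(i) + 1) for i in q)

    domains = ET.SubElement(root, "MeshDomains")
    sd = ET.SubElement(domains, "ShellDomain", name="leaflets", mat="leaflet")
    ET.SubElement(sd, "shell_thickness").text = _fmt(mat.thickness)
    if has_truss:
        td = ET.SubElement(domains, "TrussDomain", name="chordae", mat="chordae")
        ET.SubElement(td, "area").text = _fmt(float(chordae.segment_csa[0]))
        if not np.allclose(chordae.segment_csa, chordae.segment_csa[0]):
            md = ET.SubElement(root, "MeshData")
            ed = ET.SubElement(md, "ElementData", name="area", elem_set="chordae")
            for k, a in enumerate(chordae.segment_csa, start=1):
                ET.SubElement(ed, "e", lid=str(k)).text = _fmt(a)

    bcs = ET.SubElement(root, "Boundary")
    for name in (["annulus", "papillary"] if has_truss else ["annulus"]):
        bc = ET.SubElement(bcs, "bc", name=f"fix_{name}", type="zero displacement",
                           node_set=name)
        for dof in ("x_dof", "y_dof", "z_dof"):
            ET.SubElement(bc, dof).text = "1"

    loads = ET.SubElement(root, "Loads")
    sl = ET.SubElement(loads, "surface_load", name="systolic", type="pressure",
                       surface="ventricular")
    pr = ET.SubElement(sl, "pressure", lc="1")
    pr.text = _fmt(config.pressure_peak * MMHG_TO_MPA)
    ET.SubElement(sl, "symmetric_stiffness").text = "1"

    contact = ET.SubElement(root, "Contact")
    cp = ET.SubElement(contact, "contact", type=FEB_CONTACT_TYPE, name="leaflet_contact",
                       surface_pair="self")
    ET.SubElement(cp, "kc").text = _fmt(config.contact_penalty)

    ld = ET.SubElement(root, "LoadData")
    lc = ET.SubElement(ld, "load_controller", id="1", type="loadcurve")
    ET.SubElement(lc, "interpolate").text = "LINEAR"
    pts = ET.SubElement(lc, "points")
    ET.SubElement(pts, "pt").text = "0,0"
    ET.SubElement(pts, "pt").text = f"{_F(config.ramp_time)},1"

    ET.indent(root, space="  ")
    data = ET.tostring(root, encoding="unicode")
    with open(path, "w", newline="\n") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write(data)
        fh.write("\n")


def parse_feb(path) -> dict:
    """Re-parse a written deck: counts and the headline numeric values."""
    root = ET.parse(path).getroot()
    out = {"version": root.get("version")}
    mesh = root.find("Mesh")
    out["n_nodes"] = len(mesh.find("Nodes"))
    out["n_quads"] = 0
    out["n_trusses"] = 0
    for el in mesh.findall("Elements"):
        if el.get("type") == "quad4":
            out["n_quads"] += len(el)
        elif el.get("type") == "line2":
            out["n_trusses"] += len(el)
    sd = root.find("MeshDomains/ShellDomain/shell_thickness")
    out["shell_thickness"] = float(sd.text)
    for m in root.find("Material"):
        if m.get("type") == FEB_MAT_TRUSS:
            out["truss_modulus"] = float(m.find("E").text)
        if m.get("type") == FEB_MAT_LEE_SACKS:
            out["c0_mpa"] = float(m.find("c0").text)
            out["c1_mpa"] = float(m.find("c1").text)
            out["c2"] = float(m.find("c2").text)
            out["bulk_mpa"] = float(m.find("k").text)
    st = root.find("Control/time_stepper")
    out["dtmin"] = float(st.find("dtmin").text)
    out["dtmax"] = float(st.find("dtmax").text)
    out["pressure_mpa"] = float(root.find("Loads/surface_load/pressure").text)
    pts = root.findall("LoadData/load_controller/points/pt")
    out["ramp_time"] = float(pts[-1].text.split(",")[0])
    out["analysis"] = root.find("Control/analysis").text
    out["integration"] = root.find("Control/solver/integration").text
    return out


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path) -> str:
    return str(path) + ".meta.json"


def _model_sidecar(model: ValveModel) -> dict:
    return {
        "annulus_nodes": [int(i) for i in model.annulus_nodes],
        "free_edge_paths": [[int(i) for i in p] for p in model.free_edge_paths],
        "papillary_tips": np.asarray(model.papillary_tips).tolist(),
        "thickness": float(model.thickness),
        "leaflet_label": [int(i) for i in model.leaflet_label],
        "meta": {k: v for k, v in model.meta.items()
                 if not k.startswith("_") and _jsonable(v)},
    }


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _write_vtk_xml(path, points, cells, cell_kind, point_data=None, cell_data=None):
    """Minimal ASCII VTK XML writer. cell_kind: 'quad'|'line'|'poly'."""
    points = np.asarray(points, dtype=float)
    lines = []
    n_cells = len(cells)
    if cell_kind == "quad":
        grid_tag = "UnstructuredGrid"
        piece = f'<Piece NumberOfPoints="{len(points)}" NumberOfCells="{n_cells}">'
    else:
        grid_tag = "PolyData"
        n_lines = n_cells if cell_kind == "line" else 0
        n_polys = n_cells if cell_kind == "poly" else 0
        piece = (f'<Piece NumberOfPoints="{len(points)}" NumberOfVerts="0" '
                 f'NumberOfLines="{n_lines}" NumberOfStrips="0" NumberOfPolys="{n_polys}">')
    lines.append('<?xml version="1.0"?>')
    lines.append(f'<VTKFile type="{grid_tag}" version="1.0" byte_order="LittleEndian">')
    lines.append(f"<{grid_tag}>")
    lines.append(piece)
    lines.append('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    lines.extend(" ".join(_F(c) for c in p) for p in points)
    lines.append("</DataArray></Points>")

    conn = " ".join(" ".join(str(int(i)) for i in c) for c in cells)
    offsets = np.cumsum([len(c) for c in cells])
    off_txt = " ".join(str(o) for o in offsets)
    if grid_tag == "UnstructuredGrid":
        lines.append("<Cells>")
        lines.append(f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>')
        lines.append(f'<DataArray type="Int64" Name="offsets" format="ascii">{off_txt}</DataArray>')
        lines.append('<DataArray type="UInt8" Name="types" format="ascii">'
                     + " ".join(["9"] * n_cells) + "</DataArray>")
        lines.append("</Cells>")
    else:
        tag = "Lines" if cell_kind == "line" else "Polys"
        lines.append(f"<{tag}>")
        lines.append(f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>')
        lines.append(f'<DataArray type="Int64" Name="offsets" format="ascii">{off_txt}</DataArray>')
        lines.append(f"</{tag}>")

    for tag, data in (("PointData", point_data), ("CellData", cell_data)):
        if data:
            lines.append(f"<{tag}>")
            for name, arr in data.items():
                arr = np.asarray(arr)
                typ = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
                body = " ".join(str(int(v)) if typ == "Int64" else _F(v) for v in arr.ravel())
                ncomp = arr.shape[1] if arr.ndim == 2 else 1
                lines.append(f'<DataArray type="{typ}" Name="{name}" '
                             f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>')
            lines.append(f"</{tag}>")
    lines.append("</Piece>")
    lines.append(f"</{grid_tag}>")
    lines.append("</VTKFile>")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_vtk_xml(path):
    root = ET.parse(path).getroot()
    grid = root[0]
    piece = grid.find("Piece")
    pts = np.fromstring(piece.find("Points/DataArray").text.replace("\n", " "), sep=" ")
    points = pts.reshape(-1, 3)
    cells_parent = piece.find("Cells")
    if cells_parent is None:
        cells_parent = piece.find("Polys")
    if cells_parent is None:
        cells_parent = piece.find("Lines")
    conn = offs = None
    for da in cells_parent.findall("DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text.replace("\n", " "), dtype=np.int64, sep=" ")
        elif da.get("Name") == "offsets":
            offs = np.fromstring(da.text.replace("\n", " "), dtype=np.int64, sep=" ")
    cells = np.split(conn, offs[:-1]) if len(offs) else []
    data = {"point": {}, "cell": {}}
    for tag, key in (("PointData", "point"), ("CellData", "cell")):
        td = piece.find(tag)
        if td is not None:
            for da in td.findall("DataArray"):
                dtype = np.int64 if da.get("type") == "Int64" else float
                arr = np.fromstring(da.text.replace("\n", " "), dtype=dtype, sep=" ")
                ncomp = int(da.get("NumberOfComponents", "1"))
                if ncomp > 1:
                    arr = arr.reshape(-1, ncomp)
                data[key][da.get("Name")] = arr
    return points, cells, data


def write_mesh(model: ValveModel, path) -> None:
    """Export the valve surface; format from the file suffix
    (.vtu/.vtp/.stl/.obj/.ply). Labelled formats get a JSON sidecar."""
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".vtu", ".vtp"):
        ann_order = np.full(model.n_nodes, -1, dtype=np.int64)
        ann_order[model.annulus_nodes] = np.arange(len(model.annulus_nodes))
        fe_leaf = np.full(model.n_nodes, -1, dtype=np.int64)
        for l, p in enumerate(model.free_edge_paths):
            fe_leaf[np.asarray(p)] = l
        pdata = {"annulus_order": ann_order, "free_edge_leaflet": fe_leaf}
        cdata = {"leaflet_label": model.leaflet_label}
        kind = "quad" if ext == ".vtu" else "poly"
        _write_vtk_xml(path, model.nodes, list(model.quads), kind, pdata, cdata)
        with open(_sidecar_path(path), "w", newline="\n") as fh:
            json.dump(_model_sidecar(model), fh, indent=1, sort_keys=True)
    elif ext == ".stl":
        tris = []
        for q in model.quads:
            tris.append([q[0], q[1], q[2]])
            tris.append([q[0], q[2], q[3]])
        with open(path, "w", newline="\n") as fh:
            fh.write("solid valve\n")
            for t in tris:
                p = model.nodes[t]
                n = np.cross(p[1] - p[0], p[2] - p[0])
                nn = np.linalg.norm(n)
                n = n / nn if nn > 0 else n
                fh.write("facet normal " + " ".join(_F(c) for c in n) + "\n outer loop\n")
                for v in p:
                    fh.write("  vertex " + " ".join(_F(c) for c in v) + "\n")
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid valve\n")
    elif ext == ".obj":
        with open(path, "w", newline="\n") as fh:
            for p in model.nodes:
                fh.write("v " + " ".join(_F(c) for c in p) + "\n")
            for q in model.quads:
                fh.write("f " + " ".join(str(int(i) + 1) for i in q) + "\n")
    elif ext == ".ply":
        with open(path, "w", newline="\n") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {model.n_nodes}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {model.n_quads}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p in model.nodes:
                fh.write(" ".join(_F(c) for c in p) + "\n")
            for q in model.quads:
                fh.write("4 " + " ".join(str(int(i)) for i in q) + "\n")
    else:
        raise ValueError(f"unsupported mesh format {ext!r}")


def read_mesh(path) -> ValveModel:
    """Read a valve surface; returns ``labelled=False`` (empty feature sets)
    when no sidecar/labels are available (STL/OBJ/PLY)."""
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".vtu", ".vtp"):
        points, cells, data = _read_vtk_xml(path)
        quads = np.asarray([c for c in cells if len(c) == 4], dtype=np.int64)
        side = _sidecar_path(path)
        if os.path.exists(side):
            with open(side) as fh:
                sc = json.load(fh)
            return ValveModel(
                nodes=points, quads=quads,
                annulus_nodes=np.asarray(sc["annulus_nodes"], dtype=np.int64),
                free_edge_paths=[np.asarray(p, dtype=np.int64) for p in sc["free_edge_paths"]],
                leaflet_label=np.asarray(sc["leaflet_label"], dtype=np.int64),
                papillary_tips=np.asarray(sc["papillary_tips"], dtype=float).reshape(-1, 3),
                thickness=float(sc["thickness"]), meta=dict(sc.get("meta", {})),
            )
        label = data["cell"].get("leaflet_label", np.zeros(len(quads), dtype=np.int64))
        return ValveModel(nodes=points, quads=quads,
                          annulus_nodes=np.empty(0, dtype=np.int64),
                          free_edge_paths=[], leaflet_label=np.asarray(label),
                          papillary_tips=np.empty((0, 3)), labelled=False)
    if ext == ".obj":
        verts, faces = [], []
        with open(path) as fh:
            for line in fh:
                t = line.split()
                if not t:
                    continue
                if t[0] == "v":
                    verts.append([float(x) for x in t[1:4]])
                elif t[0] == "f":
                    faces.append([int(x.split("/")[0]) - 1 for x in t[1:]])
        quads = np.asarray([f for f in faces if len(f) == 4], dtype=np.int64)
        return ValveModel(nodes=np.asarray(verts), quads=quads.reshape(-1, 4),
                          annulus_nodes=np.empty(0, dtype=np.int64), free_edge_paths=[],
                          leaflet_label=np.zeros(len(quads), dtype=np.int64),
                          papillary_tips=np.empty((0, 3)), labelled=False)
    if ext == ".ply":
        with open(path) as fh:
            line = fh.readline()
            nv = nf = 0
            while "end_header" not in line:
                if line.startswith("element vertex"):
                    nv = int(line.split()[-1])
                elif line.startswith("element face"):
                    nf = int(line.split()[-1])
                line = fh.readline()
            verts = [[float(x) for x in fh.readline().split()[:3]] for _ in range(nv)]
            faces = []
            for _ in range(nf):
                t = fh.readline().split()
                faces.append([int(x) for x in t[1:1 + int(t[0])]])
        quads = np.asarray([f for f in faces if len(f) == 4], dtype=np.int64)
        return ValveModel(nodes=np.asarray(verts), quads=quads.reshape(-1, 4),
                          annulus_nodes=np.empty(0, dtype=np.int64), free_edge_paths=[],
                          leaflet_label=np.zeros(len(quads), dtype=np.int64),
                          papillary_tips=np.empty((0, 3)), labelled=False)
    if ext == ".stl":
        verts, vmap, tris = [], {}, []
        with open(path) as fh:
            cur = []
            for line in fh:
                t = line.split()
                if t and t[0] == "vertex":
                    key = tuple(float(x) for x in t[1:4])
                    if key not in vmap:
                        vmap[key] = len(verts)
                        verts.append(list(key))
                    cur.append(vmap[key])
                    if len(cur) == 3:
                        tris.append(cur)
                        cur = []
        # triangles only: represent as degenerate quads (last node repeated)
        quads = np.asarray([[a, b, c, c] for a, b, c in tris], dtype=np.int64)
        return ValveModel(nodes=np.asarray(verts), quads=quads.reshape(-1, 4),
                          annulus_nodes=np.empty(0, dtype=np.int64), free_edge_paths=[],
                          leaflet_label=np.zeros(len(quads), dtype=np.int64),
                          papillary_tips=np.empty((0, 3)), labelled=False)
    raise ValueError(f"unsupported mesh format {ext!r}")


def write_chordae_vtp(chordae: ChordaeSet, model: ValveModel, path) -> None:
    """Chordae network as a VTK XML line set with csa/chord_id/chord_class
    cell arrays; topology metadata in the JSON sidecar."""
    path = str(path)
    allx = chordae.all_nodes(model.nodes)
    cdata = {
        "csa": chordae.segment_csa,
        "chord_id": chordae.chord_id,
        "chord_class": chordae.chord_class[chordae.chord_id],
    }
    _write_vtk_xml(path, allx, list(chordae.segments), "line", None, cdata)
    side = {
        "n_valve_nodes": int(chordae.n_valve_nodes),
        "chord_class": [int(c) for c in chordae.chord_class],
        "insertion_centers": np.asarray(chordae.insertion_centers).tolist(),
        "papillary_label": [int(p) for p in chordae.papillary_label],
        "papillary_node_index": [int(i) for i in chordae.papillary_node_index],
    }
    with open(_sidecar_path(path), "w", newline="\n") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)


def read_chordae_vtp(path) -> ChordaeSet:
    path = str(path)
    points, cells, data = _read_vtk_xml(path)
    with open(_sidecar_path(path)) as fh:
        sc = json.load(fh)
    n_valve = int(sc["n_valve_nodes"])
    return ChordaeSet(
        n_valve_nodes=n_valve,
        extra_nodes=points[n_valve:],
        segments=np.asarray([c for c in cells], dtype=np.int64).reshape(-1, 2),
        segment_csa=np.asarray(data["cell"]["csa"], dtype=float),
        chord_id=np.asarray(data["cell"]["chord_id"], dtype=np.int64),
        chord_class=np.asarray(sc["chord_class"], dtype=np.int64),
        insertion_centers=np.asarray(sc["insertion_centers"], dtype=float).reshape(-1, 3),
        papillary_label=np.asarray(sc["papillary_label"], dtype=np.int64),
        papillary_node_index=np.asarray(sc["papillary_node_index"], dtype=np.int64),
    )
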