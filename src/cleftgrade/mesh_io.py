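"""Triangle-mesh container and I/O in the formats surface models ship in.

Surface models of the maxilla are exchanged as VTK polydata (legacy ``.vtk``
or XML ``.vtp``), Wavefront OBJ or PLY.  This module reads any of those into a
single in-memory :class:`TriangleMesh`, preserves named per-vertex scalar
arrays (the carrier for SurfGradCAM heatmaps), and writes them back out so the
results open in standard mesh viewers.

VTK files are parsed directly (ASCII legacy polydata and ASCII XML polydata);
OBJ and PLY delegate to :mod:`trimesh`.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "normalize_pose",
]


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or violates an invariant."""


@dataclass
class TriangleMesh:
    """Indexed triangle mesh with optional named per-vertex scalar arrays.

    Vertices are ``(n, 3)`` float64 in arbitrary model units; faces are
    ``(m, 3)`` int64 with 0-based vertex indices.  ``vertex_scalars`` maps an
    array name (e.g. ``"surfgradcam_class3"``) to one float per vertex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.vertex_scalars = {
            k: np.asarray(v, dtype=np.float64).ravel()
            for k, v in self.vertex_scalars.items()
        }
        self.validate()

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> None:
        if self.n_vertices == 0:
            raise MeshFormatError("empty mesh: zero vertices")
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshFormatError(
                f"face index out of range [0, {self.n_vertices})"
            )
        for name, arr in self.vertex_scalars.items():
            if arr.shape != (self.n_vertices,):
                raise MeshFormatError(
                    f"scalar array {name!r} has length {arr.shape[0]}, "
                    f"expected {self.n_vertices}"
                )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.vertex_scalars.items()},
        )

    def face_normals(self) -> np.ndarray:
        """Unnormalized face normals via the right-hand rule."""
        v = self.vertices
        f = self.faces
        return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])


def _fan_triangulate(polygons: list[list[int]]) -> np.ndarray:
    """Split arbitrary simple polygons into triangle fans around vertex 0."""
    tris: list[tuple[int, int, int]] = []
    for poly in polygons:
        if len(poly) < 3:
            continue
        for i in range(1, len(poly) - 1):
            tris.append((poly[0], poly[i], poly[i + 1]))
    return np.asarray(tris, dtype=np.int64).reshape(-1, 3)


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata


def _read_vtk(path: Path) -> TriangleMesh:
    try:
        tokens_lines = path.read_text().splitlines()
    except UnicodeDecodeError as exc:  # binary legacy VTK
        raise MeshFormatError(f"{path}: binary legacy VTK is not supported") from exc

    # tokenize lazily, keeping track for error messages
    toks: list[str] = []
    for ln in tokens_lines:
        toks.extend(ln.split())

    def expect(i: int, word: str) -> None:
        if i >= len(toks) or toks[i].upper() != word:
            got = toks[i] if i < len(toks) else "<eof>"
            raise MeshFormatError(f"{path}: expected {word}, got {got!r}")

    i = 0
    # header: "# vtk DataFile Version x.y" then title line then ASCII then DATASET
    while i < len(toks) and toks[i].upper() != "ASCII":
        if toks[i].upper() == "BINARY":
            raise MeshFormatError(f"{path}: binary legacy VTK is not supported")
        i += 1
    expect(i, "ASCII")
    i += 1
    expect(i, "DATASET")
    if toks[i + 1].upper() != "POLYDATA":
        raise MeshFormatError(f"{path}: DATASET {toks[i + 1]} is not POLYDATA")
    i += 2

    vertices = np.empty((0, 3))
    polygons: list[list[int]] = []
    scalars: dict[str, np.ndarray] = {}
    n_points = 0

    while i < len(toks):
        key = toks[i].upper()
        if key == "POINTS":
            n_points = int(toks[i + 1])
            i += 3  # POINTS n dtype
            flat = np.array(toks[i : i + 3 * n_points], dtype=np.float64)
            vertices = flat.reshape(n_points, 3)
            i += 3 * n_points
        elif key == "POLYGONS":
            n_poly = int(toks[i + 1])
            total = int(toks[i + 2])
            i += 3
            j = 0
            for _ in range(n_poly):
                arity = int(toks[i + j])
                poly = [int(t) for t in toks[i + j + 1 : i + j + 1 + arity]]
                polygons.append(poly)
                j += arity + 1
            if j != total:
                raise MeshFormatError(f"{path}: POLYGONS size mismatch")
            i += j
        elif key == "POINT_DATA":
            if int(toks[i + 1]) != n_points:
                raise MeshFormatError(f"{path}: POINT_DATA count != POINTS count")
            i += 2
        elif key == "SCALARS":
            name = toks[i + 1]
            ncomp = 1
            # optional numComp token after dtype
            if i + 3 < len(toks) and toks[i + 3].isdigit():
                ncomp = int(toks[i + 3])
                i += 4
            else:
                i += 3
            if toks[i].upper() == "LOOKUP_TABLE":
                i += 2
            vals = np.array(toks[i : i + n_points * ncomp], dtype=np.float64)
            scalars[name] = vals.reshape(n_points, ncomp)[:, 0] if ncomp > 1 else vals
            i += n_points * ncomp
        elif key == "FIELD":
            n_arrays = int(toks[i + 2])
            i += 3
            for _ in range(n_arrays):
                name, ncomp, ntup = toks[i], int(toks[i + 1]), int(toks[i + 2])
                i += 4  # name ncomp ntuples dtype
                vals = np.array(toks[i : i + ncomp * ntup], dtype=np.float64)
                if ntup == n_points and ncomp == 1:
                    scalars[name] = vals
                i += ncomp * ntup
        elif key in ("CELL_DATA", "LINES", "VERTICES", "TRIANGLE_STRIPS"):
            raise MeshFormatError(f"{path}: unsupported section {key}")
        else:
            raise MeshFormatError(f"{path}: unrecognized token {toks[i]!r}")

    return TriangleMesh(vertices, _fan_triangulate(polygons), scalars)


def _write_vtk(path: Path, mesh: TriangleMesh) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncleftgrade surface model\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if mesh.vertex_scalars:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            fh.write(f"FIELD FieldData {len(mesh.vertex_scalars)}\n")
            for name, arr in mesh.vertex_scalars.items():
                fh.write(f"{name} 1 {mesh.n_vertices} float\n")
                fh.write(" ".join(f"{x:.9g}" for x in arr) + "\n")


# ---------------------------------------------------------------------------
# VTK XML polydata (.vtp), ASCII appended-free flavour


def _read_vtp(path: Path) -> TriangleMesh:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise MeshFormatError(f"{path}: not well-formed XML ({exc})") from exc
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise MeshFormatError(f"{path}: no PolyData/Piece element")

    def data_array(el: ET.Element) -> np.ndarray:
        if el.get("format", "ascii") != "ascii":
            raise MeshFormatError(f"{path}: only ascii-format DataArray supported")
        return np.array((el.text or "").split(), dtype=np.float64)

    pts_el = piece.find("./Points/DataArray")
    if pts_el is None:
        raise MeshFormatError(f"{path}: missing Points DataArray")
    vertices = data_array(pts_el).reshape(-1, 3)

    polys = piece.find("Polys")
    polygons: list[list[int]] = []
    if polys is not None:
        conn = off = None
        for el in polys.findall("DataArray"):
            if el.get("Name") == "connectivity":
                conn = data_array(el).astype(np.int64)
            elif el.get("Name") == "offsets":
                off = data_array(el).astype(np.int64)
        if conn is None or off is None:
            raise MeshFormatError(f"{path}: Polys missing connectivity/offsets")
        start = 0
        for end in off:
            polygons.append(list(conn[start:end]))
            start = int(end)

    scalars: dict[str, np.ndarray] = {}
    pdata = piece.find("PointData")
    if pdata is not None:
        for el in pdata.findall("DataArray"):
            name = el.get("Name", "scalars")
            ncomp = int(el.get("NumberOfComponents", "1"))
            vals = data_array(el)
            if ncomp == 1:
                scalars[name] = vals

    return TriangleMesh(vertices, _fan_triangulate(polygons), scalars)


def _write_vtp(path: Path, mesh: TriangleMesh) -> None:
    root = ET.Element(
        "VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian"
    )
    pd = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        pd,
        "Piece",
        NumberOfPoints=str(mesh.n_vertices),
        NumberOfPolys=str(mesh.n_faces),
    )
    pdata = ET.SubElement(piece, "PointData")
    for name, arr in mesh.vertex_scalars.items():
        el = ET.SubElement(
            pdata, "DataArray", type="Float32", Name=name, format="ascii"
        )
        el.text = " ".join(f"{x:.9g}" for x in arr)
    points = ET.SubElement(piece, "Points")
    el = ET.SubElement(
        points, "DataArray", type="Float32", NumberOfComponents="3", format="ascii"
    )
    el.text = " ".join(f"{x:.9g}" for x in mesh.vertices.ravel())
    polys = ET.SubElement(piece, "Polys")
    el = ET.SubElement(polys, "DataArray", type="Int64", Name="connectivity", format="ascii")
    el.text = " ".join(str(i) for i in mesh.faces.ravel())
    el = ET.SubElement(polys, "DataArray", type="Int64", Name="offsets", format="ascii")
    el.text = " ".join(str(3 * (i + 1)) for i in range(mesh.n_faces))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# OBJ / PLY via trimesh


def _read_trimesh(path: Path, kind: str) -> TriangleMesh:
    try:
        tm = trimesh.load(str(path), file_type=kind, process=False, force="mesh")
    except Exception as exc:
        raise MeshFormatError(f"{path}: failed to parse as {kind}: {exc}") from exc
    if tm.vertices.shape[0] == 0:
        raise MeshFormatError(f"{path}: empty mesh: zero vertices")
    scalars: dict[str, np.ndarray] = {}
    raw = tm.metadata.get("_ply_raw")
    if raw and "vertex" in raw:
        vdata = raw["vertex"]["data"]
        names = (
            vdata.dtype.names
            if isinstance(vdata, np.ndarray) and vdata.dtype.names
            else (vdata.keys() if isinstance(vdata, dict) else ())
        )
        for name in names:
            if name in ("x", "y", "z", "nx", "ny", "nz", "red", "green", "blue", "alpha"):
                continue
            col = vdata[name]
            col = np.asarray(col, dtype=np.float64).ravel()
            if col.shape == (tm.vertices.shape[0],):
                scalars[name] = col
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), scalars)


def _write_trimesh(path: Path, mesh: TriangleMesh, kind: str) -> None:
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if mesh.vertex_scalars:
        if kind == "obj":
            warnings.warn(
                "OBJ has no per-vertex scalar standard; dropping scalar arrays",
                stacklevel=3,
            )
        else:
            for name, arr in mesh.vertex_scalars.items():
                tm.vertex_attributes[name] = arr.astype(np.float32)
    if kind == "ply":
        tm.export(str(path), file_type="ply", encoding="ascii")
    else:
        tm.export(str(path), file_type=kind)


# ---------------------------------------------------------------------------

_FORMATS = ("vtk", "vtp", "obj", "ply")


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None and fmt != "auto":
        if fmt not in _FORMATS:
            raise MeshFormatError(f"unknown mesh format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise MeshFormatError(f"cannot infer mesh format from suffix of {path}")


def read_mesh(path: str | Path, fmt: str | None = "auto") -> TriangleMesh:
    """Read a triangle mesh, fan-triangulating any non-triangle polygons.

    Parameters
    ----------
    path
        File to read.
    fmt
        One of ``vtk``, ``vtp``, ``obj``, ``ply`` or ``"auto"`` (use suffix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _detect_format(path, fmt)
    if kind == "vtk":
        return _read_vtk(path)
    if kind == "vtp":
        return _read_vtp(path)
    return _read_trimesh(path, kind)


def write_mesh(path: str | Path, mesh: TriangleMesh, fmt: str | None = "auto") -> None:
    """Write a mesh, storing ``vertex_scalars`` as named point-data arrays.

    OBJ cannot carry point data; scalar arrays are dropped with a warning.
    """
    path = Path(path)
    mesh.validate()
    kind = _detect_format(path, fmt)
    if kind == "vtk":
        _write_vtk(path, mesh)
    elif kind == "vtp":
        _write_vtp(path, mesh)
    else:
        _write_trimesh(path, mesh, kind)


def normalize_pose(mesh: TriangleMesh) -> TriangleMesh:
    """Center the vertex centroid at the origin and scale max radius to 1.

    No rotational alignment is applied: the surrounding multi-view camera
    sphere makes the downstream classifier tolerant to orientation, so only
    translation and isotropic scale are removed.
    """
    centered = mesh.vertices - mesh.vertices.mean(axis=0)
    radius = np.linalg.norm(centered, axis=1).max()
    if radius <= 0 or not np.isfinite(radius):
        raise ValueError("degenerate mesh: all vertices coincide (zero scale)")
    return TriangleMesh(
        centered / radius,
        mesh.faces.copy(),
        {k: v.copy() for k, v in mesh.vertex_scalars.items()},
    )
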