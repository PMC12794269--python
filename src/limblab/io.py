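"""Readers and writers for the formats the pipeline touches.

* multi-page TIFF stacks (microscope output), page-major axis order (z, y, x)
* a VTI-style XML "ImageData" structured grid holding data, spacing and
  origin losslessly (base64-encoded raw scalars, no compression)
* surface meshes as ASCII PLY or legacy-VTK ASCII polydata, with optional
  per-vertex scalars
"""

from __future__ import annotations

import base64
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile

from .core import FormatError, SurfaceMesh, VoxelGrid

__all__ = [
    "read_tiff_stack",
    "write_tiff_stack",
    "read_grid",
    "write_grid",
    "read_mesh",
    "write_mesh",
]


# ---------------------------------------------------------------------------
# TIFF stacks


def read_tiff_stack(
    path: str | Path,
    spacing: tuple[float, float, float],
    axes_order: tuple[int, int, int] = (0, 1, 2),
    channel_name: str = "",
) -> VoxelGrid:
    """Read a multi-page TIFF into a grid with ``data[z][y][x]`` page order.

    ``spacing`` is attached verbatim, in array-axis order.  ``axes_order``
    permutes the stored axes for microscopes that emit a different layout.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"TIFF stack not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"TIFF stack {path} has no pages")
    if len(pages) == 1 and pages[0].ndim == 3:
        # single volumetric page (ImageDepth): already a (z, y, x) stack
        pages = list(pages[0])
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"page {i} of {path} is not a scalar 2D image")
        if page.shape != shape0:
            raise FormatError(
                f"page {i} of {path} has shape {page.shape}, expected {shape0}"
            )
    data = np.stack(pages, axis=0)
    if tuple(axes_order) != (0, 1, 2):
        data = np.transpose(data, axes_order)
    return VoxelGrid(data=data, spacing=spacing, channel_name=channel_name)


def write_tiff_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid as a multi-page TIFF (axis 0 = pages)."""
    path = Path(path)
    tifffile.imwrite(path, grid.data, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# VTI-style structured grids

_VTK_TYPES = {
    "uint8": "UInt8",
    "int8": "Int8",
    "uint16": "UInt16",
    "int16": "Int16",
    "uint32": "UInt32",
    "int32": "Int32",
    "uint64": "UInt64",
    "int64": "Int64",
    "float32": "Float32",
    "float64": "Float64",
}
_NUMPY_TYPES = {v: k for k, v in _VTK_TYPES.items()}


def write_grid(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid as XML ImageData with inline base64 scalars.

    The layout mirrors the uncompressed VTI convention: ``WholeExtent``
    counts points per axis, ``Spacing``/``Origin`` carry the physical
    calibration, and the scalar array is stored x-fastest.  Data, spacing
    and origin round-trip losslessly (same scalar dtype).
    """
    path = Path(path)
    dtype = str(grid.data.dtype)
    if dtype not in _VTK_TYPES:
        raise FormatError(f"unsupported scalar type {dtype}")
    n0, n1, n2 = grid.data.shape
    # VTI stores x-fastest; our axis 0 is the slowest — keep the array's own
    # order by declaring extent (axis2, axis1, axis0)
    extent = f"0 {n2 - 1} 0 {n1 - 1} 0 {n0 - 1}"
    spacing = f"{grid.spacing[2]!r} {grid.spacing[1]!r} {grid.spacing[0]!r}"
    origin = f"{grid.origin[2]!r} {grid.origin[1]!r} {grid.origin[0]!r}"
    raw = np.ascontiguousarray(grid.data).tobytes()
    header = np.uint64(len(raw)).tobytes()
    payload = base64.b64encode(header + raw).decode("ascii")
    name = grid.channel_name or "scalars"
    text = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="ImageData" version="1.0" byte_order="LittleEndian" '
        'header_type="UInt64">\n'
        f'  <ImageData WholeExtent="{extent}" Origin="{origin}" Spacing="{spacing}">\n'
        f'    <Piece Extent="{extent}">\n'
        f'      <PointData Scalars="{name}">\n'
        f'        <DataArray type="{_VTK_TYPES[dtype]}" Name="{name}" '
        f'format="binary" NumberOfComponents="1">\n'
        f"          {payload}\n"
        "        </DataArray>\n"
        "      </PointData>\n"
        "    </Piece>\n"
        "  </ImageData>\n"
        "</VTKFile>\n"
    )
    path.write_text(text, encoding="ascii")
    return path


def read_grid(path: str | Path) -> VoxelGrid:
    """Read a grid written by :func:`write_grid`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"grid file not found: {path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"corrupt grid file {path}: {exc}") from exc
    image = root.find("ImageData")
    if image is None:
        raise FormatError(f"{path} is not an ImageData file")
    ext = [int(v) for v in image.attrib["WholeExtent"].split()]
    sp = [float(v) for v in image.attrib["Spacing"].split()]
    og = [float(v) for v in image.attrib["Origin"].split()]
    array = image.find("Piece/PointData/DataArray")
    if array is None or array.text is None:
        raise FormatError(f"{path} has no scalar array")
    dtype = _NUMPY_TYPES.get(array.attrib.get("type", ""))
    if dtype is None:
        raise FormatError(f"unknown scalar type in {path}")
    blob = base64.b64decode(array.text.strip())
    nbytes = int(np.frombuffer(blob[:8], dtype=np.uint64)[0])
    raw = blob[8 : 8 + nbytes]
    if len(raw) != nbytes:
        raise FormatError(f"truncated scalar payload in {path}")
    shape = (ext[5] - ext[4] + 1, ext[3] - ext[2] + 1, ext[1] - ext[0] + 1)
    expected = int(np.prod(shape)) * np.dtype(dtype).itemsize
    if nbytes != expected:
        raise FormatError(
            f"scalar payload of {path} has {nbytes} bytes, expected {expected}"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(shape).copy()
    return VoxelGrid(
        data=data,
        spacing=(sp[2], sp[1], sp[0]),
        origin=(og[2], og[1], og[0]),
        channel_name=array.attrib.get("Name", ""),
    )


# ---------------------------------------------------------------------------
# surface meshes

_MESH_DIALECTS = ("ply", "vtk-ascii")


def write_mesh(mesh: SurfaceMesh, path: str | Path, dialect: str | None = None) -> Path:
    """Write a mesh as ASCII PLY or legacy-VTK ASCII polydata.

    The dialect is inferred from the extension (``.ply`` / ``.vtk``) unless
    given explicitly.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".ply": "ply", ".vtk": "vtk-ascii"}.get(path.suffix.lower())
    if dialect not in _MESH_DIALECTS:
        raise FormatError(
            f"unknown mesh dialect for {path}; supported: {', '.join(_MESH_DIALECTS)}"
        )
    if dialect == "ply":
        _write_ply(mesh, path)
    else:
        _write_vtk(mesh, path)
    return path


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    head = path.read_bytes()[:16]
    if head.startswith(b"ply"):
        return _read_ply(path)
    if head.startswith(b"# vtk"):
        return _read_vtk(path)
    raise FormatError(
        f"unrecognized mesh format in {path}; supported: {', '.join(_MESH_DIALECTS)}"
    )


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    lines = ["ply", "format ascii 1.0", f"element vertex {mesh.n_vertices}"]
    lines += [f"property float64 {ax}" for ax in "xyz"]
    if mesh.scalars is not None:
        lines.append("property float64 quality")
    lines += [
        f"element face {mesh.n_faces}",
        "property list uchar int32 vertex_indices",
        "end_header",
    ]
    for i, v in enumerate(mesh.vertices):
        row = f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}"
        if mesh.scalars is not None:
            row += f" {float(mesh.scalars[i])!r}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n", encoding="ascii")


def _read_ply(path: Path) -> SurfaceMesh:
    lines = path.read_text(encoding="ascii").splitlines()
    n_vert = n_face = 0
    props: list[str] = []
    i = 0
    element = None
    for i, line in enumerate(lines):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise FormatError(f"{path}: only ASCII PLY is supported")
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            props.append(tok[-1])
        elif tok[0] == "end_header":
            break
    body = lines[i + 1 :]
    if len(body) < n_vert + n_face:
        raise FormatError(f"{path}: truncated PLY body")
    vrows = np.array([[float(x) for x in r.split()] for r in body[:n_vert]])
    cols = {p: j for j, p in enumerate(props)}
    verts = vrows[:, [cols["x"], cols["y"], cols["z"]]]
    scal = vrows[:, cols["quality"]] if "quality" in cols else None
    faces = []
    for r in body[n_vert : n_vert + n_face]:
        tok = [int(x) for x in r.split()]
        if tok[0] != 3:
            raise FormatError(f"{path}: non-triangular face with {tok[0]} vertices")
        faces.append(tok[1:4])
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64).reshape(-1, 3), scal)


def _write_vtk(mesh: SurfaceMesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "limblab surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    for v in mesh.vertices:
        lines.append(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    if mesh.scalars is not None:
        lines += [
            f"POINT_DATA {mesh.n_vertices}",
            "SCALARS quality double 1",
            "LOOKUP_TABLE default",
        ]
        lines += [f"{float(s)!r}" for s in mesh.scalars]
    path.write_text("\n".join(lines) + "\n", encoding="ascii")


def _read_vtk(path: Path) -> SurfaceMesh:
    tokens = path.read_text(encoding="ascii").split("\n")
    verts = faces = scal = None
    i = 0
    try:
        while i < len(tokens):
            tok = tokens[i].split()
            if tok and tok[0] == "POINTS":
                n = int(tok[1])
                flat = " ".join(tokens[i + 1 :]).split()
                # points may wrap lines arbitrarily; consume 3n floats
                verts = np.array(flat[: 3 * n], dtype=float).reshape(n, 3)
                consumed = 0
                count = 0
                for j in range(i + 1, len(tokens)):
                    count += len(tokens[j].split())
                    consumed += 1
                    if count >= 3 * n:
                        break
                i += consumed
            elif tok and tok[0] == "POLYGONS":
                n = int(tok[1])
                rows = []
                for j in range(i + 1, i + 1 + n):
                    r = [int(x) for x in tokens[j].split()]
                    if r[0] != 3:
                        raise FormatError(f"{path}: non-triangular polygon")
                    rows.append(r[1:4])
                faces = np.array(rows, dtype=np.int64).reshape(-1, 3)
                i += n
            elif tok and tok[0] == "SCALARS":
                nv = len(verts) if verts is not None else 0
                vals = " ".join(tokens[i + 2 :]).split()
                scal = np.array(vals[:nv], dtype=float)
                i += 2
            i += 1
    except (IndexError, ValueError) as exc:
        raise FormatError(f"corrupt VTK polydata in {path}: {exc}") from exc
    if verts is None or faces is None:
        raise FormatError(f"{path}: missing POINTS or POLYGONS section")
    return SurfaceMesh(verts, faces, scal)
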