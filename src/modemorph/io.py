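"""Surface and per-vertex-map file I/O.

Supported mesh formats:

* VTK legacy ASCII polydata — one strict dialect: ``DATASET POLYDATA`` with a
  ``POINTS`` section and a ``POLYGONS`` section whose entries all have a
  leading count of 3.  Anything else is rejected with the offending line.
* OFF (Object File Format), triangles only.
* FreeSurfer binary surface (read/write, via nibabel).

Per-vertex scalars travel as CSV ``vertex,value`` tables or FreeSurfer curv
files; binary cortex masks as FreeSurfer-style label files (0-based vertex
indices) or one-column CSV vertex lists.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import nibabel.freesurfer.io as fsio
import numpy as np

from .mesh import SurfaceMap, TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "MeshFormatError",
    "UnsupportedTopologyError",
    "read_mesh",
    "write_mesh",
    "read_scalar_csv",
    "write_scalar_csv",
    "read_curv",
    "write_curv",
    "read_label_mask",
    "write_label_mask",
]

MESH_FORMATS = ("vtk", "off", "freesurfer")


class MeshFormatError(ValueError):
    """Malformed or unsupported mesh file content."""


class UnsupportedTopologyError(MeshFormatError):
    """The file contains non-triangular polygons."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower().replace("-legacy", "").replace("freesurfer-surface", "freesurfer")
        if fmt not in MESH_FORMATS:
            raise ValueError(f"unknown mesh format {fmt!r}; expected one of {MESH_FORMATS}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        return "vtk"
    if suffix == ".off":
        return "off"
    return "freesurfer"


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata (strict single dialect)
# ---------------------------------------------------------------------------

def _vtk_error(lineno: int, msg: str) -> MeshFormatError:
    return MeshFormatError(f"VTK parse error at line {lineno}: {msg}")


def _read_vtk(path: Path) -> TriangleMesh:
    lines = path.read_text().splitlines()

    def tokens_from(start: int, count: int, section: str) -> tuple[list[str], int]:
        toks: list[str] = []
        i = start
        while len(toks) < count:
            if i >= len(lines):
                raise _vtk_error(len(lines), f"truncated {section} section: expected {count} values")
            toks.extend(lines[i].split())
            i += 1
        if len(toks) > count:
            raise _vtk_error(i, f"{section} section has more values than declared")
        return toks, i

    if len(lines) < 5:
        raise _vtk_error(1, "file too short for a legacy VTK header")
    if not lines[0].startswith("# vtk DataFile Version"):
        raise _vtk_error(1, f"expected '# vtk DataFile Version ...', got {lines[0]!r}")
    if lines[2].strip().upper() != "ASCII":
        raise _vtk_error(3, f"only ASCII files are supported, got {lines[2]!r}")
    if lines[3].split() != ["DATASET", "POLYDATA"]:
        raise _vtk_error(4, f"expected 'DATASET POLYDATA', got {lines[3]!r}")

    hdr = lines[4].split()
    if len(hdr) != 3 or hdr[0] != "POINTS" or hdr[2].lower() not in ("float", "double"):
        raise _vtk_error(5, f"expected 'POINTS <n> float|double', got {lines[4]!r}")
    try:
        n_pts = int(hdr[1])
    except ValueError:
        raise _vtk_error(5, f"non-integer point count {hdr[1]!r}") from None

    toks, i = tokens_from(5, 3 * n_pts, "POINTS")
    try:
        verts = np.array(toks, dtype=np.float64).reshape(n_pts, 3)
    except ValueError:
        raise _vtk_error(6, "non-numeric coordinate in POINTS section") from None

    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines):
        raise _vtk_error(len(lines), "missing POLYGONS section")
    hdr = lines[i].split()
    if len(hdr) != 3 or hdr[0] != "POLYGONS":
        raise _vtk_error(i + 1, f"expected 'POLYGONS <n> <size>', got {lines[i]!r}")
    try:
        n_poly, total = int(hdr[1]), int(hdr[2])
    except ValueError:
        raise _vtk_error(i + 1, "non-integer POLYGONS header counts") from None

    toks, _ = tokens_from(i + 1, total, "POLYGONS")
    faces = np.empty((n_poly, 3), dtype=np.int64)
    pos = 0
    for f in range(n_poly):
        if pos >= total:
            raise _vtk_error(i + 1, "POLYGONS section shorter than declared size")
        count = int(toks[pos])
        if count != 3:
            raise UnsupportedTopologyError(
                f"polygon {f} has {count} vertices; only triangles are supported"
            )
        faces[f] = [int(t) for t in toks[pos + 1 : pos + 4]]
        pos += 4
    if pos != total:
        raise _vtk_error(i + 1, "POLYGONS declared size does not match entries")
    return TriangleMesh(vertices=verts, faces=faces, name=path.stem)


def _write_vtk(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 4.2\n")
        fh.write(f"{mesh.name or 'surface'}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# OFF
# ---------------------------------------------------------------------------

def _read_off(path: Path) -> TriangleMesh:
    raw = [
        (i + 1, ln.split("#", 1)[0].strip())
        for i, ln in enumerate(path.read_text().splitlines())
    ]
    lines = [(no, ln) for no, ln in raw if ln]
    if not lines or lines[0][1] != "OFF":
        raise MeshFormatError(f"OFF parse error at line 1: missing 'OFF' magic in {path}")
    no, counts = lines[1]
    parts = counts.split()
    if len(parts) != 3:
        raise MeshFormatError(f"OFF parse error at line {no}: expected 'nv nf ne'")
    n_v, n_f = int(parts[0]), int(parts[1])
    body = lines[2:]
    if len(body) < n_v + n_f:
        raise MeshFormatError(f"OFF file truncated: need {n_v + n_f} body lines, found {len(body)}")
    verts = np.empty((n_v, 3))
    for k in range(n_v):
        no, ln = body[k]
        vals = ln.split()
        if len(vals) != 3:
            raise MeshFormatError(f"OFF parse error at line {no}: expected 3 coordinates")
        verts[k] = [float(x) for x in vals]
    faces = np.empty((n_f, 3), dtype=np.int64)
    for k in range(n_f):
        no, ln = body[n_v + k]
        vals = ln.split()
        if int(vals[0]) != 3:
            raise UnsupportedTopologyError(
                f"OFF line {no}: polygon with {vals[0]} vertices; only triangles supported"
            )
        if len(vals) != 4:
            raise MeshFormatError(f"OFF parse error at line {no}: expected '3 i j k'")
        faces[k] = [int(x) for x in vals[1:4]]
    return TriangleMesh(vertices=verts, faces=faces, name=path.stem)


def _write_off(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_mesh(path: str | os.PathLike, format: str | None = None) -> TriangleMesh:
    """Read a surface mesh, preserving vertex order.

    ``format`` is one of ``"vtk"``, ``"off"``, ``"freesurfer"``; when omitted
    it is inferred from the extension (anything other than ``.vtk``/``.off``
    is treated as a FreeSurfer binary surface).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "off":
        return _read_off(path)
    verts, faces = fsio.read_geometry(str(path))
    return TriangleMesh(vertices=np.asarray(verts, float), faces=np.asarray(faces, np.int64), name=path.name)


def write_mesh(mesh: TriangleMesh, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write ``mesh``; the file round-trips through :func:`read_mesh` with
    identical connectivity and coordinates to text precision (17 significant
    digits, i.e. bit-exact for doubles)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "off":
        _write_off(mesh, path)
    else:
        fsio.write_geometry(str(path), mesh.vertices, mesh.faces)
    return path


def read_scalar_csv(path: str | os.PathLike, mesh: TriangleMesh | None = None,
                    mask: np.ndarray | None = None) -> SurfaceMap:
    """Read a per-vertex scalar map from CSV ``vertex,value`` rows.

    A single header line is permitted.  Every vertex of the mesh must appear
    exactly once when a mesh is supplied.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln:
                continue
            parts = ln.split(",")
            if lineno == 1 and not parts[0].strip().lstrip("-").isdigit():
                continue  # header
            if len(parts) != 2:
                raise MeshFormatError(f"{path}:{lineno}: expected 'vertex,value'")
            rows.append((int(parts[0]), float(parts[1])))
    if not rows:
        raise MeshFormatError(f"{path}: empty scalar map")
    idx = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    n = mesh.n_vertices if mesh is not None else idx.max() + 1
    if np.unique(idx).size != n or idx.min() != 0 or idx.max() != n - 1:
        raise MeshFormatError(f"{path}: vertex indices must cover 0..{n - 1} exactly once")
    values = np.empty(n)
    values[idx] = vals
    if mask is None:
        mask = np.ones(n, bool)
    return SurfaceMap(values=values, mask=mask, mesh=mesh, name=path.stem)


def write_scalar_csv(smap: SurfaceMap, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("vertex,value\n")
        for i, v in enumerate(smap.values):
            fh.write(f"{i},{v:.17g}\n")
    return path


def read_curv(path: str | os.PathLike, mesh: TriangleMesh | None = None,
              mask: np.ndarray | None = None) -> SurfaceMap:
    """Read a FreeSurfer curv (per-vertex scalar) file."""
    vals = np.asarray(fsio.read_morph_data(str(path)), dtype=np.float64)
    if mask is None:
        mask = np.ones(len(vals), bool)
    return SurfaceMap(values=vals, mask=mask, mesh=mesh, name=Path(path).stem)


def write_curv(smap: SurfaceMap, path: str | os.PathLike) -> Path:
    n_faces = smap.mesh.n_faces if smap.mesh is not None else 0
    fsio.write_morph_data(str(path), smap.values, fnum=n_faces)
    return Path(path)


def read_label_mask(path: str | os.PathLike, n_vertices: int) -> np.ndarray:
    """Read a binary cortex mask from a FreeSurfer label or one-column CSV.

    Returns a boolean array of length ``n_vertices`` with True at listed
    (0-based) vertex indices.
    """
    path = Path(path)
    if path.suffix == ".label":
        idx = np.asarray(fsio.read_label(str(path)), dtype=np.int64)
    else:
        idx = []
        with open(path) as fh:
            for ln in fh:
                tok = ln.strip().split(",")[0]
                if tok and tok.lstrip("-").isdigit():
                    idx.append(int(tok))
        idx = np.asarray(idx, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n_vertices):
        raise MeshFormatError(f"{path}: label index out of range for {n_vertices} vertices")
    mask = np.zeros(n_vertices, bool)
    mask[idx] = True
    return mask


def write_label_mask(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write mask as a one-column CSV of 0-based vertex indices."""
    path = Path(path)
    idx = np.flatnonzero(np.asarray(mask).astype(bool))
    with open(path, "w") as fh:
        fh.write("vertex\n")
        for i in idx:
            fh.write(f"{i}\n")
    return path
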