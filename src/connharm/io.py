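"""File formats: meshes (OFF/PLY/FreeSurfer), streamlines (TCK/TRK/plain
text), sparse matrices (Matrix Market), label and map files.

Conventions: coordinates are mm throughout; internal indexing is 0-based,
text interchange formats keep their own convention (Matrix Market is
1-based, handled by scipy).  Plain-text streamlines are one "x y z" line
per point, blank-line separated tracks.  Label files are two-column text
(vertex_index, label); map files are one 0/1 per vertex per line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io
import scipy.sparse as sp
import trimesh

from .types import CorticalMesh, InvalidInputError, StreamlineSet

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_streamlines",
    "write_streamlines",
    "read_sparse",
    "write_sparse",
    "read_labels",
    "write_labels",
    "read_map",
    "write_map",
]


class ParseError(ValueError):
    """A file could not be parsed; the message locates the problem."""


def _format_of(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    return path.suffix.lstrip(".").lower()


def read_mesh(
    path, fmt: Optional[str] = None, hemisphere: Optional[np.ndarray] = None
) -> CorticalMesh:
    """Read a triangulated surface (OFF, PLY, or FreeSurfer geometry).

    Vertex order is preserved exactly (no merging or re-indexing), so
    companion per-vertex files stay aligned.  Hemisphere labels are not part
    of mesh formats; pass them or attach via :func:`read_labels`.
    """
    path = Path(path)
    f = _format_of(path, fmt)
    if f in ("off", "ply"):
        try:
            tm = trimesh.load(str(path), file_type=f, process=False)
        except Exception as err:
            raise ParseError(f"{path}: cannot parse as {f.upper()}: {err}") from err
        if not hasattr(tm, "faces") or len(tm.faces) == 0:
            raise ParseError(f"{path}: no triangles found")
        vertices = np.asarray(tm.vertices, dtype=float)
        triangles = np.asarray(tm.faces, dtype=np.int64)
    elif f in ("freesurfer", "fs", "surf"):
        # optional real-data convenience; needs a FreeSurfer geometry file
        import nibabel.freesurfer as nfs

        try:
            vertices, triangles = nfs.read_geometry(str(path))
        except Exception as err:
            raise ParseError(f"{path}: cannot parse as FreeSurfer surface: {err}") from err
        vertices = np.asarray(vertices, dtype=float)
        triangles = np.asarray(triangles, dtype=np.int64)
    else:
        raise ParseError(f"{path}: unknown mesh format {f!r}")
    if hemisphere is None:
        hemisphere = np.zeros(len(vertices), dtype=np.int64)
    return CorticalMesh(vertices, triangles, np.asarray(hemisphere))


def write_mesh(mesh: CorticalMesh, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    f = _format_of(path, fmt)
    if f not in ("off", "ply"):
        raise ParseError(f"unsupported mesh output format {f!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(str(path), file_type=f)


def read_streamlines(path, fmt: Optional[str] = None) -> StreamlineSet:
    """Read streamlines (TCK, TRK, or blank-line-separated plain text)."""
    path = Path(path)
    f = _format_of(path, fmt)
    if f in ("tck", "trk"):
        import nibabel.streamlines as nibs

        obj = nibs.load(str(path))
        tracks = [np.asarray(s, dtype=float) for s in obj.streamlines]
        return StreamlineSet(tracks)
    if f in ("txt", "text", "dat"):
        tracks = []
        current = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    if current:
                        tracks.append(np.array(current))
                        current = []
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                    )
                try:
                    current.append([float(p) for p in parts])
                except ValueError as err:
                    raise ParseError(f"{path}:{lineno}: {err}") from err
        if current:
            tracks.append(np.array(current))
        return StreamlineSet(tracks)
    raise ParseError(f"{path}: unknown streamline format {f!r}")


def write_streamlines(streamlines: StreamlineSet, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    f = _format_of(path, fmt)
    if f in ("tck", "trk"):
        import nibabel.streamlines as nibs

        tractogram = nibs.Tractogram(
            streamlines.tracks, affine_to_rasmm=np.eye(4)
        )
        nibs.save(tractogram, str(path))
        return
    if f in ("txt", "text", "dat"):
        with open(path, "w") as fh:
            for track in streamlines.tracks:
                for p in track:
                    fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
                fh.write("\n")
        return
    raise ParseError(f"unsupported streamline output format {f!r}")


def read_sparse(path) -> sp.csr_matrix:
    """Matrix Market coordinate file -> CSR (symmetric flag expanded)."""
    try:
        M = scipy.io.mmread(str(path))
    except Exception as err:
        raise ParseError(f"{path}: cannot parse Matrix Market file: {err}") from err
    return sp.csr_matrix(M)


def write_sparse(M: sp.spmatrix, path, symmetric: bool = True) -> None:
    """Write a sparse matrix in Matrix Market coordinate format.

    Integer-valued matrices round-trip exactly (written with the integer
    field); the symmetric flag stores only the lower triangle.
    """
    M = sp.coo_matrix(M)
    symmetry = "symmetric" if symmetric and (abs(M - M.T)).nnz == 0 else "general"
    if M.nnz and np.all(M.data == np.round(M.data)):
        M = M.astype(np.int64)
        field = "integer"
    else:
        field = "real"
    scipy.io.mmwrite(str(path), M, field=field, symmetry=symmetry)


def read_labels(path) -> np.ndarray:
    """Two-column text (vertex_index, label) -> dense label array."""
    data = np.loadtxt(path, dtype=np.int64, ndmin=2)
    if data.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns (vertex_index, label)")
    out = np.zeros(data[:, 0].max() + 1, dtype=np.int64)
    out[data[:, 0]] = data[:, 1]
    return out


def write_labels(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels, dtype=np.int64)
    np.savetxt(path, np.column_stack([np.arange(labels.size), labels]), fmt="%d")


def read_map(path) -> np.ndarray:
    """One 0/1 per vertex per line -> binary array."""
    values = np.loadtxt(path, dtype=np.int64, ndmin=1)
    if values.size and not np.isin(values, (0, 1)).all():
        raise ParseError(f"{path}: map values must be 0/1")
    return values


def write_map(values: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=np.int64), fmt="%d")


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
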