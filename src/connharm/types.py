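"""Domain containers shared across the pipeline.

The analysis lives on a triangulated cortical surface with ``m`` vertices.
Local (gray-matter) connectivity is read off the mesh edge graph; long-range
(white-matter) connectivity is a sparse streamline-count matrix built by
intersecting tractography polylines with the mesh.  Everything downstream
(Laplacian harmonics, alterations, statistics) operates on sparse symmetric
``m x m`` matrices indexed by mesh vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

LEFT = 0
RIGHT = 1


class InvalidParameterError(ValueError):
    """A parameter is outside its documented range."""


class InvalidInputError(ValueError):
    """An input object violates a structural precondition."""


class DegenerateDistributionError(ValueError):
    """A statistic is undefined because the underlying distribution is constant."""


class UndefinedRatioError(ValueError):
    """The local/long-range connection ratio is undefined (no edges at all)."""


@dataclass
class CorticalMesh:
    """Triangulated cortical surface with per-vertex hemisphere labels.

    vertices : (m, 3) float array, coordinates in mm.
    triangles : (t, 3) int array, indices into ``vertices``.
    hemisphere : (m,) int array, 0 = left, 1 = right.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.hemisphere = np.asarray(self.hemisphere, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError("vertices must be an (m, 3) array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.m
        ):
            raise InvalidInputError("triangle indices out of range")
        if self.hemisphere.shape != (self.m,):
            raise InvalidInputError("hemisphere labels must cover all vertices")

    @property
    def m(self) -> int:
        return self.vertices.shape[0]

    def edge_array(self) -> np.ndarray:
        """Unique undirected mesh edges as an (e, 2) array with i < j."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass
class StreamlineSet:
    """Tractography streamlines as 3-D polylines in mm.

    Every track has at least 3 points: the direction used when linearly
    extending a bound is defined by the endpoint and the third-last point.
    """

    tracks: list

    def __post_init__(self) -> None:
        self.tracks = [np.asarray(t, dtype=float) for t in self.tracks]
        for t in self.tracks:
            if t.ndim != 2 or t.shape[1] != 3:
                raise InvalidInputError("each track must be an (n, 3) array")
            if t.shape[0] < 3:
                raise InvalidInputError("each track needs >= 3 points")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def lengths(self) -> np.ndarray:
        """Per-track arc length (sum of segment lengths), mm."""
        return np.array(
            [np.linalg.norm(np.diff(t, axis=0), axis=1).sum() for t in self.tracks]
        )


@dataclass
class AtlasParcellation:
    """Vertex -> region map with contiguous region ids starting at 0."""

    region_of: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.region_of = np.asarray(self.region_of, dtype=np.int64)
        if self.region_of.size and (
            self.region_of.min() < 0 or self.region_of.max() >= self.n_regions
        ):
            raise InvalidInputError("region ids must lie in [0, n_regions)")


@dataclass
class RSNMap:
    """Binary per-vertex membership map of a resting-state network (M = 2 states)."""

    values: np.ndarray
    M: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise InvalidInputError("RSN map must be binary")
        self.values = self.values.astype(np.int8)


@dataclass
class WeightedConnectome:
    """Streamline-count matrix C with companion mean-track-length matrix.

    C : sparse symmetric nonnegative integer matrix; C[i, j] counts streamlines
        whose bounds resolved to vertices i and j.
    Lbar : mean track length (mm) per connected pair, defined where C > 0.
    mu_C, sigma_C : mean / population SD of the nonzero weight population,
        filled by :func:`connharm.build.zscore_weights`.
    Cz : z-scored weights on the same support.
    """

    C: sp.csr_matrix
    Lbar: sp.csr_matrix
    mu_C: Optional[float] = None
    sigma_C: Optional[float] = None
    Cz: Optional[sp.csr_matrix] = None
    n_kept: int = 0
    n_discarded_short: int = 0
    n_discarded_unresolved: int = 0
    n_discarded_selfloop: int = 0

    @property
    def m(self) -> int:
        return self.C.shape[0]


@dataclass
class LocalAdjacency:
    """Binary gray-matter adjacency from the mesh (kernel width 1 or 2 edges)."""

    A_l: sp.csr_matrix
    kernel_width: int
    edge_lengths: Optional[np.ndarray] = None  # aligned with edges(); mesh-edge mm

    @property
    def m(self) -> int:
        return self.A_l.shape[0]


@dataclass
class LongRangeAdjacency:
    """Binary white-matter adjacency obtained by thresholding z-scored weights."""

    A_c: sp.csr_matrix
    z_C: Optional[float] = None

    @property
    def m(self) -> int:
        return self.A_c.shape[0]


@dataclass
class CombinedConnectome:
    """Binary union A of local and long-range adjacency on one vertex set."""

    A: sp.csr_matrix
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.A.shape[0]


@dataclass
class HarmonicBasis:
    """Ascending eigenpairs of the graph Laplacian (connectome harmonics).

    Harmonic k = 1 is the constant mode of a connected graph.  ``eigenvalues``
    and columns of ``eigenvectors`` are stored in ascending-eigenvalue order;
    ``basis.psi(k)`` returns harmonic k with 1-based indexing.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (m, K), unit-norm columns
    zero_tol: float = 1e-8

    @property
    def K(self) -> int:
        return self.eigenvalues.size

    @property
    def m(self) -> int:
        return self.eigenvectors.shape[0]

    def psi(self, k: int) -> np.ndarray:
        """Harmonic ψ_k, 1-based (ψ_1 is the lowest mode)."""
        if not 1 <= k <= self.K:
            raise InvalidParameterError(f"harmonic index {k} outside [1, {self.K}]")
        return self.eigenvectors[:, k - 1]


def check_symmetric_binary(A: sp.spmatrix, name: str = "A") -> sp.csr_matrix:
    """Validate a binary symmetric zero-diagonal sparse matrix, return CSR."""
    A = sp.csr_matrix(A)
    if (A != A.T).nnz:
        raise InvalidInputError(f"{name} must be symmetric")
    if A.diagonal().any():
        raise InvalidInputError(f"{name} must have zero diagonal")
    if A.nnz and not np.isin(A.data, (0, 1)).all():
        raise InvalidInputError(f"{name} must be binary")
    A.eliminate_zeros()
    return A


def upper_edges(A: sp.spmatrix) -> np.ndarray:
    """Undirected edges of a symmetric matrix as an (e, 2) array with i < j."""
    coo = sp.triu(A, k=1).tocoo()
    return np.column_stack([coo.row, coo.col]).astype(np.int64)


def edges_to_adjacency(edges: np.ndarray, m: int) -> sp.csr_matrix:
    """Build a binary symmetric adjacency from an (e, 2) edge array."""
    if len(edges) == 0:
        return sp.csr_matrix((m, m))
    i, j = edges[:, 0], edges[:, 1]
    data = np.ones(len(edges))
    A = sp.coo_matrix((data, (i, j)), shape=(m, m))
    A = A + A.T
    A.data[:] = 1.0
    return A.tocsr()
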