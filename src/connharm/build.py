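"""High-resolution connectome construction.

Long-range (white-matter) connectivity: each tractography streamline is
intersected with the cortical surface mesh at both bounds; the terminal
segment is tested first and, if it misses, the bound is linearly extended
(default 3 mm) along the direction from the third-last point to the
endpoint and tested again.  A resolved track increments the streamline
count C[i, j] between the mesh vertices nearest the two intersection
points and accumulates its arc length into the mean-track-length matrix.
Tracks shorter than a minimum length (default 10 mm), tracks with an
unresolved bound, tracks whose endpoint lies farther than ``max_gap_mm``
(default 5 mm) from the surface, and self-loops are discarded.

Local (gray-matter) connectivity: vertices within graph distance 1 or 2 on
the mesh edge graph (the local diffusion kernel width).

The weighted counts are z-scored over the nonzero weight population
(population SD) so that integer adjacency thresholds z_C are expressed in
standard deviations of the weight distribution; thresholding and the
binary union with the local adjacency give the combined connectome.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .types import (
    CombinedConnectome,
    CorticalMesh,
    DegenerateDistributionError,
    InvalidInputError,
    InvalidParameterError,
    LocalAdjacency,
    LongRangeAdjacency,
    StreamlineSet,
    UndefinedRatioError,
    WeightedConnectome,
    check_symmetric_binary,
    upper_edges,
)

__all__ = [
    "intersect_track_end",
    "build_long_range",
    "build_local_adjacency",
    "zscore_weights",
    "threshold_long_range",
    "combine",
    "local_ratio",
]

_EPS = 1e-12


def _segment_triangle_hits(p0, p1, v0, v1, v2):
    """Moller-Trumbore segment/triangle test, vectorized over triangles.

    Returns (idx, t): indices of hit triangles and the segment parameter
    t in [0, 1] of each intersection point.  Segments lying in a triangle's
    plane are treated as misses.
    """
    d = p1 - p0
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > _EPS
    inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = p0 - v0
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = (q @ d) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t >= -tol) & (t <= 1 + tol)
    return np.flatnonzero(hit), np.clip(t[hit], 0.0, 1.0)


def _point_triangle_distance(p, v0, v1, v2):
    """Distance from one point to each triangle (vectorized over triangles)."""
    # project into the triangle plane, clamp barycentrics to the triangle
    e0 = v1 - v0
    e1 = v2 - v0
    w = p - v0
    a = np.einsum("ij,ij->i", e0, e0)
    b = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    d = np.einsum("ij,ij->i", e0, w)
    e = np.einsum("ij,ij->i", e1, w)
    det = np.maximum(a * c - b * b, _EPS)
    s = np.clip((c * d - b * e) / det, 0.0, 1.0)
    t = np.clip((a * e - b * d) / det, 0.0, 1.0)
    # clamp to edges where s + t > 1
    over = s + t > 1.0
    if over.any():
        ss, tt = s[over], t[over]
        tot = ss + tt
        s[over], t[over] = ss / tot, tt / tot
    # refine: candidate closest points on the three edges as well
    cand = [v0 + s[:, None] * e0 + t[:, None] * e1]
    for pa, pe in ((v0, e0), (v0, e1), (v1, v2 - v1)):
        u = np.clip(np.einsum("ij,ij->i", p - pa, pe) / np.maximum(np.einsum("ij,ij->i", pe, pe), _EPS), 0, 1)
        cand.append(pa + u[:, None] * pe)
    dists = np.stack([np.linalg.norm(p - q, axis=1) for q in cand])
    return dists.min(axis=0)


class _MeshIntersector:
    """Cached spatial structures for repeated track-end resolution."""

    def __init__(self, mesh: CorticalMesh):
        self.mesh = mesh
        tri = mesh.triangles
        self.v0 = mesh.vertices[tri[:, 0]]
        self.v1 = mesh.vertices[tri[:, 1]]
        self.v2 = mesh.vertices[tri[:, 2]]
        self.centroids = (self.v0 + self.v1 + self.v2) / 3.0
        self.tri_radius = np.max(
            [
                np.linalg.norm(self.v0 - self.centroids, axis=1),
                np.linalg.norm(self.v1 - self.centroids, axis=1),
                np.linalg.norm(self.v2 - self.centroids, axis=1),
            ]
        )
        self.tree = cKDTree(self.centroids)

    def candidates(self, p0, p1):
        mid = 0.5 * (p0 + p1)
        r = 0.5 * np.linalg.norm(p1 - p0) + self.tri_radius + 1e-6
        return np.asarray(self.tree.query_ball_point(mid, r), dtype=np.int64)

    def segment_hit(self, p0, p1, prefer="far"):
        """Nearest-to-endpoint intersection of segment p0->p1 with the mesh.

        ``prefer='far'`` keeps the hit with the largest t (terminal segments
        run toward the endpoint at t=1); ``'near'`` keeps the smallest t
        (extension segments start at the endpoint at t=0).  Returns the
        assigned vertex index or None.
        """
        cand = self.candidates(p0, p1)
        if len(cand) == 0:
            return None
        idx, t = _segment_triangle_hits(p0, p1, self.v0[cand], self.v1[cand], self.v2[cand])
        if len(idx) == 0:
            return None
        best = np.argmax(t) if prefer == "far" else np.argmin(t)
        tri_id = int(cand[idx[best]])
        point = p0 + t[best] * (p1 - p0)
        verts = self.mesh.triangles[tri_id]
        d = np.linalg.norm(self.mesh.vertices[verts] - point, axis=1)
        # nearest triangle vertex; ties broken by lowest vertex index
        order = np.lexsort((verts, d))
        return int(verts[order[0]])

    def surface_gap(self, p, k: int = 24) -> float:
        """Distance from a point to the nearest surface point (exact within
        the k nearest triangles by centroid, exhaustive fallback)."""
        k = min(k, len(self.centroids))
        _, near = self.tree.query(p, k=k)
        near = np.atleast_1d(near)
        d = _point_triangle_distance(p, self.v0[near], self.v1[near], self.v2[near]).min()
        # the true nearest triangle is within d of p only if its centroid is
        # within d + tri_radius; enlarge the candidate set if needed
        extra = self.tree.query_ball_point(p, d + self.tri_radius)
        extra = np.asarray(extra, dtype=np.int64)
        if len(extra):
            d = min(d, _point_triangle_distance(p, self.v0[extra], self.v1[extra], self.v2[extra]).min())
        return float(d)


def _intersector(mesh: CorticalMesh) -> _MeshIntersector:
    cached = getattr(mesh, "_intersector", None)
    if cached is None or cached.mesh is not mesh:
        cached = _MeshIntersector(mesh)
        mesh._intersector = cached
    return cached


def intersect_track_end(
    track: np.ndarray,
    mesh: CorticalMesh,
    which_end: str = "end",
    extension_mm: float = 3.0,
    max_gap_mm: float = 5.0,
) -> Optional[int]:
    """Resolve one track bound to a mesh vertex, or None.

    The terminal segment (endpoint and its neighbor) is tested against the
    mesh first.  If it misses and the endpoint lies within ``max_gap_mm`` of
    the surface, the bound is extended by ``extension_mm`` along the
    direction from the third-last point to the endpoint and tested again.
    The assigned vertex is the hit triangle's vertex nearest the
    intersection point (ties: lowest index).
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[0] < 3:
        raise InvalidInputError("track needs >= 3 points")
    if extension_mm < 0:
        raise InvalidParameterError("extension must be nonnegative")
    if which_end not in ("start", "end"):
        raise InvalidParameterError("which_end must be 'start' or 'end'")
    if which_end == "start":
        endpoint, inner, third = track[0], track[1], track[2]
    else:
        endpoint, inner, third = track[-1], track[-2], track[-3]
    inter = _intersector(mesh)

    hit = inter.segment_hit(inner, endpoint, prefer="far")
    if hit is not None:
        return hit
    if inter.surface_gap(endpoint) > max_gap_mm:
        return None
    direction = endpoint - third
    norm = np.linalg.norm(direction)
    if norm < _EPS:
        return None
    ext = endpoint + extension_mm * direction / norm
    return inter.segment_hit(endpoint, ext, prefer="near")


def build_long_range(
    streamlines: StreamlineSet,
    mesh: CorticalMesh,
    min_track_length_mm: float = 10.0,
    extension_mm: float = 3.0,
    max_gap_mm: float = 5.0,
) -> WeightedConnectome:
    """Streamline-count connectome C and mean-track-length matrix Lbar.

    Tracks below the minimum length are discarded before intersection;
    tracks with an unresolved bound or with both bounds on one vertex are
    discarded; every surviving track increments C symmetrically by 1.
    """
    if mesh.m == 0 or len(mesh.triangles) == 0:
        raise InvalidInputError("mesh is empty")
    m = mesh.m
    counts: dict = {}
    length_sum: dict = {}
    n_short = n_unresolved = n_self = n_kept = 0
    for track in streamlines.tracks:
        length = float(np.linalg.norm(np.diff(track, axis=0), axis=1).sum())
        if length < min_track_length_mm:
            n_short += 1
            continue
        i = intersect_track_end(track, mesh, "start", extension_mm, max_gap_mm)
        j = intersect_track_end(track, mesh, "end", extension_mm, max_gap_mm)
        if i is None or j is None:
            n_unresolved += 1
            continue
        if i == j:
            n_self += 1
            continue
        key = (i, j) if i < j else (j, i)
        counts[key] = counts.get(key, 0) + 1
        length_sum[key] = length_sum.get(key, 0.0) + length
        n_kept += 1
    if counts:
        ij = np.array(list(counts.keys()), dtype=np.int64)
        w = np.array(list(counts.values()), dtype=float)
        ls = np.array([length_sum[k] for k in counts], dtype=float)
        C = sp.coo_matrix((w, (ij[:, 0], ij[:, 1])), shape=(m, m))
        L = sp.coo_matrix((ls / w, (ij[:, 0], ij[:, 1])), shape=(m, m))
        C = (C + C.T).tocsr()
        L = (L + L.T).tocsr()
    else:
        C = sp.csr_matrix((m, m))
        L = sp.csr_matrix((m, m))
    return WeightedConnectome(
        C=C,
        Lbar=L,
        n_kept=n_kept,
        n_discarded_short=n_short,
        n_discarded_unresolved=n_unresolved,
        n_discarded_selfloop=n_self,
    )


def build_local_adjacency(mesh: CorticalMesh, kernel_width: int = 2) -> LocalAdjacency:
    """Local gray-matter adjacency: vertices within ``kernel_width`` mesh edges.

    Width 1 is the mesh edge set itself; width 2 additionally connects
    second neighbors.  Edge lengths (Euclidean vertex distances, mm) are
    attached for the anisotropy alteration.
    """
    if kernel_width not in (1, 2):
        raise InvalidParameterError("kernel width must be 1 or 2")
    m = mesh.m
    e = mesh.edge_array()
    A1 = sp.coo_matrix(
        (np.ones(2 * len(e)), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(m, m),
    ).tocsr()
    if kernel_width == 1:
        A = A1.copy()
    else:
        A = A1 + A1 @ A1
        A.setdiag(0)
        A.eliminate_zeros()
    A.data[:] = 1.0
    edges = upper_edges(A)
    lengths = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    return LocalAdjacency(A_l=A.tocsr(), kernel_width=kernel_width, edge_lengths=lengths)


def zscore_weights(wc: WeightedConnectome) -> WeightedConnectome:
    """z-score the streamline counts over the nonzero weight population.

    mu and sigma (population SD) are taken over the nonzero upper-triangular
    weights only, so integer thresholds z_C measure standard deviations of
    the observed weight distribution.
    """
    w = sp.triu(wc.C, k=1).tocoo().data
    if len(np.unique(w)) < 2:
        raise DegenerateDistributionError(
            "z-scoring needs at least two distinct nonzero weights"
        )
    mu = float(w.mean())
    sigma = float(w.std())  # population SD
    Cz = wc.C.copy().astype(float)
    Cz.data = (Cz.data - mu) / sigma
    wc.mu_C, wc.sigma_C, wc.Cz = mu, sigma, Cz
    return wc


def threshold_long_range(wc: WeightedConnectome, z_C: float = 1.0) -> LongRangeAdjacency:
    """Binarize the z-scored weights: keep pairs with Cz > z_C."""
    if wc.Cz is None:
        raise InvalidInputError("call zscore_weights first")
    Cz = wc.Cz.tocoo()
    keep = Cz.data > z_C
    A = sp.coo_matrix(
        (np.ones(keep.sum()), (Cz.row[keep], Cz.col[keep])), shape=Cz.shape
    ).tocsr()
    return LongRangeAdjacency(A_c=A, z_C=z_C)


def combine(local: LocalAdjacency, longrange: LongRangeAdjacency) -> CombinedConnectome:
    """Binary union A of the local and long-range adjacencies."""
    if local.m != longrange.m:
        raise InvalidInputError("adjacency dimensions differ")
    A = (local.A_l + longrange.A_c).tocsr()
    A.data[:] = 1.0
    A = check_symmetric_binary(A, "A")
    return CombinedConnectome(
        A=A,
        provenance={"z_C": longrange.z_C, "kernel_width": local.kernel_width},
    )


def local_ratio(local: LocalAdjacency, longrange: LongRangeAdjacency) -> float:
    """Proportion r of local connections among all connections.

    Undirected edge counts of each matrix independently, i.e.
    r = tr(A_l^2) / (tr(A_l^2) + tr(A_c^2)) for binary symmetric matrices.
    """
    if local.m != longrange.m:
        raise InvalidInputError("adjacency dimensions differ")
    n_local = local.A_l.nnz / 2
    n_long = longrange.A_c.nnz / 2
    if n_local + n_long == 0:
        raise UndefinedRatioError("no connections at all")
    return n_local / (n_local + n_long)
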