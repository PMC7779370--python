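"""Synthetic two-hemisphere brains: meshes, streamlines, parcellations, RSN maps.

The generator replaces MRI-derived inputs (FreeSurfer surface templates and a
whole-brain tractogram) with objects that reproduce the statistical structure
the downstream analysis relies on:

* two disjoint ellipsoidal hemisphere meshes with edge lengths on the
  1-6 mm scale of cortical surface templates;
* streamline polylines that terminate near the surface, with a length
  distribution skewed toward short fibers, a minority of inter-hemispheric
  tracks, and a heavy-tailed pairwise weight distribution (streamlines
  follow a finite pool of fiber bundles with log-normal popularity, so
  repeated vertex pairs occur);
* a contiguous region parcellation (farthest-point seeds + nearest-seed
  geodesic assignment) standing in for an anatomical atlas;
* planted binary "resting-state network" patches (whole atlas regions),
  with a configurable fraction of intra-hemispheric streamlines connecting
  vertices inside the planted patches so that map-aligned long-range
  structure exists to be destroyed by randomization.

Analytic spherical harmonics on a jitter-free hemisphere provide the
validation oracle for the sphere limit of the graph-Laplacian eigenmodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import trimesh
from scipy.special import sph_harm_y

from .types import (
    AtlasParcellation,
    CorticalMesh,
    InvalidParameterError,
    RSNMap,
    StreamlineSet,
)

__all__ = [
    "SynthBrainConfig",
    "make_hemisphere_mesh",
    "make_brain",
    "make_streamlines",
    "make_rsn",
    "spherical_harmonic_reference",
]


@dataclass
class SynthBrainConfig:
    """Parameters of the synthetic brain.

    Defaults emulate a down-scaled cortical dataset: two 642-vertex
    ellipsoidal hemisphere meshes (icosphere subdivision 3, radius 30 mm,
    half-axes scaled 1.35/1.0/0.75) whose ~4 mm edges sit inside the
    1-6 mm local-connectivity length scale of real surface templates;
    20,000 streamlines over bundle pools with log-normal popularity and a
    log-normal chord-length target (median ~ 35 mm for plain association
    bundles; map-aligned bundles stay within a patch and are shorter),
    giving a short-fiber-skewed length histogram with a long
    inter-hemispheric tail; 20% inter-hemispheric tracks;
    Gaussian endpoint scatter of 0.5 mm around the surface; 24 atlas-like
    regions; and a 10-region planted network organized in lobes, with 35%
    of intra-hemispheric tracks following map-aligned bundles.
    """

    subdivisions: int = 3
    radius_mm: float = 30.0
    hemisphere_axes: Tuple[float, float, float] = (1.35, 1.0, 0.75)
    hemisphere_gap_mm: float = 10.0
    vertex_jitter_mm: float = 0.3
    n_streamlines: int = 20_000
    inter_fraction: float = 0.2
    length_shape: Tuple[float, float] = (3.55, 0.5)  # log-normal (mu, sigma) of mm
    endpoint_offset_sd_mm: float = 0.5
    short_track_fraction: float = 0.05
    n_regions_per_hemisphere: int = 12
    n_rsn_patches: int = 10
    rsn_streamline_fraction: float = 0.35
    rsn_patches_per_cluster: int = 1
    n_bundles_plain: int = 3400
    n_bundles_rsn: int = 1200
    n_bundles_inter: int = 1500
    bundle_popularity_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subdivisions < 0:
            raise InvalidParameterError("subdivisions must be >= 0")
        if self.radius_mm <= 0:
            raise InvalidParameterError("radius_mm must be positive")
        if self.hemisphere_gap_mm <= 0:
            raise InvalidParameterError("hemisphere gap must be positive")
        if self.vertex_jitter_mm < 0:
            raise InvalidParameterError("vertex jitter must be nonnegative")
        if self.endpoint_offset_sd_mm < 0:
            raise InvalidParameterError("endpoint offset sd must be nonnegative")
        if self.n_streamlines < 0:
            raise InvalidParameterError("n_streamlines must be >= 0")
        for name in ("inter_fraction", "short_track_fraction", "rsn_streamline_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.n_regions_per_hemisphere < 1:
            raise InvalidParameterError("need at least one region per hemisphere")
        if self.n_rsn_patches < 0:
            raise InvalidParameterError("n_rsn_patches must be >= 0")


def make_hemisphere_mesh(
    subdivisions: int,
    radius_mm: float,
    center: np.ndarray = (0.0, 0.0, 0.0),
    vertex_jitter_mm: float = 0.0,
    seed: int = 0,
    hemisphere_label: int = 0,
    axes: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CorticalMesh:
    """One hemisphere as a (jittered, optionally ellipsoidal) icosphere.

    With jitter 0 and unit axes the mesh is an exact sphere of the given
    radius: an icosphere with ``10 * 4**subdivisions + 2`` vertices.
    ``axes`` scales the three half-axes (brain hemispheres are longer
    front-to-back than top-to-bottom), which also breaks the spherical
    eigenvalue degeneracies.  Jitter adds isotropic Gaussian displacement
    per vertex; it must stay well below the edge length to keep triangles
    non-degenerate.
    """
    if subdivisions < 0:
        raise InvalidParameterError("subdivisions must be >= 0")
    if radius_mm <= 0:
        raise InvalidParameterError("radius must be positive")
    if vertex_jitter_mm < 0:
        raise InvalidParameterError("jitter must be nonnegative")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    vertices = np.asarray(ico.vertices, dtype=float) * np.asarray(axes, dtype=float)
    vertices = vertices + np.asarray(center, dtype=float)
    if vertex_jitter_mm > 0:
        rng = np.random.default_rng(seed)
        vertices = vertices + rng.normal(0.0, vertex_jitter_mm, vertices.shape)
    labels = np.full(len(vertices), hemisphere_label, dtype=np.int64)
    return CorticalMesh(vertices, np.asarray(ico.faces), labels)


def _parcellate_hemisphere(
    mesh: CorticalMesh, vertex_ids: np.ndarray, n_regions: int, rng: np.random.Generator
) -> np.ndarray:
    """Farthest-point seeding + nearest-seed geodesic assignment on one hemisphere."""
    sub = {v: i for i, v in enumerate(vertex_ids)}
    edges = mesh.edge_array()
    mask = np.isin(edges[:, 0], vertex_ids) & np.isin(edges[:, 1], vertex_ids)
    e = edges[mask]
    i = np.array([sub[v] for v in e[:, 0]])
    j = np.array([sub[v] for v in e[:, 1]])
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = len(vertex_ids)
    G = sp.coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n)).tocsr()

    seeds = [int(rng.integers(n))]
    dist = csgraph.dijkstra(G, indices=seeds[0])
    for _ in range(n_regions - 1):
        seeds.append(int(np.argmax(dist)))
        dist = np.minimum(dist, csgraph.dijkstra(G, indices=seeds[-1]))
    all_dist = csgraph.dijkstra(G, indices=seeds)
    return np.argmin(all_dist, axis=0)


def make_brain(
    config: SynthBrainConfig,
) -> Tuple[CorticalMesh, np.ndarray, AtlasParcellation]:
    """Two disjoint hemisphere meshes merged into one vertex/triangle list.

    Hemisphere centers sit on the x axis at a center-to-center separation of
    ``2 * radius + gap``, so the surfaces are separated by ``gap`` mm.  The
    parcellation partitions each hemisphere into contiguous geodesic patches;
    region ids 0..n-1 are left-hemisphere, the rest right-hemisphere.
    """
    r, gap = config.radius_mm, config.hemisphere_gap_mm
    offset = r * config.hemisphere_axes[0] + gap / 2.0
    left = make_hemisphere_mesh(
        config.subdivisions, r, (-offset, 0, 0), config.vertex_jitter_mm,
        seed=config.seed, hemisphere_label=0, axes=config.hemisphere_axes,
    )
    right = make_hemisphere_mesh(
        config.subdivisions, r, (offset, 0, 0), config.vertex_jitter_mm,
        seed=config.seed + 1, hemisphere_label=1, axes=config.hemisphere_axes,
    )
    m_left = left.m
    vertices = np.vstack([left.vertices, right.vertices])
    triangles = np.vstack([left.triangles, right.triangles + m_left])
    hemisphere = np.concatenate([left.hemisphere, right.hemisphere])
    mesh = CorticalMesh(vertices, triangles, hemisphere)

    rng = np.random.default_rng(config.seed + 2)
    n_reg = config.n_regions_per_hemisphere
    region = np.empty(mesh.m, dtype=np.int64)
    for h, base in ((0, 0), (1, n_reg)):
        ids = np.flatnonzero(hemisphere == h)
        region[ids] = base + _parcellate_hemisphere(mesh, ids, n_reg, rng)
    parcellation = AtlasParcellation(region, 2 * n_reg)
    return mesh, hemisphere, parcellation


def make_rsn(
    parcellation: AtlasParcellation, n_rsn_patches: int, seed: int = 0
) -> RSNMap:
    """Plant a binary network map as a union of whole atlas regions."""
    if n_rsn_patches < 0 or n_rsn_patches > parcellation.n_regions:
        raise InvalidParameterError(
            "n_rsn_patches must lie in [0, n_regions]"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(parcellation.n_regions, size=n_rsn_patches, replace=False)
    values = np.isin(parcellation.region_of, chosen).astype(np.int8)
    return RSNMap(values)


# --- streamline generation -------------------------------------------------

def _hemisphere_center(mesh: CorticalMesh, hemisphere_labels: np.ndarray, h: int) -> np.ndarray:
    return mesh.vertices[hemisphere_labels == h].mean(axis=0)


def _arc_points(s1: np.ndarray, s2: np.ndarray, centers: Tuple[np.ndarray, np.ndarray],
                shrink: Tuple[float, ...]) -> np.ndarray:
    """Interior waypoints: lerp the chord, pull each point toward its center."""
    ts = np.linspace(0.0, 1.0, len(shrink) + 2)[1:-1]
    pts = []
    for t, sh in zip(ts, shrink):
        q = (1 - t) * s1 + t * s2
        c = (1 - t) * centers[0] + t * centers[1]
        pts.append(c + (q - c) * sh)
    return np.array(pts)


def _sample_plain_bundles(
    rng, ids, D, n_bundles, length_shape
):
    """Intra-hemispheric vertex pairs near log-normal target chord lengths."""
    mu_log, sd_log = length_shape
    pairs = []
    for _ in range(n_bundles):
        h = int(rng.integers(2))
        local = D[h]
        ii = int(rng.integers(len(ids[h])))
        target = float(rng.lognormal(mu_log, sd_log))
        band = np.flatnonzero(np.abs(local[ii] - target) < 3.0)
        band = band[band != ii]
        if len(band):
            jj = int(rng.choice(band))
        else:
            order = np.argsort(np.abs(local[ii] - target))
            jj = int(order[1] if order[0] == ii else order[0])
        pairs.append((ids[h][ii], ids[h][jj], h))
    return pairs


def make_streamlines(
    mesh: CorticalMesh,
    hemisphere_labels: np.ndarray,
    config: SynthBrainConfig,
    parcellation: Optional[AtlasParcellation] = None,
    rsn: Optional[RSNMap] = None,
) -> StreamlineSet:
    """Sample streamline polylines between surface anchor vertices.

    Streamlines follow a finite pool of fiber *bundles* — fixed vertex
    pairs with log-normal popularity — the way tractography streamlines
    concentrate on white-matter tracts.  This makes pair counts (the
    connectome weights) heavy-tailed, with repeated pairs whose counts
    survive z-score thresholding.  Each track routes through the interior
    with >= 3 waypoints and displaces its endpoints by isotropic Gaussian
    noise of sd ``endpoint_offset_sd_mm``.  Track categories:

    * inter-hemispheric (probability ``inter_fraction``): bundles with one
      anchor per hemisphere, routed through the inter-hemispheric gap;
    * short (overall fraction ``short_track_fraction``): two nearby vertices
      in one hemisphere, total arc length < 10 mm, to exercise the
      minimum-track-length filter;
    * RSN-aligned (fraction ``rsn_streamline_fraction`` of the remaining
      intra tracks, when an ``rsn`` map is given): bundles with both anchors
      inside the planted patches of one hemisphere — the map-aligned
      structure that intra-hemispheric randomization destroys;
    * plain intra: bundles whose second anchor sits near a log-normal
      target chord length from the first, skewing the length histogram
      toward short fibers.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_streamlines
    if n == 0:
        return StreamlineSet([])

    hemisphere_labels = np.asarray(hemisphere_labels)
    V = mesh.vertices
    ids = {h: np.flatnonzero(hemisphere_labels == h) for h in (0, 1)}
    single = len(ids[1]) == 0  # single-hemisphere mesh: everything is intra
    centers = {0: _hemisphere_center(mesh, hemisphere_labels, 0)}
    if single:
        ids[1] = ids[0]
        centers[1] = centers[0]
        inter_fraction = 0.0
    else:
        centers[1] = _hemisphere_center(mesh, hemisphere_labels, 1)
        inter_fraction = config.inter_fraction
    # pairwise chord distances within each hemisphere, for length-targeted pairs
    D = {0: np.linalg.norm(V[ids[0]][:, None, :] - V[ids[0]][None, :, :], axis=2)}
    D[1] = D[0] if single else np.linalg.norm(
        V[ids[1]][:, None, :] - V[ids[1]][None, :, :], axis=2
    )
    # planted-network clusters: per hemisphere, the map's patches (regions)
    # are chunked into clusters of `rsn_patches_per_cluster`; map-aligned
    # bundles pair vertices within one cluster, so each cluster becomes a
    # coherent community of long-range connections
    rsn_clusters = []
    rsn_mask = np.zeros(mesh.m, dtype=bool)
    if rsn is not None and config.rsn_streamline_fraction > 0:
        rsn_mask = rsn.values.astype(bool)
        size = max(config.rsn_patches_per_cluster, 1)
        for h in (0,) if single else (0, 1):
            sel = ids[h][rsn_mask[ids[h]]]
            if len(sel) < 2:
                continue
            if parcellation is None:
                rsn_clusters.append(sel)
                continue
            regions = np.unique(parcellation.region_of[sel])
            n_cl = max(1, int(np.ceil(len(regions) / size)))
            if n_cl == 1:
                rsn_clusters.append(sel)
                continue
            # geometric clustering: farthest-point anchors over region
            # centroids, nearest-anchor assignment -> spatially coherent
            # lobes of map regions
            cent = np.array(
                [V[parcellation.region_of == r].mean(axis=0) for r in regions]
            )
            anchors = [int(rng.integers(len(regions)))]
            dist = np.linalg.norm(cent - cent[anchors[0]], axis=1)
            for _ in range(n_cl - 1):
                nxt = int(np.argmax(dist))
                anchors.append(nxt)
                dist = np.minimum(dist, np.linalg.norm(cent - cent[nxt], axis=1))
            assign = np.argmin(
                np.array([np.linalg.norm(cent - cent[a], axis=1) for a in anchors]),
                axis=0,
            )
            for c in range(n_cl):
                chunk = regions[assign == c]
                members = sel[np.isin(parcellation.region_of[sel], chunk)]
                if len(members) >= 2:
                    rsn_clusters.append(members)

    # --- bundle pools with log-normal popularity ---
    slog = config.bundle_popularity_sigma

    def popularity(k):
        p = rng.lognormal(0.0, slog, k)
        return p / p.sum()

    # plain bundles avoid planted-network vertices so the map leaves no
    # long-range degree footprint: alignment lives in the pairing, which
    # degree-preserving randomization can destroy
    plain_ids = {h: ids[h][~rsn_mask[ids[h]]] for h in (0, 1)}
    if min(len(plain_ids[0]), len(plain_ids[1])) < 2:
        plain_ids, D_plain = ids, D
    else:
        plain_pos = {h: np.flatnonzero(~rsn_mask[ids[h]]) for h in (0, 1)}
        D_plain = {h: D[h][np.ix_(plain_pos[h], plain_pos[h])] for h in (0, 1)}
    plain = _sample_plain_bundles(
        rng, plain_ids, D_plain, config.n_bundles_plain, config.length_shape
    )
    p_plain = popularity(len(plain))
    rsn_bundles, p_rsn = [], None
    if rsn_clusters:
        # map-aligned bundles: both anchors inside one planted cluster, with
        # a minimum chord so the resulting short tracks survive the
        # 10 mm track-length filter
        for _ in range(config.n_bundles_rsn):
            sel = rsn_clusters[int(rng.integers(len(rsn_clusters)))]
            ia = int(rng.integers(len(sel)))
            d = np.linalg.norm(V[sel] - V[sel[ia]], axis=1)
            far = np.flatnonzero(d >= 8.0)
            ib = int(rng.choice(far)) if len(far) else int(np.argmax(d))
            a, b = sel[ia], sel[ib]
            rsn_bundles.append((int(a), int(b), int(hemisphere_labels[a])))
        p_rsn = popularity(len(rsn_bundles))
    inter_bundles, p_inter = [], None
    if not single:
        for _ in range(config.n_bundles_inter):
            a = int(rng.choice(ids[0]))
            b = int(rng.choice(ids[1]))
            inter_bundles.append((a, b))
        p_inter = popularity(len(inter_bundles))

    p_short = (
        config.short_track_fraction / (1.0 - inter_fraction)
        if inter_fraction < 1.0
        else 0.0
    )
    is_inter = rng.random(n) < inter_fraction
    u_short = rng.random(n)
    u_rsn = rng.random(n)
    tracks = []
    for t in range(n):
        if is_inter[t]:
            a, b = inter_bundles[int(rng.choice(len(inter_bundles), p=p_inter))]
            s1, s2 = V[a], V[b]
            mid = 0.5 * (centers[0] + centers[1])
            inner = _arc_points(s1, s2, (centers[0], centers[1]), (0.7, 0.85, 0.7))
            inner[1] = mid  # route through the gap midpoint
            pts = np.vstack([s1, inner, s2])
        elif u_short[t] < p_short:
            h = 0 if single else int(rng.integers(2))
            pool, local = ids[h], D[h]
            ii = int(rng.integers(len(pool)))
            near = np.flatnonzero((local[ii] > 0) & (local[ii] < 6.0))
            jj = int(rng.choice(near)) if len(near) else (ii + 1) % len(pool)
            s1, s2 = V[pool[ii]], V[pool[jj]]
            mid = centers[h] + (0.5 * (s1 + s2) - centers[h]) * 0.97
            pts = np.vstack([s1, mid, s2])
        else:
            if rsn_bundles and u_rsn[t] < config.rsn_streamline_fraction:
                a, b, h = rsn_bundles[int(rng.choice(len(rsn_bundles), p=p_rsn))]
            else:
                a, b, h = plain[int(rng.choice(len(plain), p=p_plain))]
            s1, s2 = V[a], V[b]
            pts = np.vstack(
                [s1, _arc_points(s1, s2, (centers[h], centers[h]), (0.93, 0.88, 0.93)), s2]
            )
        if config.endpoint_offset_sd_mm > 0:
            pts = pts.copy()
            pts[0] += rng.normal(0, config.endpoint_offset_sd_mm, 3)
            pts[-1] += rng.normal(0, config.endpoint_offset_sd_mm, 3)
        tracks.append(pts)
    return StreamlineSet(tracks)


# --- analytic oracle -------------------------------------------------------

def spherical_harmonic_reference(
    degree_l: int, order_m: int, mesh: CorticalMesh, center: np.ndarray = None
) -> np.ndarray:
    """Real spherical harmonic Y_lm sampled at the mesh vertex directions.

    On a jitter-free sphere mesh these are the continuum limit of the
    low-frequency graph-Laplacian eigenmodes; distinct (l, m) vectors are
    mutually orthogonal under vertex summation up to discretization error.
    Uses the real basis: sqrt(2) * (-1)^m * Re/Im of the complex harmonic
    for m > 0 / m < 0, and Y_l0 for m = 0.
    """
    if abs(order_m) > degree_l:
        raise InvalidParameterError("|m| must not exceed l")
    c = mesh.vertices.mean(axis=0) if center is None else np.asarray(center, float)
    d = mesh.vertices - c
    r = np.linalg.norm(d, axis=1)
    theta = np.arccos(np.clip(d[:, 2] / r, -1.0, 1.0))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])  # azimuth
    y = sph_harm_y(degree_l, abs(order_m), theta, phi)
    if order_m > 0:
        return np.sqrt(2.0) * (-1) ** order_m * np.real(y)
    if order_m < 0:
        return np.sqrt(2.0) * (-1) ** order_m * np.imag(y)
    return np.real(y)
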