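"""Connectome construction: intersection, filters, z-scoring, thresholding."""

import numpy as np
import pytest
import scipy.sparse as sp

from connharm import build, synth
from connharm.types import (
    CorticalMesh,
    DegenerateDistributionError,
    InvalidInputError,
    InvalidParameterError,
    StreamlineSet,
    UndefinedRatioError,
    WeightedConnectome,
    upper_edges,
)
from conftest import single_triangle_mesh


def brute_force_intersections(p0, p1, mesh):
    """Oracle: exhaustive segment-triangle test via plane + barycentric solve."""
    hits = []
    for tid, (a, b, c) in enumerate(mesh.triangles):
        v0, v1, v2 = mesh.vertices[a], mesh.vertices[b], mesh.vertices[c]
        M = np.column_stack([v1 - v0, v2 - v0, -(p1 - p0)])
        if abs(np.linalg.det(M)) < 1e-12:
            continue
        u, v, t = np.linalg.solve(M, p0 - v0)
        if u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9 and -1e-9 <= t <= 1 + 1e-9:
            hits.append((tid, float(np.clip(t, 0, 1))))
    return hits


def oracle_assign(track, mesh, which_end, extension_mm=3.0, max_gap_mm=5.0):
    """Independent re-implementation of the track-end resolution contract."""
    if which_end == "start":
        endpoint, inner, third = track[0], track[1], track[2]
    else:
        endpoint, inner, third = track[-1], track[-2], track[-3]

    def vertex_of(tid, point):
        verts = mesh.triangles[tid]
        d = np.linalg.norm(mesh.vertices[verts] - point, axis=1)
        order = np.lexsort((verts, d))
        return int(verts[order[0]])

    hits = brute_force_intersections(inner, endpoint, mesh)
    if hits:
        tid, t = max(hits, key=lambda h: h[1])
        return vertex_of(tid, inner + t * (endpoint - inner))
    gap = brute_surface_gap(endpoint, mesh)
    if gap > max_gap_mm:
        return None
    d = endpoint - third
    n = np.linalg.norm(d)
    if n < 1e-12:
        return None
    ext = endpoint + extension_mm * d / n
    hits = brute_force_intersections(endpoint, ext, mesh)
    if hits:
        tid, t = min(hits, key=lambda h: h[1])
        return vertex_of(tid, endpoint + t * (ext - endpoint))
    return None


def brute_surface_gap(p, mesh, n=24):
    """Oracle point-to-surface distance by barycentric grid sampling of every
    triangle (accurate to a fraction of the edge length)."""
    uv = np.array(
        [(i / n, j / n) for i in range(n + 1) for j in range(n + 1 - i)]
    )
    v0 = mesh.vertices[mesh.triangles[:, 0]][:, None, :]
    e1 = mesh.vertices[mesh.triangles[:, 1]][:, None, :] - v0
    e2 = mesh.vertices[mesh.triangles[:, 2]][:, None, :] - v0
    pts = v0 + uv[None, :, 0:1] * e1 + uv[None, :, 1:2] * e2
    return float(np.linalg.norm(pts - p, axis=2).min())


class TestIntersectTrackEnd:
    def test_centroid_hit_breaks_tie_to_lowest_vertex(self):
        mesh = single_triangle_mesh()
        centroid = mesh.vertices.mean(axis=0)
        track = np.array(
            [centroid + [0, 0, 3.0], centroid + [0, 0, 1.0], centroid + [0, 0, -1.0]]
        )
        assert build.intersect_track_end(track, mesh, "end") == 0

    def test_matches_brute_force_oracle_on_random_segments(self, icosphere2, rng):
        mesh = icosphere2
        n_agree = 0
        for _ in range(200):
            # segments from interior points to near-surface points
            a = rng.normal(size=3)
            a = a / np.linalg.norm(a)
            inner = a * rng.uniform(5, 25)
            outer = a * rng.uniform(28, 33) + rng.normal(0, 2, 3)
            third = inner * 0.8
            track = np.array([third, inner, outer])
            got = build.intersect_track_end(track, mesh, "end")
            want = oracle_assign(track, mesh, "end")
            assert got == want
            n_agree += got is not None
        assert n_agree > 50  # the fixture is not trivially all-misses

    def test_far_endpoint_returns_none(self, icosphere2):
        track = np.array([[0, 0, 40.0], [0, 0, 45.0], [0, 0, 50.0]])
        assert build.intersect_track_end(track, icosphere2, "end", 3.0, 5.0) is None

    def test_short_track_rejected(self, icosphere2):
        with pytest.raises(InvalidInputError):
            build.intersect_track_end(np.zeros((2, 3)), icosphere2, "end")


class TestBuildLongRange:
    def test_empty_streamlines(self, icosphere2):
        wc = build.build_long_range(StreamlineSet([]), icosphere2)
        assert wc.C.nnz == 0
        assert wc.n_kept == 0

    def test_two_identical_tracks_weight_two(self, icosphere2):
        v = icosphere2.vertices
        track = np.array(
            [v[0], v[0] * 0.7, (v[0] + v[50]) * 0.35, v[50] * 0.7, v[50]]
        )
        tracks = StreamlineSet([track, track.copy()])
        wc = build.build_long_range(tracks, icosphere2, min_track_length_mm=10)
        i = build.intersect_track_end(track, icosphere2, "start")
        j = build.intersect_track_end(track, icosphere2, "end")
        assert wc.C[i, j] == 2
        length = np.linalg.norm(np.diff(track, axis=0), axis=1).sum()
        assert wc.Lbar[i, j] == pytest.approx(length)

    def test_minimum_track_length_filter(self, icosphere2):
        # an 8 mm track is discarded even with perfect intersections
        v = icosphere2.vertices
        nbr = np.argsort(np.linalg.norm(v - v[0], axis=1))[1]
        track = np.array([v[0], (v[0] + v[nbr]) / 2 * 0.98, v[nbr]])
        assert np.linalg.norm(np.diff(track, axis=0), axis=1).sum() < 10
        wc = build.build_long_range(StreamlineSet([track]), icosphere2)
        assert wc.n_discarded_short == 1
        assert wc.C.nnz == 0

    def test_counts_partition_input(self, tiny_connectome, tiny_streamlines):
        wc, _, _ = tiny_connectome
        tracks, _ = tiny_streamlines
        total = (
            wc.n_kept
            + wc.n_discarded_short
            + wc.n_discarded_unresolved
            + wc.n_discarded_selfloop
        )
        assert total == len(tracks)

    def test_symmetry_zero_diagonal(self, tiny_connectome):
        wc, _, _ = tiny_connectome
        assert (wc.C != wc.C.T).nnz == 0
        assert not wc.C.diagonal().any()
        assert (wc.Lbar != wc.Lbar.T).nnz == 0

    def test_matches_oracle_on_fixture(self, icosphere2, tiny_config, rng):
        """End-to-end check against the exhaustive assignment oracle."""
        import dataclasses

        cfg = dataclasses.replace(tiny_config, n_streamlines=120)
        tracks = synth.make_streamlines(icosphere2, icosphere2.hemisphere, cfg)
        wc = build.build_long_range(tracks, icosphere2)
        C_oracle = {}
        for t in tracks.tracks:
            if np.linalg.norm(np.diff(t, axis=0), axis=1).sum() < 10:
                continue
            i = oracle_assign(t, icosphere2, "start")
            j = oracle_assign(t, icosphere2, "end")
            if i is None or j is None or i == j:
                continue
            key = (min(i, j), max(i, j))
            C_oracle[key] = C_oracle.get(key, 0) + 1
        got = {tuple(e): wc.C[e[0], e[1]] for e in upper_edges(wc.C)}
        assert got == C_oracle

    def test_empty_mesh_rejected(self):
        mesh = CorticalMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int), np.zeros(0, dtype=int))
        with pytest.raises(InvalidInputError):
            build.build_long_range(StreamlineSet([]), mesh)


class TestLocalAdjacency:
    def test_single_triangle(self):
        local = build.build_local_adjacency(single_triangle_mesh(), 1)
        assert local.A_l.nnz == 6  # 3 undirected edges

    def test_icosahedron_degree_five(self):
        mesh = synth.make_hemisphere_mesh(0, 30.0)
        local = build.build_local_adjacency(mesh, 1)
        assert (np.asarray(local.A_l.sum(axis=1)).ravel() == 5).all()

    def test_width_two_matches_bfs_oracle(self, icosphere2):
        local1 = build.build_local_adjacency(icosphere2, 1)
        local2 = build.build_local_adjacency(icosphere2, 2)
        # BFS oracle: count vertices within graph distance 2
        from scipy.sparse.csgraph import shortest_path

        d = shortest_path(local1.A_l, unweighted=True)
        for v in range(0, icosphere2.m, 13):
            want = int(((d[v] > 0) & (d[v] <= 2)).sum())
            assert local2.A_l[v].nnz == want

    def test_invalid_width(self, icosphere2):
        with pytest.raises(InvalidParameterError):
            build.build_local_adjacency(icosphere2, 3)


def weights_matrix(weights):
    """Path-graph connectome with prescribed weights, for arithmetic fixtures."""
    m = len(weights) + 1
    C = sp.lil_matrix((m, m))
    L = sp.lil_matrix((m, m))
    for i, w in enumerate(weights):
        C[i, i + 1] = C[i + 1, i] = w
        L[i, i + 1] = L[i + 1, i] = 10.0 + i
    return WeightedConnectome(C=C.tocsr(), Lbar=L.tocsr())


class TestZScoreAndThreshold:
    def test_zscore_arithmetic(self):
        wc = build.zscore_weights(weights_matrix([1, 2, 3]))
        assert wc.mu_C == pytest.approx(2.0)
        z = sorted(sp.triu(wc.Cz, k=1).tocoo().data)
        assert z == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)

    def test_zscore_population_moments(self, tiny_connectome):
        wc, _, _ = tiny_connectome
        z = sp.triu(wc.Cz, k=1).tocoo().data
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_weights_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            build.zscore_weights(weights_matrix([2, 2, 2]))

    def test_threshold_extremes(self, tiny_connectome):
        wc, _, _ = tiny_connectome
        z = sp.triu(wc.Cz, k=1).tocoo().data
        low = build.threshold_long_range(wc, z.min() - 1)
        high = build.threshold_long_range(wc, z.max() + 1)
        assert low.A_c.nnz == wc.C.nnz
        assert high.A_c.nnz == 0

    def test_five_weight_example(self):
        # weights {1,1,1,1,10}: only the strong pair exceeds z_C = 1
        wc = build.zscore_weights(weights_matrix([1, 1, 1, 1, 10]))
        lr = build.threshold_long_range(wc, 1.0)
        assert lr.A_c.nnz == 2  # one undirected edge
        assert lr.A_c[4, 5] == 1

    def test_threshold_nestedness(self, tiny_connectome):
        wc, _, _ = tiny_connectome
        prev = None
        for z_C in (-2.0, 0.0, 1.0, 2.0):
            edges = {tuple(e) for e in upper_edges(build.threshold_long_range(wc, z_C).A_c)}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestCombineAndRatio:
    def test_union_not_sum(self, tiny_connectome):
        _, local, longrange = tiny_connectome
        combined = build.combine(local, longrange)
        assert combined.A.max() == 1
        n_local = local.A_l.nnz // 2
        n_long = longrange.A_c.nnz // 2
        overlap = (local.A_l.multiply(longrange.A_c)).nnz // 2
        assert combined.A.nnz // 2 == n_local + n_long - overlap

    def test_empty_longrange_identity(self, icosphere2):
        from connharm.types import LongRangeAdjacency

        local = build.build_local_adjacency(icosphere2, 1)
        lr = LongRangeAdjacency(A_c=sp.csr_matrix((icosphere2.m, icosphere2.m)))
        combined = build.combine(local, lr)
        assert (combined.A != local.A_l).nnz == 0
        assert build.local_ratio(local, lr) == 1.0

    def test_ratio_arithmetic(self):
        from connharm.types import LocalAdjacency, LongRangeAdjacency

        # explicit matrices with 100 and 50 undirected edges
        def banded(m, k):
            A = sp.lil_matrix((m, m))
            count = 0
            for i in range(m):
                for j in range(i + 1, m):
                    if count == k:
                        break
                    A[i, j] = A[j, i] = 1
                    count += 1
            return A.tocsr()

        local = LocalAdjacency(A_l=banded(30, 100), kernel_width=1)
        lr = LongRangeAdjacency(A_c=banded(30, 50))
        assert build.local_ratio(local, lr) == pytest.approx(2 / 3)

    def test_ratio_monotone_in_threshold(self, tiny_connectome):
        wc, local, _ = tiny_connectome
        prev = -1.0
        for z_C in (-2.0, 0.0, 0.5, 1.0, 2.0):
            lr = build.threshold_long_range(wc, z_C)
            r = build.local_ratio(local, lr)
            assert r >= prev
            prev = r

    def test_undefined_ratio(self):
        from connharm.types import LocalAdjacency, LongRangeAdjacency

        empty = sp.csr_matrix((5, 5))
        with pytest.raises(UndefinedRatioError):
            build.local_ratio(
                LocalAdjacency(A_l=empty, kernel_width=1),
                LongRangeAdjacency(A_c=empty),
            )
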