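"""Alteration operators: trimming, callosectomy, anisotropy, randomization,
mesh smoothing."""

import numpy as np
import pytest
import scipy.sparse as sp

from connharm import alterations, build, synth
from connharm.types import (
    InvalidParameterError,
    LocalAdjacency,
    LongRangeAdjacency,
    edges_to_adjacency,
    upper_edges,
)


def fixture_longrange(lengths, m=None):
    """Path-shaped long-range adjacency with prescribed mean track lengths."""
    m = m or len(lengths) + 1
    edges = np.array([(i, i + 1) for i in range(len(lengths))])
    A = edges_to_adjacency(edges, m)
    L = sp.lil_matrix((m, m))
    for (i, j), l in zip(edges, lengths):
        L[i, j] = L[j, i] = l
    return LongRangeAdjacency(A_c=A), L.tocsr()


class TestTrim:
    def test_eta_zero_identity(self):
        lr, L = fixture_longrange([5, 10, 15, 20])
        out = alterations.trim_long_range(lr, L, 0)
        assert (out.A_c != lr.A_c).nnz == 0

    def test_eta_hundred_empties(self):
        lr, L = fixture_longrange([5, 10, 15, 20])
        assert alterations.trim_long_range(lr, L, 100).A_c.nnz == 0

    def test_descending_removes_longest_first(self):
        lr, L = fixture_longrange([5, 10, 15, 20])
        out = alterations.trim_long_range(lr, L, 50, "descending")
        kept = {tuple(e) for e in upper_edges(out.A_c)}
        assert kept == {(0, 1), (1, 2)}  # lengths 5 and 10 survive

    def test_ascending_removes_shortest_first(self):
        lr, L = fixture_longrange([5, 10, 15, 20])
        out = alterations.trim_long_range(lr, L, 50, "ascending")
        kept = {tuple(e) for e in upper_edges(out.A_c)}
        assert kept == {(2, 3), (3, 4)}

    def test_random_reproducible_and_counted(self):
        lr, L = fixture_longrange(list(range(1, 21)))
        a = alterations.trim_long_range(lr, L, 35, "random", seed=3)
        b = alterations.trim_long_range(lr, L, 35, "random", seed=3)
        assert (a.A_c != b.A_c).nnz == 0
        assert a.A_c.nnz // 2 == 20 - round(0.35 * 20)

    def test_invalid_eta(self):
        lr, L = fixture_longrange([5, 10])
        with pytest.raises(InvalidParameterError):
            alterations.trim_long_range(lr, L, 101)


class TestCallosectomy:
    def _fixture(self):
        # 10 left + 10 right vertices; 40 inter edges + 10 intra edges
        inter = [(a, 10 + (a + b) % 10) for a in range(10) for b in range(4)]
        intra = [(i, i + 1) for i in range(9)] + [(10, 12)]
        edges = np.array(inter + intra)
        A = edges_to_adjacency(edges, 20)
        L = sp.lil_matrix((20, 20))
        for n, (i, j) in enumerate(edges):
            L[i, j] = L[j, i] = 5.0 + n
        labels = np.array([0] * 10 + [1] * 10)
        return LongRangeAdjacency(A_c=A), L.tocsr(), labels, set(map(tuple, intra))

    def test_kappa_zero_identity(self):
        lr, L, labels, _ = self._fixture()
        out = alterations.callosectomy(lr, labels, 0)
        assert (out.A_c != lr.A_c).nnz == 0

    def test_exact_count_removed(self):
        lr, L, labels, intra = self._fixture()
        out = alterations.callosectomy(lr, labels, 25, "random", seed=1)
        kept = {tuple(e) for e in upper_edges(out.A_c)}
        kept_inter = {e for e in kept if e not in intra}
        assert len(kept_inter) == 30  # 40 - round(0.25 * 40)

    def test_intra_untouched(self):
        lr, L, labels, intra = self._fixture()
        out = alterations.callosectomy(lr, labels, 80, "descending", seed=0, Lbar=L)
        kept = {tuple(e) for e in upper_edges(out.A_c)}
        assert intra <= kept

    def test_full_split_disconnects(self):
        lr, L, labels, intra = self._fixture()
        out = alterations.callosectomy(lr, labels, 100, "descending", Lbar=L)
        e = upper_edges(out.A_c)
        assert (labels[e[:, 0]] == labels[e[:, 1]]).all()

    def test_random_mode_capped_at_99(self):
        lr, L, labels, _ = self._fixture()
        with pytest.raises(InvalidParameterError):
            alterations.callosectomy(lr, labels, 100, "random")


class TestAnisotropy:
    def test_rho_zero_identity(self, icosphere2):
        local = build.build_local_adjacency(icosphere2, 1)
        out = alterations.anisotropy(local, 0)
        assert (out.A_l != local.A_l).nnz == 0

    def test_random_mode_binomial(self):
        # ~10,000 edges, rho=30: removal count within the 99% binomial interval
        rng = np.random.default_rng(0)
        m = 600
        pairs = {tuple(sorted(rng.choice(m, 2, replace=False))) for _ in range(12000)}
        edges = np.array(sorted(pairs))[:10000]
        local = LocalAdjacency(
            A_l=edges_to_adjacency(edges, m), kernel_width=1,
            edge_lengths=np.ones(len(edges)),
        )
        out = alterations.anisotropy(local, 30, "random", seed=11)
        removed = local.A_l.nnz // 2 - out.A_l.nnz // 2
        n = local.A_l.nnz // 2
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(removed - 0.3 * n) < 2.58 * sd

    def test_descending_removes_longest(self, icosphere2):
        local = build.build_local_adjacency(icosphere2, 2)
        edges = upper_edges(local.A_l)
        longest = edges[np.argmax(local.edge_lengths)]
        out = alterations.anisotropy(local, 1e-9 + 100.0 / len(edges), "descending")
        kept = {tuple(e) for e in upper_edges(out.A_l)}
        assert tuple(longest) not in kept

    def test_invalid_rho(self, icosphere2):
        local = build.build_local_adjacency(icosphere2, 1)
        with pytest.raises(InvalidParameterError):
            alterations.anisotropy(local, -5)


class TestRandomize:
    def _fixture(self, n_edges=500, m=120, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([0] * (m // 2) + [1] * (m // 2))
        pairs = set()
        while len(pairs) < n_edges:
            i, j = rng.choice(m, 2, replace=False)
            pairs.add((min(i, j), max(i, j)))
        edges = np.array(sorted(pairs))
        return LongRangeAdjacency(A_c=edges_to_adjacency(edges, m)), labels

    @pytest.mark.parametrize("scheme", alterations.SCHEMES)
    def test_edge_count_conserved(self, scheme):
        lr, labels = self._fixture()
        for s in range(10):
            out = alterations.randomize_long_range(lr, labels, scheme, seed=s)
            assert out.A_c.nnz == lr.A_c.nnz

    def test_global_preserves_degrees(self):
        lr, labels = self._fixture()
        out = alterations.randomize_long_range(lr, labels, "global", seed=1)
        assert (out.A_c.sum(axis=1) == lr.A_c.sum(axis=1)).all()

    def test_inter_leaves_intra_blocks_identical(self):
        lr, labels = self._fixture()
        out = alterations.randomize_long_range(lr, labels, "inter", seed=2)
        e_in = upper_edges(lr.A_c)
        e_out = upper_edges(out.A_c)
        intra_in = {tuple(e) for e in e_in if labels[e[0]] == labels[e[1]]}
        intra_out = {tuple(e) for e in e_out if labels[e[0]] == labels[e[1]]}
        assert intra_in == intra_out
        # and inter-degrees per node conserved
        def inter_deg(edges):
            d = np.zeros(len(labels), int)
            for i, j in edges:
                if labels[i] != labels[j]:
                    d[i] += 1
                    d[j] += 1
            return d

        assert (inter_deg(e_in) == inter_deg(e_out)).all()

    def test_intra_leaves_inter_block_identical(self):
        lr, labels = self._fixture()
        out = alterations.randomize_long_range(lr, labels, "intra", seed=3)
        e_in = {tuple(e) for e in upper_edges(lr.A_c) if labels[e[0]] != labels[e[1]]}
        e_out = {tuple(e) for e in upper_edges(out.A_c) if labels[e[0]] != labels[e[1]]}
        assert e_in == e_out

    @pytest.mark.parametrize("scheme", ["intra", "inter+intra"])
    def test_within_block_degrees_preserved(self, scheme):
        lr, labels = self._fixture()
        out = alterations.randomize_long_range(lr, labels, scheme, seed=4)

        def block_degrees(A):
            e = upper_edges(A)
            d = {"intra": np.zeros(len(labels), int), "inter": np.zeros(len(labels), int)}
            for i, j in e:
                key = "inter" if labels[i] != labels[j] else "intra"
                d[key][i] += 1
                d[key][j] += 1
            return d

        din, dout = block_degrees(lr.A_c), block_degrees(out.A_c)
        assert (din["intra"] == dout["intra"]).all()
        assert (din["inter"] == dout["inter"]).all()

    def test_actually_shuffles(self):
        lr, labels = self._fixture()
        out = alterations.randomize_long_range(lr, labels, "global", seed=5)
        assert (out.A_c != lr.A_c).nnz > 0

    def test_reproducible(self):
        lr, labels = self._fixture()
        a = alterations.randomize_long_range(lr, labels, "inter+intra", seed=6)
        b = alterations.randomize_long_range(lr, labels, "inter+intra", seed=6)
        assert (a.A_c != b.A_c).nnz == 0

    def test_tiny_block_warns_and_passes_through(self):
        lr, labels = self._fixture(n_edges=1, m=10)
        with pytest.warns(UserWarning):
            out = alterations.randomize_long_range(lr, labels, "global", seed=0)
        assert (out.A_c != lr.A_c).nnz == 0


class TestSmoothMesh:
    def test_zero_iterations_identity(self, icosphere2):
        out = alterations.smooth_mesh(icosphere2, 0)
        assert (out.vertices == icosphere2.vertices).all()

    def test_topology_preserved(self, icosphere2):
        out = alterations.smooth_mesh(icosphere2, 8)
        assert (out.triangles == icosphere2.triangles).all()

    def test_jittered_sphere_radius_variance_decreases(self):
        mesh = synth.make_hemisphere_mesh(2, 30.0, vertex_jitter_mm=0.8, seed=3)
        out = alterations.smooth_mesh(mesh, 21)
        var_before = np.var(np.linalg.norm(mesh.vertices - mesh.vertices.mean(0), axis=1))
        var_after = np.var(np.linalg.norm(out.vertices - out.vertices.mean(0), axis=1))
        assert var_after < var_before
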