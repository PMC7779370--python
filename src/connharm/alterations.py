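"""Connectome alteration operators.

Each operator perturbs one ingredient of the combined connectome while
leaving the rest untouched:

* trimming (eta): remove a percentage of long-range connections ranked by
  mean track length (longest-first, shortest-first, or random);
* callosectomy (kappa): the same, restricted to inter-hemispheric
  long-range connections (random mode capped at 99% so the hemispheres
  stay connected through at least one edge);
* anisotropy (rho): remove local mesh-kernel edges, randomly per edge with
  probability rho/100 or by ascending/descending Euclidean edge length;
* randomization: degree-preserving double-edge swaps of the long-range
  connections, restricted to the inter-hemispheric block (bipartite swaps),
  the intra-hemispheric blocks (each hemisphere independently), both, or
  applied globally in one batch;
* mesh smoothing (f_i iterations): Laplacian smoothing with
  inverse-vertex-distance weights, recomputed from the current coordinates
  each pass; the triangle list is never changed.

All operators preserve symmetry and binarity and are reproducible under a
seed; null parameters (0% / 0 iterations / 0 swaps) return inputs unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .types import (
    CorticalMesh,
    InvalidParameterError,
    LocalAdjacency,
    LongRangeAdjacency,
    edges_to_adjacency,
    upper_edges,
)

__all__ = [
    "trim_long_range",
    "callosectomy",
    "anisotropy",
    "randomize_long_range",
    "smooth_mesh",
]

ORDERS = ("ascending", "descending", "random")
SCHEMES = ("inter", "intra", "inter+intra", "global")


def _edge_lengths_from_lbar(edges: np.ndarray, Lbar: sp.spmatrix) -> np.ndarray:
    Lbar = sp.csr_matrix(Lbar)
    return np.array([Lbar[i, j] for i, j in edges])


def _select_removal(
    edges: np.ndarray,
    lengths: np.ndarray,
    n_remove: int,
    order: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices (into ``edges``) of the connections to remove."""
    if order == "random":
        return rng.choice(len(edges), size=n_remove, replace=False)
    # deterministic rank by length; ties broken by vertex-pair lexicographic order
    keys = (edges[:, 1], edges[:, 0], -lengths if order == "descending" else lengths)
    return np.lexsort(keys)[:n_remove]


def trim_long_range(
    longrange: LongRangeAdjacency,
    Lbar: sp.spmatrix,
    eta: float,
    order: str = "descending",
    seed: int = 0,
) -> LongRangeAdjacency:
    """Remove a percentage eta of long-range connections by mean track length.

    ``descending`` removes the longest tracks first, ``ascending`` the
    shortest first, ``random`` a uniform sample; exactly
    round(eta/100 * n_edges) undirected edges are removed.
    """
    if not 0 <= eta <= 100:
        raise InvalidParameterError("eta must lie in [0, 100]")
    if order not in ORDERS:
        raise InvalidParameterError(f"order must be one of {ORDERS}")
    edges = upper_edges(longrange.A_c)
    n_remove = int(round(eta / 100.0 * len(edges)))
    if n_remove == 0:
        return LongRangeAdjacency(A_c=longrange.A_c.copy(), z_C=longrange.z_C)
    lengths = _edge_lengths_from_lbar(edges, Lbar)
    rng = np.random.default_rng(seed)
    drop = _select_removal(edges, lengths, n_remove, order, rng)
    keep = np.setdiff1d(np.arange(len(edges)), drop)
    return LongRangeAdjacency(
        A_c=edges_to_adjacency(edges[keep], longrange.m), z_C=longrange.z_C
    )


def callosectomy(
    longrange: LongRangeAdjacency,
    hemisphere_labels: np.ndarray,
    kappa: float,
    order: str = "random",
    seed: int = 0,
    Lbar: sp.spmatrix = None,
) -> LongRangeAdjacency:
    """Remove a percentage kappa of inter-hemispheric long-range connections.

    Intra-hemispheric connections are returned untouched.  Random mode is
    capped at kappa <= 99 to avoid totally disconnected hemispheres; the
    ordered modes rank by mean track length (``Lbar`` required) and allow
    the full 100% split.
    """
    if order not in ORDERS:
        raise InvalidParameterError(f"order must be one of {ORDERS}")
    hi = 99 if order == "random" else 100
    if not 0 <= kappa <= hi:
        raise InvalidParameterError(f"kappa must lie in [0, {hi}] for order={order}")
    labels = np.asarray(hemisphere_labels)
    edges = upper_edges(longrange.A_c)
    inter = labels[edges[:, 0]] != labels[edges[:, 1]]
    inter_edges = edges[inter]
    n_remove = int(round(kappa / 100.0 * len(inter_edges)))
    if n_remove == 0:
        return LongRangeAdjacency(A_c=longrange.A_c.copy(), z_C=longrange.z_C)
    lengths = None
    if order != "random":
        if Lbar is None:
            raise InvalidParameterError("ordered callosectomy needs the Lbar matrix")
        lengths = _edge_lengths_from_lbar(inter_edges, Lbar)
    rng = np.random.default_rng(seed)
    drop = _select_removal(inter_edges, lengths, n_remove, order, rng)
    keep_inter = np.setdiff1d(np.arange(len(inter_edges)), drop)
    kept = np.vstack([edges[~inter], inter_edges[keep_inter]])
    return LongRangeAdjacency(
        A_c=edges_to_adjacency(kept, longrange.m), z_C=longrange.z_C
    )


def anisotropy(
    local: LocalAdjacency,
    rho: float,
    order: str = "random",
    seed: int = 0,
    edge_lengths: np.ndarray = None,
) -> LocalAdjacency:
    """Remove local gray-matter edges ("anisotropy").

    Random mode removes each edge independently with probability rho/100
    (per-edge Bernoulli); ordered modes remove round(rho/100 * n_edges)
    edges by ascending or descending Euclidean edge length.
    """
    if not 0 <= rho <= 100:
        raise InvalidParameterError("rho must lie in [0, 100]")
    if order not in ORDERS:
        raise InvalidParameterError(f"order must be one of {ORDERS}")
    edges = upper_edges(local.A_l)
    lengths = edge_lengths if edge_lengths is not None else local.edge_lengths
    if rho == 0:
        return LocalAdjacency(local.A_l.copy(), local.kernel_width, lengths)
    rng = np.random.default_rng(seed)
    if order == "random":
        keep_mask = rng.random(len(edges)) >= rho / 100.0
        keep = np.flatnonzero(keep_mask)
    else:
        if lengths is None:
            raise InvalidParameterError("ordered anisotropy needs edge lengths")
        n_remove = int(round(rho / 100.0 * len(edges)))
        drop = _select_removal(edges, np.asarray(lengths), n_remove, order, rng)
        keep = np.setdiff1d(np.arange(len(edges)), drop)
    kept_lengths = np.asarray(lengths)[keep] if lengths is not None else None
    return LocalAdjacency(
        A_l=edges_to_adjacency(edges[keep], local.m),
        kernel_width=local.kernel_width,
        edge_lengths=kept_lengths,
    )


def _double_edge_swaps(
    edges: set,
    rng: np.random.Generator,
    n_attempts: int,
    bipartite_sides: tuple = None,
) -> set:
    """Degree-preserving rewiring of an undirected edge set.

    Plain mode: pick edges (a, b), (c, d), rewire to (a, d), (c, b) after a
    random orientation flip, skipping swaps that would create self-loops or
    duplicate edges.  Bipartite mode (``bipartite_sides = (left_set,)``
    membership test array): edges are oriented left->right and rewired to
    (a, d), (c, b), preserving each node's within-block degree.
    """
    edge_list = list(edges)
    n = len(edge_list)
    if n < 2:
        return edges
    pos = {e: i for i, e in enumerate(edge_list)}
    is_left = bipartite_sides
    for _ in range(n_attempts):
        i1, i2 = rng.integers(n), rng.integers(n)
        if i1 == i2:
            continue
        a, b = edge_list[i1]
        c, d = edge_list[i2]
        if is_left is not None:
            # orient both edges left -> right
            if not is_left[a]:
                a, b = b, a
            if not is_left[c]:
                c, d = d, c
            new1, new2 = (a, d), (c, b)
        else:
            if rng.random() < 0.5:
                c, d = d, c
            new1, new2 = (a, d), (c, b)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        new1 = (new1[0], new1[1]) if new1[0] < new1[1] or is_left is not None else (new1[1], new1[0])
        new2 = (new2[0], new2[1]) if new2[0] < new2[1] or is_left is not None else (new2[1], new2[0])
        if new1 in pos or new2 in pos or new1 == new2:
            continue
        old1 = edge_list[i1]
        old2 = edge_list[i2]
        del pos[old1]
        del pos[old2]
        edge_list[i1], edge_list[i2] = new1, new2
        pos[new1], pos[new2] = i1, i2
    return set(edge_list)


def randomize_long_range(
    longrange: LongRangeAdjacency,
    hemisphere_labels: np.ndarray,
    scheme: str = "global",
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> LongRangeAdjacency:
    """Degree-preserving shuffle of the long-range connections.

    ``inter`` rewires only the inter-hemispheric block with bipartite swaps
    (intra blocks bit-identical); ``intra`` rewires each hemisphere's
    intra block independently (inter block bit-identical); ``inter+intra``
    does both; ``global`` rewires all long-range edges in a single batch.
    Every node's within-block degree is conserved, as is the edge count.
    """
    if scheme not in SCHEMES:
        raise InvalidParameterError(f"scheme must be one of {SCHEMES}")
    labels = np.asarray(hemisphere_labels)
    edges = upper_edges(longrange.A_c)
    rng = np.random.default_rng(seed)
    is_left = labels == labels.min()

    def as_set(arr):
        return {(int(i), int(j)) for i, j in arr}

    inter_mask = labels[edges[:, 0]] != labels[edges[:, 1]]
    blocks = []
    if scheme == "global":
        blocks.append((as_set(edges), None))
    else:
        inter_edges = edges[inter_mask]
        intra = edges[~inter_mask]
        left_intra = intra[is_left[intra[:, 0]]]
        right_intra = intra[~is_left[intra[:, 0]]]
        if scheme in ("inter", "inter+intra"):
            # orient inter edges left -> right for the bipartite swaps
            oriented = np.where(
                is_left[inter_edges[:, 0]][:, None], inter_edges, inter_edges[:, ::-1]
            )
            blocks.append((as_set(oriented), is_left))
        else:
            blocks.append((as_set(inter_edges), "fixed"))
        for block in (left_intra, right_intra):
            if scheme in ("intra", "inter+intra"):
                blocks.append((as_set(block), None))
            else:
                blocks.append((as_set(block), "fixed"))

    out = []
    for block, mode in blocks:
        if isinstance(mode, str) and mode == "fixed":
            out.extend(block)
            continue
        if len(block) < 2:
            warnings.warn("block has fewer than 2 edges; returned unshuffled")
            out.extend(block)
            continue
        shuffled = _double_edge_swaps(
            block, rng, n_attempts=swaps_per_edge * len(block), bipartite_sides=mode
        )
        out.extend(shuffled)
    arr = np.array([(min(e), max(e)) for e in sorted(out)], dtype=np.int64)
    return LongRangeAdjacency(
        A_c=edges_to_adjacency(arr, longrange.m)
        if len(arr)
        else sp.csr_matrix((longrange.m, longrange.m)),
        z_C=longrange.z_C,
    )


def smooth_mesh(mesh: CorticalMesh, f_i: int) -> CorticalMesh:
    """Laplacian mesh smoothing with inverse-vertex-distance weights.

    Each iteration replaces every vertex by the weighted mean of its mesh
    neighbors, with weights 1/dist recomputed from the current coordinates;
    the triangle list is unchanged.  ``f_i`` is typically taken from the
    Fibonacci sequence (0, 8, 21, 89).
    """
    if f_i < 0:
        raise InvalidParameterError("f_i must be >= 0")
    V = mesh.vertices.copy()
    if f_i == 0:
        return CorticalMesh(V, mesh.triangles.copy(), mesh.hemisphere.copy())
    edges = mesh.edge_array()
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    for _ in range(f_i):
        d = np.linalg.norm(V[i] - V[j], axis=1)
        w = 1.0 / np.maximum(d, 1e-12)
        W = sp.coo_matrix((w, (i, j)), shape=(mesh.m, mesh.m)).tocsr()
        norm = np.asarray(W.sum(axis=1)).ravel()
        V = np.asarray(W @ V) / norm[:, None]
    return CorticalMesh(V, mesh.triangles.copy(), mesh.hemisphere.copy())
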