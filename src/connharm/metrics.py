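"""Similarity metrics and surrogate statistics.

Mutual information between a harmonic and a binary network map: the
harmonic values are discretized into N = 16 equal-width bins over their
range, the map contributes M = 2 states, and MI is computed from the joint
vertex-count histogram in natural-log units (nats).

Correlation matrices |Pearson| compare two harmonic sets index-by-index,
either vertex-wise (same mesh) or region-wise after projecting each
harmonic to the unweighted per-region mean in an atlas parcellation
(required whenever the two bases live on different vertex orderings).

The surrogate statistic pools a window of consecutive harmonics
k in {k0, ..., k0 + n_k - 1} and reports the Monte-Carlo probability that a
surrogate connectome's MI reaches the original's:
p = (1 + #{MI_surr >= MI_orig}) / (1 + N_surr * n_k).
Multiple-comparison control is Benjamini-Hochberg (default FDR 0.1) or
Bonferroni, via statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import (
    AtlasParcellation,
    HarmonicBasis,
    InvalidInputError,
    RSNMap,
)

__all__ = [
    "MIResult",
    "mutual_information",
    "project_to_atlas",
    "correlation_matrix",
    "surrogate_pvalue",
    "benjamini_hochberg",
    "bonferroni",
    "mi_window",
]


@dataclass
class MIResult:
    """Mutual information of one harmonic with a binary map, in nats."""

    mi: float
    n_bins: int
    joint: np.ndarray  # (N, M) joint probabilities, sums to 1
    p_psi: np.ndarray
    p_map: np.ndarray


def mutual_information(psi: np.ndarray, v_map, N: int = 16) -> MIResult:
    """MI(psi_k, v) with the harmonic in N equal-width bins, map binary.

    Empty joint-histogram cells contribute 0.  A constant harmonic or a
    constant map carries no information: MI = 0 is returned with a warning.
    """
    psi = np.asarray(psi, dtype=float)
    v = v_map.values if isinstance(v_map, RSNMap) else np.asarray(v_map)
    if psi.shape != v.shape:
        raise InvalidInputError("harmonic and map must have the same length")
    if N < 1:
        raise InvalidInputError("need at least one bin")
    lo, hi = float(psi.min()), float(psi.max())
    M = 2
    if hi == lo or v.min() == v.max():
        warnings.warn("constant harmonic or constant map: MI = 0")
        return MIResult(0.0, N, np.zeros((N, M)), np.zeros(N), np.zeros(M))
    # equal-width bins over [min, max]; the top edge is inclusive
    idx = np.minimum(((psi - lo) / (hi - lo) * N).astype(int), N - 1)
    joint = np.zeros((N, M))
    np.add.at(joint, (idx, v.astype(int)), 1.0)
    joint /= joint.sum()
    p_n = joint.sum(axis=1)
    p_m = joint.sum(axis=0)
    nz = joint > 0
    mi = float(
        np.sum(joint[nz] * np.log(joint[nz] / np.outer(p_n, p_m)[nz]))
    )
    return MIResult(max(mi, 0.0), N, joint, p_n, p_m)


def mi_window(
    basis: HarmonicBasis, v_map, k0: int = 7, n_k: int = 5, N: int = 16
) -> np.ndarray:
    """MI of harmonics k0 .. k0 + n_k - 1 (1-based) with a binary map."""
    return np.array(
        [mutual_information(basis.psi(k), v_map, N).mi for k in range(k0, k0 + n_k)]
    )


def project_to_atlas(vector: np.ndarray, parcellation: AtlasParcellation) -> np.ndarray:
    """Unweighted per-region mean of a vertex vector."""
    vector = np.asarray(vector, dtype=float)
    region = parcellation.region_of
    if vector.shape != region.shape:
        raise InvalidInputError("vector and parcellation lengths differ")
    counts = np.bincount(region, minlength=parcellation.n_regions)
    if (counts == 0).any():
        raise InvalidInputError("parcellation has empty regions")
    sums = np.bincount(region, weights=vector, minlength=parcellation.n_regions)
    return sums / counts


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    nx, ny = np.linalg.norm(xd), np.linalg.norm(yd)
    if nx == 0 or ny == 0:
        warnings.warn("constant vector in correlation: defined as 0")
        return 0.0
    return abs(float(xd @ yd) / (nx * ny))


def correlation_matrix(
    basis_a: HarmonicBasis,
    basis_b: HarmonicBasis,
    K: int,
    space: str = "vertex",
    parcellation: AtlasParcellation = None,
) -> np.ndarray:
    """K x K matrix of |Pearson| between two harmonic sets.

    ``space='vertex'`` correlates raw eigenvectors (bases must share a
    mesh); ``space='atlas'`` first projects each harmonic to per-region
    means, which is mandatory when vertex orderings differ between meshes.
    """
    if space not in ("vertex", "atlas"):
        raise InvalidInputError("space must be 'vertex' or 'atlas'")
    if K > min(basis_a.K, basis_b.K):
        raise InvalidInputError("K exceeds the number of computed harmonics")
    if space == "atlas":
        if parcellation is None:
            raise InvalidInputError("atlas space requires a parcellation")
        A = np.column_stack(
            [project_to_atlas(basis_a.psi(k), parcellation) for k in range(1, K + 1)]
        )
        B = np.column_stack(
            [project_to_atlas(basis_b.psi(k), parcellation) for k in range(1, K + 1)]
        )
    else:
        if basis_a.m != basis_b.m:
            raise InvalidInputError("vertex space requires bases on the same mesh")
        A = basis_a.eigenvectors[:, :K]
        B = basis_b.eigenvectors[:, :K]
    P = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            P[i, j] = _abs_pearson(A[:, i], B[:, j])
    return P


def surrogate_pvalue(mi_orig: np.ndarray, mi_surr: np.ndarray) -> float:
    """Monte-Carlo probability that surrogate MI reaches the original.

    ``mi_orig``: length-n_k MI values of the original connectome's
    harmonics; ``mi_surr``: (N_surr, n_k) MI values of the surrogates.
    p = (1 + #{MI_surr >= MI_orig}) / (1 + N_surr * n_k), in (0, 1].
    """
    mi_orig = np.asarray(mi_orig, dtype=float)
    mi_surr = np.asarray(mi_surr, dtype=float)
    if mi_surr.ndim != 2 or mi_surr.shape[1] != mi_orig.shape[0]:
        raise InvalidInputError("mi_surr must be (N_surr, n_k) aligned with mi_orig")
    exceed = int(np.sum(mi_surr >= mi_orig[None, :]))
    return (1 + exceed) / (1 + mi_surr.size)


def benjamini_hochberg(p_values, q: float = 0.1) -> np.ndarray:
    """Step-up FDR control; returns boolean rejection flags."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Reject where p <= alpha / n_tests; returns boolean flags."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    return p_values <= alpha / p_values.size
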