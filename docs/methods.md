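# Methods

## Overview

`connharm` studies how *connectome harmonics* — eigenvectors of the graph
Laplacian of a combined gray+white-matter connectivity graph on a cortical
surface mesh — respond to controlled alterations of that graph.  The
pipeline has five stages:

1. **Synthetic brain.**  Two ellipsoidal hemisphere meshes, a geodesic
   region parcellation, a planted binary network map ("RSN"), and a
   tractography-like streamline set.
2. **Connectome construction.**  Long-range connectivity C from
   streamline–mesh intersection; local connectivity A_ℓ from the mesh
   edge graph (kernel width Λ_s ∈ {1, 2}); z-scored weights thresholded at
   z_C give the binary long-range adjacency A_c; the combined connectome is
   A = A_ℓ ∪ A_c.
3. **Alterations.**  Trimming (η), callosectomy (κ), anisotropy (ρ), mesh
   smoothing (f_i), and four degree-preserving randomization schemes.
4. **Harmonics.**  L = ½((D−A)+(D−A)ᵀ); ascending eigenpairs (λ_k, ψ_k),
   numbered from k = 1 (the constant mode of a connected graph).
5. **Statistics.**  Mutual information MI(ψ_k, v) between each harmonic and
   the binary map (N = 16 equal-width harmonic bins, M = 2 map states,
   natural log); |Pearson| correlation matrices between harmonic sets
   (vertex- or atlas-space); the Monte-Carlo summary statistic
   p_MI_surr = (1 + #{MI_surr ≥ MI_orig}) / (1 + N_surr·n_k) pooled over
   harmonics k ∈ {k0, …, k0+n_k−1} (defaults k0 = 7, n_k = 5,
   N_surr = 100); Benjamini–Hochberg control at FDR 0.1.

## Model and key parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| f_i | 0 (range {0, 8, 21, 89}) | iterations | Laplacian mesh smoothing with inverse-vertex-distance weights |
| z_C | 1 | weight SD | adjacency threshold on z-scored streamline counts |
| Λ_s | 2 | mesh edges | local diffusion kernel width (graph distance) |
| η | 0 | % | long-range connections trimmed by mean track length |
| κ | 0 | % | inter-hemispheric connections removed (callosectomy) |
| ρ | 0 | % | local mesh-kernel edges removed (anisotropy) |
| min track length | 10 | mm | shorter streamlines are discarded |
| extension | 3 | mm | linear extension of a track bound that misses the surface, along the direction from the third-last point to the endpoint |
| max gap | 5 | mm | maximum endpoint-to-surface distance before a track is discarded |
| K | 100 | — | number of harmonics computed |
| N | 16 | bins | harmonic discretization for MI |
| k0, n_k, N_surr | 7, 5, 100 | — | surrogate statistic window and ensemble size |

**z-score population.**  μ_C and σ_C are computed over the *nonzero*
upper-triangular weights only, with the population (not sample) standard
deviation.  Including the ~m²/2 structural zeros would collapse σ_C and
make integer thresholds z_C meaningless; conditioning on W > 0 matches how
the weight distribution is usually reported.

**Intersection details.**  The terminal segment of a track is tested
against the mesh first; if it misses and the endpoint lies within the
maximum gap of the surface, the extended segment is tested.  When a segment
crosses several triangles the intersection nearest the track endpoint is
used (the extension exists to recover near-misses).  The assigned vertex is
the hit triangle's vertex nearest the intersection point, ties broken by
lowest vertex index.  Tracks with both ends on one vertex (self-loops) are
discarded.  The fast path prunes candidate triangles with a KD-tree over
triangle centroids using an exact covering radius, so it is equivalent to
the exhaustive test (asserted against a brute-force oracle in the suite).

**Edge counting for the local ratio r.**  r = n_local/(n_local + n_long)
with undirected edge counts, equivalently tr(A_ℓ²)/(tr(A_ℓ²)+tr(A_c²)) for
binary symmetric zero-diagonal matrices (the trace of such a matrix itself
is identically zero, so only the squared form is meaningful).

**Eigensolver.**  Problems up to 4096 vertices use a dense symmetric
solver (`scipy.linalg.eigh`, index subset); larger ones use shift-invert
Lanczos with a fixed all-ones-plus-indexed-perturbation starting vector.
Both paths are bit-reproducible.  Eigenvector signs are fixed by making
each vector's largest-magnitude entry positive.  An eigenvalue counts as
zero below 1e−8 relative to the largest computed eigenvalue; the count of
zero modes equals the number of connected components (asserted against a
union-find oracle).  Within a degenerate multiplet individual vectors are
solver-dependent, so cross-basis property tests compare subspaces via
principal angles while the reported correlation matrices use per-vector
|Pearson|.

**Randomization.**  Degree-preserving double-edge swaps (≈10·|E| attempted
swaps per block).  The *inter* scheme uses bipartite swaps on the
inter-hemispheric block (both endpoints keep their inter-degree); *intra*
shuffles each hemisphere's diagonal block independently; *inter+intra*
does both; *global* swaps all long-range edges in one batch.  Untouched
blocks are returned bit-identical.

**Ordering conventions.**  Trimming and ordered callosectomy rank edges by
the mean track length matrix (the only stored length statistic), ties
broken by vertex-pair lexicographic order.  Trimming and callosectomy
remove an exact rounded count of edges in every mode; anisotropy's random
mode removes each edge independently with probability ρ/100 (its ordered
modes remove an exact count by Euclidean edge length).  Random callosectomy
is capped at 99% so the hemispheres never disconnect by chance.

## The synthetic brain

The generator replaces MRI-derived inputs (surface templates and a
whole-brain tractogram) while preserving the statistical structure the
analysis depends on.  Defaults define the reference dataset used by the
tests and the acceptance script:

* **Mesh**: two icosphere-based hemispheres, subdivision 3 (642 vertices
  each, 1284 total), radius 30 mm, half-axes scaled by (1.35, 1.0, 0.75) —
  hemispheres are longer front-to-back than top-to-bottom, which also
  removes the spherical eigenvalue degeneracies — vertex jitter 0.3 mm,
  inter-hemispheric gap 10 mm.  Edge lengths fall in the 1–6 mm range of
  cortical surface templates.  The fidelity target is graph structure and
  edge-length scale, not cortical folding: the analysis consumes only the
  mesh graph and coordinates.
* **Parcellation**: farthest-point seeding with nearest-seed geodesic
  assignment, 12 regions per hemisphere — contiguous, roughly equal-area
  patches standing in for an anatomical atlas.
* **Network map**: 10 regions drawn at random, a binary map covering ~40%
  of vertices, playing the role of a resting-state network's cortical
  footprint.
* **Streamlines** (20,000): tracks follow a finite pool of fiber *bundles*
  (fixed vertex pairs with log-normal popularity), the way tractography
  streamlines concentrate on white-matter tracts; this yields a
  heavy-tailed pairwise weight distribution with repeated pairs whose
  counts survive the z-score threshold.  20% of tracks are
  inter-hemispheric; 5% are deliberately shorter than 10 mm to exercise
  the minimum-length filter; endpoints are scattered around the surface
  with 0.5 mm isotropic Gaussian noise so the extension/gap machinery is
  exercised.  Intra-hemispheric tracks run just beneath the surface
  (shallow arcs); plain association bundles target log-normal chord
  lengths (median ≈ 35 mm), while inter-hemispheric tracks routed through
  the gap provide the long tail; the overall length histogram is skewed
  toward short fibers.
* **Planted structure**: a configurable fraction (default 35%) of
  intra-hemispheric tracks follows *map-aligned* bundles whose endpoints
  both lie inside one planted patch (chord ≥ 8 mm so the track survives
  the length filter).  Plain bundles avoid map vertices, so expected
  long-range degree is approximately flat across the cortex: the map
  alignment lives in the *pairing* of endpoints, not in the degree
  sequence.  This matters because the surrogate null model preserves
  degrees — a plant encoded in degrees would survive randomization (or be
  re-assembled by it), while a pairing plant is destroyed by
  intra-hemispheric swaps and preserved by inter-hemispheric ones, which
  is exactly the contrast the randomization experiment measures.  Each
  planted patch contributes one low-frequency map-aligned eigenmode, so
  with ten patches the aligned modes populate the harmonic window 7–11
  used by the surrogate statistic.

What the generator does *not* emulate: cortical folding and curvature,
subject-level variability, distance-dependent connection probability
gradients, and diffusion-imaging artifacts.  Passing tests therefore show
that the pipeline's operators and statistics behave correctly on graphs
with the assumed structure, not that the anatomical conclusions transfer
to any particular empirical dataset.

## The sphere limit and the l = 3 split

On a jitter-free icosphere with kernel width 1 and no long-range
connections, the low graph-Laplacian eigenmodes are discrete spherical
harmonics.  The first 16 eigenvalues cluster into multiplicity blocks
1, 3, 5, 7 (degrees l = 0…3), recovered by cutting the spectrum at the
three largest gaps.  One caveat is exact and scale-invariant: the mesh has
icosahedral, not spherical, symmetry, and the 7-dimensional l = 3
rotation multiplet is reducible over the icosahedral group — it splits
into exactly degenerate 3- and 4-fold sub-levels ~13% apart at every
subdivision level.  The split stays below every between-block gap, so the
block structure is unambiguous; the l ≤ 2 multiplets are degenerate to
machine precision and their spans align with the analytic harmonics to a
few degrees of principal angle.

## Problem sizes

The reference experiments use 1284-vertex brains, 20,000 streamlines,
K ≤ 100 harmonics, and 100 surrogates per randomization scheme; these
sizes make the complete analysis reproducible in minutes on one CPU while
preserving every qualitative contrast the pipeline is designed to measure.
Unit and property tests use smaller fixtures (162–642 vertices, ≤ 2,000
tracks).

## Known limitations

* At this mesh resolution the proportion of local connections at z_C = 1
  is r ≈ 0.93 (the long-range graph holds ~800 binary edges).  Reaching
  the r ≈ 0.7 regime of a 20k-vertex cortex with 20 million streamlines
  would require either far more streamlines or a coarser local kernel;
  the directional experiments therefore operate in a sparser long-range
  regime than the full-scale analysis.
* In this sparse regime the MI of harmonics 7–11 with the map is *carried*
  by the planted long-range structure.  Length-ordered trimming of either
  order removes that support, so the trimming experiment does not
  reproduce the full-scale behavior in which removing the longest fibers
  first raises the MI toward the local-connectivity-dominated limit —
  that behavior presupposes a baseline MI *below* the local limit, i.e.
  long-range connections that net-suppress the alignment.  The trimming
  operator itself is fully exercised (exact counts, ordering, ties,
  nestedness); only this one directional contrast is out of reach of the
  synthetic regime, and the corresponding end-to-end test documents the
  measured values.
* The Monte-Carlo window statistic compares harmonics index-by-index and
  is sensitive to spectral reordering near degeneracies; results are
  reported at fixed seeds, and seed-to-seed variability of the synthetic
  geometry is visible mainly as variation in which harmonic indices carry
  the planted alignment.
* MI values depend on the binning convention (equal-width over the
  observed range, natural log); they are internally consistent across the
  pipeline but not directly comparable to MI computed with other
  conventions.
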