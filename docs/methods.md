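# Methods

This note documents the models behind `surfshape`, the parameters that
matter, what the synthetic benchmark does and does not emulate, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Surface meshes

All geometry lives on closed, consistently oriented triangle meshes with
coordinates in Å. Area is the sum of triangle areas; enclosed volume is the
divergence-theorem signed volume (orientation is repaired by one global face
flip when the signed volume is negative); the centroid is the area-weighted
mean of triangle centroids. Per-vertex normals average incident face normals
weighted by the interior angle at the vertex — on rough, bumpy surfaces this
is markedly more stable than unweighted or area-weighted averaging.
Non-manifold or open meshes are rejected with the boundary-edge count.
Cotangent weights of near-collinear triangles (marching-cubes output contains
them) are clamped to |cot| ≤ 1e6, standard finite-element practice.

PLY (ASCII and binary little-endian) and OFF are read through `trimesh` with
processing disabled, so vertex order and topology round-trip exactly; files
are written as ASCII with 9 significant digits, which round-trips
coordinates well below the 1e-6 Å contract (binary PLY would truncate to
float32). Non-geometry PLY properties (color, confidence) are ignored.

## Synthetic benchmark generator

The generator emulates the structure of NMR-derived surface benchmarks:
protein-level classes that split into species-level classes, one entry per
species whose conformers are near-identical copies, and sequences that are
nearly conserved within a class and unrelated across classes.

* **Pseudo-structures.** A protein analog is a connected cluster of
  `n_blobs` soft spheres (radii 1.4–2.6 Å, default 14 blobs) grown by
  sequential attachment. Its surface is the iso-level e⁻¹ of the Gaussian
  field Σᵢ exp(−‖x−cᵢ‖²/rᵢ²) triangulated by marching cubes (default grid
  48³ for benchmarks, 64³ elsewhere); at that level a single blob of radius
  r yields exactly the sphere of radius r. Satellite components (possible
  after strong deformation) are dropped in benchmark generation, since
  spectral descriptors require a connected surface.
* **Hierarchy.** Species differ from their class base by a smooth radial
  deformation: three random directional lobes g(x̂) = Σⱼ wⱼ (x̂·vⱼ)²,
  normalized to unit peak, displace atoms radially by up to
  `species_scale` Å (default 1.0). Conformers add isotropic atom jitter of
  `conformer_scale` Å (default 0.1). Each (protein, species) pair is one
  domain-level entry holding its conformers, mirroring how the conformers
  of one NMR entry share the lowest classification level.
* **Hinge classes.** A fraction of protein classes is built as two blob
  clusters joined by a three-atom linker. Conformers rotate the distal
  linker atom plus the second cluster about the axis through the middle
  linker atom, sweeping 130° evenly (≥ 120° by construction); rotating the
  distal linker atom with the cluster keeps every link distance constant,
  so the surface stays connected and the enclosed volume is preserved to
  about 1% across the sweep while pseudo-atom RMSD between extreme
  conformers exceeds 10 Å — the open/closed two-domain regime of
  calmodulin-like proteins.
* **Sequences.** Each class draws a uniform random sequence of length
  3·n_blobs (≥ 20); species mutate 10% of sites; conformers share their
  entry's sequence, as NMR models do. Within-class identity is then ≈ 0.8+
  and cross-class identity is that of unrelated random sequences.
* **Determinism.** One root seed; per-class child seeds come from
  `numpy.random.SeedSequence.spawn`, making the whole benchmark bitwise
  reproducible.

What the generator does *not* emulate: real solvent-excluded-surface
chemistry (probe-rolling cusps, cavities), secondary-structure-driven
surface texture, realistic NMR ensemble statistics, and homology between
classes. Passing tests therefore demonstrate correct and discriminative
machinery on globular, bumpy, hierarchically organized surfaces — not
performance on real SES meshes.

## Descriptors

**Spectral (shape_dna).** Cotangent-FEM stiffness S and lumped barycentric
mass M; the generalized problem S φ = λ M φ is solved by shift-invert ARPACK
at σ slightly below 0 with a fixed start vector (a dense LAPACK path serves
as test oracle). The signature is (λ₂…λ_k)·A (k = 50 by default, first
eigenvalue dropped); area normalization makes it scale-free, which is the
usual reading of "normalized eigenvalues" (division by λ₂ is available as
an option). On the subdivision-4 icosphere the first nonzero eigenvalues
match l(l+1) to a few tenths of a percent.

**3D Zernike (zernike3d).** Surface samples (area-weighted, 80 000 by
default) are deposited onto a `grid_n`³ grid (default 96) by trilinear
cloud-in-cell splatting; the weighted voxel centers are centered on the
*sample* center of mass and scaled so the farthest *sample* lies at radius
0.7 of the unit ball. Using sample statistics rather than voxel statistics
for the normalization matters: the farthest occupied voxel jitters by a
lattice cell between orientations, and since F_nl scales as r_maxⁿ a 1%
scale jitter corrupts order-20 terms by ~20%. With sample-based
normalization the rotation error of the full descriptor is ~0.1%.
Radial polynomials R_nl are built by exact rational Gram–Schmidt
orthonormalization of r^l, r^{l+2}, …, r^n under the unit-ball measure
r² dr (positive leading coefficient); each Z_nlm is expanded into Cartesian
monomials through the solid-harmonic Legendre series, so all moments reduce
to one vectorized geometric-moment pass. A direct per-point R_nl·Y_lm
integration oracle validates the expansion to 1e-9. Order 20 yields the
canonical 121 invariants; a solid (filled) voxelization is available behind
the `fill` flag.

**Viewpoint feature histogram (vfh).** The surface centroid acts as the
viewpoint. The original formulation's reference normal (mean normal of the
scan) has no closed-surface analog — the area-weighted mean of outward
normals is identically zero by the divergence theorem — so the Darboux
frame is anchored to the dominant principal axis of the area-weighted
vertex distribution, sign-fixed by positive skewness. Five blocks (cos α,
cos φ, θ, normalized centroid distance; 45 bins each; and the 128-bin
viewpoint cosine histogram) are each normalized to unit mass; vertices
contribute with their lumped area share so the histograms approximate
surface integrals independent of tessellation density. Rigid-motion
invariance is exact up to floating point.

**Panoramic projections (panorama).** The surface (60 000 area-weighted
samples) is projected onto cylinders around the three principal axes
(descending variance; signs fixed by positive skew; right-handed). The
depth map D(h, φ) (64 × 128) records, per cell, the cylinder radius
(2 × max radial extent) minus the outermost sample radius; the height range
covers the central 99% of the h-distribution so thin protrusions do not
stretch the map into empty rows. Bent surfaces are legitimately invisible
from much of the cylinder, so empty cells simply record depth 0 and only a
miss fraction above 90% aborts. Features per map: magnitudes of the lowest
16×16 DFT block (invariant to azimuthal rotation) and the 7 sub-band
energies of a 2-level Haar decomposition; 3 × 263 = 789 values. The
composite distance averages the length-normalized Manhattan and Canberra
distances with equal weight, the simplest symmetric combination of the two.

## Retrieval statistics

The query is always excluded from its own ranking; distance ties break by
original index. FT uses the first |C|−1 targets and ST the first 2|C|−1
(the literal second-tier window; 2(|C|−1) is available via a flag), both
with denominator |C|−1. MAP averages precision at the ranks of relevant
targets. PR curves use max-precision-at-recall ≥ r interpolation on a
20-point grid. Singleton classes are excluded with a warning. Top-k class
counts report the population SD. All statistics are validated against naive
enumeration oracles, exactly, and are invariant under monotone transforms
of the dissimilarities.

## Distant surficial homologs

Pairwise sequence identity comes from global Needleman–Wunsch alignment
(BLOSUM62, gap open 10, extend 0.5) with the gap-inclusive alignment-length
denominator (shorter-sequence and ungapped-column denominators are options,
since identity-ratio conventions differ between tools). Dissimilarity
matrices are min–max normalized over off-diagonal entries. For each method,
each query's best target is argmin_{j≠i}(H + M)[i, j]; a pair is a
consensus homolog when at least `min_methods` (default 2) methods propose
it, with reciprocal hits merged onto the unordered pair. No identity cutoff
is imposed; reports sort pairs by identity.

## lDDT

All heavy atoms shared between reference and model (by chain, residue
number, atom name) are scored; hydrogens can be included by flag; no
stereochemistry penalty is applied. Reference pairs are collected with a
k-d tree within the 15 Å inclusion radius, intra-residue pairs excluded,
and the score averages the conserved-distance fractions at 0.5/1/2/4 Å.
The implementation is exact against a double-loop oracle and rigid-motion
invariant to 1e-9. Published per-conformer values for the calmodulin
ensemble (PDB 1dmo) can be reproduced through the CLI with a user-supplied
file; coordinate data is not bundled.

## Experiment sizes and design choices

The package's experiments are desk-scale by design:

* *Retrieval experiment*: 5 × 4 × 5 = 100 surfaces with strong separation
  (species 1.0 Å ≫ conformer 0.1 Å) — small enough to run in minutes, large
  enough for 100-query statistics.
* *Conformer tracking*: one 30-conformer hinge class among 150 distractor
  surfaces (N = 180). The random-ranking expectation of same-class members
  in a top-30 window is k(|C|−1)/(N−1) ≈ 4.9; N was chosen as large as a
  few minutes of compute allows so that this baseline sits far below the
  class size, approximating the low-baseline regime of full-size benchmarks
  (where N is in the thousands and the baseline is ≪ 1).
* *Homolog consensus*: an 18-surface benchmark with one planted pair —
  two entries from different classes given identical meshes and unrelated
  sequences. Recovery requires every step (normalization, H + M argmin,
  multi-method consensus) to work; the planted pair's identity is that of
  random sequences (< 0.2) and its normalized shape distance is 0.
* Benchmark-scale descriptor parameters are reduced relative to the
  library defaults (spectrum k = 30; Zernike grid 64, order 12; 40 000
  projection samples) to match the coarser 48³ benchmark meshes.

## Known limitations

* The PANORAMA variant implements one depth map per axis with DFT + Haar
  features; the published method's second (normal-deviation) map type is
  not implemented.
* Near-spherical shapes have degenerate principal axes; the lexicographic
  tie-break keeps results deterministic but axis-dependent features are
  then uninformative (a warning is logged).
* The metaball surface is smoother than a real solvent-excluded surface at
  probe-cusp features; descriptor rankings on real SES meshes may differ.
* `pairwise_sequence_identity` is O(N²) alignments; for benchmarks beyond a
  few hundred entries this becomes the dominant cost.
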