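# Methods

This note records the models, conventions and numerical choices behind
`pantherin`, in the order the pipeline applies them, together with what
the synthetic-data generators do and do not emulate.

## Generalized Procrustes superimposition

Configurations of k ≥ 3 homologous 2-D landmarks are centred, scaled to
unit centroid size (the square root of summed squared distances from the
centroid) and iteratively rotated onto the running consensus until the
consensus moves by less than `tol` (default 1e-10, cap 100 iterations;
convergence is typically reached in well under 10). Rotations are
restricted to det +1: anatomical lateral views have fixed handedness, so
reflections are never allowed. The consensus is the arithmetic mean of
the aligned configurations. Orientation is fixed for identifiability by
rotating the whole solution so the consensus optimally matches the first
specimen's centred, scaled configuration; the choice is arbitrary and
affects no distance, score magnitude or downstream statistic.

The analysis works in the linearised (tangent) space at the consensus —
the standard small-variation assumption. No explicit
stereographic/orthogonal projection is applied to the aligned
coordinates; instead all score bases are constructed inside the tangent
space (below), which is equivalent for the quantities reported.

## Thin-plate spline and bending energy

The interpolating map between two configurations is the 2-D thin-plate
spline with kernel U(r) = r² log r² (the fundamental solution of the
biharmonic equation; U(0) := 0, the limit value). Weights and affine
coefficients come from the bordered kernel system; the side conditions
Σwᵢ = 0 and Σwᵢ Pᵢ = 0 hold by construction, making the map exact at
the landmarks and minimal in bending energy among all interpolants.
Collinear references make the system singular and are rejected with a
suggestion to jitter or re-examine the landmark scheme.

Bending energy is the integral over the plane of the squared second
derivatives, summed over the x and y component maps. For this kernel
the integral has the closed form **16π · trace(WᵀKW)**: Δ²U = 16π δ for
U = r² log r², so integrating by parts under the side conditions
collapses the integral to the kernel quadratic form. The constant is
verified in the test suite against midpoint-rule numerical integration
of the analytic second derivatives over a half-width-60 square (relative
error ≲ 0.5%; the integrand decays as r⁻⁴ thanks to the side
conditions, so the truncated domain suffices for a 1% check). Affine
maps have exactly zero weights and therefore zero bending energy.

## Partial and relative warps

The bending-energy matrix of the consensus is the upper-left k×k block
of the inverse bordered kernel matrix — positive semi-definite with a
3-dimensional null space (the affine functions 1, x, y). Its
eigenvectors with nonzero eigenvalue are the principal warps; each
specimen's deviation from the consensus projects onto them separately in
x and y, giving 2(k−3) partial-warp scores (interleaved x, y per warp,
as the classic tools order them).

The uniform (affine) component is computed by the *complement* method:
an orthonormal basis of the orthogonal complement of the non-uniform
subspace within the tangent space, i.e. orthogonal to the four
similarity directions (two translations, scale, rotation at the
consensus) and to every principal-warp direction. This leaves exactly
two dimensions; the pair spans the same subspace as any other uniform
parameterisation, though individual axes need not coincide with a
particular tool's "uniform X/Y". Because all 2k−4 basis vectors are
orthonormal, partial + uniform scores conserve the tangent-space sum of
squares exactly (a Parseval identity asserted to 1e-9 in the tests).

Relative warps at α = 0 (the default and the only exponent used in the
shipped analyses) are the principal components of the covariance matrix
of the stacked scores; the uniform pair is included by default and can
be excluded with a flag, since published analyses differ on this point.
Nonzero α re-weights partial-warp pairs by λ^(−α/2) before the PCA.
Eigenvalues are clipped at zero against round-off and sorted descending;
components follow the sign convention "first nonzero loading positive",
making results reproducible across LAPACK builds.

## Maximum parsimony

Characters are unordered multistate (symbols 0–9) with equal weight —
the default treatment for morphological matrices when no ordering is
published. `?` is treated by Fitch optimisation as the full state set,
and is excluded from the observed-state counts used by the ensemble
indices (the usual PAUP-style convention).

* **Fitch length** is computed with state-set bitmasks vectorised over
  characters; degree-2 roots are suppressed so rooted and unrooted
  inputs score identically. Multifurcating nodes are scored by
  sequential pairwise combination (equivalent to scoring an arbitrary
  binary resolution).
* **Exact search** is a branch-and-bound over taxon-addition order with
  the greedy-addition length as the initial bound, pruning partial trees
  strictly longer than the incumbent (adding taxa never shortens a
  tree). It returns *every* most-parsimonious tree, deduplicated by
  canonical bipartition sets. It is the default up to 12 taxa.
* **Heuristic search** runs 10 random-addition sequences, each followed
  by SPR hill-climbing that keeps all equally best trees and explores
  the equal-length plateau breadth-first (capped at 200 trees). All
  randomness flows from a single integer seed through a dedicated
  substream, so runs are exactly reproducible.
* **Ensemble indices**: mᵢ = observed states − 1, gᵢ = scored taxa −
  modal state count; CI = Σmᵢ/L, HI = 1 − CI (exact), RI = (Σg − L)/(Σg
  − Σm) over parsimony-informative characters only (characters with gᵢ =
  mᵢ contribute nothing to retention and are excluded from the RI sums),
  RC = CI·RI (exact). Uninformative characters are included in CI by
  default; `informative_only=True` gives the stricter convention, since
  published matrices do not always say which was used. A tree of length
  0 has no defined CI and is reported as an explicit error.
* **Strict consensus** intersects bipartition sets and rebuilds the
  (possibly multifurcating) tree displaying exactly the shared splits.
* **Bootstrap** resamples characters with replacement, searches each
  replicate heuristically (2 random-addition starts — a standard
  speed/thoroughness compromise for replicates), takes the replicate's
  strict consensus and counts split frequencies; support is the
  percentage of replicates displaying the clade.

## Distance trees

Distances between per-specimen or per-group-mean score vectors are
Euclidean or squared Euclidean. Group aggregation uses the mean score
vector (median available), since per-specimen trees are rarely the
published object. UPGMA merges the pair of clusters with minimal
average linkage; node height is half the merge distance, so the output
is ultrametric by construction. Ties are broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its alphabetically first member), making the tree deterministic under
label permutation of the input matrix.

UPGMA roots by ultrametricity, not by an outgroup; an outgroup serves
only as a polarity check. `outgroup_orient` therefore never re-roots:
it reports whether the designated outgroup is exactly one child clade of
the root (monophyletic-basal) and otherwise names the smallest clade
containing it.

## Traditional morphometrics

Ratios are plain quotients of positive measurements; rounding (half-up,
3 decimals for fractions, 1 for percent) happens only at the reporting
layer, never inside computations. Range comparisons use closed
intervals, with a "lower range" qualifier for values below the interval
midpoint. Size adjustment for PCA is either per-variable division by
condylobasal length (the default, mirroring how craniodental proportions
are conventionally reported) or Mosimann log-shape residuals; both feed
a covariance-matrix PCA. Incomplete specimens are dropped case-wise and
recorded.

Discriminant classification assigns a specimen to the group with the
nearest centroid in Mahalanobis distance under the pooled within-group
covariance. When any group has fewer members than variables + 2 the
pooled matrix is shrunk toward its diagonal, S* = (1−γ)S + γ·diag(S)
with γ = 0.25 by default (enough to stabilise inversion without
overwhelming the covariance structure at these sample sizes; settable).
Jackknifed accuracy repeats the *entire* fit — centroids and covariance
— with each specimen withheld. Classical stepwise variable selection is
replaced by an optional, deterministic greedy forward selection on
Wilks' lambda (F-to-enter threshold 0.05, ties to the earlier column),
off by default: automatic selection can overfit small samples, so the
caller must ask for it.

## Biomechanics

The bite-force model returns relative (dimension mm²) force outputs:
temporalis = sqrt(((ZW − (BW+POW)/2)/2)·TFL)·MAT and masseter =
sqrt(((CFL+MSW)/2)·MSL)·MAM, summed per side and doubled. ZW below
(BW+POW)/2 would put a negative number under the root and is rejected as
an inconsistent measurement set. The model is monotone in every input
and scales as length².

Body mass is predicted by OLS of log10(mass) on log10(CBL) over species
means; specimen tables are averaged within species *after* log
transformation (geometric means — the natural choice on the regression's
own scale). Back-transformation is direct (10^ŷ) with no bias
correction by default, matching how such predictions are conventionally
quoted; Duan's smearing estimator is available behind a flag.

## Synthetic data

The generators emulate the statistical *structure* the analyses assume,
not felid anatomy:

* **Landmarks**: group mean shape + i.i.d. isotropic Gaussian noise
  (default sd 0.01 on unit-scale shapes, the magnitude of digitizing +
  individual variation relative to skull size), then a random similarity
  transform (rotation uniform on the circle, scale in [0.5, 2],
  translation in [−10, 10]) that Procrustes must remove.
* **Characters**: binary characters each marking the clade below one
  internal edge of a known generating tree; with probability
  `homoplasy_rate` one outside taxon convergently acquires the derived
  state, adding exactly one extra step. `ensure_coverage` cycles the
  first characters over all internal edges so every edge is marked at
  least twice — the regime in which the generating topology is provably
  the unique MPT. The simulator is deliberately binary; multistate
  handling in the engine is tested with hand-built fixtures.
* **Measurements**: per specimen, a shared lognormal size factor
  (sd 0.1 on the log scale, i.e. ~10% body-size variation) times
  per-variable lognormal noise (cv 0.05, typical craniodental
  measurement scatter), guaranteeing positivity.

Each generator draws from its own named substream of the single seed, so
outputs are bit-reproducible and mutually independent. Passing tests on
these data demonstrates that the algorithms recover known structure
under their own assumptions (isotropy, tree-compatible characters,
lognormal allometry); they do not show robustness to correlated landmark
noise, character-state ordering, missing-data patterns or measurement
error structure in real museum samples.

## Problem sizes and verification

The exhaustive oracles that validate the parsimony engine run at sizes
where exhaustion is tractable and still discriminating: Fitch lengths
are checked against brute-force minimization over all internal-state
assignments on random 8-taxon trees, and branch-and-bound MPT sets
against Fitch-scoring all 135,135 nine-taxon topologies (vectorised over
trees). Bending energy is verified against numerical integration on a
5-landmark case; UPGMA against independent average-linkage clustering;
relative warps against a direct PCA of the score matrix. Bootstrap
demonstrations use ~100 replicates on 6–8 taxa; the engine accepts the
conventional 1000.

## Known limitations

* 2-D landmarks only; no sliding semilandmarks.
* Parsimony is unordered/equal-weights Fitch; no Sankoff step matrices,
  and search is tuned for ≤ ~25 taxa.
* The uniform-component axes are basis-dependent (the spanned subspace,
  and hence all PCA results, are not).
* Published tree statistics and the published body-mass prediction
  depend on supplementary data tables that are not redistributed here;
  the corresponding tests activate only when those files are supplied
  under `data/supplementary/`.
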