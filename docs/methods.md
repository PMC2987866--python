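# Methods

This note documents the models, conventions and numerical choices behind
wingmorph, in the order the pipeline runs.

## Landmark data model

A configuration is an ordered set of k ≥ 3 two-dimensional landmarks in
pixel coordinates; landmark i is assumed operationally homologous across
specimens (positional homology), and missing landmarks are not supported.
The digitizer's coordinate convention is preserved as-is: superimposition
removes position, scale and orientation, so no axis flipping or origin
normalization is ever applied. An optional scale factor (length per pixel)
makes centroid sizes comparable across imaging devices; its absence is a
validation warning, not an error, because shape analysis itself is
scale-free.

Each configuration carries a unique `specimen_id` plus an `individual_id`
that defaults to it. Replicated digitizations of one individual keep
distinct specimen ids (preserving the dataset uniqueness invariant) while
sharing the individual id, which is what the repeatability ANOVA groups on.

TPS parsing is deliberately liberal (upper/lower-case `LM=`, CRLF or LF,
comma or whitespace separators) because files in the wild vary; writing
uses 17 significant digits so read–write round-trips are bit-exact.

## Superimposition

2-D configurations are handled as complex k-vectors: rotation is a unit
complex multiplication and the optimal rotation aligning centered shapes
zₘ onto z_t is the phase of ⟨zₘ, z_t⟩, giving closed-form pairwise fits
with no iteration. Reflections are excluded by construction (determinant +1
always): wings are digitized on one side, and a reflection-tolerant fit
would silently mask left/right digitization mistakes.

GPA iterates: rotate every unit preshape to the current consensus, replace
the consensus by the renormalized mean, stop when the consensus changes by
less than 1e-10 (Frobenius) or after 100 iterations (then flagged
unconverged rather than raising; realistic datasets converge in ~3–6
iterations). Because the normalized mean is the constrained optimum of the
summed squared deviations, the objective trace is provably nonincreasing.
Every specimen is fixed at unit centroid size (partial-Procrustes
convention) — the simplest convention with a clean size/shape separation;
`scale="full"` applies the least-squares optimal per-specimen scale
instead.

Two details make the result well-defined rather than merely
well-defined-up-to-rotation:

* **Canonical consensus orientation.** The consensus is rotated so its
  principal axis (from the second complex moment Σz²) lies along x, with a
  deterministic sign rule. Being intrinsic to the shape, this makes the GPA
  output invariant both to input order and to similarity transforms of any
  input specimen — two invariants that an "anchor on the first specimen"
  convention cannot satisfy simultaneously.
* **Permutation-invariant initialization.** The starting consensus is the
  renormalized mean of canonically oriented preshapes, so reordering the
  input changes nothing beyond floating-point summation order.

Tangent coordinates are the orthogonal projection of aligned preshapes at
the consensus pole, v = x − (x·c)c (stereographic projection is not
offered). Distances: partial = 2 sin(ρ/2), full = sin ρ, geodesic = ρ,
with cos ρ = |⟨ẑₐ, ẑ_b⟩|. Cosines within 1e-15 of 1 are snapped to 1;
otherwise √(2−2cos ρ) would amplify last-bit rounding on identical shapes
into ~1e-8 of spurious distance. The default variant everywhere is
partial, the tangent-space-compatible choice.

## Shape variables

The thin-plate-spline bending-energy matrix is the upper k×k block of the
inverse bordered system built from U(r) = r² log r² and the affine border
[1 | x | y]; it has exactly three zero eigenvalues (the affine null space)
for any non-collinear reference, and the k−3 positive-eigenvalue
eigenvectors are the principal warps. The reference is always the current
GPA consensus.

Partial-warp scores project each specimen's tangent residual onto every
principal warp in x and y, plus two uniform (affine) scores. No
bending-energy weighting is applied (weight exponent α = 0), so the full
score basis is orthonormal and partial-warp space is an exact isometric
rotation of tangent space — consequently classification is identical
whether run on partial warps, full-rank relative warps, or raw tangent
coordinates, and the choice of basis can never change an assignment.

The uniform component is built deterministically from the two
non-similarity affine generators applied to the consensus — pure stretch
diag(1, −1) and pure shear — Gram-Schmidted against the scale and rotation
directions. Affine deformations have zero bending energy, so these vectors
are automatically orthogonal to every principal warp and span the uniform
subspace exactly. (A generic null-space computation would span the same
subspace but with an arbitrary basis that rotates discontinuously under
infinitesimal input changes, making per-variable statistics such as
repeatability irreproducible across equivalent superimpositions.)

Relative warps are the principal components of partial-warp scores —
unstandardized, unweighted — taken about the tangent-space origin (the
consensus) rather than the sample mean, so the consensus maps to zero
scores in either representation; after GPA the two centers agree to high
order, making this numerically indistinguishable from covariance PCA.

Shape variables are consensus-dependent: adding one specimen changes every
score. Score objects therefore record a hash of their consensus, and any
attempt to combine scores from different superimpositions raises.

## Classification

**Procrustes classification** assigns each unknown to the species at the
shortest Procrustes distance, either to the species consensus
(`nearest_consensus`, default) or to the closest reference individual
(`nearest_individual`); both distance sets are always reported. Group
dispersion is ignored by design — that is the method's known limitation.

**Mahalanobis classification** fits a canonical variate analysis on
reference shape variables: pooled within-group covariance S_w (divisor
n − g), between-group scatter, generalized eigenvectors for up to g − 1
canonical axes, distances via a cached Cholesky factorization of S_w.
Dimension control: by default the fewest relative-warp axes explaining 95%
of variance, capped at n − g − 1 so S_w stays invertible; an explicit
`retain` (count or fraction) and a ridge term (ridge · tr(S_w)/m on the
diagonal) are available, and a singular S_w raises rather than being
silently pseudo-inverted.

The **one-by-one protocol** is mandatory for Mahalanobis identification:
each unknown separately joins the references for one GPA, shape variables
are computed relative to that joint consensus, the discriminant model is
fitted on the reference rows exclusively, and the unknown is projected in
as supplementary data. Entering many unknowns at once would shift the
consensus toward the unknowns and degrade the discrimination among
references; batch processing is therefore not implemented (each unknown's
assignment is provably independent of the order and composition of the
unknown set).

Assignment always takes the shortest distance; exact ties (within 1e-9
relative) break to the lexicographically first species label and are
flagged. Each record also carries an **outlier flag**, raised when the
unknown's distance to the winning group exceeds the 95th percentile of
that group's own member-to-center distances — a concrete version of the
discrimination-vs-identification caveat: the nearest group may still be
far. The flag is conservative in high retained dimension, where an
external specimen's Mahalanobis distance is systematically larger than a
training member's; with the default 95%-variance retention expect it to
fire on a substantial fraction of genuine members, and prefer a modest
explicit `retain` when the flag matters.

Error tables report per-species and total `misassigned/total (percent)`
cells with integer-rounded percentages. Validation uses leave-one-out:
each reference is removed in turn and classified by the full protocol
against the rest (species with a single specimen are excluded with a
warning). Output is labeled with the validation design used. LOO can also
run with `query_replicates`: the held-out individual then enters as an
independent re-digitization of itself (matched by individual id), which is
the design for measuring how a second user's digitization degrades
identification against a single-user reference bank.

## Measurement error and the user effect

Repeatability per variable comes from a one-way ANOVA with individuals as
groups: s²_among = (MS_among − MS_within)/n₀ with the standard unbalanced
coefficient n₀ = (N − Σnᵢ²/N)/(a − 1) (equal to the replicate count r when
balanced); R = s²_among/(s²_among + MS_within), with negative variance
estimates truncated at zero so R ∈ [0, 1]. Under the null (no true
individual differences) the truncated estimator is biased upward by
O(1/√n) — about +0.04 at 100 individuals × 2 replicates — which the tests
account for by averaging over seeds. Variables default to the partial-warp
scores of one joint GPA over all digitizations (the space classification
operates in); raw aligned coordinates are an option. Summaries are
mean ± SD across variables.

The user comparison computes each user's own-replicate R and the pooled R
with both users' digitizations treated as replicates; the difference
(one-user minus two-user) is the repeatability cost of the user effect.
The session-scatter diagnostic compares all pairwise Procrustes distances
measured in two sessions; the RMS perpendicular deviation from the
identity line, √(mean((d₁−d₂)²)/2), measures how digitization error
amplifies in the distances that classification ultimately uses.

## Synthetic data generator

The generator emulates a multi-species digitization study with known
ground truth, and its defaults are the study conditions the tests run at:

* **Template**: a fixed, documented 11-landmark stylized wing (asymmetric,
  non-collinear) at unit centroid size; regular polygons for generic k.
* **Species means**: the template moved along random tangent directions by
  the geodesic angle 2 arcsin(separation/2), so each mean's partial
  Procrustes distance from the template equals `separation` exactly;
  realized pairwise distances between means are recorded as ground truth.
* **Specimens**: mean + isotropic Gaussian coordinate noise (SD
  `sigma_shape`, default 0.01 on the unit-size mean), then a random
  similarity transform (uniform rotation, log-scale ±0.2, bounded
  translation) emulating arbitrary digitizing frames. Noise is applied
  before the transform because pointing happens in image space.
* **Digitization error**: per user, one persistent offset vector per
  landmark (SD `delta_persistent`) plus fresh pointing noise per
  digitization (SD `sigma_point`), both scaled by the specimen's centroid
  size since pointing error is proportional to rendered size. Defaults
  `sigma_point = 0.005` and `delta_persistent = 0.01` (= 2σ_point) give a
  one-user repeatability near 0.8 — the level reported for real insect
  wing data — via the 4:1 variance ratio with the default `sigma_shape`.
* **Study designs**: replicated sessions for the ANOVA; a two-user
  repeatability study (both users digitize everything twice); and the
  reference-bank exchange design — references digitized by user 1, query
  re-digitizations by user 1 (one-user) or user 2 (two-user), the latter
  sharing the same pointing-noise realization plus the persistent offset so
  the one-/two-user comparison is paired. Species separation 0.05 in that
  scenario puts the one-user identification error at the few-percent level
  published two-species wing studies report.
* **Overlap oracle**: for overlapping species the expected error is
  estimated by a Monte-Carlo Bayes classifier (10⁵ draws) on the planted
  tangent-space model — two isotropic Gaussians at the recorded realized
  mean separation — since no closed form survives the superimposition
  pipeline. Observed leave-one-out error sits slightly above the Bayes
  error because the discriminant model is estimated from finite references.

Everything is driven by explicit seeds; equal seeds give byte-identical
TPS output.

## What the synthetic tests do and do not show

The generator's noise is isotropic and Gaussian, offsets are random across
landmarks, and within-species covariance is spherical. Real digitization
error concentrates on hard landmarks, real within-species variation is
anisotropic (and partly allometric), and mounting/photography error is not
modeled at all. Passing tests therefore demonstrate the correctness of the
algorithms and the qualitative direction of the user effect, not the error
rates to expect on any particular real dataset. Allometry removal,
semilandmarks, outline methods and 3-D data are out of scope.

## Numerical summary

| Quantity | Choice |
| --- | --- |
| GPA tolerance / max iterations | 1e-10 Frobenius on consensus / 100 |
| Distance variant default | partial Procrustes |
| Cosine snap for identical shapes | 1 − 1e-15 |
| Bending zero-eigenvalue test | 1e-9 relative |
| CVA retention default | 95% variance, capped at n − g − 1 |
| Singular S_w condition bound | 1e12 |
| Tie tolerance / outlier percentile | 1e-9 relative / 95th |
| Negative variance components | truncated to 0 |
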