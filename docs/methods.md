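# Methods

This note documents the models, numerical conventions and design choices
behind each stage of the pipeline, and what the synthetic-data generator
does and does not emulate.

## Procrustes superimposition

Configurations of k = 21 landmarks (k ≥ 3 supported) are centred, scaled
to unit centroid size and iteratively rotated onto a consensus by the
SVD-based least-squares rotation. Fitting is *partial* Procrustes: unit
size is fixed once and never re-optimised during rotation, and
reflections are disallowed (determinant forced to +1) because all
specimens are same-side lateral views. The consensus is the
coordinate-wise mean re-normalised to unit size; iteration stops when it
moves by less than 1e-10 (root summed squared coordinate change), with a
100-iteration cap — in practice 3–5 iterations suffice. Because a GPA
solution is unique only up to a global rotation, the final solution is
rotated to a canonical orientation (consensus principal axes aligned
with the coordinate axes, signs fixed by the largest-|x| landmark); this
makes output invariant to input order, which the tests check to 1e-7.

## Partial warps and the uniform component

The thin-plate-spline kernel U(r) = r² log r² over the consensus
landmarks gives the bending-energy matrix (upper-left block of the
inverted TPS system). Its eigenvectors with positive eigenvalue — the
principal warps, k − 3 of them in 2-D — applied separately to x and y,
plus two uniform directions, form the shape-variable basis. The uniform
directions are computed by the complement method: the part of the
6-dimensional affine subspace orthogonal to translation, rotation and
scaling at the consensus. We use the orthonormal (α = 0) weighting, so
the W′ score matrix (2k − 4 = 38 columns) is an isometric rotation of
Procrustes residual space: per-specimen squared score norms equal
squared residual norms, and any ordination of W′ equals the same
ordination of the residuals. The identity is exact only up to the
residuals' out-of-tangent component, which is O(‖r‖²) (the aligned
specimens sit on the unit sphere, not in the tangent plane); at the
within-species deviations used here (‖r‖ ≈ 0.02–0.08) the discrepancy is
≤ 1e-6 and irrelevant to any downstream result. Whether the uniform
component belongs in W′ is a long-standing convention difference between
software families; both choices are rotations of the same space, we
include it by default and expose `include_uniform=False`.

## Canonical variate analysis

CVA solves the between/within generalized eigenproblem with the pooled
within-group covariance (divisor n − g). Because shape variables are
usually more numerous than residual degrees of freedom, features are
first projected onto their pooled principal components, keeping
components with eigenvalue > 1e-10 **and at most n − g of them** — the
cap is what actually guarantees a nonsingular within-group matrix when
n − g is the binding constraint. Axes are scaled to unit pooled
within-group variance; Mahalanobis distances between group means are
computed in the full within-group metric rather than the retained
canonical axes. Assignment (and leave-one-out cross-validation) uses the
minimum Mahalanobis distance with uniform priors; the leave-one-out loop
refits the discriminant but not the superimposition, whose per-fold
change is negligible. The pairwise permutation test permutes labels
within each species pair and uses p = (1 + #{perm ≥ obs}) / (n_perm + 1).

## Classification tree

The meristic key is grown by greedy binary Gini partitioning over the
six ordinal counts, evaluating every midpoint between consecutive
observed values. Ties in impurity decrease are broken by predictor order
(NSLL, NSALL, NSULL, NRDF, NRPF, NRAF) then lower threshold, so trees
are fully deterministic. Stopping defaults are min_parent = 10,
min_child = 5, max_depth = 5: common statistical-package defaults
(100/50) cannot produce a four-leaf tree from a 145-specimen sample, so
smaller limits are the usable regime at this scale. Validation is
stratified 10-fold cross-validation with a fixed seed (fold count drops
to the smallest class size when needed); leave-one-out is available.
Ties at a threshold descend left (x ≤ t).

## Molecular summaries

A column is variable when it shows ≥ 2 distinct bases among {A,C,G,T};
variation involving only N is ignored, and a gapped column with a single
base is not variable while one with two bases is, regardless of gaps —
the right convention for coding genes without indels. Pairwise identity
and p-distance exclude positions where either sequence has a gap or N.
Distance matrices default to the uncorrected p-distance, averaged
without weights when two markers share a roster (the combination rule is
pluggable, as are JC69 and K2P corrections; the choice is recorded in
`metric_tag`). Diagnostic differences between two taxa are columns fixed
for different bases in each, classified as transition or transversion,
plus maximal runs of columns gapped in every member of one taxon and
occupied in the other. Band-length attribution uses configurable
intervals defaulting to the genus-diagnostic Cyfun P bands (~310 bp,
~410 bp, ~440 bp, ±15 bp); the intermediate band identifies genus
*Squalius* only. Because a single "similarity" figure for a group is
ambiguous, summaries report mean, min and max over pairs. Global
alignment (for unaligned inputs) is Needleman–Wunsch with match +1,
mismatch −1, gap open −5, extend −1.

PCOA Gower-centres −½D², eigendecomposes, and scales eigenvectors by the
square roots of the positive eigenvalues; Lingoes and Cailliez
corrections are available for non-Euclidean input and skipped with a log
notice when unnecessary. Axis signs are fixed so each axis's
largest-magnitude loading is positive. Exactly two axes feed the
integration stage.

## Two-block PLS

The integration model is the SVD of the between-block covariance
(divisor n − 1) of the centred shape block (W′) against the centred
genetic block (2 PCOA axes) — covariance, not correlation, matching the
convention of the morphometric PLS tools; a correlation mode exists.
Latent pairs are ordered by singular value; each pair's R is the Pearson
correlation of its paired scores, the first pair additionally gets a
linear-fit R² (= R₁²) and a Spearman ρ for the monotonic-trend reading.
Signs are fixed so each pair correlates positively. The permutation test
permutes rows of the genetic block (one-sided, upper tail, default
n_perm = 999); for n ≤ 7 all n! permutations are enumerated. P-values
are reported per pair without multiplicity correction. The group report
computes latent-space centroids, between/within spread ratios per axis,
and flags specimens whose genetic latent-1 score falls on the opposite
half-plane from their group's majority — the signature of a specimen
whose genotype contradicts its morphological identity.

## Synthetic data generator

The generator emulates a four-species sympatric sample with default
group sizes (65, 26, 27, 27):

* **Landmarks** — species mean shapes (four hand-designed 21-landmark
  fish outlines differing in body depth, dorsal-fin position, eye height
  and caudal-peduncle height; versioned TPS fixture) plus isotropic
  Gaussian landmark noise, then arbitrary rotation/translation/scale.
  Pairwise Procrustes distances between the mean shapes span
  0.024–0.059 (mean ≈ 0.039). The default noise sd (0.004 per
  coordinate, unit-centroid-size scale; doubled for the *S. lucumonis*-
  like species, whose within-group spread is twice the others') was
  calibrated so the default conditions land in the low-90s
  leave-one-out accuracy regime of the real study sample, and is then
  fixed.
* **Meristics** — counts drawn uniformly from species-specific integer
  intervals, designed so NSLL separates coarsely and NRAF/NRPF refine,
  with deliberate overlap so the cross-validated key accuracy sits near
  0.9 rather than 1.
* **Sequences** — site-independent, equal-rate substitutions down a
  fixed little tree: a shared ancestor, a clade ancestor for the two
  congeners (so their sequences are mutually closest), then species tip
  branches; within-species variants arise at 1/20 the tip rate. Cyfun P
  additionally carries species-specific deletion blocks, including a
  17 bp terminal deletion in the *S. lucumonis*-like species, giving
  genus-diagnostic band lengths.
* **Integrated datasets** — species mean shapes are an isometric
  embedding of the species' genetic PCOA centroids into shape tangent
  space (offsets scaled to 0.04 rms Procrustes magnitude), so
  between-species shape offsets are proportional to genetic distances
  by construction. Shape noise is then set analytically from the target
  first-pair correlation: with between-centroid top eigenvalue λ₁,
  within-species genetic variance w₁ along that axis and embedding
  scale c, R = cλ₁ / √((c²λ₁ + σ²)(λ₁ + w₁)), solved for σ. Targets
  above the attainable bound √(λ₁/(λ₁ + w₁)) raise an error that
  reports the bound. An optional planted outlier swaps one specimen's
  sequences for a within-species variant of another species' haplotype.

What the generator does **not** emulate: allometry (no size–shape
correlation), landmark digitisation error structure (noise is isotropic
and homoscedastic), coalescent genealogies or recombination (haplotype
counts on simulated individuals exceed real ones), rate heterogeneity
and transition bias, realistic indel evolution. Passing tests therefore
demonstrate that the estimators recover planted structure of realistic
magnitude, not that real specimens would behave identically.

The synthetic reference haplotype sets in `synthetic_references.py` are
fixtures, not simulations: frozen deterministic constructions that plant
the reported summary structure of the study's deposited sequences
(variable-site counts, haplotype counts, the three Squalius diagnostics
and 17 bp deletion, intra-species identities and band lengths) so the
summary-statistics code can be exercised against exact known truth. No
sequence in them matches any deposited accession. One arithmetic note:
24 variable sites out of 840 is 2.857%, which standard rounding reports
as 2.9%.

## Problem sizes and determinism

Statistical checks run at the sizes they describe: 20 replicate datasets
for the cross-validated accuracies, 50 for first-pair R recovery, 100
for outlier flagging, 500 null replicates (n_perm = 99) for the
permutation-calibration checks. Every stochastic routine takes an
explicit seed; identical (parameters, seed) reproduce serialized
datasets byte-for-byte.

## Known limitations

* CVA axes and assignments are undefined when a class has a single
  member; the code refuses rather than guesses.
* The half-plane outlier flag assumes the first genetic latent axis
  separates the relevant groups; for groups straddling the axis no flag
  is raised.
* The integrated generator calibrates noise against the realized
  genetic ordination of its own sequences, so `analytic_r` is exact for
  the constructed means but the fitted R at finite n varies around it
  (±0.02 at n = 145).
* TPS grid warping is a minimal numerical implementation intended for
  checking interpolation properties and coarse visualisation, not
  publication-quality deformation-grid rendering.
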