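# Methods

This note documents the statistical models behind vestmorph, the
conventions and defaults the package commits to, what the synthetic-data
generator does and does not emulate, and the numerical choices that a
user comparing results against other software should know about.

## The Brownian covariance and its λ transform

Every phylogenetic computation consumes a rooted, time-calibrated tree
with branch lengths in Ma.  Under Brownian motion (BM) with rate σ², a
trait's tip values are jointly Gaussian with covariance σ²·C, where
`C[i, j]` is the depth (root-path length) of the most recent common
ancestor of tips i and j and `C[i, i]` the depth of tip i.  The package
computes C from patristic distances, `C[i, j] = (dᵢ + dⱼ − dist(i, j))/2`,
which is exact for any rooted tree, ultrametric or not — fossil tips
attached with positive tip ages simply end above the present.

Pagel's λ rescales the off-diagonal of C and leaves the diagonal alone.
On the tree side this is equivalent to multiplying internal branches by λ
and stretching pendant branches to preserve tip depths; the simulator
uses exactly that construction so that simulated data and the covariance
algebra agree by definition.  λ is restricted to [0, 1]: 0 is a star
phylogeny, 1 full BM structure.  (Some implementations search λ slightly
above 1 up to the largest value keeping C positive definite; this package
deliberately stops at 1, the interpretable range.)

Branch lengths are mandatory in input Newick — a missing length raises
rather than silently defaulting — because a silent unit-length default
would change every covariance downstream.  A `unit_lengths` flag exists
for constructing toy topologies in tests.

### The reference chronogram

`datasets.anthropoid_tree()` ships a 27-species, 4-clade anthropoid
phylogeny (3 platyrrhines, 16 cercopithecoids, 3 hylobatids, 5 hominids)
with the per-species specimen counts of the reference design (142
individuals).  The topology follows the consensus molecular phylogeny of
these species; node ages are nominal literature-informed values (root at
41 Ma, catarrhine crown 30 Ma, hominoid crown 20 Ma, *Pan–Homo* 7 Ma, …).
It is a fixture for simulation and testing, not a citable chronogram.
`add_reference_fossils` grafts an *Oreopithecus* lineage on the hominoid
stem at 21 Ma (tip 6.75 Ma, the midpoint of its 7.0–6.5 Ma last
occurrence) and an *Australopithecus* tip as sister to *Homo* (tip at the
4.02 Ma first-appearance datum; the 5.0 Ma stem age is nominal, as no
published estimate pins it).

## Generalized Procrustes analysis

GPA centres each k×3 configuration at the origin, optionally scales to
unit centroid size (the package's scale convention), optionally mirrors
right-side specimens by negating x, and then iteratively rotates every
configuration to the running consensus using the Kabsch solution with a
determinant correction so reflections are never introduced.  Iteration
stops when the consensus moves less than 1e-8 RMS or after 100 rounds;
a final pass re-aligns all configurations to the converged consensus so
the returned consensus is exactly their coordinate-wise mean.  Fixed
landmarks only: semilandmark sliding is out of scope, as is any surface
or diffeomorphic registration — deformation descriptors computed by such
pipelines enter the package as ready-made vectors with
`provenance="deformation"`.

## Between-group PCA

Group means are unweighted by group size and the grand mean is the mean
of group means (the textbook bgPCA; the reference design is near
balanced, so the choice is immaterial there but must be fixed).  The
eigendecomposition runs through an SVD of the g×p centred mean matrix,
giving at most g−1 informative axes; the default retains g−1 (three axes
for four clades).  Eigenvector signs follow the convention that each
axis's largest-magnitude loading is positive.

Leave-one-out classification holds the eigenbasis fixed and recomputes
only the left-out specimen's group centroid; assignment is by Euclidean
distance in the retained score space.  Refitting the basis per fold is
available (`refit=True`) but is not the default: with near-balanced
groups and descriptors far outnumbering groups, the basis is essentially
unchanged by one specimen and the fixed-basis variant matches
centroid-distance classification as usually reported.

Typicality probabilities use the pooled within-group covariance of scores
(summed centred cross-products over n − g, with optional ridge
ε·trace/m for near-singular cases) and the χ²(m) upper tail at the
squared Mahalanobis distance, m being the retained axes.  An F-based
small-sample variant (`method="f"`) uses
`F = d²(ν−m+1) / (νm(1+1/n_k))` with ν = n − g.  The χ² form is the
default; the two converge as group sizes grow.  Probabilities are
deliberately not normalized across groups: a specimen may be atypical of
every group, the expected outcome for a morphology outside the sampled
variation, and p < 0.05 is read as "outside that group's variability".

The hierarchical-clustering check uses Ward linkage on Euclidean
distances by default (configurable — published analyses often leave the
linkage unstated), cuts at g clusters, labels each cluster by its
majority group, and reports per-group recovery percentages.

## Phylogenetic signal

**Pagel's λ** maximises the MVN log-likelihood of tip values with mean
â·1 and covariance σ²·C(λ).  â and σ² have closed-form profiles
(â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹y, σ² = rᵀC⁻¹r/n), so the search is a bounded
scalar optimisation on [0, 1] (tolerance 1e-6) with both endpoints
evaluated explicitly, making boundary optima exact.  Significance is a
likelihood-ratio test against λ = 0 on 1 df.  Cross-checked against an
independent R implementation: interior optima agree to ~2e-5 and
log-likelihoods to 1e-5.

**Blomberg's K** is the observed ratio of raw to phylogenetically
whitened mean squares divided by its BM expectation (formula in the
README); **K_mult** replaces squares by squared Euclidean norms in trait
space, whitening the â-centred tip matrix with C^{-1/2} from the
eigendecomposition of C.  K_mult reduces to K exactly at p = 1.  Both are
tested by shuffling values across tips: p = (1 + #{K_perm ≥ K_obs}) /
(n_perm + 1), default 999 permutations, seed mandatory.  Fewer than 99
permutations are refused (p-resolution floor).

Signal statistics operate on one value (or vector) per tip — species
means of the specimen table, the conventional per-tip summary when the
tree has species as tips.

Small-sample behaviour worth knowing: at n = 27, λ̂ is precise near the
boundaries (mean absolute error ≈ 0.03 at λ* = 0, ≈ 0.13 at λ* = 1 on the
reference tree) but weakly identified in the interior — at λ* = 0.5 the
MAE is ≈ 0.32, and independent implementations show the same spread on
the same simulations.  This is a property of the estimator at this sample
size, not of the implementation; interior λ estimates from ~27 species
should be read as noisy.

## Regression battery

Size variables follow the convention ln Vol = ln(Vol^{1/3}) and
ln VolSC = ln(VolSC^{1/3}) (natural logs of cube roots of volumes, mm³),
against ln L (log summed canal streamline length, mm).  Isometry of
ln VolSC on ln L then means slope 1, and the isometry verdict comes from
the position of the 95% slope CI relative to 1.  Misreading this
convention changes every volume-length slope by a factor of 3.

OLS runs per specimen; PGLS runs per species (species means; geometric
means for the measurement table so log-scale averaging is exact) with
error covariance ∝ C at λ = 1, i.e. pure BM — no simultaneous λ
estimation.  PGLS R² is defined as 1 − GLS-RSS / GLS-TSS about the
phylogenetic mean; GLS has no canonical R², so this choice is stated
rather than assumed.  CIs use t quantiles on n − 2 df.  The multivariate
shape-on-size regression pools sums of squares across descriptor columns
and tests R² by permuting the size vector (seeded, ≥ 99 permutations).
ANCOVA is the classical two-stage partial-F construction: the
group×covariate interaction tested against the full model (homogeneity of
slopes), then the group main effect within the common-slope model
(homogeneity of intercepts, the grade-shift test).

## Ancestral states and phylomorphospace

Internal-node states under BM are the conditional expectations of the
joint tip+node Gaussian given the tips, with the GLS mean â as the
unconditional mean: `ẑ = â + C_zy C_yy⁻¹ (y − â1)`.  The dense
conditioning is exact and cheap at these tree sizes; no pruning recursion
is used.  Estimation variances are GLS prediction variances,
σ̂²[(C_zz − C_zy C_yy⁻¹ C_yz) + (1 − C_zy C_yy⁻¹ 1)²/(1ᵀC_yy⁻¹1)], with
σ̂² on the conventional n−1 denominator; estimates and variances both
match the standard R implementation to ~1e-6 on the reference tree.  The
root estimate equals â, and its variance is positive (the mean itself is
estimated).  Zero-length pendant edges are refused by name — they make
the tip system singular.

A phylomorphospace places tips at their ordination scores and internal
nodes at the per-axis ML reconstructions, drawing the tree's edges
through the scatter.  Ancestral (or any) scores back-project linearly:
descriptor = grand mean + Σ scoreⱼ·eigenvectorⱼ, reshaped to k×3 for
landmark-provenance tables.  For deformation descriptors the
back-projection deliberately stops at the descriptor vector — turning a
momentum vector back into a surface requires the original diffeomorphic
machinery and is out of scope.

## The synthetic-data generator

`simulate_shape_sample` draws species mean descriptors by BM along the
reference chronogram (rate 1 per Ma per trait by default, p = 12),
adds each clade's offset vector (default: magnitude 25 along distinct
coordinate axes), and scatters individuals around species means with
i.i.d. Gaussian noise (sd 1).  Specimen counts default to the reference
design's per-species numbers (142 total).  The offset magnitude was
chosen once so that clades are nearly separable in bgPC space — the
empirical regime in which comparative vestibular analyses report > 95%
cross-validated classification — while within-clade variation retains
the BM structure the signal statistics expect.  `simulate_allometry`
draws ln L uniform on [2.7, 3.7] per specimen and builds
ln VolSC^{1/3} = intercept(group) + 0.9·ln L + N(0, 0.1²), with a 0.5
log-unit hominid intercept shift; whole-vestibule volume is canal volume
inflated by a fixed factor.  `make_fossil_specimen` interpolates between
a clade mean and the root state with weight w plus within-species noise,
the geometry of a stem member.

What this emulates: the group structure, phylogenetic covariance,
within-species noise, allometric grade shift, and out-of-sample fossil
placement of a comparative vestibular dataset.  What it does not:
anatomical landmark geometry beyond a stylised three-ring template
(three circular arcs of 15 points in near-orthogonal planes — curved 3D
structure for GPA, no claim of realism), surface topology, measurement
error covariance between descriptors, unequal within-species variances,
or non-BM evolutionary processes (OU, early-burst).  Tests passing on
these generators therefore validate the estimators' algebra and
calibration under the stated model, not robustness to model violations
in real data.

Everything is deterministic given the config seed; each generator writes
its `SimTruth` (true species means, internal states, regression
parameters, manifest) alongside the data, and no recovery test reads
truth through the pipeline under test.

## Numerical choices

- Linear solves via Cholesky; a failure triggers one jitter of
  1e-10·tr(C)/n, then an error.
- C^{-1/2} for K_mult via eigendecomposition; non-positive eigenvalues
  raise (rank-deficient C).
- bgPCA degenerate case (all group means equal) is flagged, with zero
  eigenvalues and zero variance fractions rather than NaNs.
- Permutation p-values use the (1+b)/(1+m) estimator; seeds are required
  everywhere randomness appears, and the CLI derives per-stage seeds from
  one master seed by hashing stage names (stable, independent streams).
- Confusion matrices are row-normalized to percentages; ties in HCA
  majority labelling resolve to the lexicographically first group.

## Problem sizes used in the shipped checks

The calibration suite runs at the study's own scale: n = 27 tips for all
signal statistics (500 replicates for λ recovery and K, 300 for K_mult,
500 outer replicates for permutation type-I error), 142 specimens for
classification, 200 replicates for PGLS coverage and ANCOVA power, 100
random cases for the GPA and ancestral-state oracle comparisons.

## Known limitations

- λ is only searched on [0, 1]; data truly exceeding λ = 1 (stronger
  similarity than BM allows) pile up at the boundary.
- PGLS fixes λ = 1; no simultaneous signal-and-slope estimation.
- Ancestral reconstruction assumes homogeneous-rate BM; rate shifts or
  selection regimes are out of scope.
- bgPCA with few groups and many descriptors can separate groups by
  construction; the HCA check and the ≤ g−1 axis cap mitigate but do not
  remove this, and conclusions about real group structure should lean on
  the cross-validated rates.
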