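# Methods notes

## Network construction

Correlation matrices are symmetrized on load as (M + Mᵀ)/2 with the
diagonal forced to 1. Thresholding keeps the E = ⌈d·N(N−1)/2⌉ largest
positive off-diagonal correlations at density d; the ceiling convention
reproduces the standard 4,020-edge count for N = 232 at d = 15%. Negative
correlations are never retained. Ties at the cut are broken by
lexicographic (i, j) order, which makes thresholding deterministic. Group
networks average raw correlations elementwise (no Fisher-z) before
thresholding. Nodes left edgeless by thresholding stay in the node set;
their entropy is missing (NaN) and they are excluded from all means rather
than zero-filled.

## Edge graph

Only edge pairs sharing exactly one node receive a similarity; all other
pairs are structural zeros. The modified connectivity profile sets a
node's self-weight to its mean retained-edge weight, so the Tanimoto
coefficient stays well defined for directly connected endpoint pairs; dot
products run over all N coordinates including the diagonals. Construction
enumerates each node's incident-edge pairs (O(Σ_i k_i²)) with per-node
profile caching, and is verified in tests against a literal O(E²) scan.
Similarity is invariant to global rescaling of the weights (numerator and
denominator both scale by c²).

## Module detection

Louvain runs use networkx's seeded implementation at resolution 1.0
(exposed as a parameter; there is no principled default beyond 1.0 for
this application). Instance seeds are base_seed + 0..n−1, so an ensemble
is exactly reproducible. The module number of a network is the modal count
over instances with frequency ties broken toward the smaller count
(parsimony); entropy and modularity are instance averages. Modularity is
the weighted Newman–Girvan Q, computed in-package and cross-checked
against both networkx and a brute-force double loop.

Consensus clustering re-clusters the module co-occurrence matrix (the
fraction of instances co-assigning each edge pair), taken as a dense
weighted graph without thresholding, and iterates until every run of an
iteration returns the same partition up to label permutation (max 20
iterations; on failure the most frequent partition is returned with a
`converged=False` flag). Canonical first-occurrence relabelling makes the
permutation-invariant equality test cheap.

## Nodal overlap

The entropy normalizer is log₂ of the node's *own* involved-module count,
not the global module count, with conventions 0·log 0 = 0 and H = 0 for a
single involved module. Instance averaging is performed on the normalized
entropy. Module maps record each node's edge share per module; map
matching maximizes Pearson correlation across nodes and allows
many-to-one matches. System composition counts member nodes (any edge in
the module by default; threshold configurable) per functional system.

## Longitudinal models

Age effects use linear mixed models fitted by maximum likelihood:
y_ij = β0 + b_i + (β_age + b_age,i)·age_ij + β_sex·sex_i + β_mFD·mFD_ij + ε_ij,
and a quadratic variant adding fixed and random age² terms. Random effects
are independent (diagonal covariance) by default — with 1–3 scans per
subject a full covariance is weakly identified — and the full structure is
available via `diagonal_re=False`. Age is entered in years, uncentered
(fixed-effect inference is invariant to centering). Non-convergent fits
fall back to a random-intercept-only model and are flagged; fits that
still fail propagate as missing. Model choice is by AIC with exact ties
going to the linear model; the node-wise age map takes the highest-order
fixed age term of the chosen model (age for linear, age² for quadratic).
FDR correction is Benjamini–Hochberg. Calibration on synthetic nulls (200
subjects, the default 1/2/3-scan mix) puts the fixed-age type-I rate at
~4–5% at α = 0.05, with slight conservatism attributable to ML variance
estimation under few scans per subject.

Spatial-autocorrelation-preserving surrogates permute the map, smooth the
permutation with Gaussian distance kernels over a 5-point log-spaced
bandwidth grid (spanning the 5th percentile to the maximum of the pairwise
distances), score each candidate — after rank-remapping onto the original
value multiset — by squared variogram mismatch over 10 distance-quantile
lag bins, and keep the best (including the raw permutation as a candidate,
so spatially white maps reduce to plain permutations). Every surrogate is
an exact permutation of the input. Surrogate-corrected correlation
p-values are two-sided add-one estimates.

## Prediction

Both pipelines use linear-kernel ε-SVR with C = 1, ε = 0.1 (the common
library defaults) and min–max feature scaling estimated on the training
split only; constant features scale to 0. Age prediction stratifies folds
by sorting on age and dealing consecutive blocks round-robin after a
seeded within-block shuffle — folds differ in size by at most one and
track the global age mean far better than random splits. One scan per
subject is selected uniformly at random to avoid leaking longitudinal
scans across folds; the fold seed is held fixed across selection repeats
so identical selections give identical accuracies. Contribution weights
are primal coefficients of a full-data refit, averaged over repeats, with
positive and negative node weights aggregated separately per system.
Residualization before prediction removes estimated sex, motion and
subject-specific random-effect contributions from each measure (BLUP
shrinkage means a little residual noise is absorbed too). The
structure-to-entropy pipeline cross-validates over nodes (random,
unstratified folds) and calibrates significance against a null pooled over
per-scan entropy shuffles; permutation counts default to desk scale
(tens to hundreds) and are parameters.

## Synthetic generators

`gen_overlapping_network` plants block structure via memberships: each
node gets one primary module (round-robin) and a fraction get a second,
*randomly chosen* module. The expected correlation of a pair is
between + within · |shared| / min(|m_i|, |m_j|) plus symmetric Gaussian
noise, clipped into (−1, 1). Random second-membership pairs matter: if all
dual nodes shared the same module pair they would themselves form a
coherent block, and edge-level clustering would assign them a module of
their own, collapsing their entropy instead of raising it. Defaults
(within 0.6, between 0.05, noise 0.05, overlap 0.3) give planted dual
nodes roughly double the entropy of single nodes at 15% density.

`gen_longitudinal_cohort` follows the linear mixed model exactly: the
default composition is 166 one-scan, 92 two-scan and 47 three-scan
subjects (305 subjects, 491 scans), baseline ages uniform on 6–14 yr,
follow-ups one year apart with 0.1-yr jitter, sex Bernoulli(0.5), mFD
lognormal with median 0.1 mm, default random-effect SDs 0.05 (intercept)
and 0.01/yr (slope) and residual SD 0.05 — magnitudes chosen so that the
planted slopes of a few hundredths per year are detectable but not
trivial, matching the effect scale of developmental connectome measures.

`gen_structural_features` couples six features linearly to standardized
entropy with loadings signed positive for the thickness analogue and
negative for the rest, plus Gaussian noise. `gen_coordinates` places nodes
on a Fibonacci sphere lattice under a seeded random rotation (radius
100 mm), giving well-spread coordinates for surrogate testing. All
generators draw from named substreams of one master seed.

What the generators do **not** emulate: real haemodynamic time series and
their autocorrelation, spatially smooth parcel geometry, distance-dependent
connectivity, site or scanner effects, and realistic missingness. Passing
tests therefore demonstrate the pipeline's correctness and statistical
calibration under its own model assumptions, not performance on empirical
MRI cohorts.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: networks of 60–232
nodes, ensembles of 8–20 Louvain instances, permutation nulls of tens to
hundreds, 446 × 100 shuffle pools on 40-node scans, and 500-replicate
model-calibration suites. Ensemble sizes of 100 instances and 10,000
permutations remain the defaults of the corresponding functions. Every
stochastic step takes an explicit seed; repeated calls with the same seed
are bit-identical.

## Known limitations

- Only directly connected edge pairs (one shared node) contribute to the
  edge graph; indirect interedge relationships are ignored.
- Louvain is greedy; the modal-count and consensus machinery quantifies
  but does not remove its run-to-run variability.
- The surrogate generator matches variograms over a fixed bandwidth grid;
  highly anisotropic spatial structure may be matched imperfectly.
- Mixed-model inference uses Wald z-tests on ML fits; small-sample
  corrections (e.g., Satterthwaite) are not implemented.
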