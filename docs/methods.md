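# Methods

`connmanifold` re-implements, as a tested library, an analysis pipeline for
reward-based motor learning with functional-connectivity manifolds: subjects
repeatedly trace a hidden rewarded trajectory while their brain activity is
recorded; per-epoch covariance matrices are centered on the SPD manifold to
remove subject-level offsets, embedded into a low-dimensional connectivity
manifold, and summarized per region by *eccentricity*; behavioral learning is
summarized by a functional-PCA *learning score*; epoch contrasts and
spin-test inference connect the two. Everything runs end to end on a
synthetic study generator, so every claim the test suite makes is a claim
about data whose ground truth is known.

## Task geometry and reward scoring

The start position is the origin; the target is a marker at distance
D = 60 mm along +y. The visible path is a half-cycle sine
x(y) = 0.15·D·sin(πy/D); the rewarded path is its mirror image across x = 0.
A trial's score reads the traced x position at the first upward crossing of
each y ∈ {10, 20, 30, 40, 50, 60} mm, sums absolute deviations E from the
reward path, normalizes by the same sum N for a reference sine of amplitude
0.5·D, and returns

    score = 100 · (1 − E/N), clipped to [0, 100].

Only this form reproduces both printed anchors: a perfectly traced visible
path scores 40 (E/N = 0.3·ΣsinN/0.5·Σsin = 0.6) and the reward path scores
100; the straight line up the midline scores 70. First-crossing
interpolation handles non-monotone paths the way an online scorer must.

Trial processing: RT is the time to reach 10% of D, MT the remaining time to
D. Exclusions (all trials retained with reasons): no arrival within 4.5 s
(timeout); any pre-arrival sample at the device-dropout sentinel position
(cursor jump — sentinel samples are removed before computing arrival, since
the jump corrupts the y trace); and the slowest 0.05% of pooled trials by MT
and by RT separately (ceil count, no lower trim). Path variability at trial
t is the mean absolute x deviation from the 7-trial sliding-window mean path
over 10 equally spaced y points (y = D/10 … D; the anchor excludes y = 0,
matching a k = 1…10 sampling convention).

## Covariance estimation and Riemannian centering

Per subject and epoch, region time series (z-scored; for real data,
denoised first — see below) give Ledoit–Wolf shrinkage covariances, SPD even
when regions outnumber volumes. Under the affine-invariant metric on the SPD
cone, the centering is:

1. log map at the subject mean: T_ij = S̄ᵢ^{1/2} log(S̄ᵢ^{-1/2} S_ij S̄ᵢ^{-1/2}) S̄ᵢ^{1/2}
2. transport to the grand mean: T^c_ij = G_i T_ij G_iᵀ with G_i = S̄gm^{1/2} S̄ᵢ^{-1/2}
3. exp map at the grand mean: S^c_ij = S̄gm^{1/2} exp(S̄gm^{-1/2} T^c_ij S̄gm^{-1/2}) S̄gm^{1/2}

S̄ᵢ is the Karcher (geometric) mean of subject i's epochs, S̄gm the Karcher
mean over all subjects and epochs (fixed-point iteration from the arithmetic
mean, unit step, tolerance 1e-10, max 200 iterations). The three-step
composite is mathematically the congruence S ↦ G_i S G_iᵀ; we ship the
three-step form and use the one-step congruence as an independent oracle in
tests (agreement to 1e-8 relative Frobenius). Matrix functions go through
symmetric eigendecomposition with an eigenvalue floor of 1e-12 — below the
floor is an error, never a silent clamp, because a near-singular covariance
signals a data problem.

Consequences that the tests rely on: within-subject affine distances are
exactly preserved; each subject's centered epoch mean equals S̄gm; and
congruence-type subject offsets are removed exactly. One subtlety follows
from the last point: with J = 3 epochs, removing each subject's own mean
makes the epoch deviations mean-zero per subject, so the between/within
distance ratio after centering is √(1 − 1/J) ≈ 0.82, not 1 — between-subject
comparisons lose the shared part of the deviations. The cluster-removal test
asserts this exact value rather than an idealized 1.0.

## Manifold construction and eccentricity

Each centered matrix is row-thresholded to its top 10% of off-diagonal
connections per row (by signed value, ties to the lower index; the result
may be asymmetric), rows are compared by cosine similarity to form an
affinity matrix, and the column-mean-centered affinity is decomposed by PCA
(SVD). PCA is used rather than a nonlinear embedding for reliability; the
sign of each component is fixed by making its largest-magnitude loading
positive, so embeddings are deterministic. The analysis uses the top d = 3
components.

The template is the embedding of the Karcher mean of all centered baseline
matrices. Every subject/epoch embedding is aligned to the template by
orthogonal Procrustes — rotation/reflection only, no scaling or translation,
so inter-region distances and hence eccentricity comparisons across epochs
are undistorted. Eccentricity is each region's Euclidean norm about the
origin; centered PCA scores put the template centroid at the origin, and a
fixed origin keeps epochs comparable. High eccentricity reads as network
segregation; on the synthetic template it correlates positively with node
strength and negatively with participation coefficient (computed on the
row-thresholded matrix, symmetrized by max(w, wᵀ) with negative retained
weights zeroed).

Because eccentricity is a global functional of the whole covariance, a
connectivity change confined to one network genuinely shifts other regions'
coordinates (about 30% of the target-network magnitude in noiseless truth).
Detection tests that need a localized ground truth therefore use the
thresholded-strength contrast, whose truth-level change is confined to the
affected rows; the eccentricity contrast is held to the detection bar only.

## Preprocessing (real-data path)

Confound regression (e.g., the 34 motion/physiological regressors) and a
discrete-cosine high-pass basis (128 s cutoff) are removed in one joint OLS
projection; then a zero-phase order-5 Butterworth low-pass (100 s cutoff);
then per-region z-scoring. The default cutoff pair leaves a narrow passband
(0.0078–0.01 Hz); the code applies the configured values and warns rather
than guessing intent. Scans are spliced into three 210-volume epochs after
discarding 6 leading buffer volumes; the late epoch is anchored to the end
of the learning scan (mirroring a first/last-70-trials design), leaving a
mid-scan gap. The synthetic path skips confound regression (the generator
produces stationary Gaussian series) and applies z-scoring only.

## Behavioral learning scores (functional PCA)

Trial scores are averaged in 8-trial bins (200 trials → 25 bins). Each
curve is smoothed with a cubic B-spline basis with knots at the bin centers
under a squared-second-derivative roughness penalty; one shared penalty
weight is chosen by generalized cross-validation (minimizing the mean GCV
over subjects on a log grid from 1e-6 to 1e4). Smoothed curves are evaluated
on a 101-point grid and decomposed by a trapezoid-quadrature-weighted
eigendecomposition of their covariance. A subject's learning score is their
loading on the top component, with the sign fixed so that a positive score
accompanies better final-quarter performance. On noiseless single-mode
curves the recovery is essentially exact (variance explained > 0.99, score
correlation |r| > 0.999); exact knot placement and the GCV grid are free
choices, and these recovery properties are the correctness contract.

## Inference

Region-wise epoch contrasts are paired two-tailed t-tests with
Benjamini–Hochberg FDR at q = 0.05 across regions (zero-variance differences
get p = 1 with a warning). Seed contrasts average the centered covariance
rows over the seed set per subject and contrast epochs region-wise,
reporting the unthresholded t-map plus its 17-network mean summary.

Brain–behavior inference correlates each region's eccentricity change with
the learning score across subjects, averages the correlations within each of
the 17 networks, and ranks the network mean against a spin null: per spin,
one uniform random rotation (mirrored across hemispheres) is applied to the
parcel centroids on the unit sphere and values are reassigned by greedy
unique nearest-centroid matching in random order — a true permutation, so
every spin preserves the multiset of values; subcortical regions never
rotate. Spin p-values use the (b+1)/(m+1) convention (never exactly zero),
two-sided. A network is significant only if its spin test passes at level q
AND its subject-level correlation of network-mean eccentricity change with
the score differs from zero after BH-FDR across networks. Two notes: the
observed network statistic is the mean of region correlations while the
zero-test uses the network-mean time course — both definitions are computed
and reported (`r` and `r_subject`). And the FDR step is applied to the
zero-test only: the spin p-value's resolution (2/(m+1) two-sided) makes a
17-network BH correction unsatisfiable at 500 spins, so the spin component
is assessed at level q per network. Greedy unique matching carries a small
map-specific bias (a known property of unique-reassignment spin nulls);
unbiasedness holds in expectation over value maps, and the calibration tests
confirm the dual rule's type-I error stays below q.

## Synthetic study generator

The generator emulates the study's statistical structure at configurable
scale (defaults: 36 subjects × 3 epochs × 210 volumes, 120 regions, TR 2 s):

- **Base covariance**: unit-diagonal block-correlation matrix over 7
  contiguous networks (17 fine networks nested inside), between-network
  correlation 0.05, within-network correlation graded across networks from
  0.2 to 0.4 (mean 0.3). The grading reflects that real functional networks
  differ in cohesion; it is what gives segregated networks their higher
  strength and eccentricity.
- **Subject identity**: a congruence perturbation A_i B A_iᵀ with
  A_i = expm(0.4·Z_i), Z_i random symmetric with entries ~ N(0, 1/R). A
  congruence — not additive noise — because that is the offset class the
  centering removes exactly, making cluster removal a provable property.
  The 0.4 magnitude makes raw covariances cluster by subject
  (between/within distance ratio ≈ 1.3 at full scale) against Ledoit–Wolf
  sampling noise at 210 volumes.
- **Epoch effect**: +0.2 added to the target network's within-block
  correlations in the early and late learning epochs, applied after the
  congruence so that exactly the designated rows/columns of each truth
  matrix change. Non-positive-definite results raise an error advising a
  smaller delta.
- **Time series**: i.i.d. multivariate Gaussian draws (Cholesky), seeded per
  subject/epoch from one root seed.
- **Centroids**: each network gets a direction on the unit sphere; members
  scatter around it or its x-mirror with Gaussian tangent noise (a
  von-Mises–Fisher-style concentration); hemisphere is the sign of x.
- **Learning curves**: 200 trials; population mean 40 + 25·(1 − e^(−t/50))
  (starting at the visible-path score); a single saturating learning mode
  scaled by subject aptitude (fast/slow mixture at ±10 points, SD 4); i.i.d.
  Gaussian trial noise (SD 10), clipped to [0, 100]. A trajectory-level
  REINFORCE-style simulator (`behavior.simulate_learner`) generates full
  fingertip paths when trajectories are needed: exploration around a signed
  sine amplitude, with the mean amplitude drifting toward explored values
  that beat a running score baseline at a rate set by aptitude.

What the generator does *not* emulate — hemodynamics, temporal
autocorrelation, motion artifacts, non-Gaussian tails, spatially continuous
(non-block) covariance structure — bounds what passing tests show: they
validate the estimators, geometry, and inference logic under the assumed
statistical structure, not robustness to fMRI nuisance structure.

## Problem sizes in the test suite

Property and acceptance tests run at desk scale, chosen as the smallest
sizes at which each property is statistically decidable: the congruence
oracle on 20 random sets of dimension 4–50; cluster removal at the full
36 × 120 × 210 design; epoch-effect recovery over 200 simulations at
12 subjects × 42 regions × 120 volumes/epoch; inference calibration over
200 null runs (68 regions, 500 spins) plus 25 power runs at n = 36.

## Pipeline and caching

The CLI (`connmanifold`) exposes one subcommand per stage
(simulate → covary → center → manifold → eccentricity → contrast →
behavior → infer) plus `run`. Stages communicate through TSV tables in a
single run directory; a stage errors by name when its inputs are missing,
and a prefix of the pipeline is resumable from the files on disk. The
manifest records the config echo, stage timings and a SHA-256 of every
produced file; caching is presence-based rather than hash-keyed — with
deterministic seeds, re-running a stage reproduces byte-identical outputs,
which the manifest hashes make checkable.

## Known limitations

- The real-data adapter expects already-extracted region time series;
  scanner-native formats are out of scope.
- The Karcher mean uses unit-step fixed-point iteration; widely dispersed
  covariance sets could require damping (not needed for clustered sets).
- Greedy spin matching is quadratic per spin; parcellations beyond a few
  thousand regions would need a faster assignment.
- With three epochs, post-centering between-subject distances are
  structurally deflated by √(2/3); any downstream statistic comparing
  between- to within-subject variability after centering must account for
  this.
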