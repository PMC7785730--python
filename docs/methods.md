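# Methods

This note documents the models and procedures phenofuse implements, the
defaults it ships, what the synthetic cohorts do and do not emulate, and
the numerical and design choices made where the method description left
room.

## Preprocessing chain

The cleaning chain runs in a fixed order: (i) missingness filters,
(ii) robust outlier screening, (iii) median imputation, (iv) batch
adjustment, (v) control-referenced residualization, (vi) z-scoring.

**Missingness.** Features missing in ≥ 20% of subjects are dropped first;
then subjects missing ≥ 20% of the remaining features. Both thresholds are
inclusive and configurable. Because the feature stage runs first, a
feature that is the sole offender for a subject can rescue that subject —
the order matters and is part of the contract.

**Outliers.** Per modality, a subject's score is the fraction of features
on which |x − median| / (1.4826·MAD) exceeds `n_mads` (default 5; features
with zero MAD are skipped). Subjects scoring above 10% are flagged.
Screening is per-modality with the union of flags applied to all
modalities, so every downstream stage sees a common patient set. The
deviation scale and thresholds are configurable; the defaults flag a
subject only when a sizable share of its features are far outside the
robust bulk.

**Batch adjustment** is the parametric empirical-Bayes location/scale
model: per-feature batch locations and scales estimated on standardized
data, shrunk across features toward per-batch normal / inverse-gamma
priors (method-of-moments hyperparameters, iterative conditional means),
then removed; covariates supplied to the model are protected. With narrow
feature panels the shrinkage has little to borrow and residual
sampling-noise differences of order σ·√(2/n_b) remain by design;
`shrink=False` switches to raw per-feature location/scale removal, which
equalizes per-batch feature means exactly.

**Residualization** fits, per feature, ordinary least squares on *healthy
controls only* against intercept, age, sex and age×sex (plus optional
extra columns such as total intracranial volume), and subtracts the
control-fitted predictions from the patients. Disease-specific offsets
beyond covariate effects therefore survive. **Z-scoring** uses
patient-only means and sample SDs (ddof = 1).

## Patient similarity networks

Distances are squared Euclidean (a cityblock option exists; other metrics
are out of scope). The scaled exponential kernel evaluates a Gaussian
density *at* the squared distance with a locally adaptive bandwidth
σ = μ(m_i + m_j + ρ²_ij)/3, where m_i is the mean squared distance from i
to its K nearest neighbors (self excluded — a zero self-distance would
deflate σ). Both the argument and the bandwidth live on the
squared-distance scale, so the exponent is O(1) for any data scale and μ
directly controls how wide a distribution of edge weights survives. The
widely used reference implementations of this kernel compute the neighbor
means over squared distances; the notation of the bandwidth admits a
literal reading with root-distance means, so both are available
(`squared_means`, default the reference convention). A σ floor of 1e-12
guards duplicate-patient degeneracies.

The concatenation baseline stacks all features, takes cosine similarity
and rescales it from [−1, 1] to [0, 2] so spectral clustering never sees
negative weights.

**Hyperparameter grid.** K spans 5–105 (integers, evenly spaced) and μ
spans 0.3–10 (log-spaced), 100 values each in the full search. The
shipped desk-scale default subsamples the same ranges at 20×20; the full
100×100 grid is a config switch. Grid cells are computed independently
and the result is identical regardless of evaluation order. Grid K values
at or above the cohort size are dropped (a K-nearest-neighborhood needs
K < n).

## Fusion

Each affinity matrix is normalized two ways: the full transition matrix P
(diagonal ½, off-diagonal row-normalized to ½ — the half/half split
avoids the instability a plain row normalization inherits from the
arbitrary self-similarity) and the sparse local kernel S (row-normalized
over the K-nearest-neighbor set, which *includes* the node itself;
configurable). Ties at the K-th neighbor are all kept, making S
independent of sort order. The update

P(v) ← S(v) · mean of the other P · S(v)ᵀ

runs for all modalities per sweep, each result symmetrized and
re-normalized through the same P construction; S is computed once and
never updated. Iteration stops at convergence (mean absolute change of
the averaged P below 1e-6) or after 20 sweeps, whichever is first — the
cap is authoritative. The fused network is the symmetrized average of the
final P(v). A single-modality "fusion" returns the normalized symmetrized
input; `max_iter=0` returns the average of the initial normalized
networks.

A note on an exactness limit: with m identical inputs the update reduces
to P ← S P Sᵀ, which is *not* an algebraic identity — the iteration
converges to a nearby stationary matrix of the diffusion (order-1e-2
elementwise at n = 20), not to the input itself. The tested invariants
are therefore: all per-modality matrices remain exactly equal to each
other, the iteration reaches a genuine fixed point (one further update
moves the converged matrix by < 1e-8), and every P stays row-stochastic
with diagonal ½ after every sweep.

## Consensus biotypes

Every fused network is clustered at k = 2, 3, 4 by normalized-Laplacian
spectral clustering: the k trailing eigenvectors of D^(−1/2) W D^(−1/2)
are row-normalized and clustered by k-means with 50 seeded restarts
(deterministic given the seed). Disconnected networks with more components
than k are reported rather than silently split.

**Stability.** Cell stability is the mean z-Rand agreement between a
cell's partition and its 4-connected grid neighbors (edge and corner
cells use their existing neighbors), computed separately per k. The
z-Rand statistic standardizes the co-pair count by its exact mean and
variance under the permutation model with fixed cluster sizes; the moment
formulas are verified in the tests against exhaustive enumeration of all
relabelings at small n. Degenerate (single-cluster or all-singleton)
partitions have zero variance and return 0.

**Retention** pools the values of the three stability surfaces and keeps
cells strictly exceeding the pooled 95th percentile in any surface
(strictness configurable); each retained cell contributes its partitions
at all three k. The pipeline falls back to inclusive retention when small
saturated surfaces tie at the maximum.

**Consensus.** The pooled partitions form a co-assignment matrix (fraction
of partitions placing each pair together), thresholded at a chance level
estimated by permutation: each replicate independently shuffles every
partition's labels, rebuilds the matrix, and records its off-diagonal
mean; the mean over 100 replicates is the threshold. The thresholded
matrix is clustered by seeded Louvain modularity maximization
(resolution 1, 100 restarts); if restarts disagree, their own
co-assignment matrix becomes the next round's graph, up to 20 rounds,
after which the best-modularity partition is returned. The consensus
cluster count is emergent, never pre-specified.

Agreement metrics: NMI with arithmetic-mean normalization (zero-entropy
partitions return 0 by convention, and NMI is only compared between
same-k partitions); modularity under the degree-product null, normalized
by total weight so Q ∈ [−1, 1] (a single all-patients cluster scores
exactly 0); a label-permutation p-value for Q with the add-one rule.

## Phenotypic axes

Each retained fused network is sparsified row-wise — off-diagonal entries
below the row's 90th percentile (computed over off-diagonal entries) are
zeroed; the diagonal self-weight and percentile ties survive — and
re-expressed as the cosine similarity between the sparsified rows. The
diffusion map uses anisotropic normalization α = 0.5 (the Fokker–Planck
convention), eigendecomposes the transition operator through its symmetric
conjugate, drops the trivial constant eigenvector, and at t = 0 scales
component c by λ_c/(1−λ_c) — the multiscale convention emphasizing global
structure (λ^t for t > 0 is switchable). Variance explained is each
retained eigenvalue's share of the leading nontrivial spectrum (10
components by default); a numerically flat spectrum is flagged degenerate
and reported with equal shares.

Embeddings from all retained cells are aligned by generalized orthogonal
Procrustes analysis — rotations and reflections only, no scaling or
translation, to an iterated mean, stopping when the mean moves < 1e-9.
Before alignment each member's columns are sign-fixed (absolute-maximum
coordinate positive), which stabilizes the otherwise arbitrary axis
orientations; final axis signs remain arbitrary and are documented as
such. The mean of the aligned members is the reported embedding.
Components are kept up to ≥ 10% *cumulative* variance explained — read
literally as the smallest leading set reaching 10% (the alternative
per-component reading is noted but not implemented).

Held-out prediction uses five-fold cross-validation: patients are
shuffled (seeded) into near-equal folds; OLS with intercept on the first
five axes is fit on the training folds; per-fold Pearson correlations
between predictions and actual held-out scores are reported with their
mean and SD.

## The synthetic cohorts

The generator emulates the statistical structure the pipeline must
survive: five modalities of strongly unequal width (defaults 68, 16, 12,
6, 30; the widest experiments use 1000), a small number of latent
subgroups expressed weakly in every modality, an independent standard
normal severity gradient shared across modalities (optionally correlated
with the subgroups), linear age/sex/age×sex effects with coefficients
shared between patients and controls (so control-referenced
residualization is well-posed; age ~ U[45, 80], sex ~ Bernoulli(½)),
additive per-batch feature offsets, i.i.d. Gaussian noise, MCAR missing
cells, and outlier subjects shifted ≈ 12 robust SDs on half their
features.

**Effect-size convention.** `cluster_sep` and `gradient_loading` are
modality-level effect sizes with a mild dimensionality compensation: the
expected squared centroid separation in a p-feature modality is
1.25 · sep² · (2p)^(1/4) noise-variance units. The exponent matters:
at 0 a 1000-feature modality contributes nothing (its distance noise
grows like √p and swamps a fixed signal), while at ½ or 1 it becomes
individually sufficient and dominates. The ¼ compromise makes every
modality weakly and comparably informative — at the default sep = 1.5 no
single modality recovers the subgroups (adjusted Rand ≈ 0.5 at best) but
their fusion does (≈ 0.85–0.95 at signal-bearing grid cells) — which is
precisely the regime the method is for.

What the generator does *not* emulate: feature–feature correlation within
a modality (features are conditionally independent given the latent
structure), heavy-tailed or skewed marginals, informative missingness,
site-by-severity interactions, and longitudinal structure. Passing tests
therefore demonstrate the machinery's correctness and its qualitative
behavior under weak distributed signal — not performance claims for any
particular real dataset.

## Problem sizes and determinism

The shipped study conditions run n = 150 patients with modalities
(1000, 16, 12, 6, 30) over a 20×20 grid — large enough for the
dimensionality-balance and planted-recovery contrasts to be stable, small
enough that the full consensus pipeline completes in about a minute on
one CPU; the 100×100 grid of the full search is a config switch. One
master seed expands through a seed sequence into per-stage seeds (all
below 2³¹), and a rerun with an identical config is byte-identical.

## Known limitations

- The stability-selection step retains the top pooled percentile of
  z-Rand surfaces. On weak-signal synthetic landscapes the most *stable*
  grid regions are the most parameter-insensitive ones — heavily smoothed
  high-K/high-μ cells whose (identical) partitions are mediocre — so
  consensus over retained cells can underperform consensus over the whole
  grid, and both can underperform the best single grid cell. Stability is
  not accuracy; on data where signal-bearing regions are also the
  parameter-stable ones the selection helps, but that is a property of
  the data, not a guarantee of the procedure.
- Empirical-Bayes batch adjustment needs enough features to estimate its
  priors; for panels of a handful of features prefer `shrink=False`.
- Louvain consensus with 100 restarts on a dense thresholded matrix is
  the runtime bottleneck for cohorts beyond a few hundred patients.
- The generator's conditional-independence assumption makes
  concatenation look worse than it may be on correlated real features;
  the balance *contrast* (fusion spreads NMI more evenly across
  modalities) is the robust claim.
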