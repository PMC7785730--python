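# phenofuse

Multimodal patient phenotyping by **similarity network fusion (SNF)**:
consensus "biotypes" and continuous phenotypic axes from several
patient-by-feature tables of very different widths.

Clinical cohorts are characterized by many data sources at once — imaging
morphometry with hundreds of regional features next to a handful of
biofluid assays and a few dozen clinical scores. The field-standard way to
combine them, concatenating the feature tables, lets the widest table
dominate every downstream analysis. phenofuse instead builds a patient
similarity network *per modality*, fuses the networks by iterative
cross-network diffusion, and derives two complementary representations of
patient heterogeneity from the fused network:

- **categorical** — spectral clustering across an exhaustive hyperparameter
  grid, z-Rand stability selection, and modularity-maximization consensus
  into emergent patient subgroups;
- **continuous** — diffusion-map embeddings of the stable grid cells,
  aligned by generalized orthogonal Procrustes analysis and averaged into a
  compact set of phenotypic axes.

A first-class synthetic-cohort generator plants subgroup structure, a
severity gradient, covariate effects, batch offsets, missingness and
outliers, so every stage is testable end-to-end without any data access.

## The model

Each modality's feature matrix yields squared Euclidean distances
ρ²(x_i, x_j), converted to similarities with a locally adaptive scaled
exponential kernel

    W(i,j) = (2πσ²)^(-1/2) · exp( −ρ²(x_i,x_j)² / 2σ² ),
    σ      = μ · ( mean_{N_i} ρ² + mean_{N_j} ρ² + ρ²(x_i,x_j) ) / 3,

where N_i are patient i's K nearest neighbors; K controls neighborhood
size, μ the edge-weight spread. Each W is split into a full transition
matrix **P** (diagonal ½, off-diagonal row-normalized to ½) and a sparse
local kernel **S** (row-normalized over the K nearest neighbors). Fusion
iterates, for every modality v among m,

    P(v) ← S(v) · [ Σ_{k≠v} P(k) / (m−1) ] · S(v)ᵀ,

re-normalizing after every sweep, for up to 20 iterations; the fused
network is the symmetrized average of the final P(v).

Subgroup quality is measured by Newman–Girvan modularity
Q = Σ_ij (A_ij − P_ij) δ(σ_i, σ_j) / 2m, partition agreement by the z-Rand
index and NMI, and subgroup-discriminating features by one-way ANOVAs with
Benjamini–Hochberg FDR. The continuous path thresholds each fused network
row-wise at the 90th weight percentile, takes cosine similarity, embeds
with a diffusion map at t = 0 (anisotropic normalization α = 0.5), and
keeps the leading axes reaching 10% cumulative variance explained.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

`examples/02_fuse_and_cluster.py` generates a 150-patient cohort with
three weak planted subgroups spread across five modalities (one with 1000
features) and compares each modality alone against the fused network:

```
kernel settings: K=20 neighbors, mu=0.5
  modality_1   (1000 features) alone: ARI = -0.01
  modality_2   (  16 features) alone: ARI = 0.29
  modality_3   (  12 features) alone: ARI = 0.29
  modality_4   (   6 features) alone: ARI = 0.51
  modality_5   (  30 features) alone: ARI = 0.17
fused network (5 iterations): ARI = 0.79
concatenation baseline:                        ARI = 0.01
```

No single modality recovers the subgroups (adjusted Rand ≤ 0.51), and
concatenation is destroyed by the 1000-feature modality's noise — but the
fused network reaches ARI 0.79. The other examples walk through cohort
cleaning (`01`), grid-consensus biotypes (`03`, consensus ARI 0.94 on a
5×5 grid with Q = 0.358, permutation p = 0.001), phenotypic axes (`04`,
dominant axis tracks the planted severity gradient at |r| = 0.79 and
predicts a held-out score at cross-validated r = 0.78), and the one-config
full pipeline (`05`).

The same pipeline runs from the shell:

```sh
phenofuse synth --n-patients 150 --dims 68,16,12,6,30 --seed 1 -o cohort/
phenofuse run -i cohort/ -o results/ --n-k 20 --n-mu 20 --seed 1
phenofuse no-mri -i cohort/ -o reduced/ -x modality_1,modality_2 --seed 1
```

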