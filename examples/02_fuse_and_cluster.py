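"""Fuse per-modality patient networks and compare with each modality alone.

Builds the scaled-exponential-kernel similarity network of each modality,
fuses them by iterative cross-network diffusion, and shows that spectral
clustering of the fused network recovers the planted subgroups far better
than any single modality — the core argument for fusion over concatenation.
"""

from sklearn.metrics import adjusted_rand_score

from phenofuse import (CohortSpec, affinity_kernel, concat_affinity,
                       generate_cohort, snf, spectral_cluster,
                       squared_euclidean)

spec = CohortSpec(n_patients=150, n_controls=50,
                  modality_dims=(1000, 16, 12, 6, 30), n_clusters=3,
                  cluster_sep=1.5, gradient_loading=0.0, noise_sd=1.0, seed=1)
tables, truth = generate_cohort(spec)

K, mu = 20, 0.5
networks = []
print(f"kernel settings: K={K} neighbors, mu={mu}")
for t in tables:
    W = affinity_kernel(squared_euclidean(t), K=K, mu=mu)
    part = spectral_cluster(W, k=3, seed=0)
    ari = adjusted_rand_score(truth.labels, part.labels)
    print(f"  {t.name:12s} ({t.shape[1]:4d} features) alone: ARI = {ari:.2f}")
    networks.append(W)

fused = snf(networks, K=K, max_iter=20)
part = spectral_cluster(fused, k=3, seed=0)
print(f"fused network ({fused.iterations} iterations): "
      f"ARI = {adjusted_rand_score(truth.labels, part.labels):.2f}")

concat = spectral_cluster(concat_affinity(tables), k=3, seed=0)
print(f"concatenation baseline:                        "
      f"ARI = {adjusted_rand_score(truth.labels, concat.labels):.2f}")
print("fusion combines five individually weak sources; concatenation is "
      "dominated by the 1000-feature modality's noise")
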