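"""Patient similarity networks.

A patient similarity network is built in two steps: a pairwise distance
matrix over the patients of one modality, then a scaled exponential kernel
that converts distances into similarities. The kernel bandwidth adapts to
local density: for each pair (i, j) it is the average of the mean distance
from i to its K nearest neighbors, the mean distance from j to its K nearest
neighbors, and the i-j distance itself, scaled by mu. Small mu keeps only
the strongest edges; large mu retains a wide distribution of edge weights.

The module also provides the field-standard baseline: horizontally
concatenate all modalities and take cosine similarity, rescaled to [0, 2]
so spectral clustering sees no negative weights.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics.pairwise import cosine_similarity

from .datatypes import AffinityMatrix, DistanceMatrix, ModalityTable

__all__ = [
    "squared_euclidean",
    "affinity_kernel",
    "concat_affinity",
    "kernel_grid",
    "SIGMA_FLOOR",
]

#: Bandwidth floor guarding against sigma = 0 on duplicate-patient inputs.
SIGMA_FLOOR = 1e-12


def squared_euclidean(table: ModalityTable, metric: str = "sqeuclidean") -> DistanceMatrix:
    """Pairwise squared Euclidean distances between patients of one modality.

    ``metric`` may be "sqeuclidean" (default) or "cityblock"; other metrics
    are intentionally not offered.
    """
    if metric not in ("sqeuclidean", "cityblock"):
        raise ValueError(f"unsupported metric {metric!r}")
    X = table.values
    if np.isnan(X).any():
        raise ValueError(
            f"modality {table.name!r} has missing cells; impute before "
            "computing distances")
    D = cdist(X, X, metric=metric)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=D, patients=table.patients, metric=metric)


def _neighbor_mean_distance(D: np.ndarray, K: int) -> np.ndarray:
    """Mean distance from each patient to its K nearest neighbors (self excluded)."""
    n = D.shape[0]
    # mask the diagonal so a patient is never its own neighbor
    masked = D + np.diag(np.full(n, np.inf))
    part = np.sort(masked, axis=1)[:, :K]
    return part.mean(axis=1)


def affinity_kernel(
    D: DistanceMatrix,
    K: int,
    mu: float,
    squared_means: bool = True,
) -> AffinityMatrix:
    """Scaled exponential kernel turning squared distances into similarities.

    The kernel is the Gaussian density evaluated at the squared distance:
    W(i, j) = exp(-d_ij^2 / (2 sigma^2)) / sqrt(2 pi sigma^2), with
    sigma = mu * (mean_i + mean_j + d_ij) / 3, where mean_i is the average
    distance from i to its K nearest neighbors (self excluded). Both d_ij and
    sigma live on the squared-distance scale, so the exponent is O(1) and mu
    directly controls how wide a distribution of edge weights survives.
    With ``squared_means=True`` (default) the neighbor averages are taken
    over the squared distances held in ``D``, matching the reference kernel
    lineage; with False, the averages of the root distances are squared (the
    literal reading of the bandwidth's notation).
    """
    n = D.n
    if not (1 <= K < n):
        raise ValueError(f"K must satisfy 1 <= K < n={n}, got {K}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")

    d = D.values
    if squared_means:
        means = _neighbor_mean_distance(d, K)
        sigma = (means[:, None] + means[None, :] + d) / 3.0
    else:
        root = np.sqrt(d)
        means = _neighbor_mean_distance(root, K) ** 2
        sigma = (means[:, None] + means[None, :] + d) / 3.0
    sigma = mu * sigma
    sigma = np.maximum(sigma, SIGMA_FLOOR)

    W = np.exp(-(d**2) / (2.0 * sigma**2)) / np.sqrt(2.0 * np.pi * sigma**2)
    W = (W + W.T) / 2.0
    return AffinityMatrix(values=W, patients=D.patients, K=K, mu=mu)


def concat_affinity(tables: list[ModalityTable]) -> AffinityMatrix:
    """Concatenation baseline: stack features, cosine similarity, scale to [0, 2].

    Cosine similarity lies in [-1, 1]; adding one shifts it to [0, 2] so the
    downstream spectral clustering never sees negative weights.
    """
    if not tables:
        raise ValueError("need at least one modality table")
    patients = tables[0].patients
    for t in tables[1:]:
        if t.patients != patients:
            raise ValueError(
                f"modality {t.name!r} has mismatched patients; all tables "
                "must share the same patients in the same order")
    X = np.hstack([t.values for t in tables])
    if np.isnan(X).any():
        raise ValueError("concatenated matrix has missing cells")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [patients[i] for i in np.where(norms == 0)[0]]
        raise ValueError(f"zero-norm patient rows: {bad}")
    W = cosine_similarity(X) + 1.0
    W = np.clip((W + W.T) / 2.0, 0.0, 2.0)
    return AffinityMatrix(values=W, patients=patients, K=None, mu=None)


def kernel_grid(
    K_range: tuple[int, int] = (5, 105),
    mu_range: tuple[float, float] = (0.3, 10.0),
    n_K: int = 100,
    n_mu: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """The hyperparameter grid of the exhaustive search.

    K: ``n_K`` unique integers evenly spaced over ``K_range`` (inclusive);
    mu: ``n_mu`` points log-spaced over ``mu_range`` (inclusive).
    """
    K_values = np.unique(np.round(np.linspace(K_range[0], K_range[1], n_K)).astype(int))
    if len(K_values) != n_K:
        raise ValueError(
            f"K grid of {n_K} values over {K_range} produced only "
            f"{len(K_values)} unique integers; widen the range")
    mu_values = np.logspace(np.log10(mu_range[0]), np.log10(mu_range[1]), n_mu)
    return K_values, mu_values
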