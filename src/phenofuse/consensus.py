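"""Categorical patient representation: clustering across the grid and consensus.

The hyperparameter grid yields one fused network per (K, mu) cell; each is
spectrally clustered at k = 2, 3, 4. Stability of a cell is the average
z-Rand agreement between its partition and its four grid neighbors,
computed separately per k. Cells exceeding the pooled 95th percentile of
the three stability surfaces (in any surface) are retained; their
partitions at all three k are pooled into a patient co-assignment matrix,
thresholded at a permutation-null chance level, and clustered by iterative
Louvain modularity maximization into an emergent consensus partition whose
cluster count is not pre-specified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .datatypes import AffinityMatrix, FusedNetwork, Partition

logger = logging.getLogger(__name__)

__all__ = [
    "spectral_cluster", "zrand", "stability_surface", "select_stable",
    "coassignment", "permutation_threshold", "consensus_partition",
    "nmi", "ModularityModel", "modularity", "modularity_pvalue",
]


def spectral_cluster(
    net: FusedNetwork | AffinityMatrix,
    k: int,
    seed: int = 0,
) -> Partition:
    """Normalized-Laplacian spectral clustering with seeded k-means.

    The symmetric normalized Laplacian's k trailing eigenvectors are
    row-normalized (Ng–Jordan–Weiss embedding) and clustered with k-means
    using 50 seeded restarts. Deterministic given the seed.
    """
    W = net.values
    n = W.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n={n}, got {k}")
    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp > k:
        raise ValueError(
            f"network has {n_comp} connected components but only k={k} "
            "clusters requested")

    d = W.sum(axis=1)
    if (d <= 0).any():
        raise ValueError("network has isolated (zero-degree) patients")
    inv_sqrt = 1.0 / np.sqrt(d)
    A = inv_sqrt[:, None] * W * inv_sqrt[None, :]
    A = (A + A.T) / 2.0
    # k largest eigenvectors of D^-1/2 W D^-1/2 == k smallest of L_sym
    _, vecs = eigh(A, subset_by_index=[n - k, n - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vecs / norms
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    labels = km.fit_predict(emb)
    patients = getattr(net, "patients", [str(i) for i in range(n)])
    source = (getattr(net, "K", None), getattr(net, "mu", None), k)
    return Partition(labels=labels, patients=patients, k=k, source=source)


def _pair_counts(labels: np.ndarray) -> tuple[float, np.ndarray]:
    """(number of within-cluster pairs, cluster sizes)."""
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1) // 2).sum()), counts


def zrand(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """z-scored Rand pair-counting statistic between two partitions.

    The observed count w of patient pairs co-clustered in both partitions is
    standardized by its mean and variance under the permutation model (all
    relabelings of one partition equally likely, cluster sizes fixed),
    following the pair-counting moments of the z-Rand index. Degenerate
    partitions (all singletons or a single cluster) have zero variance and
    return 0 by convention.
    """
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same patients")
    n = len(a)
    M = n * (n - 1) / 2.0

    M1, sizes1 = _pair_counts(a)
    M2, sizes2 = _pair_counts(b)

    # observed co-pair count via the contingency table
    pair_ids = a.astype(np.int64) * (b.max() + 1) + b
    _, joint = np.unique(pair_ids, return_counts=True)
    w = float((joint * (joint - 1) // 2).sum())

    mean_w = M1 * M2 / M

    def _C(Mx: float, sizes: np.ndarray) -> float:
        return (n * (n**2 - 3 * n - 2) - 8 * (n + 1) * Mx
                + 4 * float((sizes.astype(float) ** 3).sum()))

    C1, C2 = _C(M1, sizes1), _C(M2, sizes2)
    var_w = (M / 16.0
             - (4 * M1 - 2 * M) ** 2 * (4 * M2 - 2 * M) ** 2 / (256.0 * M**2)
             + C1 * C2 / (16.0 * n * (n - 1) * (n - 2))
             + ((4 * M1 - 2 * M) ** 2 - 4 * C1 - 4 * M)
             * ((4 * M2 - 2 * M) ** 2 - 4 * C2 - 4 * M)
             / (64.0 * n * (n - 1) * (n - 2) * (n - 3)))
    if var_w <= 1e-14:
        logger.debug("zrand: degenerate partition pair (zero variance); returning 0")
        return 0.0
    return (w - mean_w) / np.sqrt(var_w)


def stability_surface(partitions: np.ndarray, k: int | None = None) -> np.ndarray:
    """Mean z-Rand agreement of each grid cell with its 4-neighborhood.

    ``partitions`` is a 2-d object array (K-axis by mu-axis) of Partition.
    Edge and corner cells average over their existing neighbors only.
    """
    grid = np.asarray(partitions, dtype=object)
    if grid.ndim != 2:
        raise ValueError("partitions must form a 2-d grid")
    nK, nmu = grid.shape
    surface = np.zeros((nK, nmu))
    for i in range(nK):
        for j in range(nmu):
            vals = []
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < nK and 0 <= jj < nmu:
                    vals.append(zrand(grid[i, j], grid[ii, jj]))
            surface[i, j] = np.mean(vals)
    return surface


def select_stable(
    surfaces: dict[int, np.ndarray],
    pct: float = 95.0,
    strict: bool = True,
) -> list[tuple[int, int]]:
    """Grid cells whose stability exceeds the pooled percentile in any surface.

    The threshold is the ``pct``-th percentile of the values of *all*
    surfaces pooled together; a cell is retained if it exceeds the threshold
    in at least one surface (strictly by default). Returns (i, j) grid
    indices; each retained cell carries its partitions at every k forward.
    """
    if not (0 <= pct < 100):
        raise ValueError(f"pct must lie in [0, 100), got {pct}")
    mats = list(surfaces.values())
    if not mats:
        raise ValueError("no stability surfaces supplied")
    pooled = np.concatenate([m.ravel() for m in mats])
    thresh = np.percentile(pooled, pct)
    op = np.greater if strict else np.greater_equal
    keep = np.zeros(mats[0].shape, dtype=bool)
    for m in mats:
        keep |= op(m, thresh)
    cells = [tuple(idx) for idx in np.argwhere(keep)]
    if not cells:
        raise ValueError(
            f"no grid cell exceeds the pooled {pct}th percentile "
            f"({thresh:.4g}); surfaces may be degenerate (constant)")
    return cells


def coassignment(partitions: list[Partition]) -> np.ndarray:
    """Fraction of partitions assigning each patient pair to the same cluster."""
    if not partitions:
        raise ValueError("need at least one partition")
    n = partitions[0].n
    C = np.zeros((n, n))
    for p in partitions:
        if p.n != n:
            raise ValueError("partitions must cover the same patients")
        lab = p.labels
        C += (lab[:, None] == lab[None, :])
    C /= len(partitions)
    return C


def permutation_threshold(
    partitions: list[Partition],
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Chance co-assignment level from a label-permutation null.

    Each replicate independently shuffles every partition's labels across
    patients, rebuilds the co-assignment matrix, and records its
    off-diagonal mean; the mean over replicates is returned.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    n = partitions[0].n
    off = ~np.eye(n, dtype=bool)
    reps = []
    for _ in range(n_perm):
        perm = [Partition(labels=rng.permutation(p.labels), patients=p.patients)
                for p in partitions]
        reps.append(coassignment(perm)[off].mean())
    return float(np.mean(reps))


def _best_louvain(G: nx.Graph, n_restarts: int, rng: np.random.Generator,
                  resolution: float = 1.0) -> list[np.ndarray]:
    """Run seeded Louvain ``n_restarts`` times; return the label arrays."""
    n = G.number_of_nodes()
    runs = []
    for _ in range(n_restarts):
        seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed)
        labels = np.empty(n, dtype=int)
        for ci, members in enumerate(comms):
            for node in members:
                labels[node] = ci
        runs.append(labels)
    return runs


def consensus_partition(
    C: np.ndarray,
    threshold: float,
    seed: int = 0,
    n_restarts: int = 100,
    max_rounds: int = 20,
    resolution: float = 1.0,
    patients: list[str] | None = None,
) -> Partition:
    """Iterative Louvain consensus over a thresholded co-assignment matrix.

    Entries at or below ``threshold`` are zeroed; the remaining weighted
    graph is clustered by Louvain modularity maximization with
    ``n_restarts`` seeded restarts. If the restarts disagree, their own
    co-assignment matrix (thresholded the same way) becomes the next
    round's graph, until all restarts return an identical partition or
    ``max_rounds`` is hit — in which case the best-modularity partition of
    the final round is returned. The cluster count is emergent.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    rng = np.random.default_rng(seed)
    patients = patients or [str(i) for i in range(n)]

    mat = C.copy()
    for rnd in range(max_rounds):
        mat = np.where(mat > threshold, mat, 0.0)
        np.fill_diagonal(mat, 0.0)
        if not mat.any():
            raise ValueError(
                "thresholded co-assignment matrix is fully disconnected")
        G = nx.from_numpy_array(mat)
        runs = _best_louvain(G, n_restarts, rng, resolution)
        canon = [tuple(_occurrence_canon(r)) for r in runs]
        if len(set(canon)) == 1:
            return Partition(labels=_canonical_labels(runs[0]), patients=patients,
                             k=None, source="consensus")
        logger.debug("consensus round %d: %d distinct restarts", rnd + 1,
                     len(set(canon)))
        mat = coassignment([Partition(labels=r, patients=patients) for r in runs])
    # did not stabilize: return the best-modularity partition of the last round
    model = ModularityModel.from_affinity(np.where(C > threshold, C, 0.0))
    best = max(runs, key=lambda r: modularity(model, r))
    logger.warning("consensus did not stabilize in %d rounds; returning "
                   "best-modularity partition", max_rounds)
    return Partition(labels=_canonical_labels(best), patients=patients,
                     k=None, source="consensus")


def _occurrence_canon(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters in order of first occurrence (label-permutation invariant)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, v in enumerate(labels):
        out[i] = mapping.setdefault(int(v), len(mapping))
    return out


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by decreasing size (deterministic presentation)."""
    vals, counts = np.unique(labels, return_counts=True)
    order = vals[np.argsort(-counts, kind="stable")]
    mapping = {v: i for i, v in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


def nmi(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Normalization is the arithmetic mean of the two label entropies. A
    zero-entropy (single-cluster) partition returns 0 by convention.
    """
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same patients")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        logger.debug("nmi: zero-entropy partition; returning 0 by convention")
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


@dataclass
class ModularityModel:
    """Observed similarity A, degree-product null P_exp, and B = A - P_exp."""

    A: np.ndarray
    P_exp: np.ndarray
    B: np.ndarray
    total_weight: float

    @classmethod
    def from_affinity(cls, A: np.ndarray) -> "ModularityModel":
        A = np.asarray(A, dtype=float)
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if (A < 0).any():
            raise ValueError("similarity matrix must be nonnegative")
        two_m = A.sum()
        if two_m <= 0:
            raise ValueError("similarity matrix has zero total weight")
        deg = A.sum(axis=1)
        P_exp = np.outer(deg, deg) / two_m
        return cls(A=A, P_exp=P_exp, B=A - P_exp, total_weight=two_m)


def modularity(model: ModularityModel | np.ndarray,
               p: Partition | np.ndarray) -> float:
    """Newman–Girvan modularity Q of a partition on a weighted network.

    Q = sum_ij B_ij * [sigma_i == sigma_j] / total weight, with
    B = A - deg deg^T / total. Q lies in [-1, 1]; a single all-patients
    cluster scores exactly 0 under the degree-product null.
    """
    if not isinstance(model, ModularityModel):
        model = ModularityModel.from_affinity(np.asarray(model))
    labels = p.labels if isinstance(p, Partition) else np.asarray(p)
    if len(labels) != model.A.shape[0]:
        raise ValueError("partition length does not match network size")
    same = labels[:, None] == labels[None, :]
    return float(model.B[same].sum() / model.total_weight)


def modularity_pvalue(
    model: ModularityModel | np.ndarray,
    p: Partition | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for Q: labels shuffled across patients.

    Returns (Q observed, p), with p = (1 + #{Q_perm >= Q_obs}) / (n_perm + 1).
    """
    if not isinstance(model, ModularityModel):
        model = ModularityModel.from_affinity(np.asarray(model))
    labels = p.labels if isinstance(p, Partition) else np.asarray(p)
    rng = np.random.default_rng(seed)
    q_obs = modularity(model, labels)
    count = sum(modularity(model, rng.permutation(labels)) >= q_obs
                for _ in range(n_perm))
    return q_obs, (1.0 + count) / (n_perm + 1.0)
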