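"""Similarity network fusion.

Each modality's affinity matrix W is split into two normalized views: a full
transition matrix P carrying similarity to *all* other patients, and a
sparse local kernel S carrying similarity only to each patient's K nearest
neighbors. Fusion then iteratively diffuses each modality's full view
through the average of the other modalities' views, restricted to local
neighborhoods:

    P^(v)  <-  S^(v) @ mean_{k != v}(P^(k)) @ S^(v).T

After every sweep each P is re-normalized (half the mass on the diagonal,
half spread over the off-diagonal in proportion to similarity), which keeps
the iteration row-stochastic and numerically stable. The local kernels S
are computed once from the inputs and never updated. The fused network is
the symmetrized average of the final transition matrices.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .affinity import affinity_kernel, kernel_grid, squared_euclidean
from .datatypes import AffinityMatrix, FusedNetwork, ModalityTable

logger = logging.getLogger(__name__)

__all__ = ["FusionState", "normalize_full", "normalize_local", "snf",
           "grid_fuse", "write_grid"]


@dataclass
class FusionState:
    """Internal state of the fusion: per-modality transition matrices.

    ``P_list`` holds the full transition matrix of each modality after the
    last executed iteration (each row sums to 1: half on the diagonal, half
    spread over the off-diagonal); ``S_list`` the fixed sparse local
    kernels (each row sums to 1 with at most K+1 nonzeros when the
    neighborhood includes the node itself).
    """

    P_list: list[np.ndarray]
    S_list: list[np.ndarray]
    m: int
    iteration: int
    max_iter: int


def normalize_full(W: np.ndarray | AffinityMatrix) -> np.ndarray:
    """Full transition matrix P: diagonal 1/2, off-diagonal row-normalized to 1/2.

    P(i, j) = W(i, j) / (2 * sum_{k != i} W(i, k)) for j != i, P(i, i) = 1/2.
    The half/half split sidesteps the self-similarity instability of a plain
    row normalization. Every row sums to exactly 1.
    """
    W = W.values if isinstance(W, AffinityMatrix) else np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if (row <= 0).any():
        bad = np.where(row <= 0)[0].tolist()
        raise ValueError(f"rows {bad} have nonpositive off-diagonal sums")
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def normalize_local(
    W: np.ndarray | AffinityMatrix,
    K: int,
    include_self: bool = True,
) -> np.ndarray:
    """Sparse local kernel S: each row keeps only the K-nearest-neighbor mass.

    S(i, j) = W(i, j) / sum_{k in N_i} W(i, k) if j in N_i, else 0. By
    default the neighbor set N_i includes i itself (self-similarity is
    maximal), so each row has up to K+1 nonzeros. Ties at the K-th neighbor
    are all kept, which makes the result independent of sort order.
    """
    W = W.values if isinstance(W, AffinityMatrix) else np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (1 <= K < n):
        raise ValueError(f"K must satisfy 1 <= K < n={n}, got {K}")
    masked = W.copy()
    if include_self:
        # ensure the self-edge always survives by treating it as +inf
        np.fill_diagonal(masked, np.inf)
    else:
        np.fill_diagonal(masked, -np.inf)
    # threshold = K-th largest masked value per row; keep ties
    kth = np.sort(masked, axis=1)[:, -(K + (1 if include_self else 0))]
    keep = masked >= kth[:, None]
    n_ties = int(keep.sum() - (K + (1 if include_self else 0)) * n)
    if n_ties > 0:
        logger.debug("normalize_local kept %d tied neighbor entries beyond K", n_ties)
    S = np.where(keep, W, 0.0)
    if include_self:
        np.fill_diagonal(S, np.diag(W))
    row = S.sum(axis=1)
    if (row <= 0).any():
        bad = np.where(row <= 0)[0].tolist()
        raise ValueError(f"rows {bad} have nonpositive neighbor sums")
    return S / row[:, None]


def snf(
    W_list: list[AffinityMatrix] | list[np.ndarray],
    K: int,
    max_iter: int = 20,
    tol: float = 1e-6,
    include_self: bool = True,
    return_state: bool = False,
) -> FusedNetwork | tuple[FusedNetwork, FusionState]:
    """Fuse per-modality similarity networks into one patient network.

    Iterates the cross-network diffusion update for at most ``max_iter``
    sweeps, stopping early once the mean absolute change of the averaged
    transition matrix falls below ``tol``. ``max_iter=0`` returns the
    average of the initial normalized networks (no message passing). A
    single input network is returned normalized and symmetrized unchanged.
    """
    if not W_list:
        raise ValueError("need at least one affinity matrix")
    patients = None
    mats = []
    for W in W_list:
        if isinstance(W, AffinityMatrix):
            if patients is None:
                patients = W.patients
            elif W.patients != patients:
                raise ValueError("affinity matrices have mismatched patient orderings")
            mats.append(W.values)
        else:
            mats.append(np.asarray(W, dtype=float))
    n = mats[0].shape[0]
    if patients is None:
        patients = [str(i) for i in range(n)]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all affinity matrices must share the same shape")
    m = len(mats)

    P_list = [normalize_full(W) for W in mats]
    if m == 1:
        F = (P_list[0] + P_list[0].T) / 2.0
        out = FusedNetwork(values=F, patients=patients, K=K, iterations=0)
        if return_state:
            return out, FusionState(P_list=P_list, S_list=[], m=1,
                                    iteration=0, max_iter=max_iter)
        return out
    S_list = [normalize_local(W, K, include_self=include_self) for W in mats]

    prev_avg = sum(P_list) / m
    iterations = 0
    for it in range(max_iter):
        P_sum = sum(P_list)
        new_list = []
        for v in range(m):
            others = (P_sum - P_list[v]) / (m - 1)
            new = S_list[v] @ others @ S_list[v].T
            new_list.append(normalize_full((new + new.T) / 2.0))
        P_list = new_list
        iterations = it + 1
        avg = sum(P_list) / m
        delta = np.abs(avg - prev_avg).mean()
        prev_avg = avg
        if delta < tol:
            break

    F = sum(P_list) / m
    F = (F + F.T) / 2.0
    out = FusedNetwork(values=F, patients=patients, K=K, iterations=iterations)
    if return_state:
        return out, FusionState(P_list=P_list, S_list=S_list, m=m,
                                iteration=iterations, max_iter=max_iter)
    return out


def grid_fuse(
    tables: list[ModalityTable],
    K_values=None,
    mu_values=None,
    max_iter: int = 20,
    metric: str = "sqeuclidean",
    squared_means: bool = True,
) -> dict[tuple[int, float], FusedNetwork]:
    """Fuse the modalities at every (K, mu) combination of the grid.

    Distance matrices are computed once per modality; each grid cell then
    builds its kernels and runs the fusion independently, so the map's
    contents do not depend on evaluation order.
    """
    if K_values is None or mu_values is None:
        default_K, default_mu = kernel_grid()
        K_values = default_K if K_values is None else K_values
        mu_values = default_mu if mu_values is None else mu_values
    K_values = list(K_values)
    mu_values = list(mu_values)
    if not K_values or not mu_values:
        raise ValueError("K_values and mu_values must be nonempty")

    dists = [squared_euclidean(t, metric=metric) for t in tables]
    out: dict[tuple[int, float], FusedNetwork] = {}
    for K, mu in itertools.product(K_values, mu_values):
        try:
            W_list = [affinity_kernel(D, K=int(K), mu=float(mu),
                                      squared_means=squared_means) for D in dists]
            fused = snf(W_list, K=int(K), max_iter=max_iter)
        except Exception as exc:  # annotate the offending cell
            raise RuntimeError(f"grid cell (K={K}, mu={mu}) failed: {exc}") from exc
        fused.mu = float(mu)
        out[(int(K), float(mu))] = fused
    return out


def write_grid(grid: dict[tuple[int, float], FusedNetwork], outdir: str | Path) -> Path:
    """Persist one fused network per grid cell plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for (K, mu), net in sorted(grid.items()):
        cell = f"K{K:03d}_mu{mu:08.4f}"
        path = outdir / f"fused_{cell}.tsv"
        net.write_tsv(path)
        manifest.append({"K": K, "mu": mu, "iterations": net.iterations,
                         "path": path.name})
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps({"cells": manifest}, indent=2))
    return mpath
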