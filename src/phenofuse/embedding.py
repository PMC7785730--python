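"""Continuous patient representation: diffusion-map phenotypic axes.

Each retained fused network is sparsified (per-patient edges below the 90th
weight percentile are dropped), re-expressed as a cosine similarity between
the sparsified neighborhood profiles, and embedded with a diffusion map at
diffusion time t = 0 using the Fokker–Planck density normalization
(alpha = 0.5). The per-cell embeddings are brought into a common frame with
a generalized orthogonal Procrustes analysis (rotations and reflections
only) and averaged into a single set of phenotypic axes. Axis signs are
arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr
from sklearn.metrics.pairwise import cosine_similarity

from .datatypes import Embedding, FusedNetwork, ModalityTable

logger = logging.getLogger(__name__)

__all__ = [
    "threshold_and_cosine", "diffusion_embed", "procrustes_align",
    "AlignedEnsemble", "select_components", "cv_predict",
    "feature_axis_correlations",
]


def threshold_and_cosine(net: FusedNetwork | np.ndarray, pct: float = 90.0) -> np.ndarray:
    """Row-wise percentile sparsification followed by cosine re-similarity.

    For each patient's row, off-diagonal weights below that row's ``pct``-th
    percentile are zeroed (ties at the percentile and the diagonal
    self-weight survive); the possibly asymmetric result is converted back
    to a symmetric affinity by taking cosine similarity between rows.
    """
    W = net.values if isinstance(net, FusedNetwork) else np.asarray(net, float)
    n = W.shape[0]
    if not (0 <= pct < 100):
        raise ValueError(f"pct must lie in [0, 100), got {pct}")
    off_mask = ~np.eye(n, dtype=bool)
    T = np.zeros_like(W)
    for i in range(n):
        row_off = W[i, off_mask[i]]
        thr = np.percentile(row_off, pct)
        keep = (W[i] >= thr) & off_mask[i]
        T[i, keep] = W[i, keep]
        T[i, i] = W[i, i]
    norms = np.linalg.norm(T, axis=1)
    if (norms == 0).any():
        bad = np.where(norms == 0)[0].tolist()
        raise ValueError(f"rows {bad} are all-zero after thresholding")
    C = cosine_similarity(T)
    C = np.clip((C + C.T) / 2.0, 0.0, None)
    return C


def diffusion_embed(
    aff: np.ndarray,
    alpha: float = 0.5,
    t: float = 0.0,
    n_components: int = 10,
    patients: list[str] | None = None,
    source=None,
) -> Embedding:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    The affinity is density-normalized with anisotropic exponent ``alpha``
    (0.5 approximates Fokker–Planck diffusion), converted to a Markov
    transition operator, and eigendecomposed through its symmetric
    conjugate. The trivial constant eigenvector is dropped. At t = 0 each
    component c is scaled by lambda_c / (1 - lambda_c), the multiscale
    convention emphasizing global structure; for t > 0 the scale is
    lambda_c ** t. ``var_explained`` is each retained eigenvalue's share of
    the leading nontrivial spectrum.
    """
    A = np.asarray(aff, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("affinity must be a symmetric square matrix")
    if (A < 0).any():
        raise ValueError("affinity must be nonnegative")
    n_conn, _ = connected_components((A > 0).astype(int), directed=False)
    if n_conn > 1:
        raise ValueError(f"affinity graph is disconnected ({n_conn} components)")

    d = A.sum(axis=1)
    if alpha > 0:
        A = A / np.outer(d**alpha, d**alpha)
        d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    M = inv_sqrt[:, None] * A * inv_sqrt[None, :]
    M = (M + M.T) / 2.0

    n_keep = min(n_components + 1, n)
    vals, vecs = eigh(M, subset_by_index=[n - n_keep, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # right eigenvectors of the transition operator, gauge-fixed so the
    # trivial eigenvector is the constant 1
    psi = inv_sqrt[:, None] * vecs
    psi = psi / psi[:, [0]]

    lam = vals[1:]
    comps = psi[:, 1:]
    if np.ptp(lam) < 1e-10:
        logger.warning("diffusion_embed: degenerate flat spectrum; embedding "
                       "carries no preferred axes")
    if t == 0:
        scale = lam / np.maximum(1.0 - lam, 1e-12)
    else:
        scale = np.sign(lam) * np.abs(lam) ** t
    coords = comps * scale[None, :]

    pos = np.maximum(lam, 0.0)
    total = pos.sum()
    if total > 1e-12:
        var = pos / total
    else:  # flat spectrum: no axis explains anything, report equal shares
        var = np.full_like(pos, 1.0 / max(len(pos), 1))
    return Embedding(coords=coords, patients=patients or [str(i) for i in range(n)],
                     var_explained=var, t=t, alpha=alpha, source=source)


def _sign_fix(X: np.ndarray) -> np.ndarray:
    """Flip each column so its absolute-maximum coordinate is positive."""
    idx = np.argmax(np.abs(X), axis=0)
    signs = np.sign(X[idx, np.arange(X.shape[1])])
    signs[signs == 0] = 1.0
    return X * signs[None, :]


@dataclass
class AlignedEnsemble:
    """Procrustes-aligned embeddings, their alignment target, and their mean."""

    embeddings: list[Embedding]
    reference: np.ndarray
    mean: Embedding


def procrustes_align(
    ensemble: list[Embedding],
    tol: float = 1e-9,
    max_iter: int = 100,
) -> AlignedEnsemble:
    """Generalized orthogonal Procrustes alignment to an iterated mean.

    Each member is rotated/reflected (no scaling, no translation) to the
    evolving mean configuration until the mean moves less than ``tol``.
    Before alignment each member's columns are sign-fixed (absolute-maximum
    coordinate positive), which stabilizes the otherwise arbitrary axis
    orientations. The returned mean embedding averages the aligned members;
    its variance-explained profile is the member average.
    """
    if len(ensemble) < 2:
        raise ValueError("generalized Procrustes needs at least 2 embeddings")
    shape = ensemble[0].coords.shape
    patients = ensemble[0].patients
    for e in ensemble[1:]:
        if e.coords.shape != shape:
            raise ValueError("all embeddings must share shape "
                             f"({shape} vs {e.coords.shape})")
        if e.patients != patients:
            raise ValueError("all embeddings must share patient ordering")
    mats = [_sign_fix(e.coords.copy()) for e in ensemble]
    for i, X in enumerate(mats):
        if np.linalg.matrix_rank(X) < min(X.shape):
            logger.warning("procrustes_align: member %d is rank-deficient", i)

    ref = mats[0].copy()
    aligned = mats
    for _ in range(max_iter):
        aligned = []
        for X in mats:
            R, _ = orthogonal_procrustes(X, ref)
            aligned.append(X @ R)
        new_ref = np.mean(aligned, axis=0)
        shift = np.abs(new_ref - ref).max()
        ref = new_ref
        if shift < tol:
            break

    var = np.mean([e.var_explained for e in ensemble], axis=0)
    var = np.sort(var)[::-1]
    out_members = [
        Embedding(coords=X, patients=patients, var_explained=var,
                  t=ensemble[i].t, alpha=ensemble[i].alpha,
                  source=ensemble[i].source)
        for i, X in enumerate(aligned)
    ]
    mean_emb = Embedding(coords=ref, patients=patients, var_explained=var,
                         t=ensemble[0].t, alpha=ensemble[0].alpha,
                         source="aligned-mean")
    return AlignedEnsemble(embeddings=out_members, reference=ref, mean=mean_emb)


def select_components(E: Embedding, cum_var: float = 0.10) -> Embedding:
    """Smallest leading component set reaching the cumulative variance cutoff."""
    if not (0 < cum_var <= 1):
        raise ValueError(f"cum_var must lie in (0, 1], got {cum_var}")
    csum = np.cumsum(E.var_explained)
    reached = np.nonzero(csum >= cum_var - 1e-12)[0]
    n_keep = int(reached[0]) + 1 if len(reached) else E.n_components
    return Embedding(coords=E.coords[:, :n_keep], patients=E.patients,
                     var_explained=E.var_explained[:n_keep], t=E.t,
                     alpha=E.alpha, source=E.source)


def cv_predict(
    E: Embedding,
    scores: np.ndarray,
    n_folds: int = 5,
    n_dims: int = 5,
    seed: int = 0,
) -> dict:
    """Cross-validated linear prediction of a held-out clinical score.

    Patients are shuffled (seeded) into ``n_folds`` near-equal folds; an
    ordinary least squares model with intercept on the first ``n_dims``
    embedding dimensions is fit on the training folds and its predictions
    are Pearson-correlated with the actual held-out scores. Returns per-fold
    correlations plus their mean and SD.
    """
    y = np.asarray(scores, dtype=float)
    n = len(y)
    if n != E.coords.shape[0]:
        raise ValueError("scores must cover the embedding's patients")
    if np.isnan(y).any():
        raise ValueError("scores must be complete (no missing values)")
    if n_dims > E.n_components:
        raise ValueError(f"n_dims={n_dims} exceeds available components "
                         f"({E.n_components})")
    X = np.column_stack([np.ones(n), E.coords[:, :n_dims]])
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_folds)
    rs = []
    for f, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
        pred = X[test] @ beta
        if np.std(y[test]) == 0:
            raise ValueError(f"fold {f} has zero score variance")
        rs.append(float(pearsonr(pred, y[test])[0]))
    return {"fold_r": rs, "mean_r": float(np.mean(rs)), "sd_r": float(np.std(rs)),
            "n_folds": n_folds, "n_dims": n_dims, "seed": seed}


def feature_axis_correlations(
    tables: list[ModalityTable],
    E: Embedding,
) -> "pd.DataFrame":
    """Pearson correlation of every input feature with every embedding axis.

    Returns a tidy frame (modality, feature, dimension, r) sorted by |r|
    within each dimension — the workflow for naming what each phenotypic
    axis tracks.
    """
    import pandas as pd

    rows = []
    coords = E.coords
    for t in tables:
        X = t.values
        for j, feat in enumerate(t.features):
            x = X[:, j]
            sx = x - x.mean()
            denom_x = np.sqrt((sx**2).sum())
            for c in range(coords.shape[1]):
                yc = coords[:, c] - coords[:, c].mean()
                denom = denom_x * np.sqrt((yc**2).sum())
                r = float(sx @ yc / denom) if denom > 0 else np.nan
                rows.append({"modality": t.name, "feature": feat,
                             "dimension": c + 1, "r": r})
    df = pd.DataFrame(rows)
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(["dimension", "abs_r"], ascending=[True, False])
    return df.drop(columns="abs_r").reset_index(drop=True)
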