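"""Biotype characterization statistics.

Which input features discriminate the consensus subgroups (one-way ANOVAs
with Benjamini–Hochberg FDR across all features jointly), and how much each
single modality agrees with the multimodal solution (per-modality NMI and
modularity concordance — the dimensionality-balance comparison between
fusion and plain concatenation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .affinity import affinity_kernel, squared_euclidean
from .consensus import ModularityModel, modularity, nmi, spectral_cluster
from .datatypes import ModalityTable, Partition
from .fusion import snf

__all__ = ["anova_by_group", "modality_concordance", "balance_comparison"]


def anova_by_group(
    tables: list[ModalityTable],
    p: Partition,
    q_thresh: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-feature one-way ANOVA across consensus groups, BH-corrected jointly.

    Returns one row per feature with the F statistic, raw p, BH q over all
    features of all modalities pooled, per-group means, and a significance
    flag at ``q < q_thresh``. ``welch=True`` drops the equal-variance
    assumption. Features with zero variance within every group are reported
    with F = 0 and p = 1 rather than an error.
    """
    labels = p.labels
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("partition must have at least 2 groups")
    counts = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups {small} have fewer than 2 members")

    rows = []
    for t in tables:
        if t.patients != p.patients:
            raise ValueError(f"modality {t.name!r} patients do not match partition")
        X = t.values
        for j, feat in enumerate(t.features):
            samples = [X[labels == g, j] for g in groups]
            if all(np.ptp(s) == 0 for s in samples) and \
                    np.ptp([s[0] for s in samples]) == 0:
                F, pval = 0.0, 1.0
            elif welch:
                res = stats.alexandergovern(*samples)
                F, pval = float(res.statistic), float(res.pvalue)
            else:
                F, pval = stats.f_oneway(*samples)
            row = {"modality": t.name, "feature": feat, "F": float(F),
                   "p": float(pval)}
            for g in groups:
                row[f"mean_g{g}"] = float(np.mean(X[labels == g, j]))
            rows.append(row)
    df = pd.DataFrame(rows)
    _, q, *_ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] < q_thresh
    return df.sort_values("q", kind="stable").reset_index(drop=True)


def modality_concordance(
    multimodal_p: Partition,
    tables: list[ModalityTable],
    K: int,
    mu: float,
    k: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-modality agreement with a multimodal partition.

    For each modality: build its unimodal affinity at the same kernel
    settings, spectrally cluster it at the same cluster count, and report
    NMI(unimodal, multimodal); also apply the multimodal partition directly
    to the unimodal network and report its modularity there.
    """
    k = k or multimodal_p.n_clusters
    rows = []
    for t in tables:
        if t.patients != multimodal_p.patients:
            raise ValueError(f"modality {t.name!r} patients do not match partition")
        W = affinity_kernel(squared_euclidean(t), K=K, mu=mu)
        uni = spectral_cluster(W, k=k, seed=seed)
        model = ModularityModel.from_affinity(W.values)
        rows.append({
            "modality": t.name,
            "nmi": nmi(uni, multimodal_p),
            "modularity": modularity(model, multimodal_p),
            "unimodal_modularity": modularity(model, uni),
        })
    return pd.DataFrame(rows)


def balance_comparison(
    tables: list[ModalityTable],
    snf_partition: Partition,
    concat_partition: Partition,
    K: int,
    mu: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Dimensionality-balance contrast between fusion and concatenation.

    Computes the per-modality NMI concordance table for both multimodal
    partitions and their ranges (max - min across modalities): a smaller
    range means the integration treats modalities of unequal feature
    counts more evenly.
    """
    out = []
    for method, part in (("snf", snf_partition), ("concat", concat_partition)):
        tab = modality_concordance(part, tables, K=K, mu=mu,
                                   k=part.n_clusters, seed=seed)
        tab.insert(0, "method", method)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
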