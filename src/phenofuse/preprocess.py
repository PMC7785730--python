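"""Data cleaning chain.

Fixed stage order: missingness filters -> robust outlier removal -> median
imputation -> empirical-Bayes batch adjustment -> residualization against
covariate effects estimated in healthy controls -> z-scoring. Subjects
dropped in any modality are dropped from all modalities, so every stage
downstream of the filters sees a common patient set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CleaningReport, ModalityTable

logger = logging.getLogger(__name__)

__all__ = [
    "filter_missing", "remove_outliers", "impute_median", "adjust_batch",
    "make_design", "residualize_on_controls", "zscore_patients",
    "clean_pipeline",
]

MAD_SCALE = 1.4826  # consistency constant: MAD -> SD under normality


def filter_missing(
    table: ModalityTable,
    feature_thresh: float = 0.2,
    subject_thresh: float = 0.2,
) -> tuple[ModalityTable, CleaningReport]:
    """Drop features, then subjects, with too much missing data.

    Features missing in >= ``feature_thresh`` of subjects are removed
    first; subjects missing >= ``subject_thresh`` of the *remaining*
    features are removed second. Both thresholds are inclusive.
    """
    for name, thr in (("feature_thresh", feature_thresh),
                      ("subject_thresh", subject_thresh)):
        if not (0 < thr <= 1):
            raise ValueError(f"{name} must lie in (0, 1], got {thr}")
    df = table.data
    feat_frac = df.isna().mean(axis=0)
    bad_feats = feat_frac[feat_frac >= feature_thresh].index.tolist()
    kept = df.drop(columns=bad_feats)
    if kept.shape[1] == 0:
        raise ValueError(
            f"modality {table.name!r}: all features dropped at the "
            "feature-missingness stage")
    subj_frac = kept.isna().mean(axis=1)
    bad_subj = subj_frac[subj_frac >= subject_thresh].index.tolist()
    kept = kept.drop(index=bad_subj)
    if kept.shape[0] == 0:
        raise ValueError(
            f"modality {table.name!r}: all subjects dropped at the "
            "subject-missingness stage")
    report = CleaningReport(
        dropped_features={table.name: [str(f) for f in bad_feats]},
        dropped_subjects={str(s): "missingness" for s in bad_subj},
    )
    return ModalityTable(name=table.name, data=kept), report


def outlier_scores(table: ModalityTable, n_mads: float = 5.0) -> pd.Series:
    """Fraction of features on which each subject deviates > n_mads robust SDs.

    Deviation is |x - median| / (1.4826 * MAD) per feature; features with
    zero MAD are skipped. Missing cells never count as deviant.
    """
    if n_mads <= 0:
        raise ValueError(f"n_mads must be positive, got {n_mads}")
    X = table.values
    med = np.nanmedian(X, axis=0)
    mad = MAD_SCALE * np.nanmedian(np.abs(X - med), axis=0)
    usable = mad > 0
    if not usable.any():
        return pd.Series(0.0, index=table.data.index)
    with np.errstate(invalid="ignore"):
        dev = np.abs(X[:, usable] - med[usable]) / mad[usable]
    flags = (dev > n_mads) & ~np.isnan(dev)
    return pd.Series(flags.mean(axis=1), index=table.data.index)


def remove_outliers(
    table: ModalityTable,
    n_mads: float = 5.0,
    flag_fraction: float = 0.1,
) -> tuple[ModalityTable, CleaningReport]:
    """Drop subjects whose robust deviation score flags them as outliers.

    A subject is an outlier when more than ``flag_fraction`` of (usable)
    features deviate from the feature median by more than ``n_mads`` robust
    SDs. With all-constant features (zero MAD everywhere) nobody is flagged.
    """
    if table.shape[0] < 3:
        raise ValueError("outlier screening needs at least 3 subjects")
    scores = outlier_scores(table, n_mads=n_mads)
    bad = scores[scores > flag_fraction].index.tolist()
    kept = table.data.drop(index=bad)
    if kept.shape[0] == 0:
        raise ValueError(f"modality {table.name!r}: all subjects flagged as outliers")
    report = CleaningReport(dropped_subjects={str(s): "outlier" for s in bad})
    return ModalityTable(name=table.name, data=kept), report


def impute_median(table: ModalityTable) -> tuple[ModalityTable, CleaningReport]:
    """Fill missing cells with the per-feature median across subjects."""
    df = table.data
    fully_missing = df.columns[df.isna().all(axis=0)].tolist()
    if fully_missing:
        raise ValueError(
            f"modality {table.name!r}: features {fully_missing} have no "
            "observed values; run filter_missing first")
    n_missing = int(df.isna().sum().sum())
    filled = df.fillna(df.median(axis=0))
    report = CleaningReport(imputed_cells={table.name: n_missing})
    return ModalityTable(name=table.name, data=filled), report


def adjust_batch(
    table: ModalityTable,
    batch: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    shrink: bool = True,
) -> ModalityTable:
    """Parametric empirical-Bayes location/scale batch adjustment (ComBat).

    Per feature, additive and multiplicative batch effects are estimated
    jointly with (protected) covariate effects, shrunk across features
    toward common per-batch priors — normal for locations, inverse-gamma
    for scales, solved by the standard iterative conditional means — and
    removed. Covariate-associated variation is restored untouched.

    ``shrink=False`` skips the empirical-Bayes pooling and removes the raw
    per-feature location/scale estimates, which equalizes per-batch feature
    means exactly (useful for small feature panels where cross-feature
    pooling has little to borrow).
    """
    df = table.data
    n, p = df.shape
    batch = pd.Series(np.asarray(batch), index=df.index) if not isinstance(
        batch, pd.Series) else batch.reindex(df.index)
    if batch.isna().any():
        raise ValueError("batch labels missing for some subjects")
    levels, counts = np.unique(batch.to_numpy(), return_counts=True)
    if len(levels) < 2:
        raise ValueError(f"batch adjustment needs >= 2 batches, got "
                         f"{len(levels)} ({levels.tolist()})")
    singles = levels[counts < 2].tolist()
    if singles:
        raise ValueError(f"singleton batches not supported: {singles}")

    Y = df.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("impute missing cells before batch adjustment")
    n_batch = len(levels)
    onehot = (batch.to_numpy()[:, None] == levels[None, :]).astype(float)

    if covariates is not None:
        C = covariates.reindex(df.index).to_numpy(dtype=float)
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("covariate design is rank deficient")
        # drop any covariate column confounded with the batch indicators
        X = np.hstack([onehot, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariates are collinear with batch indicators")
    else:
        C = np.zeros((n, 0))
        X = onehot

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    gamma_hat_ls = beta[:n_batch]                  # per-batch feature means
    beta_cov = beta[n_batch:]
    prop = counts / n
    alpha = prop @ gamma_hat_ls                    # weighted grand mean
    fitted_no_batch = np.outer(np.ones(n), alpha) + C @ beta_cov
    resid = Y - (onehot @ gamma_hat_ls + C @ beta_cov)
    var_pooled = (resid**2).sum(axis=0) / n
    var_pooled = np.maximum(var_pooled, 1e-12)

    Z = (Y - fitted_no_batch) / np.sqrt(var_pooled)

    # batch effect estimates on standardized data
    gamma_hat = np.linalg.lstsq(onehot, Z, rcond=None)[0]
    delta_hat = np.empty((n_batch, p))
    for b in range(n_batch):
        zb = Z[onehot[:, b] == 1]
        delta_hat[b] = zb.var(axis=0, ddof=1)

    if not shrink:
        adj = (Z - onehot @ gamma_hat) / np.sqrt(onehot @ np.maximum(
            delta_hat, 1e-12))
        out = adj * np.sqrt(var_pooled) + fitted_no_batch
        return ModalityTable(name=table.name,
                             data=pd.DataFrame(out, index=df.index,
                                               columns=df.columns))

    # method-of-moments hyperpriors across features
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    v = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2 + v**2) / np.maximum(s2, 1e-12)
    b_prior = (v * s2 + v**3) / np.maximum(s2, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(n_batch):
        nb = counts[b]
        zb = Z[onehot[:, b] == 1]
        g, d = gamma_hat[b].copy(), delta_hat[b].copy()
        for _ in range(100):
            g_new = (nb * tau2[b] * gamma_hat[b] + d * gamma_bar[b]) / (
                nb * tau2[b] + d)
            ss = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (b_prior[b] + 0.5 * ss) / (nb / 2.0 + a_prior[b] - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            if (np.abs(g_new - g).max() < 1e-8
                    and np.abs(d_new - d).max() < 1e-8):
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        gamma_star[b], delta_star[b] = g, d

    adj = (Z - onehot @ gamma_star) / np.sqrt(onehot @ delta_star)
    out = adj * np.sqrt(var_pooled) + fitted_no_batch
    return ModalityTable(name=table.name,
                         data=pd.DataFrame(out, index=df.index, columns=df.columns))


def make_design(
    covariates: pd.DataFrame,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Residualization design: intercept, age, sex, age x sex (+ extras).

    Age is centered at the sample mean of the supplied frame so the
    intercept is interpretable; sex is centered at 0.5.
    """
    age = covariates["age"].astype(float)
    sex = covariates["sex"].astype(float)
    design = pd.DataFrame({
        "intercept": 1.0,
        "age": age,
        "sex": sex,
        "age_sex": age * sex,
    }, index=covariates.index)
    if extra is not None:
        design = design.join(extra.astype(float))
    return design


def residualize_on_controls(
    patients: ModalityTable,
    controls: ModalityTable,
    patient_design: pd.DataFrame,
    control_design: pd.DataFrame,
) -> ModalityTable:
    """Remove covariate effects estimated by OLS in healthy controls.

    Per feature, coefficients are fit on controls only; patient residuals
    are the patient values minus the control-fitted predictions, so any
    disease-specific offset beyond the covariate effects is preserved.
    """
    if list(patient_design.columns) != list(control_design.columns):
        raise ValueError("patient and control designs must share columns")
    Xc = control_design.reindex(controls.data.index).to_numpy(dtype=float)
    Xp = patient_design.reindex(patients.data.index).to_numpy(dtype=float)
    if np.isnan(Xc).any() or np.isnan(Xp).any():
        raise ValueError("design has missing covariate values")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise ValueError(f"control design is rank deficient (rank {rank} < "
                         f"{Xc.shape[1]} columns)")
    if Xc.shape[0] <= Xc.shape[1]:
        raise ValueError("control sample must exceed the design rank")
    Yc = controls.values
    Yp = patients.values
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yp - Xp @ beta
    return ModalityTable(name=patients.name,
                         data=pd.DataFrame(resid, index=patients.data.index,
                                           columns=patients.data.columns))


def zscore_patients(table: ModalityTable, ddof: int = 1) -> ModalityTable:
    """Center each feature to mean 0 and scale to unit (sample) SD."""
    df = table.data
    sd = df.std(axis=0, ddof=ddof)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"modality {table.name!r}: zero-variance features "
                         f"{dead} cannot be z-scored")
    return ModalityTable(name=table.name, data=(df - df.mean(axis=0)) / sd)


def clean_pipeline(
    tables: list[ModalityTable],
    controls: list[ModalityTable] | None = None,
    patient_covariates: pd.DataFrame | None = None,
    control_covariates: pd.DataFrame | None = None,
    batch: pd.Series | np.ndarray | None = None,
    feature_thresh: float = 0.2,
    subject_thresh: float = 0.2,
    n_mads: float = 5.0,
    flag_fraction: float = 0.1,
) -> tuple[list[ModalityTable], CleaningReport]:
    """Run the full cleaning chain over all modalities.

    Subject drops (missingness or outliers, assessed per modality) are
    unioned across modalities so every output table covers the same
    patients. Batch adjustment runs only when ``batch`` has >= 2 levels
    among the surviving patients; residualization only when control tables
    and covariates are supplied.
    """
    report = CleaningReport()
    filtered = []
    for t in tables:
        ft, rep = filter_missing(t, feature_thresh, subject_thresh)
        report = report.merge(rep)
        filtered.append(ft)

    dropped = set(report.dropped_subjects)
    for t in filtered:
        scores = outlier_scores(t, n_mads=n_mads)
        bad = scores[scores > flag_fraction].index
        for s in bad:
            if str(s) not in dropped:
                report.dropped_subjects[str(s)] = "outlier"
        dropped |= {str(s) for s in bad}

    cleaned = []
    for t in filtered:
        keep = [p for p in t.data.index if str(p) not in dropped]
        trimmed = ModalityTable(name=t.name, data=t.data.loc[keep])
        imputed, rep = impute_median(trimmed)
        report = report.merge(rep)
        cleaned.append(imputed)

    survivors = cleaned[0].data.index
    if batch is not None:
        b = pd.Series(np.asarray(batch), index=tables[0].data.index)
        b = b.loc[survivors]
        if b.nunique() >= 2:
            cov = None
            if patient_covariates is not None:
                cov = make_design(patient_covariates.loc[survivors]
                                  ).drop(columns="intercept")
            cleaned = [adjust_batch(t, b, cov) for t in cleaned]
        else:
            logger.info("single batch among survivors; skipping adjustment")

    if controls is not None and patient_covariates is not None \
            and control_covariates is not None:
        pdes = make_design(patient_covariates.loc[survivors])
        cdes = make_design(control_covariates)
        by_name = {c.name: c for c in controls}
        out = []
        for t in cleaned:
            ctl = by_name[t.name]
            ctl = ModalityTable(name=ctl.name, data=ctl.data[t.features])
            out.append(residualize_on_controls(t, ctl, pdes, cdes))
        cleaned = out

    cleaned = [zscore_patients(t) for t in cleaned]
    return cleaned, report
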