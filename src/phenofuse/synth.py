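"""Synthetic multimodal cohort generator.

Emulates the statistical structure of a multi-source patient dataset: a
handful of modalities with strongly unequal feature counts (tens up to
~1000), a small number of latent subgroups expressed weakly in *every*
modality, a continuous latent severity gradient shared across modalities,
linear age/sex covariate effects common to patients and controls, additive
site/batch offsets, per-feature Gaussian noise, and (optionally) missing
entries and outlier subjects injected by :func:`corrupt_cohort`.

Effect-size convention: ``cluster_sep`` and ``gradient_loading`` are
*modality-level* effect sizes with a mild dimensionality compensation. For
a modality with p features, the expected squared Euclidean separation
between two cluster centroids is

    D^2(p) = EFFECT_BASE * cluster_sep^2 * (2 p) ** EFFECT_DIM_EXPONENT

noise-variance units (the gradient loading vector is scaled analogously,
with expected squared norm D^2/2). The exponent 1/4 sits between "fixed
total signal" (exponent 0, under which a wide table contributes nothing —
its distance noise grows like sqrt(p)) and "fixed per-feature signal"
(exponent 1, under which the widest table trivially dominates): each
modality is weakly and *comparably* informative, so no single modality
suffices to recover the subgroups at moderate separations but their fusion
does. Per-feature loadings are drawn once per feature, so signal is
distributed across all features of all modalities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ModalityTable

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "corrupt_cohort",
           "write_cohort"]

#: Age range (years) sampled uniformly for patients and controls.
AGE_RANGE = (45.0, 80.0)

#: Modality-level effect-size convention (see module docstring).
EFFECT_BASE = 1.25
EFFECT_DIM_EXPONENT = 0.25


def _effect_scale(effect: float, p: int) -> float:
    """Per-feature SD of a planted effect direction in a p-feature modality."""
    D2 = EFFECT_BASE * effect**2 * (2 * p) ** EFFECT_DIM_EXPONENT
    return float(np.sqrt(D2 / (2 * p)))


@dataclass
class CohortSpec:
    """Parameters of a synthetic multimodal cohort."""

    n_patients: int = 186
    n_controls: int = 87
    modality_dims: tuple[int, ...] = (68, 16, 12, 6, 30)
    modality_names: tuple[str, ...] | None = None
    n_clusters: int = 3
    cluster_sep: float = 1.5
    gradient_loading: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    n_batches: int = 1
    batch_shift: float = 0.0
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.3, "age_sex": 0.005})
    gradient_cluster_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.modality_dims = tuple(int(d) for d in self.modality_dims)
        if self.modality_names is None:
            self.modality_names = tuple(
                f"modality_{i + 1}" for i in range(len(self.modality_dims)))
        else:
            self.modality_names = tuple(self.modality_names)
        self.validate()

    def validate(self) -> None:
        for name in ("n_patients", "n_controls", "n_clusters", "n_batches"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count, got "
                                 f"{getattr(self, name)}")
        if not self.modality_dims or any(d < 1 for d in self.modality_dims):
            raise ValueError(f"modality_dims must be positive counts, got "
                             f"{self.modality_dims}")
        if len(self.modality_names) != len(self.modality_dims):
            raise ValueError("modality_names must match modality_dims in length")
        for name in ("cluster_sep", "gradient_loading", "noise_sd", "batch_shift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got "
                                 f"{getattr(self, name)}")
        for name in ("missing_rate", "outlier_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {rate}")
        if not (-1.0 <= self.gradient_cluster_corr <= 1.0):
            raise ValueError("gradient_cluster_corr must lie in [-1, 1], got "
                             f"{self.gradient_cluster_corr}")
        if self.n_clusters > self.n_patients:
            raise ValueError("n_clusters cannot exceed n_patients")

    @property
    def n_features(self) -> int:
        return sum(self.modality_dims)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    labels: np.ndarray            # cluster index per patient, in [0, n_clusters)
    gradient: np.ndarray          # latent continuous score per patient
    batch: np.ndarray             # batch index per patient
    covariates: pd.DataFrame      # age, sex per patient (index = patient IDs)
    control_covariates: pd.DataFrame
    outliers: list[str] = field(default_factory=list)  # filled by corrupt_cohort

    def write_tsv(self, path: str | Path) -> None:
        df = self.covariates.copy()
        df["label"] = self.labels
        df["gradient"] = self.gradient
        df["batch"] = self.batch
        df["outlier"] = [int(p in self.outliers) for p in df.index]
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t")


def _covariate_signal(rng: np.random.Generator, cov: pd.DataFrame, p: int,
                      effects: dict) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature linear covariate effects; returns (signal, coef matrix)."""
    age_c = cov["age"].to_numpy() - np.mean(AGE_RANGE)
    sex_c = cov["sex"].to_numpy() - 0.5
    design = np.column_stack([age_c, sex_c, age_c * sex_c])
    scales = np.array([effects.get("age", 0.0), effects.get("sex", 0.0),
                       effects.get("age_sex", 0.0)])
    coefs = rng.normal(size=(3, p)) * scales[:, None]
    return design @ coefs, coefs


def generate_cohort(spec: CohortSpec) -> tuple[list[ModalityTable], GroundTruth]:
    """Generate a clean multimodal cohort with planted structure.

    Returns one table per modality (patients stacked over rows) and the
    ground truth. Controls are returned as separate tables accessible via
    :func:`generate_controls`; see :func:`write_cohort` for the on-disk
    layout. Tables are clean — no missing cells or outliers — until
    :func:`corrupt_cohort` is applied.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_patients, spec.n_clusters

    # balanced cluster assignment, shuffled; every cluster is represented
    labels = np.repeat(np.arange(k), math.ceil(n / k))[:n]
    rng.shuffle(labels)

    gradient = rng.standard_normal(n)
    if spec.gradient_cluster_corr != 0.0:
        # blend in an ordered per-cluster offset to correlate axis and labels
        order = (labels - (k - 1) / 2.0) / max(np.std(labels), 1e-12)
        r = spec.gradient_cluster_corr
        gradient = r * order + np.sqrt(1 - r**2) * gradient

    batch = rng.integers(0, spec.n_batches, size=n)
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    control_ids = [f"C{i + 1:04d}" for i in range(spec.n_controls)]

    cov = pd.DataFrame({
        "age": rng.uniform(*AGE_RANGE, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    }, index=patient_ids)
    ctl_cov = pd.DataFrame({
        "age": rng.uniform(*AGE_RANGE, size=spec.n_controls),
        "sex": rng.integers(0, 2, size=spec.n_controls).astype(float),
    }, index=control_ids)

    tables: list[ModalityTable] = []
    control_tables: list[ModalityTable] = []
    for name, p in zip(spec.modality_names, spec.modality_dims):
        # planted effect directions under the modality-level convention
        centroids = rng.normal(scale=_effect_scale(spec.cluster_sep, p),
                               size=(k, p))
        grad_w = rng.normal(scale=_effect_scale(spec.gradient_loading, p), size=p)
        batch_off = (rng.normal(scale=spec.batch_shift, size=(spec.n_batches, p))
                     if spec.batch_shift > 0 else np.zeros((spec.n_batches, p)))

        cov_signal, coefs = _covariate_signal(rng, cov, p, spec.covariate_effects)
        X = (centroids[labels]
             + gradient[:, None] * grad_w[None, :]
             + cov_signal
             + batch_off[batch]
             + rng.normal(scale=spec.noise_sd, size=(n, p)))

        # controls share the covariate coefficients but carry no disease signal
        ctl_age = ctl_cov["age"].to_numpy() - np.mean(AGE_RANGE)
        ctl_sex = ctl_cov["sex"].to_numpy() - 0.5
        ctl_design = np.column_stack([ctl_age, ctl_sex, ctl_age * ctl_sex])
        Xc = ctl_design @ coefs + rng.normal(scale=spec.noise_sd,
                                             size=(spec.n_controls, p))

        feats = [f"{name}_f{j + 1:04d}" for j in range(p)]
        tables.append(ModalityTable(
            name=name, data=pd.DataFrame(X, index=patient_ids, columns=feats)))
        control_tables.append(ModalityTable(
            name=name, data=pd.DataFrame(Xc, index=control_ids, columns=feats)))

    truth = GroundTruth(labels=labels, gradient=gradient, batch=batch,
                        covariates=cov, control_covariates=ctl_cov)
    truth._control_tables = control_tables  # carried for residualization
    return tables, truth


def generate_controls(truth: GroundTruth) -> list[ModalityTable]:
    """Control tables generated alongside the cohort (residualization reference)."""
    return truth._control_tables


def corrupt_cohort(
    tables: list[ModalityTable],
    truth: GroundTruth,
    spec: CohortSpec,
) -> list[ModalityTable]:
    """Inject missing cells (MCAR) and outlier subjects into generated tables.

    Cells go missing independently at ``spec.missing_rate``. A fixed count
    of ``ceil(outlier_rate * n)`` subjects (when the rate is positive) is
    shifted by well over 10 robust SDs on a random half of the features of
    every modality; the flagged IDs are recorded in ``truth.outliers``.
    The input tables are not modified.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = tables[0].shape[0]
    patient_ids = tables[0].patients

    n_out = math.ceil(spec.outlier_rate * n) if spec.outlier_rate > 0 else 0
    out_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    truth.outliers = [patient_ids[i] for i in out_idx]

    corrupted = []
    for t in tables:
        X = t.values.copy()
        p = X.shape[1]
        for i in out_idx:
            cols = rng.choice(p, size=max(1, p // 2), replace=False)
            med = np.median(X[:, cols], axis=0)
            mad = 1.4826 * np.median(np.abs(X[:, cols] - med), axis=0)
            scale = np.where(mad > 0, mad, np.std(X[:, cols], axis=0) + 1e-12)
            sign = rng.choice([-1.0, 1.0], size=len(cols))
            X[i, cols] += sign * 12.0 * scale
        if spec.missing_rate > 0:
            mask = rng.random(X.shape) < spec.missing_rate
            X = np.where(mask, np.nan, X)
        corrupted.append(ModalityTable(
            name=t.name, data=pd.DataFrame(X, index=t.data.index,
                                           columns=t.data.columns)))
    return corrupted


def write_cohort(
    tables: list[ModalityTable],
    truth: GroundTruth,
    spec: CohortSpec,
    outdir: str | Path,
) -> Path:
    """Write modality tables, control tables, ground truth and spec to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in tables:
        t.write_tsv(outdir / f"{t.name}.tsv")
    for t in generate_controls(truth):
        t.write_tsv(outdir / f"{t.name}_controls.tsv")
    truth.write_tsv(outdir / "ground_truth.tsv")
    spec.to_json(outdir / "cohort_spec.json")
    return outdir
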