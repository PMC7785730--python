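"""Generate a synthetic multimodal cohort, corrupt it, and clean it up.

The generator plants three patient subgroups and a continuous severity
gradient across five modalities of very different widths, then the cleaning
chain repairs missing cells, outlier subjects, batch offsets and covariate
effects — printing what was dropped, imputed and equalized.
"""

import numpy as np

from phenofuse import CohortSpec, clean_pipeline, corrupt_cohort, generate_cohort
from phenofuse.synth import generate_controls

spec = CohortSpec(
    n_patients=120, n_controls=40, modality_dims=(68, 16, 12, 6, 30),
    n_clusters=3, cluster_sep=1.5, gradient_loading=1.0, noise_sd=1.0,
    missing_rate=0.03, outlier_rate=0.02, n_batches=2, batch_shift=0.8,
    seed=7)

tables, truth = generate_cohort(spec)
print(f"cohort: {len(tables)} modalities, "
      f"{[t.shape for t in tables]} (patients x features)")
print(f"planted: {len(np.unique(truth.labels))} subgroups, sizes "
      f"{np.bincount(truth.labels).tolist()}, gradient SD "
      f"{truth.gradient.std():.2f}")

corrupted = corrupt_cohort(tables, truth, spec)
n_missing = sum(int(np.isnan(t.values).sum()) for t in corrupted)
print(f"after corruption: {n_missing} missing cells, "
      f"{len(truth.outliers)} planted outlier subjects: {truth.outliers}")

cleaned, report = clean_pipeline(
    corrupted, controls=generate_controls(truth),
    patient_covariates=truth.covariates,
    control_covariates=truth.control_covariates, batch=truth.batch)

print(f"dropped subjects: {report.dropped_subjects}")
print(f"imputed cells per modality: {report.imputed_cells}")
X = cleaned[0].values
print(f"first modality after cleaning: shape {X.shape}, "
      f"feature means ~{np.abs(X.mean(0)).max():.2e}, "
      f"SDs ~{X.std(0, ddof=1).mean():.3f} (z-scored)")
# the planted outliers should be gone; every planted outlier that survived
# the missingness filter is removed by the robust screen
removed = set(report.dropped_subjects)
print(f"all planted outliers removed: {set(truth.outliers) <= removed}")
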