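"""Core containers shared across the pipeline.

Everything is a thin, validated wrapper around numpy arrays / pandas frames:
patient identity and provenance (kernel parameters, grid cell, seeds) travel
with the numbers so that any stage output can be written to disk and read
back without a sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ModalityTable",
    "DistanceMatrix",
    "AffinityMatrix",
    "FusedNetwork",
    "Partition",
    "Embedding",
    "CleaningReport",
]


def _check_square(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {values.shape}")
    return values


def _check_symmetric(values: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if not np.allclose(values, values.T, atol=tol, rtol=0.0):
        raise ValueError(f"{name} must be symmetric (max asymmetry "
                         f"{np.abs(values - values.T).max():.3g})")


@dataclass
class ModalityTable:
    """One patient-by-feature numeric matrix for a single data source.

    ``data`` is a pandas DataFrame indexed by patient ID with one column per
    feature. Missing entries are NaN.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)

    @property
    def patients(self) -> list[str]:
        return [str(p) for p in self.data.index]

    @property
    def features(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "patient_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, name: str | None = None) -> "ModalityTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(name=name or Path(path).stem, data=df)


@dataclass
class DistanceMatrix:
    """Symmetric patient-by-patient squared distances."""

    values: np.ndarray
    patients: list[str]
    metric: str = "sqeuclidean"

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, "DistanceMatrix")
        _check_symmetric(self.values, "DistanceMatrix")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AffinityMatrix:
    """Symmetric positive patient similarity network W with kernel provenance.

    ``K`` and ``mu`` record the neighborhood size and scaling factor of the
    scaled exponential kernel; they are None for kernels (e.g. the cosine
    concatenation baseline) that have no such parameters.
    """

    values: np.ndarray
    patients: list[str]
    K: int | None = None
    mu: float | None = None

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, "AffinityMatrix")
        _check_symmetric(self.values, "AffinityMatrix")
        if not np.isfinite(self.values).all():
            raise ValueError("affinities must be finite")
        if (self.values < 0).any():
            raise ValueError("affinities must be nonnegative")
        if self.K is not None and self.K < 1:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        if self.mu is not None and self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.patients,
                     columns=self.patients).to_csv(path, sep="\t")


@dataclass
class FusedNetwork:
    """Fused patient similarity network with (K, mu, iterations) provenance."""

    values: np.ndarray
    patients: list[str]
    K: int | None = None
    mu: float | None = None
    iterations: int | None = None

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, "FusedNetwork")
        _check_symmetric(self.values, "FusedNetwork", tol=1e-10)
        if not np.isfinite(self.values).all():
            raise ValueError("fused network must be finite")
        if (self.values < 0).any():
            raise ValueError("fused network must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.patients,
                     columns=self.patients).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, **prov) -> "FusedNetwork":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), patients=[str(p) for p in df.index], **prov)


@dataclass
class Partition:
    """Integer cluster labels for all patients.

    ``k`` is the requested cluster count; the realized number of distinct
    labels may be smaller (or, for emergent consensus partitions, unrelated).
    ``source`` records provenance: a (K, mu, k) grid cell or "consensus".
    """

    labels: np.ndarray
    patients: list[str]
    k: int | None = None
    source: tuple | str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-d integer array")
        if len(self.labels) != len(self.patients):
            raise ValueError("one label per patient required")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"patient_id": self.patients, "label": self.labels}
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class Embedding:
    """Patient-by-component diffusion coordinates.

    ``var_explained`` holds the eigenvalue share of each retained component;
    components are ordered by decreasing share. ``t`` is the diffusion time
    and ``alpha`` the anisotropic density-normalization exponent.
    """

    coords: np.ndarray
    patients: list[str]
    var_explained: np.ndarray
    t: float = 0.0
    alpha: float = 0.5
    source: tuple | str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.var_explained = np.asarray(self.var_explained, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-d (patients x components)")
        if self.coords.shape[0] != len(self.patients):
            raise ValueError("one coordinate row per patient required")
        if self.coords.shape[1] != len(self.var_explained):
            raise ValueError("one var_explained entry per component required")
        if len(self.var_explained) and np.any(np.diff(self.var_explained) > 1e-12):
            raise ValueError("components must be ordered by decreasing var_explained")
        if ((self.var_explained < -1e-12) | (self.var_explained > 1 + 1e-12)).any():
            raise ValueError("var_explained entries must lie in [0, 1]")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        cols = [f"dim{i + 1}" for i in range(self.n_components)]
        df = pd.DataFrame(self.coords, index=self.patients, columns=cols)
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t")


@dataclass
class CleaningReport:
    """What a cleaning stage removed or filled in, per modality."""

    dropped_features: dict[str, list[str]] = field(default_factory=dict)
    dropped_subjects: dict[str, str] = field(default_factory=dict)  # id -> reason
    imputed_cells: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        out = CleaningReport(
            dropped_features={**self.dropped_features},
            dropped_subjects={**self.dropped_subjects},
            imputed_cells={**self.imputed_cells},
        )
        for mod, feats in other.dropped_features.items():
            out.dropped_features.setdefault(mod, [])
            out.dropped_features[mod] += [f for f in feats
                                          if f not in out.dropped_features[mod]]
        out.dropped_subjects.update(other.dropped_subjects)
        for mod, cnt in other.imputed_cells.items():
            out.imputed_cells[mod] = out.imputed_cells.get(mod, 0) + cnt
        return out

    def to_dict(self) -> dict:
        return {
            "dropped_features": self.dropped_features,
            "dropped_subjects": self.dropped_subjects,
            "imputed_cells": self.imputed_cells,
        }
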