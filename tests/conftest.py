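import numpy as np
import pandas as pd
import pytest

from phenofuse import CohortSpec, ModalityTable, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """Clean 90-patient, 2-modality cohort with 3 planted clusters."""
    spec = CohortSpec(n_patients=90, n_controls=30, modality_dims=(10, 5),
                      n_clusters=3, cluster_sep=3.0, noise_sd=1.0,
                      gradient_loading=0.0, seed=1)
    tables, truth = generate_cohort(spec)
    return spec, tables, truth


def random_affinity(rng, n, diag=1.0):
    """Symmetric positive affinity with unit-scale off-diagonal weights."""
    A = rng.random((n, n)) + 0.05
    W = (A + A.T) / 2.0
    np.fill_diagonal(W, diag)
    return W


def block_affinity(sizes, within=1.0, between=0.05, noise=0.0, rng=None):
    """Planted block-structured affinity matrix."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    W = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise and rng is not None:
        E = rng.normal(scale=noise, size=(n, n))
        W = np.clip(W + (E + E.T) / 2.0, 1e-6, None)
    np.fill_diagonal(W, within)
    return W, labels


def table_from_array(X, name="m"):
    return ModalityTable(name=name, data=pd.DataFrame(np.asarray(X, float)))
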