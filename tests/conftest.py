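"""Shared fixtures: layouts, simulator profiles, and the Takagi–Sugeno
function-recovery experiment used by the training tests."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.cluster import KMeans

from etmt import ImpairmentProfile, make_all_layouts, make_layout
from etmt.anfis import AnfisModel, LabeledDataset, anfis_forward


@pytest.fixture(scope="session")
def layouts():
    return make_all_layouts(seed=7)


@pytest.fixture(scope="session")
def tmt_a_simple():
    return make_layout("tmt_a_simple", seed=7)


@pytest.fixture
def ideal_profile():
    """Zero-impairment observer: no strays, no replays, no jitter."""
    return ImpairmentProfile(stray_prob=0.0, revisit_prob=0.0, noise_px=0.0)


def make_recovery_experiment(seed: int = 42, n: int = 200, noise_sd: float = 0.01):
    """Data from a known 2-input, 2-rule Takagi–Sugeno model, plus a
    cluster-based initial model.

    Inputs are drawn around the two rule prototypes (the regime a
    scatter-partitioned system assumes); the initial model gets its premises
    from k-means on the inputs, zero consequent weights, and per-cluster mean
    targets as intercepts — the same construction the package uses on labeled
    cohorts.
    """
    rng = np.random.default_rng(seed)
    true_c = np.array([[-1.0, -1.0], [1.0, 1.0]])
    true_s = np.full((2, 2), 0.8)
    true_a = np.array([[0.5, -0.3], [-0.2, 0.4]])
    true_b = np.array([0.2, 0.9])
    truth = AnfisModel(true_c, true_s, true_a, true_b,
                       np.zeros(2), np.ones(2), trained=True)
    comp = rng.integers(0, 2, n)
    X = true_c[comp] + rng.normal(0, 0.8, (n, 2))
    y = anfis_forward(truth, X) + rng.normal(0, noise_sd, n)
    dataset = LabeledDataset(X=X, y=y, mean=np.zeros(2), std=np.ones(2))

    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
    sig = np.array([np.maximum(X[km.labels_ == j].std(axis=0), 0.1) for j in range(2)])
    init = AnfisModel(km.cluster_centers_.copy(), sig, np.zeros((2, 2)),
                      np.array([y[km.labels_ == j].mean() for j in range(2)]),
                      np.zeros(2), np.ones(2))
    return truth, dataset, init
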