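"""Shared fixtures: small simulated datasets reused across test modules.

Everything is generated programmatically and seeded; session scope keeps the
heavier feature tables to one computation each.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import sbsl

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def planted_small():
    """Planted-signal dataset small enough for fast unit tests."""
    cfg = sbsl.planted_config(
        seed=7, n_genes=100, n_pos_pairs=60, n_neg_pairs=60,
        n_cell_lines=50, n_patients=80, n_healthy=60,
    )
    labels, bundle = sbsl.generate_dataset(cfg)
    return cfg, labels, bundle


@pytest.fixture(scope="session")
def planted_small_features(planted_small):
    _, labels, bundle = planted_small
    return sbsl.build_feature_table(labels.pairs, bundle, n_perm=100, seed=3)


@pytest.fixture(scope="session")
def null_small():
    cfg = sbsl.null_config(
        seed=8, n_genes=100, n_pos_pairs=60, n_neg_pairs=60,
        n_cell_lines=50, n_patients=80, n_healthy=60,
    )
    labels, bundle = sbsl.generate_dataset(cfg)
    return cfg, labels, bundle


@pytest.fixture(scope="session")
def toy_classification():
    """One informative feature among noise; linear separability is partial."""
    rng = np.random.default_rng(42)
    n, p = 400, 12
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[4] = 2.0
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(int)
    return X, y
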