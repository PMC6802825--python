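"""Shared fixtures: toy maps, synthetic benchmarks, and a trained forest.

The heavyweight benchmark fixtures are session-scoped so the featurization
cost (contact maps, alignments, pairwise TM) is paid once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from rfqa import classifier as clf
from rfqa.pipeline import featurize_benchmark
from rfqa.structure_io import ContactMap, PredictedContactMap
from rfqa.synthetic_fixtures import generate_benchmark, informative_spec

TRAIN_SEED = 1
TEST_SEED = 2
FOREST_SEED = 7


def random_contact_map(length: int, n_contacts: int, rng,
                       min_separation: int = 2) -> ContactMap:
    pairs = [(i, j) for i in range(1, length + 1)
             for j in range(i + min_separation, length + 1)]
    k = min(n_contacts, len(pairs))
    idx = rng.choice(len(pairs), size=k, replace=False)
    return ContactMap(length=length,
                      contacts=frozenset(pairs[i] for i in idx),
                      min_separation=min_separation)


def random_predicted_map(length: int, n_contacts: int, rng,
                         min_separation: int = 2) -> PredictedContactMap:
    cmap = random_contact_map(length, n_contacts, rng, min_separation)
    entries = tuple((i, j, float(rng.uniform(0.3, 1.0)))
                    for i, j in sorted(cmap.contacts))
    return PredictedContactMap(length=length, entries=entries)


@pytest.fixture(scope="session")
def train_benchmark():
    return generate_benchmark(informative_spec(seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def test_benchmark():
    return generate_benchmark(informative_spec(seed=TEST_SEED))


@pytest.fixture(scope="session")
def train_features(train_benchmark):
    return featurize_benchmark(train_benchmark)


@pytest.fixture(scope="session")
def test_features(test_benchmark):
    return featurize_benchmark(test_benchmark)


@pytest.fixture(scope="session")
def trained_model(train_features):
    X, tm = train_features
    return clf.train(X, tm >= 0.5, clf.ForestConfig(seed=FOREST_SEED))
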