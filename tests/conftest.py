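"""Shared fixtures: small synthetic datasets and fitted models.

Everything is generated programmatically with fixed seeds; nothing is
read from checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import hcstopics as ht
from hcstopics import preprocess as pp


#: Gibbs schedule used throughout the tests: long enough to mix on the
#: planted corpora, short enough to keep the suite fast.
TEST_LDA = dict(n_topics=3, n_iterations=400, burn_in=100, sample_lag=10)


def planted_group_sets(dataset: ht.SyntheticDataset) -> dict[int, set[str]]:
    """Planted event groups as {group: set of endpoint names}."""
    groups: dict[int, set[str]] = {}
    for name, g in dataset.endpoint_groups.items():
        groups.setdefault(g, set()).add(name)
    return groups


def run_planted_pipeline(seed: int, n_drugs: int = 122):
    """Generate -> preprocess -> fit on the default planted conditions.

    Returns (dataset, corpus, model).
    """
    cfg = ht.SimulationConfig(n_drugs=n_drugs, seed=seed)
    dataset = ht.generate_dataset(cfg)
    auc = ht.build_auc_table(dataset.curves, dataset.controls)
    corpus = ht.build_corpus(pp.discretize(auc))
    model = ht.fit_lda(corpus, ht.LDAConfig(**TEST_LDA, seed=seed + 1))
    return dataset, corpus, model


def recovered_partition(model: ht.TopicModel) -> dict[int, set[str]]:
    """Endpoint sets per topic from the argmax assignment."""
    assignment = ht.assign_endpoints(model)
    out: dict[int, set[str]] = {}
    for _, row in assignment.iterrows():
        out.setdefault(int(row["topic"]), set()).add(row["endpoint_id"])
    return out


@pytest.fixture(scope="session")
def small_dataset() -> ht.SyntheticDataset:
    """12 drugs, 2 time points: fast but structurally complete."""
    cfg = ht.SimulationConfig(n_drugs=12, time_points_h=(6.0, 24.0), seed=42)
    return ht.generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_run():
    """One full-size planted run shared by the recovery tests."""
    return run_planted_pipeline(seed=2024)


@pytest.fixture(scope="session")
def planted_model(planted_run) -> ht.TopicModel:
    return planted_run[2]


@pytest.fixture()
def tiny_corpus() -> ht.Corpus:
    """Two documents, two terms, six tokens — enumerable exactly."""
    return ht.Corpus(
        doc_ids=("a@1", "b@1"),
        doc_drugs=("a", "b"),
        doc_times=(1.0, 1.0),
        term_ids=("u", "v"),
        counts=np.array([[2, 1], [1, 2]], dtype=np.int64),
    )
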