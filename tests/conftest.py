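"""Shared fixtures.

The expensive end-to-end fixture (18 h of balanced synthetic data pushed
through feature extraction and a 500-tree forest) is built once per session
and shared by the model-level and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import groomacc as g


@pytest.fixture(scope="session")
def balanced_pipeline():
    """Full pipeline on 18 h of balanced six-behaviour data, 500 trees.

    Balanced transition weights give every behaviour well over 2 h of data.
    Returns (labels, features, results).
    """
    configs = g.default_behaviour_configs()
    weights = g.balanced_transition_weights(configs)
    T = g.transition_matrix_from_weights(weights)
    labels = g.generate_behaviour_sequence(configs, 64800, 101, T)
    trace = g.synthesize_acceleration(labels, configs, 102)
    features = g.epoch_features(trace, labels=labels)
    results = g.BehaviourClassifier.from_dataframe(features).fit(
        n_trees=500, train_fraction=0.7, seed=103)
    return labels, features, results


@pytest.fixture(scope="session")
def small_labelled():
    """A quick labelled feature table (20 min, default ethogram)."""
    configs = g.default_behaviour_configs()
    labels = g.generate_behaviour_sequence(configs, 1200, 7)
    trace = g.synthesize_acceleration(labels, configs, 8)
    return g.epoch_features(trace, labels=labels)


def separable_features(n_per_class: int = 60, seed: int = 0) -> pd.DataFrame:
    """A toy labelled table where VeDBAs alone separates the six classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, beh in enumerate(g.BEHAVIOURS):
        for _ in range(n_per_class):
            feat = {c: rng.normal(0.0, 0.01) for c in g.FEATURE_COLUMNS}
            feat["VeDBAs"] = i + rng.uniform(0.0, 0.5)  # disjoint ranges
            rows.append({"epoch_time": pd.Timestamp("2018-08-01"), **feat,
                         "valid": True, "individual_id": "TOY", "label": beh})
    return pd.DataFrame(rows)
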