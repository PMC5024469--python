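import numpy as np
import pytest

import hmclmlp as hm


@pytest.fixture(scope="session")
def tiny_hierarchy():
    """Classes {12, 12.01, 12.01.01, 20}: a 3-deep chain plus a singleton."""
    return hm.build_hierarchy([("12", "01", "01"), ("20",)])


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic triple shared by model/evaluation tests."""
    cfg = hm.SynthConfig(depth=3, branching=2, n_instances=240,
                         n_features=12, seed=7)
    return hm.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_encoded(small_synth):
    train, valid, test = hm.preprocess_splits(
        small_synth.train, small_synth.valid, small_synth.test
    )
    return train, valid, test


@pytest.fixture(scope="session")
def trained_predicted(small_encoded):
    """One trained Predicted model, reused by every read-only test."""
    train, valid, _ = small_encoded
    hyper = hm.TrainHyper(max_epochs=25)
    return hm.train_model("Predicted", train, valid, hyper=hyper,
                          patience=5, seed=11)


def random_scores_truth(hierarchy, n, rng):
    """Random score matrix + random ancestor-closed truth over a hierarchy."""
    C = hierarchy.class_count
    scores = rng.random((n, C))
    truth = hierarchy.close_matrix((rng.random((n, C)) < 0.35).astype(np.int8))
    return scores, truth
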