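"""Shared fixtures: synthetic datasets and trained models.

Heavy artifacts (the 200-bag embedding dataset, the core-trained image
model, the slide cohort) are session-scoped so the unit tests and the
acceptance tests reuse one training run each.
"""

import numpy as np
import pytest

from ihcmil import Bag, TrainConfig, generate_embedding_bags, train
from ihcmil.pipeline import (
    cores_to_bags,
    simulate_core_cohort,
    simulate_slide_cohort,
)


@pytest.fixture(scope="session")
def embedding_dataset():
    """The 200-bag embedding fixture: labels uniform over deciles,
    noise_sd 0.5, fixed seed; split 80/20 deterministically."""
    raw = generate_embedding_bags(
        200, dim=64, instances_per_bag=(30, 60), noise_sd=0.5, seed=11
    )
    bags = [Bag(f"b{i:03d}", inst, lab) for i, (inst, lab, _) in enumerate(raw)]
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(bags))
    train_bags = [bags[i] for i in idx[:160]]
    test_bags = [bags[i] for i in idx[160:]]
    return {"raw": raw, "train": train_bags, "test": test_bags}


@pytest.fixture(scope="session")
def attention_model(embedding_dataset):
    return train(embedding_dataset["train"], TrainConfig(seed=0, pooling="attention"))


@pytest.fixture(scope="session")
def average_model(embedding_dataset):
    return train(embedding_dataset["train"], TrainConfig(seed=0, pooling="average"))


@pytest.fixture(scope="session")
def core_cohort():
    """66 rendered cores: six per decile label."""
    return simulate_core_cohort(6, seed=42)


@pytest.fixture(scope="session")
def core_bags(core_cohort):
    return cores_to_bags(core_cohort)


@pytest.fixture(scope="session")
def core_model(core_bags):
    """Attention model trained on the toy-featurized core cohort."""
    return train(core_bags, TrainConfig(seed=0))


@pytest.fixture(scope="session")
def slide_cohort():
    """20 synthetic slides with slide-level truths spanning 0-100."""
    return simulate_slide_cohort(20, seed=7)
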