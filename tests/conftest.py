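"""Shared fixtures: the toy benchmark dataset and trained networks.

The end-to-end models are expensive (minutes), so they are trained once per
session and shared by every test that exercises the full pipeline.
"""

import numpy as np
import pytest

from spikedbn import TrainConfig, build_fusion, stack_train
from spikedbn.encoders import (audio_rate_vectors, isi_encode, make_toy_digits,
                               synthetic_cochlea, tone_for_class)

#: toy benchmark operating point: 4 classes, 16x16, 800 train / 200 test,
#: total input rate 10 000 spikes/s (rate mass 20)
TOY_SEED = 42
RATE_MASS = 20.0
TRAIN_CONFIG = dict(epochs=100, momentum=0.5, sparsity_target=0.15,
                    sparsity_strength=1e-3, seed=1)
TOP_EPOCHS = 200


@pytest.fixture(scope="session")
def toy_task():
    """Synthetic digit dataset with a fixed 800/200 train/test split."""
    images, labels, _ = make_toy_digits(4, 16, 250, seed=TOY_SEED)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(images))
    return {"images": images, "labels": labels,
            "train": idx[:800], "test": idx[800:]}


@pytest.fixture(scope="session")
def trained_model(toy_task):
    """Siegert-trained 256-100-100-4 chain DBN on the toy task."""
    images, labels = toy_task["images"], toy_task["labels"]
    tr = toy_task["train"]
    onehot = np.eye(4)[labels]
    cfg = TrainConfig(**TRAIN_CONFIG)
    return stack_train(images[tr], onehot[tr], 100, 100, cfg,
                       rate_mass=RATE_MASS, top_epochs=TOP_EPOCHS)


@pytest.fixture(scope="session")
def class_audio_streams():
    """Per-class auditory event streams (4 stacked cochlea renditions)."""
    from spikedbn.events import EventStream

    def stream(c, seed):
        parts = [isi_encode(synthetic_cochlea(tone_for_class(c),
                                              seed=seed + 7 * r))
                 for r in range(4)]
        return EventStream.merge(parts)

    return {c: stream(c, 500 + 100 * c) for c in range(4)}


@pytest.fixture(scope="session")
def fusion_model(trained_model, toy_task):
    """Audio-visual fusion model built on the trained chain."""
    images, labels = toy_task["images"], toy_task["labels"]
    tr = toy_task["train"]
    onehot = np.eye(4)[labels]
    vecs, vlabels = [], []
    for c in range(4):
        for s in range(3):
            coch = synthetic_cochlea(tone_for_class(c), seed=100 * c + s)
            rv = audio_rate_vectors(isi_encode(coch), 100, 1.0)
            vecs.append(rv)
            vlabels.append(np.full(rv.shape[0], c))
    cfg = TrainConfig(**{**TRAIN_CONFIG, "epochs": TOP_EPOCHS,
                         "sparsity_strength": 0.0})
    return build_fusion(trained_model, np.vstack(vecs),
                        np.concatenate(vlabels), images[tr], onehot[tr], cfg)
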