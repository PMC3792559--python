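#!/usr/bin/env python
"""Optional full-scale MNIST run (requires the IDX files; not part of CI).

Trains the 784-500-500-10 architecture with Siegert units on the augmented
MNIST training set and evaluates rate-based and spiking accuracy on the
test set.  This is hours of compute; the toy benchmark in the test suite
exercises the identical pipeline at desk scale.

    python scripts/mnist_full.py --data-dir mnist/ --epochs 50
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path

import numpy as np

from spikedbn import (TrainConfig, classify_rate_based, classify_spiking,
                      convert_to_spiking, image_to_poisson, stack_train)
from spikedbn.encoders import read_idx
from spikedbn.engine import recognition_groups, run


def augment(images28, rng):
    """Random translations (+-15%), rotations (+-3 deg), scalings (+-10%)."""
    from spikedbn.encoders import _augment
    out = np.empty_like(images28)
    for i, img in enumerate(images28):
        shift = rng.uniform(-0.15, 0.15, 2) * 28
        out[i] = _augment(img.reshape(28, 28), shift, rng.uniform(-3, 3),
                          rng.uniform(0.9, 1.1)).ravel()
    return out


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, required=True,
                    help="directory with the four MNIST IDX files")
    ap.add_argument("--epochs", type=int, default=50)
    ap.add_argument("--rate-mass", type=float, default=60.0)
    ap.add_argument("--n-test", type=int, default=10000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    d = args.data_dir
    train_x = read_idx(d / "train-images-idx3-ubyte").reshape(-1, 784) / 255.0
    train_y = read_idx(d / "train-labels-idx1-ubyte")
    test_x = read_idx(d / "t10k-images-idx3-ubyte").reshape(-1, 784) / 255.0
    test_y = read_idx(d / "t10k-labels-idx1-ubyte")

    rng = np.random.default_rng(args.seed)
    extra = augment(train_x, rng)
    data = np.vstack([train_x, extra])
    labels = np.concatenate([train_y, train_y])
    print(f"training set {data.shape} (augmented)")

    cfg = TrainConfig(epochs=args.epochs, momentum=0.5, sparsity_target=0.15,
                      sparsity_strength=1e-3, seed=args.seed)
    t0 = time.time()
    model = stack_train(data, np.eye(10)[labels], 500, 500, cfg,
                        rate_mass=args.rate_mass)
    print(f"trained in {(time.time() - t0) / 60:.1f} min")

    te = test_x[:args.n_test]
    pred = np.array([classify_rate_based(model, x) for x in te])
    print(f"rate-based accuracy {100 * np.mean(pred == test_y[:args.n_test]):.2f}%")

    net = convert_to_spiking(model)
    groups = recognition_groups(net)
    total_rate = args.rate_mass / model.neuron.t_ref
    correct = 0
    n_spiking = min(args.n_test, 1000)
    for k in range(n_spiking):
        stream = image_to_poisson(te[k], total_rate, 1.0, seed=args.seed + k)
        out = run(net, {"visual_input": stream}, 1.0, enabled=groups)
        dec = classify_spiking(out["label"], 1.0, n_classes=10)
        correct += int(dec.class_index == test_y[k])
    print(f"spiking accuracy {100 * correct / n_spiking:.2f}% "
          f"({n_spiking} images)")


if __name__ == "__main__":
    main()
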