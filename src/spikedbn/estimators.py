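"""scikit-learn estimator facade for the Siegert-trained DBN classifier."""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dbn import classify_rate_based, stack_train
from .neuron import LifParams
from .rbm import TrainConfig

__all__ = ["SiegertDbnClassifier"]


class SiegertDbnClassifier(ClassifierMixin, BaseEstimator):
    """Deep belief network classifier with LIF firing-rate activations.

    Two stacked RBMs are trained greedily with persistent contrastive
    divergence; unit activations are normalized Siegert firing rates of LIF
    neurons (or the classic sigmoid), so a fitted model can be converted
    into an event-driven spiking network with identical weights.

    Parameters
    ----------
    n_abstraction, n_association : int
        Hidden-layer sizes of the two RBMs.
    activation : {"siegert", "sigmoid"}
        Conditional-probability rule used during training and prediction.
    epochs, batch_size, eta, sparsity_strength : training hyper-parameters
        (see :class:`spikedbn.rbm.TrainConfig`).
    lif : LifParams, optional
        Neuron constants; defaults to the generation-mode working point.
    total_rate_hz : float
        Total input spike rate the image normalization assumes.
    random_state : int
        Seed for all training randomness.

    Attributes
    ----------
    model_ : DbnModel
        The trained layered network (feed `spikedbn.engine.convert_to_spiking`).
    classes_ : ndarray
        Class labels seen during fit.
    """

    def __init__(self, n_abstraction: int = 100, n_association: int = 100,
                 activation: str = "siegert", epochs: int = 20,
                 batch_size: int = 50, eta: Optional[float] = None,
                 sparsity_strength: float = 0.0,
                 lif: Optional[LifParams] = None,
                 total_rate_hz: float = 10000.0, random_state: int = 0):
        self.n_abstraction = n_abstraction
        self.n_association = n_association
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.eta = eta
        self.sparsity_strength = sparsity_strength
        self.lif = lif
        self.total_rate_hz = total_rate_hz
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        onehot = np.eye(len(self.classes_))[y_idx]
        lif = self.lif if self.lif is not None else LifParams()
        config = TrainConfig(eta=self.eta, epochs=self.epochs,
                             batch_size=self.batch_size,
                             sparsity_strength=self.sparsity_strength,
                             seed=self.random_state)
        rate_mass = (self.total_rate_hz * lif.t_ref
                     if self.activation == "siegert" else None)
        self.model_ = stack_train(
            X, onehot, self.n_abstraction, self.n_association, config,
            activation=self.activation, lif=lif, rate_mass=rate_mass)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        idx = [classify_rate_based(self.model_, row) for row in X]
        return self.classes_[np.asarray(idx)]
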