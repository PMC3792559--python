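"""Restricted Boltzmann Machines with sigmoid or Siegert activations.

A binary RBM over visible states v and hidden states h has energy

    E(v, h) = - sum_ij w_ij v_i h_j - sum_i b_i v_i - sum_j c_j h_j

and joint probability p(v, h) = exp(-E)/Z.  Training uses persistent
contrastive divergence: model statistics come from Gibbs chains maintained
across updates, augmented with transient "fast weights" that push the chains
out of energy minima, plus an optional sparsity nudge on the hidden biases.

Two activation rules are supported for the conditional probabilities:

* ``"sigmoid"``  -- the classic logistic rule.
* ``"siegert"``  -- the normalized firing rate of an LIF neuron receiving the
  unit's inputs as Poisson spike trains.  A visible value v in [0, 1] drives
  a channel at rate v/t_ref with the synaptic weight; the bias b is an
  always-on channel at rate 1/t_ref with weight b*t_ref/tau_m, so its mean
  current contribution is exactly b.  A network trained this way converts to
  spiking LIF neurons with the weights kept verbatim.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .neuron import LifParams, sigmoid_activation, siegert_rate_batch

__all__ = [
    "RbmParameters",
    "TrainConfig",
    "energy",
    "joint_probability_exact",
    "hidden_activation_probs",
    "visible_activation_probs",
    "sample_layer",
    "cd_update",
    "persistent_cd_step",
    "fast_weight_update",
    "sparsity_adjustment",
    "train_rbm",
    "weight_unit",
]

DEFAULT_LIF = LifParams()


def weight_unit(lif: LifParams) -> float:
    """Synaptic weight whose mean current equals v_th at the maximal rate.

    A channel firing at 1/t_ref through this weight drives the free membrane
    mean to exactly the threshold: tau_m * w * (1/t_ref) = v_th.  Natural
    scale for weight initialization and learning rates under the Siegert
    activation.
    """
    return lif.v_th * lif.t_ref / lif.tau_m


@dataclass
class RbmParameters:
    """Weights and biases of one RBM (plus transient fast weights)."""

    w: np.ndarray          # (n_visible, n_hidden)
    b_v: np.ndarray        # (n_visible,)
    b_h: np.ndarray        # (n_hidden,)
    w_fast: np.ndarray = None  # same shape as w

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b_v = np.asarray(self.b_v, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        if self.w.shape != (self.b_v.size, self.b_h.size):
            raise ValueError(
                f"weight shape {self.w.shape} inconsistent with biases "
                f"({self.b_v.size} visible, {self.b_h.size} hidden)"
            )
        if self.w_fast is None:
            self.w_fast = np.zeros_like(self.w)
        else:
            self.w_fast = np.asarray(self.w_fast, dtype=float)
            if self.w_fast.shape != self.w.shape:
                raise ValueError("w_fast shape differs from w")

    @property
    def n_visible(self) -> int:
        return self.b_v.size

    @property
    def n_hidden(self) -> int:
        return self.b_h.size

    def copy(self) -> "RbmParameters":
        return RbmParameters(self.w.copy(), self.b_v.copy(), self.b_h.copy(),
                             self.w_fast.copy())


@dataclass
class TrainConfig:
    """Hyper-parameters of persistent-CD training.

    ``eta`` and ``alpha`` default to scale-aware values: under the Siegert
    activation weights live in membrane-increment units (of order
    ``weight_unit``), so the learning rate is expressed as a fraction of that
    unit; under the sigmoid the usual O(0.1) rate is used.  ``alpha``
    defaults to eta/50: the fast-weight rule is depression-only, so its
    stationary offset alpha*<vh>/(1-fast_decay) must stay small against the
    learned weights or the persistent chains sample a heavily biased model.
    """

    eta: Optional[float] = None
    alpha: Optional[float] = None
    fast_decay: float = 0.9
    epochs: int = 20
    batch_size: int = 50
    n_chains: Optional[int] = None
    sparsity_target: float = 0.1
    sparsity_strength: float = 0.0
    momentum: float = 0.5
    eta_decay: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive")
        if not 0.0 < self.fast_decay < 1.0:
            raise ValueError("fast_decay must lie in (0, 1)")
        if self.n_chains is not None and self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0.0 < self.sparsity_target < 1.0:
            raise ValueError("sparsity_target must lie in (0, 1)")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 <= self.eta_decay <= 1.0:
            raise ValueError("eta_decay must lie in [0, 1]")

    def resolved(self, activation: str, lif: LifParams) -> "TrainConfig":
        """Fill activation-dependent defaults."""
        eta = self.eta
        if eta is None:
            eta = 0.1 * weight_unit(lif) if activation == "siegert" else 0.1
        alpha = self.alpha if self.alpha is not None else eta / 50.0
        n_chains = self.n_chains if self.n_chains is not None else self.batch_size
        return replace(self, eta=eta, alpha=alpha, n_chains=n_chains)


def bias_gradient_scale(activation: str, lif: LifParams) -> float:
    """Learning-rate multiplier for bias updates.

    Under the Siegert activation a synaptic weight w enters the membrane
    mean as (tau_m/t_ref) * w while a bias enters directly, so bias steps
    must be amplified by tau_m/t_ref to learn on the same footing; under
    the sigmoid both enter identically.
    """
    return lif.tau_m / lif.t_ref if activation == "siegert" else 1.0


def energy(v, h, params: RbmParameters, include_fast: bool = False):
    """Energy E(v, h) of one or more joint states (fast weights excluded
    unless requested)."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    w = params.w + params.w_fast if include_fast else params.w
    if v.shape[-1] != params.n_visible or h.shape[-1] != params.n_hidden:
        raise ValueError("state shapes do not match RBM dimensions")
    quad = np.einsum("...i,ij,...j->...", v, w, h)
    return -(quad + v @ params.b_v + h @ params.b_h)


def joint_probability_exact(params: RbmParameters) -> np.ndarray:
    """Exact joint distribution over all (v, h) states by enumeration.

    Returns an array of shape (2**n_visible, 2**n_hidden); entry [i, j] is
    the probability of the visible/hidden states given by the binary digits
    of i and j (unit 0 = least significant bit).  Guarded to <= 20 units.
    """
    nv, nh = params.n_visible, params.n_hidden
    if nv + nh > 20:
        raise ValueError("exact enumeration limited to 20 total units")
    vs = np.array(list(itertools.product([0, 1], repeat=nv)))[:, ::-1]
    hs = np.array(list(itertools.product([0, 1], repeat=nh)))[:, ::-1]
    e = np.empty((vs.shape[0], hs.shape[0]))
    for j, h in enumerate(hs):
        e[:, j] = energy(vs, np.broadcast_to(h, (vs.shape[0], nh)), params)
    e -= e.min()  # stabilize
    p = np.exp(-e)
    return p / p.sum()


def _siegert_probs(drive, sq_drive, bias, lif: LifParams):
    """Normalized Siegert activation from weighted-input sums.

    ``drive`` = sum_i w_i x_i and ``sq_drive`` = sum_i w_i^2 x_i with x in
    [0, 1] interpreted as rates x/t_ref.  The bias enters as a constant
    (zero-variance) current offset: the spiking realization delivers it as
    clock-like periodic events, so unlike the Poisson synaptic channels it
    contributes no membrane-potential noise.
    """
    mu = (lif.tau_m / lif.t_ref) * drive + bias
    var = (lif.tau_m / 2.0) * sq_drive / lif.t_ref
    return siegert_rate_batch(lif, mu, np.broadcast_to(var, np.shape(mu)).copy()) * lif.t_ref


def hidden_activation_probs(v, params: RbmParameters, activation: str = "sigmoid",
                            lif: LifParams = DEFAULT_LIF,
                            include_fast: bool = False):
    """P(h_j = 1 | v) for each hidden unit (batched if v is 2-D)."""
    v = np.asarray(v, dtype=float)
    w = params.w + params.w_fast if include_fast else params.w
    if activation == "sigmoid":
        return sigmoid_activation(v @ w + params.b_h)
    if activation == "siegert":
        return _siegert_probs(v @ w, v @ w**2, params.b_h, lif)
    raise ValueError(f"unknown activation {activation!r}")


def visible_activation_probs(h, params: RbmParameters, activation: str = "sigmoid",
                             lif: LifParams = DEFAULT_LIF,
                             include_fast: bool = False):
    """P(v_i = 1 | h) for each visible unit (transposed-weight mirror)."""
    h = np.asarray(h, dtype=float)
    w = params.w + params.w_fast if include_fast else params.w
    if activation == "sigmoid":
        return sigmoid_activation(h @ w.T + params.b_v)
    if activation == "siegert":
        return _siegert_probs(h @ w.T, h @ (w**2).T, params.b_v, lif)
    raise ValueError(f"unknown activation {activation!r}")


def sample_layer(probs, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draws from per-unit probabilities."""
    probs = np.asarray(probs)
    return (rng.random(probs.shape) < probs).astype(float)


def _gradients(v_data, h_data, v_model, h_model):
    nd = v_data.shape[0]
    nm = v_model.shape[0]
    gw = v_data.T @ h_data / nd - v_model.T @ h_model / nm
    gbv = v_data.mean(axis=0) - v_model.mean(axis=0)
    gbh = h_data.mean(axis=0) - h_model.mean(axis=0)
    return gw, gbv, gbh


def cd_update(batch, params: RbmParameters, config: TrainConfig,
              rng: np.random.Generator, activation: str = "sigmoid",
              lif: LifParams = DEFAULT_LIF) -> RbmParameters:
    """One CD-1 update: data statistics vs. a single Gibbs reconstruction."""
    cfg = config.resolved(activation, lif)
    v_data = np.atleast_2d(np.asarray(batch, dtype=float))
    ph_data = hidden_activation_probs(v_data, params, activation, lif)
    h_samp = sample_layer(ph_data, rng)
    pv_model = visible_activation_probs(h_samp, params, activation, lif)
    v_model = sample_layer(pv_model, rng)
    ph_model = hidden_activation_probs(v_model, params, activation, lif)
    gw, gbv, gbh = _gradients(v_data, ph_data, v_model, ph_model)
    bs = bias_gradient_scale(activation, lif)
    out = params.copy()
    out.w += cfg.eta * gw
    out.b_v += cfg.eta * bs * gbv
    out.b_h += cfg.eta * bs * gbh
    return out


def fast_weight_update(params: RbmParameters, v_model, h_model,
                       config: TrainConfig) -> RbmParameters:
    """Decay the fast weights and depress along the current model sample:
    w_fast <- fast_decay * w_fast - alpha * <v h>_model."""
    v_model = np.atleast_2d(np.asarray(v_model, dtype=float))
    h_model = np.atleast_2d(np.asarray(h_model, dtype=float))
    out = params.copy()
    out.w_fast = (config.fast_decay * out.w_fast
                  - config.alpha * v_model.T @ h_model / v_model.shape[0])
    return out


def persistent_cd_step(batch, params: RbmParameters, chains,
                       config: TrainConfig, rng: np.random.Generator,
                       activation: str = "sigmoid",
                       lif: LifParams = DEFAULT_LIF,
                       learn: bool = True, velocity=None,
                       eta_scale: float = 1.0):
    """One persistent-CD update.

    ``chains`` holds the hidden states of the persistent Markov chains,
    shape (n_chains, n_hidden).  The model term advances the chains one
    Gibbs sweep using the *fast* weights (w + w_fast); the data term uses
    the regular weights only.  Returns (params, chains).  ``velocity``
    (a dict with keys "w", "b_v", "b_h") enables heavy-ball momentum
    across calls; ``eta_scale`` rescales the learning rate (annealing).
    """
    cfg = config.resolved(activation, lif)
    v_data = np.atleast_2d(np.asarray(batch, dtype=float))

    # model phase: the persistent chains advance under w + w_fast (the fast
    # weights push them out of the modes they sit in), but the gradient's
    # model statistic is evaluated under the regular weights, so the
    # transient depression never biases the learned model itself.
    # Under the Siegert rule units are continuous (firing rates): the
    # visible reconstruction stays graded, matching the graded data term;
    # hidden chain states are still sampled to keep the chains mixing.
    pv = visible_activation_probs(chains, params, activation, lif, include_fast=True)
    v_model = pv if activation == "siegert" else sample_layer(pv, rng)
    ph_chain = hidden_activation_probs(v_model, params, activation, lif,
                                       include_fast=True)
    new_chains = sample_layer(ph_chain, rng)

    out = params
    if learn:
        ph_data = hidden_activation_probs(v_data, params, activation, lif)
        ph_model = hidden_activation_probs(v_model, params, activation, lif)
        gw, gbv, gbh = _gradients(v_data, ph_data, v_model, ph_model)
        bs = bias_gradient_scale(activation, lif)
        eta = cfg.eta * eta_scale
        out = params.copy()
        if velocity is not None:
            velocity["w"] = cfg.momentum * velocity["w"] + gw
            velocity["b_v"] = cfg.momentum * velocity["b_v"] + gbv
            velocity["b_h"] = cfg.momentum * velocity["b_h"] + gbh
            gw, gbv, gbh = velocity["w"], velocity["b_v"], velocity["b_h"]
        out.w += eta * gw
        out.b_v += eta * bs * gbv
        out.b_h += eta * bs * gbh
    out = fast_weight_update(out, v_model, new_chains, cfg)
    return out, new_chains


def sparsity_adjustment(params: RbmParameters, batch_hidden_probs,
                        config: TrainConfig) -> RbmParameters:
    """Nudge hidden biases toward a target mean activation.

    Approximates sparse/selective receptive-field shaping: each hidden bias
    moves by sparsity_strength * (target - mean data-phase activation of
    that unit).  Strength 0 leaves the parameters untouched.
    """
    if config.sparsity_strength == 0.0:
        return params
    probs = np.atleast_2d(np.asarray(batch_hidden_probs, dtype=float))
    out = params.copy()
    out.b_h += config.sparsity_strength * (config.sparsity_target
                                           - probs.mean(axis=0))
    return out


def init_rbm(n_visible: int, n_hidden: int, rng: np.random.Generator,
             activation: str = "sigmoid",
             lif: LifParams = DEFAULT_LIF) -> RbmParameters:
    """Initialize an RBM at the natural weight scale of the activation.

    Under the Siegert rule hidden biases start at v_th so that units sit at
    their firing threshold; with zero bias the activation (and hence the
    gradient) would be identically zero.
    """
    if activation == "siegert":
        scale = weight_unit(lif)
        w = rng.normal(0.0, 0.5 * scale, size=(n_visible, n_hidden))
        b_v = np.zeros(n_visible)
        b_h = np.full(n_hidden, lif.v_th)
    else:
        w = rng.normal(0.0, 0.01, size=(n_visible, n_hidden))
        b_v = np.zeros(n_visible)
        b_h = np.zeros(n_hidden)
    return RbmParameters(w, b_v, b_h)


def reconstruction_cross_entropy(data, params: RbmParameters, activation: str,
                                 lif: LifParams = DEFAULT_LIF) -> float:
    """Mean per-unit cross-entropy of the deterministic up-down pass."""
    v = np.atleast_2d(np.asarray(data, dtype=float))
    ph = hidden_activation_probs(v, params, activation, lif)
    pv = visible_activation_probs(ph, params, activation, lif)
    pv = np.clip(pv, 1e-12, 1.0 - 1e-12)
    return float(np.mean(-(v * np.log(pv) + (1.0 - v) * np.log(1.0 - pv))))


def train_rbm(dataset, n_hidden: int, config: TrainConfig,
              activation: str = "sigmoid", lif: LifParams = DEFAULT_LIF,
              params: Optional[RbmParameters] = None,
              bv_clamp: Optional[tuple] = None):
    """Train one RBM with persistent CD + fast weights + sparsity.

    Returns (params, history) where history is the per-epoch reconstruction
    cross-entropy.  Fully reproducible from ``config.seed``.  ``bv_clamp``
    is an optional (indices, values) pair holding part of the visible bias
    fixed -- used when stacking, where the lower RBM's hidden bias must
    stay the single bias of the shared physical neurons.
    """
    data = np.atleast_2d(np.asarray(dataset, dtype=float))
    if data.size == 0:
        raise ValueError("empty training dataset")
    cfg = config.resolved(activation, lif)
    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_rbm(data.shape[1], n_hidden, rng, activation, lif)
    else:
        params = params.copy()
    if bv_clamp is not None:
        params.b_v[bv_clamp[0]] = bv_clamp[1]
    chains = sample_layer(np.full((cfg.n_chains, n_hidden), 0.5), rng)

    n = data.shape[0]
    velocity = {"w": np.zeros_like(params.w),
                "b_v": np.zeros_like(params.b_v),
                "b_h": np.zeros_like(params.b_h)}
    history = []
    for epoch in range(cfg.epochs):
        # linear annealing: eta (and with it alpha's offset) shrinks to
        # (1 - eta_decay) of its initial value by the last epoch
        eta_scale = 1.0 - cfg.eta_decay * epoch / max(cfg.epochs - 1, 1)
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            params, chains = persistent_cd_step(
                batch, params, chains, cfg, rng, activation, lif,
                velocity=velocity, eta_scale=eta_scale)
            if bv_clamp is not None:
                params.b_v[bv_clamp[0]] = bv_clamp[1]
            if cfg.sparsity_strength:
                ph = hidden_activation_probs(batch, params, activation, lif)
                params = sparsity_adjustment(params, ph, cfg)
        history.append(reconstruction_cross_entropy(data, params, activation, lif))
    return params, history
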