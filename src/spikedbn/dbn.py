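"""Stacking trained RBMs into deep belief networks.

Supported topologies:

* **chain** -- visual input -> abstraction -> association, with a label
  layer joined into the top RBM's visible layer (supervised information
  enters as extra visible units).
* **split input** -- after training, the visual input layer is duplicated
  into a bottom-up copy (recognition) and a top-down copy (generation);
  bottom-up and top-down weight matrices are transposes of each other.
* **fusion** -- an auditory input layer is joined into the top RBM's
  visible layer, bidirectionally connected to the association layer, so
  visual evidence, labels and auditory evidence share one generative model.

Greedy layer-wise training: the first RBM learns the image distribution;
the top RBM learns the joint distribution of first-layer activation
probabilities, one-hot labels, and (for fusion) auditory rate vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .neuron import LifParams
from .rbm import (
    DEFAULT_LIF,
    RbmParameters,
    TrainConfig,
    hidden_activation_probs,
    train_rbm,
    visible_activation_probs,
)

__all__ = [
    "LayerSpec",
    "ConnectionSpec",
    "DbnModel",
    "normalize_rate_mass",
    "stack_train",
    "split_input_layer",
    "build_fusion",
    "classify_rate_based",
]

ROLES = {"visual-input-up", "visual-input-down", "hidden", "association",
         "label", "auditory-input"}


@dataclass
class LayerSpec:
    name: str
    size: int
    role: str = "hidden"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("layer size must be >= 1")
        if self.role not in ROLES:
            raise ValueError(f"unknown layer role {self.role!r}")


@dataclass
class ConnectionSpec:
    source: str
    target: str
    weights: np.ndarray  # (source size, target size)
    direction: str = "bottom-up"  # bottom-up | top-down | bidirectional
    enabled: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.direction not in {"bottom-up", "top-down", "bidirectional"}:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class DbnModel:
    """Layered network description plus the parameters needed to run it."""

    layers: List[LayerSpec]
    connections: List[ConnectionSpec]
    neuron: LifParams = field(default_factory=LifParams)
    biases: Dict[str, np.ndarray] = field(default_factory=dict)
    rbms: List[RbmParameters] = field(default_factory=list)
    activation: str = "siegert"
    rate_mass: Optional[float] = None  # summed visible input per image
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        sizes = self.layer_sizes
        seen = set()
        for c in self.connections:
            if c.source not in sizes or c.target not in sizes:
                raise ValueError(f"connection {c.name} references unknown layer")
            if c.weights.shape != (sizes[c.source], sizes[c.target]):
                raise ValueError(f"connection {c.name} weight shape mismatch")
            if (c.source, c.target) in seen:
                raise ValueError(f"duplicate connection {c.name}")
            seen.add((c.source, c.target))

    @property
    def layer_sizes(self) -> Dict[str, int]:
        return {l.name: l.size for l in self.layers}

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def connection(self, source: str, target: str) -> ConnectionSpec:
        for c in self.connections:
            if c.source == source and c.target == target:
                return c
        raise KeyError(f"{source}->{target}")

    def has_layer(self, name: str) -> bool:
        return any(l.name == name for l in self.layers)

    @property
    def n_neurons(self) -> int:
        return sum(l.size for l in self.layers)


def normalize_rate_mass(images: np.ndarray, rate_mass: float) -> np.ndarray:
    """Scale each image so its summed intensity equals ``rate_mass``.

    ``rate_mass`` = total input rate * t_ref is the summed visible drive a
    constant-total-rate Poisson encoding delivers, so rate-trained
    activations and spiking drive agree.  Values are clipped to [0, 1].
    """
    images = np.atleast_2d(np.asarray(images, dtype=float))
    sums = images.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("cannot normalize an all-zero image")
    return np.clip(images * (rate_mass / sums), 0.0, 1.0)


def stack_train(dataset, labels, n_abstraction: int, n_association: int,
                config: TrainConfig, activation: str = "siegert",
                lif: LifParams = DEFAULT_LIF,
                rate_mass: Optional[float] = None,
                top_epochs: Optional[int] = None) -> DbnModel:
    """Greedy layer-wise training of the chain DBN.

    RBM 1: raw (rate-normalized) images -> abstraction features.
    RBM 2: [abstraction activation probabilities, one-hot labels] ->
    association.  In the converted spiking network the abstraction neurons
    keep RBM 1's hidden bias (the bottom-up recognition role); RBM 2's
    visible bias for that block only shapes the top RBM's generative model
    during training.

    The label units are a small minority of the top RBM's visible layer, so
    capturing the label joint takes the top RBM several times more sweeps
    than feature learning does; ``top_epochs`` defaults to 4x
    ``config.epochs``.
    """
    data = np.atleast_2d(np.asarray(dataset, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if labels.shape[0] != data.shape[0]:
        raise ValueError("dataset/label count mismatch")
    n_label = labels.shape[1]
    if not np.allclose(labels.sum(axis=1), 1.0):
        raise ValueError("labels must be one-hot")
    if rate_mass is None and activation == "siegert":
        rate_mass = 10000.0 * lif.t_ref
    if rate_mass is not None:
        data = normalize_rate_mass(data, rate_mass)

    rbm1, hist1 = train_rbm(data, n_abstraction, config, activation, lif)
    h1 = hidden_activation_probs(data, rbm1, activation, lif)

    top_visible = np.hstack([h1, labels])
    if top_epochs is None:
        top_epochs = 4 * config.epochs
    # sparsity shapes the *receptive fields* of the feature RBM; applied to
    # the top RBM it throttles the association capacity available to the
    # label joint, so it is switched off there
    cfg2 = TrainConfig(**{**config.__dict__, "seed": config.seed + 1,
                          "epochs": top_epochs, "sparsity_strength": 0.0})
    rbm2, hist2 = train_rbm(top_visible, n_association, cfg2, activation, lif)

    na, nl = n_abstraction, n_label
    layers = [
        LayerSpec("visual_input", data.shape[1], "visual-input-up"),
        LayerSpec("abstraction", na, "hidden"),
        LayerSpec("association", n_association, "association"),
        LayerSpec("label", nl, "label"),
    ]
    w2_abs = rbm2.w[:na]
    w2_lab = rbm2.w[na:]
    connections = [
        ConnectionSpec("visual_input", "abstraction", rbm1.w, "bottom-up"),
        ConnectionSpec("abstraction", "association", w2_abs, "bottom-up"),
        ConnectionSpec("association", "abstraction", w2_abs.T, "top-down"),
        ConnectionSpec("label", "association", w2_lab, "bottom-up"),
        ConnectionSpec("association", "label", w2_lab.T, "top-down"),
    ]
    biases = {
        "visual_input": rbm1.b_v.copy(),
        "abstraction": rbm1.b_h.copy(),
        "association": rbm2.b_h.copy(),
        "label": rbm2.b_v[na:].copy(),
    }
    return DbnModel(
        layers=layers, connections=connections, neuron=lif, biases=biases,
        rbms=[rbm1, rbm2], activation=activation, rate_mass=rate_mass,
        metadata={"config": dict(config.__dict__), "seed": config.seed,
                  "history": [hist1, hist2]},
    )


def split_input_layer(model: DbnModel) -> DbnModel:
    """Duplicate the visual input layer into a top-down generation copy.

    The new layer receives abstraction activity through the transpose of
    the shared bottom-up weight matrix; the bottom-up pathway is untouched.
    """
    if model.has_layer("visual_input_down"):
        raise ValueError("input layer already split")
    up = model.connection("visual_input", "abstraction")
    layers = model.layers + [
        LayerSpec("visual_input_down", model.layer("visual_input").size,
                  "visual-input-down")]
    connections = model.connections + [
        ConnectionSpec("abstraction", "visual_input_down", up.weights.T,
                       "top-down")]
    biases = dict(model.biases)
    biases["visual_input_down"] = model.rbms[0].b_v.copy() if model.rbms \
        else np.zeros(layers[-1].size)
    return DbnModel(layers=layers, connections=connections,
                    neuron=model.neuron, biases=biases, rbms=model.rbms,
                    activation=model.activation, rate_mass=model.rate_mass,
                    metadata=dict(model.metadata))


def build_fusion(model: DbnModel, audio_vectors, audio_labels,
                 visual_dataset, visual_labels,
                 config: TrainConfig) -> DbnModel:
    """Extend a trained chain model with an auditory input layer.

    Retrains the top RBM so its visible layer is the concatenation
    [abstraction activations, one-hot labels, auditory rate vector]; the
    auditory layer ends up bidirectionally connected to the association
    layer.  ``audio_vectors``/``audio_labels`` supply per-class auditory
    training vectors; each visual sample is paired with an auditory vector
    of the same class (cycled deterministically).
    """
    lif, activation = model.neuron, model.activation
    data = np.atleast_2d(np.asarray(visual_dataset, dtype=float))
    vis_labels = np.atleast_2d(np.asarray(visual_labels, dtype=float))
    audio = np.atleast_2d(np.asarray(audio_vectors, dtype=float))
    audio_labels = np.asarray(audio_labels)
    if data.shape[0] != vis_labels.shape[0]:
        raise ValueError("visual dataset/label count mismatch")
    if audio.shape[0] != audio_labels.shape[0]:
        raise ValueError("audio dataset/label count mismatch")
    if model.rate_mass is not None:
        data = normalize_rate_mass(data, model.rate_mass)

    rbm1 = model.rbms[0]
    na = model.layer("abstraction").size
    nl = model.layer("label").size
    nq = audio.shape[1]
    h1 = hidden_activation_probs(data, rbm1, activation, lif)

    # deterministic pairing: cycle through each class's audio vectors
    cls = vis_labels.argmax(axis=1)
    paired = np.empty((data.shape[0], nq))
    counters = {c: 0 for c in range(nl)}
    by_class = {c: np.where(audio_labels == c)[0] for c in range(nl)}
    for i, c in enumerate(cls):
        idx = by_class[int(c)]
        if idx.size == 0:
            raise ValueError(f"no audio vectors for class {c}")
        paired[i] = audio[idx[counters[int(c)] % idx.size]]
        counters[int(c)] += 1

    top_visible = np.hstack([h1, vis_labels, paired])
    cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + 2})

    # warm start from the visual top RBM
    old = model.rbms[1]
    rng = np.random.default_rng(cfg.seed)
    from .rbm import init_rbm
    init = init_rbm(na + nl + nq, old.n_hidden, rng, activation, lif)
    init.w[:na + nl] = old.w
    init.b_v[:na + nl] = old.b_v
    init.b_h[:] = old.b_h
    rbm2, hist = train_rbm(top_visible, old.n_hidden, cfg, activation, lif,
                           params=init)

    layers = [l for l in model.layers] + [
        LayerSpec("auditory_input", nq, "auditory-input")]
    w_abs = rbm2.w[:na]
    w_lab = rbm2.w[na:na + nl]
    w_aud = rbm2.w[na + nl:]
    connections = []
    for c in model.connections:
        if c.target == "association" or c.source == "association":
            continue
        connections.append(c)
    connections += [
        ConnectionSpec("abstraction", "association", w_abs, "bottom-up"),
        ConnectionSpec("association", "abstraction", w_abs.T, "top-down"),
        ConnectionSpec("label", "association", w_lab, "bottom-up"),
        ConnectionSpec("association", "label", w_lab.T, "top-down"),
        ConnectionSpec("auditory_input", "association", w_aud, "bottom-up"),
        ConnectionSpec("association", "auditory_input", w_aud.T, "top-down"),
    ]
    biases = dict(model.biases)
    biases["association"] = rbm2.b_h.copy()
    biases["label"] = rbm2.b_v[na:na + nl].copy()
    biases["auditory_input"] = rbm2.b_v[na + nl:].copy()
    return DbnModel(layers=layers, connections=connections,
                    neuron=lif, biases=biases, rbms=[rbm1, rbm2],
                    activation=activation, rate_mass=model.rate_mass,
                    metadata={**model.metadata, "fusion_history": hist,
                              "n_audio": nq})


def _top_widths(model: DbnModel):
    na = model.layer("abstraction").size
    nl = model.layer("label").size
    nq = model.layer("auditory_input").size if model.has_layer("auditory_input") else 0
    return na, nl, nq


def classify_rate_based(model: DbnModel, image) -> int:
    """Deterministic rate-based classification of one intensity image.

    Normalizes the image to the model's training rate mass, propagates
    activation probabilities bottom-up to the association layer (labels and
    audio silent), reads the label block of the top RBM's visible
    activation, and returns the argmax (ties -> lowest index).
    """
    v = np.asarray(image, dtype=float).ravel()
    if model.rate_mass is not None:
        v = normalize_rate_mass(v[None, :], model.rate_mass)[0]
    rbm1, rbm2 = model.rbms
    h1 = hidden_activation_probs(v, rbm1, model.activation, model.neuron)
    na, nl, nq = _top_widths(model)
    vis = np.concatenate([h1, np.zeros(nl + nq)])
    assoc = hidden_activation_probs(vis, rbm2, model.activation, model.neuron)
    back = visible_activation_probs(assoc, rbm2, model.activation, model.neuron)
    label_act = back[na:na + nl]
    return int(np.argmax(label_act))
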