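"""Event-driven simulation of converted spiking DBNs.

Every unit of a trained network becomes an LIF neuron; weights are copied
verbatim.  State updates happen only when spikes arrive: the membrane
potential decays exponentially between events, each arriving spike adds its
synaptic weight, and a threshold crossing emits a spike at the very
timestamp of the causing event (zero propagation delay).  Spikes arriving
within the absolute refractory period are discarded.

Biases are realized as a periodic "virtual bias channel": every layer of
LIF neurons receives clock-like events whose per-neuron weight is
b/(tau_m * f_bias), so the mean bias current matches the value used by the
Siegert activation during training.

Determinism: time is integer microseconds and simultaneous events are
processed in a fixed order (external streams in input order, then bias
ticks, then internally generated spikes in creation order), so identical
inputs and seeds give identical output streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .dbn import DbnModel
from .events import EventStream, SpikeEvent
from .neuron import LifParams

__all__ = [
    "StdpConfig",
    "NeuronState",
    "SpikingNetwork",
    "convert_to_spiking",
    "process_event",
    "run",
    "classify_spiking",
    "generate",
    "stdp_depression",
    "clock_driven_reference",
    "run_fusion_experiment",
    "recognition_groups",
    "generation_groups",
]

_LONG_AGO = -(2**62)


@dataclass
class StdpConfig:
    """Short-term depression kernel for generation mode.

    A pre/post spike pair with timing difference dt transiently depresses
    the synapse by amplitude * exp(-|dt|/tau_stdp) (two-sided kernel,
    maximal at coincidence); the depression relaxes back with tau_rec.
    ``amplitude=None`` resolves at run time to 30% of the mean absolute
    weight of the enabled connections.  The defaults are the regime in
    which the toy networks keep moving between states: the pairing window
    must cover the inter-spike intervals of a reverberating assembly
    (tens of ms at the generation working point), and the recovery must
    outlast a state so the network does not fall straight back.
    """

    amplitude: Optional[float] = None
    tau_stdp: float = 0.050
    tau_rec: float = 2.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tau_stdp <= 0 or self.tau_rec <= 0:
            raise ValueError("STDP time constants must be positive")


def stdp_depression(dt: float, config: StdpConfig) -> float:
    """Transient weight change for a pre/post pair with dt = t_pre - t_post."""
    if not config.enabled:
        return 0.0
    a = config.amplitude if config.amplitude is not None else 0.0
    return -a * float(np.exp(-abs(dt) / config.tau_stdp))


@dataclass
class NeuronState:
    """Scalar per-neuron state; reference semantics for one LIF neuron."""

    v: float = 0.0
    last_t_us: int = 0
    ref_until_us: int = _LONG_AGO
    last_spike_us: int = _LONG_AGO


def process_event(state: NeuronState, event: SpikeEvent, weight: float,
                  lif: LifParams) -> List[SpikeEvent]:
    """Deliver one input spike to one neuron; returns the emitted spikes.

    Semantics: refractory arrivals are discarded outright; otherwise the
    membrane decays by exp(-dt/tau_m) since the last update, the synaptic
    weight is added, and a threshold crossing emits a spike at the event's
    timestamp, resets to v_reset and starts the refractory window.
    """
    t = event.t_us
    if t < state.last_t_us:
        raise ValueError(
            f"stream-ordering corruption: event at {t} us precedes neuron "
            f"state time {state.last_t_us} us")
    if t < state.ref_until_us:
        return []
    dt_s = (t - state.last_t_us) * 1e-6
    state.v = state.v * np.exp(-dt_s / lif.tau_m) + weight
    state.last_t_us = t
    if state.v >= lif.v_th:
        state.v = lif.v_reset
        state.ref_until_us = t + int(round(lif.t_ref * 1e6))
        state.last_spike_us = t
        return [SpikeEvent(t, event.layer, event.unit)]
    return []


class SpikingNetwork:
    """A DBN converted into layers of LIF neurons with event routing."""

    def __init__(self, model: DbnModel, lif: Optional[LifParams] = None):
        if not model.connections:
            raise ValueError("model has no trained connections to convert")
        self.model = model
        self.lif = lif if lif is not None else model.neuron
        self.sizes: Dict[str, int] = model.layer_sizes
        # weights are the trained matrices, verbatim
        self.weights: Dict[Tuple[str, str], np.ndarray] = {
            (c.source, c.target): c.weights for c in model.connections}
        self.biases: Dict[str, np.ndarray] = {
            name: np.asarray(model.biases.get(name, np.zeros(size)), float)
            for name, size in self.sizes.items()}

    @property
    def group_names(self) -> Set[str]:
        return {f"{s}->{t}" for (s, t) in self.weights}

    @property
    def n_neurons(self) -> int:
        return self.model.n_neurons

    def mean_abs_weight(self, groups: Optional[Set[str]] = None) -> float:
        mats = [w for (s, t), w in self.weights.items()
                if groups is None or f"{s}->{t}" in groups]
        return float(np.mean([np.mean(np.abs(w)) for w in mats]))


def convert_to_spiking(model: DbnModel,
                       params: Optional[LifParams] = None) -> SpikingNetwork:
    """Convert a trained model into an event-driven spiking network."""
    return SpikingNetwork(model, params)


def recognition_groups(net: SpikingNetwork, recurrent: bool = False) -> Set[str]:
    """Connection groups active in recognition mode.

    Feed-forward: bottom-up path from the visual input to the label layer.
    Recurrent: additionally all bidirectional connections of the top RBM
    (association with abstraction, label and auditory layers).
    """
    groups = {"visual_input->abstraction", "abstraction->association",
              "association->label"}
    if recurrent:
        for (s, t) in net.weights:
            if "association" in (s, t) and "visual_input" not in (s, t):
                groups.add(f"{s}->{t}")
    return groups & net.group_names


def generation_groups(net: SpikingNetwork) -> Set[str]:
    """Connection groups active in generation mode: the recurrent top RBM,
    the top-down path to the generation copy of the input layer, and the
    spontaneous-background projections when present."""
    groups = set()
    for (s, t) in net.weights:
        if "association" in (s, t) and "visual_input" not in (s, t):
            groups.add(f"{s}->{t}")
        if s == "background":
            groups.add(f"{s}->{t}")
    if ("abstraction", "visual_input_down") in net.weights:
        groups.add("abstraction->visual_input_down")
    return groups


def add_generation_noise(model: DbnModel, n_units: int = 64,
                         weight_scale: float = 0.4, connect_p: float = 0.25,
                         seed: int = 7) -> DbnModel:
    """Attach a spontaneous-background layer for generative sampling.

    Free-running LIF dynamics are deterministic; the drifting exploration
    of the learned states needs a source of ongoing variability (in the
    live sensor system it comes from real-time event jitter).  This adds
    ``n_units`` background units sparsely connected (probability
    ``connect_p``) to the abstraction, association and label layers with
    balanced +-(weight_scale * v_th) weights, i.e. zero-mean membrane
    noise.  ``generate`` drives them with seeded Poisson trains.
    """
    from .dbn import ConnectionSpec, LayerSpec
    if model.has_layer("background"):
        return model
    rng = np.random.default_rng(seed)
    w0 = weight_scale * model.neuron.v_th
    layers = model.layers + [LayerSpec("background", n_units, "hidden")]
    conns = list(model.connections)
    for tgt in ("abstraction", "association", "label"):
        if not model.has_layer(tgt):
            continue
        size = model.layer(tgt).size
        w = (rng.choice([-1.0, 1.0], size=(n_units, size)) * w0
             * (rng.random((n_units, size)) < connect_p))
        conns.append(ConnectionSpec("background", tgt, w, "bottom-up"))
    return DbnModel(layers=layers, connections=conns, neuron=model.neuron,
                    biases=dict(model.biases), rbms=model.rbms,
                    activation=model.activation, rate_mass=model.rate_mass,
                    metadata=dict(model.metadata))


def _bias_interval_us(net: SpikingNetwork, bias_rate: Optional[float]) -> Tuple[float, int]:
    """Bias tick rate and interval.

    The periodic approximation of the constant bias current has a membrane
    ripple of about interval/tau_m; the default rate keeps that at 2%
    (never below 1/t_ref), so the tick discretization cannot perturb the
    threshold dynamics the rate model predicts.
    """
    if bias_rate is None:
        bias_rate = max(1.0 / net.lif.t_ref, 50.0 / net.lif.tau_m)
    return bias_rate, int(round(1e6 / bias_rate))


def run(net: SpikingNetwork, inputs: Dict[str, EventStream],
        duration_s: float, enabled: Optional[Set[str]] = None,
        stdp: Optional[StdpConfig] = None,
        bias_rate: Optional[float] = None) -> Dict[str, EventStream]:
    """Event-driven simulation; returns the spike stream of every layer.

    ``inputs`` maps layer names to external spike streams (the events *are*
    spikes of that layer's units and are routed onward).  ``enabled`` names
    the active connection groups ("source->target"); default is every
    connection whose spec is enabled.  With an ``stdp`` config, deliveries
    along all enabled groups are transiently depressed according to the
    most recent pre/post spike pairing.

    Simultaneous events are processed external-streams-first (in sorted
    layer order), then bias ticks, then internally generated spikes in
    creation order; identical inputs give identical outputs.
    """
    from ._engine_core import simulate_events

    lif = net.lif
    if enabled is None:
        enabled = {c.name for c in net.model.connections if c.enabled}
    unknown = enabled - net.group_names
    if unknown:
        raise ValueError(f"unknown connection groups: {sorted(unknown)}")

    layers = sorted(net.sizes)
    lindex = {name: i for i, name in enumerate(layers)}
    sizes = np.array([net.sizes[l] for l in layers], np.int64)
    layer_ofs = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
    n_total = int(sizes.sum())

    groups = [(lindex[s], lindex[t], w) for (s, t), w in net.weights.items()
              if f"{s}->{t}" in enabled]
    groups.sort(key=lambda g: (g[0], g[1]))
    g_src = np.array([g[0] for g in groups], np.int64)
    g_tgt = np.array([g[1] for g in groups], np.int64)
    w_parts, g_wofs, ofs = [], [], 0
    for _, _, w in groups:
        g_wofs.append(ofs)
        w_parts.append(np.ascontiguousarray(w, dtype=np.float64).ravel())
        ofs += w.size
    g_wofs = np.array(g_wofs, np.int64)
    w_flat = (np.concatenate(w_parts) if w_parts else np.zeros(0))

    is_lif = np.zeros(len(layers), np.bool_)
    for _, tgt, _ in groups:
        is_lif[tgt] = True

    # depression acts on every enabled delivery; the default amplitude is
    # measured over the learned model's groups (background noise
    # projections, if any, are excluded from the average)
    stdp_amp = 0.0
    stdp_inv_tau_us = 0.0
    if stdp is not None and stdp.enabled:
        model_groups = {g for g in net.group_names
                        if not g.startswith("background")}
        stdp_amp = (stdp.amplitude if stdp.amplitude is not None
                    else 0.3 * net.mean_abs_weight(model_groups))
        stdp_inv_tau_us = 1e-6 / stdp.tau_stdp

    t_ref_us = int(round(lif.t_ref * 1e6))
    inv_tau_us = 1e-6 / lif.tau_m
    duration_us = int(round(duration_s * 1e6))

    f_bias, bias_iv_us = _bias_interval_us(net, bias_rate)
    bias_w = np.concatenate([net.biases[l] / (lif.tau_m * f_bias)
                             for l in layers]) if layers else np.zeros(0)
    # silence bias drive on non-LIF layers
    for li, l in enumerate(layers):
        if not is_lif[li]:
            bias_w[layer_ofs[li]:layer_ofs[li] + sizes[li]] = 0.0
    any_bias = bool(np.any(bias_w != 0.0))

    # merge external streams (sorted layer-name order) and bias ticks;
    # stable sort keeps externals before bias at equal timestamps
    t_parts, l_parts, u_parts = [], [], []
    for name in sorted(inputs):
        stream = inputs[name]
        if name not in net.sizes:
            raise ValueError(f"input targets unknown layer {name!r}")
        if len(stream) and stream.unit.max() >= net.sizes[name]:
            raise ValueError(f"input unit index out of range for layer {name!r}")
        keep = stream.t_us < duration_us
        t_parts.append(stream.t_us[keep])
        l_parts.append(np.full(int(keep.sum()), lindex[name], np.int64))
        u_parts.append(stream.unit[keep])
    if any_bias:
        ticks = np.arange(0, duration_us, bias_iv_us, dtype=np.int64)
        t_parts.append(ticks)
        l_parts.append(np.full(ticks.size, -1, np.int64))
        u_parts.append(np.full(ticks.size, -1, np.int64))
    if t_parts:
        ev_t = np.concatenate(t_parts)
        ev_l = np.concatenate(l_parts)
        ev_u = np.concatenate(u_parts)
        order = np.argsort(ev_t, kind="stable")
        ev_t, ev_l, ev_u = ev_t[order], ev_l[order], ev_u[order]
    else:
        ev_t = np.zeros(0, np.int64)
        ev_l = np.zeros(0, np.int64)
        ev_u = np.zeros(0, np.int64)

    v = np.zeros(n_total)
    last_t = np.zeros(n_total, np.int64)
    ref_until = np.full(n_total, _LONG_AGO, np.int64)
    last_spike = np.full(n_total, _LONG_AGO, np.int64)

    g_stdp_amp = np.full(len(groups), stdp_amp, dtype=np.float64)
    rec_t, rec_l, rec_u = simulate_events(
        ev_t, ev_l, ev_u, sizes, is_lif,
        len(groups), g_src, g_tgt, g_wofs, w_flat,
        bias_w, layer_ofs,
        v, last_t, ref_until, last_spike, layer_ofs,
        inv_tau_us, lif.v_th, lif.v_reset, t_ref_us,
        g_stdp_amp, stdp_inv_tau_us)

    out: Dict[str, EventStream] = {}
    for li, name in enumerate(layers):
        mask = rec_l == li
        out[name] = EventStream(rec_t[mask], rec_u[mask], name)
    return out


@dataclass(frozen=True)
class Decision:
    """Outcome of spike-count classification; ``class_index`` is None when
    no label spike fell inside the window (no decision)."""

    class_index: Optional[int]
    latency_s: Optional[float]
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


def classify_spiking(label_stream: EventStream, window_s: float,
                     onset_s: float = 0.0,
                     n_classes: Optional[int] = None) -> Decision:
    """Winner-take-most over label spikes in a time window.

    The winner is the label unit with the most spikes inside
    [onset, onset + window) (ties -> lowest index); the latency is the time
    from stimulus onset to the winner's first spike in the window.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    t0 = int(round(onset_s * 1e6))
    t1 = t0 + int(round(window_s * 1e6))
    win = label_stream.in_window(t0, t1)
    if len(win) == 0:
        n = n_classes if n_classes is not None else 0
        return Decision(None, None, np.zeros(n, int))
    n = n_classes if n_classes is not None else int(win.unit.max()) + 1
    counts = win.counts(n)
    winner = int(np.argmax(counts))
    first = win.t_us[win.unit == winner].min()
    return Decision(winner, float(first - t0) * 1e-6, counts)


def poisson_unit_stream(layer: str, unit: int, rate_hz: float,
                        duration_s: float, rng: np.random.Generator,
                        t0_s: float = 0.0) -> EventStream:
    """Poisson spike train on a single unit (integer-microsecond times)."""
    times = []
    t = t0_s
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if t >= t0_s + duration_s:
            break
        times.append(int(round(t * 1e6)))
    return EventStream(np.array(times, np.int64),
                       np.full(len(times), unit, np.int64), layer)


def generate(net: SpikingNetwork, class_index, total_duration_s: float,
             stdp: Optional[StdpConfig] = None, stim_rate_hz: float = 500.0,
             stim_duration_s: float = 2.0, seed: int = 0,
             noise_rate_hz: float = 20.0,
             bias_rate: Optional[float] = None) -> Dict[str, EventStream]:
    """Generation mode: stimulate label unit(s), then let the network run.

    ``class_index`` may be one class or a sequence; a sequence is
    stimulated one class after another across ``stim_duration_s`` (the
    raster protocol: drive a few classes, then observe the free run).
    Requires a split-input (or fusion) model so a top-down visual layer
    exists.  With an enabled ``stdp`` config, short-term depression keeps
    pushing the network out of the state it currently samples; a
    "background" layer (see :func:`add_generation_noise`), if present, is
    driven with seeded Poisson trains at ``noise_rate_hz`` per unit.
    """
    groups = generation_groups(net)
    if "abstraction->visual_input_down" not in groups:
        raise ValueError("generation requires a split-input model "
                         "(no top-down visual layer)")
    classes = ([class_index] if np.isscalar(class_index) else
               list(class_index))
    for c in classes:
        if c >= net.sizes["label"]:
            raise ValueError("label class out of range")
    rng = np.random.default_rng(seed)
    stim_total = min(stim_duration_s, total_duration_s)
    per = stim_total / len(classes)
    stim = EventStream.merge([
        poisson_unit_stream("label", c, stim_rate_hz, per, rng, t0_s=k * per)
        for k, c in enumerate(classes)])
    inputs = {"label": stim}
    if "background" in net.sizes:
        parts = []
        for u in range(net.sizes["background"]):
            parts.append(poisson_unit_stream("background", u, noise_rate_hz,
                                             total_duration_s, rng))
        inputs["background"] = EventStream.merge(parts)
    return run(net, inputs, total_duration_s, enabled=groups,
               stdp=stdp, bias_rate=bias_rate)


def clock_driven_reference(net: SpikingNetwork, inputs: Dict[str, EventStream],
                           duration_s: float, dt_s: float = 1e-5,
                           enabled: Optional[Set[str]] = None,
                           bias_rate: Optional[float] = None
                           ) -> Dict[str, EventStream]:
    """Clock-driven simulation with identical spiking semantics (test oracle).

    Advances all membranes on a fixed grid (exponential decay per step) and
    delivers events at the grid point carrying their timestamp.  Event
    times must be multiples of dt for spike-for-spike comparison with
    :func:`run`.
    """
    if dt_s > 1e-4:
        raise ValueError("reference resolution limited to dt <= 0.1 ms")
    lif = net.lif
    if enabled is None:
        enabled = {c.name for c in net.model.connections if c.enabled}
    out_groups: Dict[str, List[Tuple[str, np.ndarray]]] = {}
    for (s, t), w in net.weights.items():
        if f"{s}->{t}" in enabled:
            out_groups.setdefault(s, []).append((t, w))
    lif_layers = sorted({t for gs in out_groups.values() for t, _ in gs})

    dt_us = int(round(dt_s * 1e6))
    duration_us = int(round(duration_s * 1e6))
    n_steps = duration_us // dt_us
    decay = float(np.exp(-dt_s / lif.tau_m))
    t_ref_us = int(round(lif.t_ref * 1e6))

    v = {l: np.zeros(net.sizes[l]) for l in lif_layers}
    ref_until = {l: np.full(net.sizes[l], _LONG_AGO, np.int64)
                 for l in lif_layers}

    f_bias, bias_iv_us = _bias_interval_us(net, bias_rate)
    bias_w = {l: net.biases[l] / (lif.tau_m * f_bias) for l in lif_layers}
    any_bias = any(np.any(bw != 0.0) for bw in bias_w.values())
    if any_bias and bias_iv_us % dt_us != 0:
        raise ValueError("bias interval must be a multiple of dt")

    # bucket external events by step
    buckets: Dict[int, List[Tuple[str, int]]] = {}
    for name in sorted(inputs):
        stream = inputs[name]
        for t, u in zip(stream.t_us, stream.unit):
            if t >= duration_us:
                continue
            if t % dt_us != 0:
                raise ValueError("event times must align with the clock grid")
            buckets.setdefault(int(t) // dt_us, []).append((name, int(u)))

    recorded: Dict[str, List[Tuple[int, int]]] = {l: [] for l in net.sizes}

    for step in range(n_steps):
        t = step * dt_us
        for l in lif_layers:
            v[l] *= decay
        queue: List[Tuple[int, str, int]] = []  # (kind, layer, unit)
        queue.extend((0, name, u) for name, u in buckets.get(step, ()))
        if any_bias and t % bias_iv_us == 0:
            queue.append((1, "", -1))
        qi = 0
        while qi < len(queue):
            kind, layer, unit = queue[qi]
            qi += 1
            if kind == 1:
                for l in lif_layers:
                    bw = bias_w[l]
                    if not np.any(bw != 0.0):
                        continue
                    _clock_deliver(l, bw, t, v, ref_until, lif, t_ref_us,
                                   recorded, queue)
                continue
            if kind == 0:
                recorded[layer].append((t, unit))
                if layer in lif_layers:
                    v[layer][unit] = lif.v_reset
                    ref_until[layer][unit] = t + t_ref_us
            for tgt, w in out_groups.get(layer, ()):
                _clock_deliver(tgt, w[unit], t, v, ref_until, lif, t_ref_us,
                               recorded, queue)

    out: Dict[str, EventStream] = {}
    for l, rec in recorded.items():
        if rec:
            t_arr, u_arr = map(np.asarray, zip(*rec))
        else:
            t_arr, u_arr = np.zeros(0, np.int64), np.zeros(0, np.int64)
        out[l] = EventStream(t_arr, u_arr, l)
    return out


def _clock_deliver(layer, w_vec, t, v, ref_until, lif, t_ref_us, recorded,
                   queue):
    active = ref_until[layer] <= t
    if not np.any(active):
        return
    vv = v[layer]
    vv[active] += w_vec[active]
    fired = np.flatnonzero(active & (vv >= lif.v_th))
    for j in fired:
        vv[j] = lif.v_reset
        ref_until[layer][j] = t + t_ref_us
        recorded[layer].append((t, int(j)))
        queue.append((2, layer, int(j)))


def run_fusion_experiment(net: SpikingNetwork, image_a, image_b, p: float,
                          audio_a: EventStream, audio_b: EventStream,
                          audio_ratio: float = 4.0, audio_share: float = 0.2,
                          total_rate_hz: float = 1000.0,
                          duration_s: float = 1.0, n_trials: int = 10,
                          seed: int = 0) -> np.ndarray:
    """Cue-integration experiment: ambiguous vision plus biased audition.

    The visual stream draws each spike from ``image_b`` with probability
    ``p`` (else ``image_a``); the auditory stream mixes ``audio_a`` and
    ``audio_b`` with spike ratio ``audio_ratio`` : 1, and contributes
    ``audio_share`` of all input spikes.  Runs recognition with the
    recurrent top-RBM groups enabled and returns per-class label-layer
    spike shares, averaged over trials.
    """
    from .encoders import image_to_poisson, mix_streams
    if not 0.0 <= p <= 1.0:
        raise ValueError("interpolation p must lie in [0, 1]")
    if not 0.0 < audio_share < 1.0:
        raise ValueError("audio share must lie in (0, 1)")
    n_label = net.sizes["label"]
    groups = recognition_groups(net, recurrent=True)
    counts = np.zeros(n_label)
    visual_rate = total_rate_hz * (1.0 - audio_share)
    target_audio = total_rate_hz * audio_share * duration_s
    for trial in range(n_trials):
        s = (seed + 7919 * trial) % (2**31 - 1)
        rng = np.random.default_rng(s)
        parts = []
        if p < 1.0:
            parts.append(image_to_poisson(image_a, visual_rate * (1 - p),
                                          duration_s, seed=s + 1))
        if p > 0.0:
            parts.append(image_to_poisson(image_b, visual_rate * p,
                                          duration_s, seed=s + 2))
        visual = EventStream.merge(parts)
        audio = mix_streams(audio_a, audio_b,
                            audio_ratio / (audio_ratio + 1.0), seed=s + 3)
        keep = min(1.0, target_audio / max(len(audio), 1))
        mask = rng.random(len(audio)) < keep
        audio = EventStream(audio.t_us[mask], audio.unit[mask],
                            audio.layer[mask])
        streams = run(net, {"visual_input": visual, "auditory_input": audio},
                      duration_s, enabled=groups)
        counts += streams["label"].counts(n_label)
    total = counts.sum()
    return counts / total if total > 0 else counts
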