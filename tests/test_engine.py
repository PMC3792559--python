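"""Event-driven LIF engine: single-neuron semantics, routing, oracles."""

import numpy as np
import pytest

from spikedbn.dbn import ConnectionSpec, DbnModel, LayerSpec
from spikedbn.engine import (
    Decision,
    NeuronState,
    SpikingNetwork,
    StdpConfig,
    classify_spiking,
    clock_driven_reference,
    convert_to_spiking,
    poisson_unit_stream,
    process_event,
    run,
    stdp_depression,
)
from spikedbn.events import EventStream, SpikeEvent
from spikedbn.neuron import (GENERATION_WORKING_POINT, LifParams, RateInputs,
                             siegert_rate)

GEN = GENERATION_WORKING_POINT


class TestProcessEvent:
    def test_subthreshold_accumulation(self):
        st = NeuronState()
        out = process_event(st, SpikeEvent(1000, "x", 0), 0.004, GEN)
        assert out == []
        assert st.v == pytest.approx(0.004)

    def test_decay_then_spike_closed_form(self):
        # second 0.004 event 1 ms later: 0.004*exp(-0.001/0.8)+0.004 >= 0.005
        st = NeuronState()
        process_event(st, SpikeEvent(0, "x", 0), 0.004, GEN)
        out = process_event(st, SpikeEvent(1000, "x", 0), 0.004, GEN)
        assert len(out) == 1 and out[0].t_us == 1000
        assert st.v == GEN.v_reset
        assert st.ref_until_us == 1000 + 2000

    def test_refractory_event_discarded(self):
        st = NeuronState()
        process_event(st, SpikeEvent(0, "x", 0), 0.01, GEN)   # spikes
        out = process_event(st, SpikeEvent(1000, "x", 0), 0.01, GEN)
        assert out == [] and st.v == GEN.v_reset
        # at exactly t_ref the neuron accepts input again
        out = process_event(st, SpikeEvent(2000, "x", 0), 0.01, GEN)
        assert len(out) == 1

    def test_time_travel_rejected(self):
        st = NeuronState()
        process_event(st, SpikeEvent(5000, "x", 0), 0.001, GEN)
        with pytest.raises(ValueError, match="ordering"):
            process_event(st, SpikeEvent(4000, "x", 0), 0.001, GEN)


class TestClassifySpiking:
    def test_majority_count_wins(self):
        s = EventStream([1000] * 10 + [2000] * 4, [3] * 10 + [5] * 4, "label")
        d = classify_spiking(s, 1.0)
        assert d.class_index == 3

    def test_single_spike_latency(self):
        s = EventStream([4000], [7], "label")
        d = classify_spiking(s, 1.0, n_classes=10)
        assert d.class_index == 7
        assert d.latency_s == pytest.approx(0.004)

    def test_tie_breaks_to_lowest_index(self):
        s = EventStream([10, 20, 30, 40], [9, 2, 9, 2], "label")
        assert classify_spiking(s, 1.0).class_index == 2

    def test_empty_stream_is_no_decision(self):
        d = classify_spiking(EventStream(), 1.0, n_classes=4)
        assert d.class_index is None and d.latency_s is None

    def test_window_restricts_counts(self):
        s = EventStream([100, 2_000_000], [1, 2], "label")
        assert classify_spiking(s, 1.0).class_index == 1

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            classify_spiking(EventStream(), 0.0)


class TestStdpDepression:
    CFG = StdpConfig(amplitude=0.01, tau_stdp=0.010, tau_rec=1.0)

    def test_distant_pairing_vanishes(self):
        assert abs(stdp_depression(0.5, self.CFG)) < 1e-10

    def test_coincidence_is_maximal_depression(self):
        assert stdp_depression(0.0, self.CFG) == pytest.approx(-0.01)

    def test_symmetric_in_sign(self):
        assert stdp_depression(0.004, self.CFG) == pytest.approx(
            stdp_depression(-0.004, self.CFG))

    def test_disabled_kernel_is_zero(self):
        cfg = StdpConfig(amplitude=0.01, enabled=False)
        assert stdp_depression(0.0, cfg) == 0.0

    def test_recovery_closed_form(self):
        # a depressed synapse relaxes with tau_rec; after 5 tau_rec the
        # residual depression is < 1% of the kernel amplitude
        d0 = stdp_depression(0.0, self.CFG)
        residual = d0 * np.exp(-5.0)
        assert abs(residual) < 0.01 * abs(d0)


def two_layer_net(seed=0, n_in=8, n_out=5, w_scale=2e-3):
    rng = np.random.default_rng(seed)
    w = np.abs(rng.normal(0, w_scale, (n_in, n_out)))
    layers = [LayerSpec("visual_input", n_in, "visual-input-up"),
              LayerSpec("abstraction", n_out, "hidden")]
    conns = [ConnectionSpec("visual_input", "abstraction", w, "bottom-up")]
    model = DbnModel(layers=layers, connections=conns, neuron=GEN,
                     biases={"abstraction": rng.normal(0, 1e-3, n_out)})
    return convert_to_spiking(model)


def random_grid_stream(rng, n_units, rate, duration, dt_us=10,
                       layer="visual_input"):
    """Poisson-ish stream with timestamps on a dt grid."""
    n = rng.poisson(rate * duration)
    t = np.sort(rng.integers(0, int(duration * 1e6) // dt_us, n)) * dt_us
    units = rng.integers(0, n_units, n)
    return EventStream(t, units, layer)


class TestRun:
    def test_empty_input_no_bias_no_output(self):
        net = two_layer_net()
        net.biases["abstraction"][:] = 0.0
        out = run(net, {"visual_input": EventStream()}, 1.0)
        assert all(len(s) == 0 for s in out.values())

    def test_feedforward_causality(self):
        net = two_layer_net()
        net.biases["abstraction"][:] = 0.0
        stream = random_grid_stream(np.random.default_rng(1), 8, 2000, 1.0)
        out = run(net, {"visual_input": stream}, 1.0)
        if len(out["abstraction"]):
            assert out["abstraction"].t_us.min() >= stream.t_us.min()

    def test_unknown_group_flag_rejected(self):
        net = two_layer_net()
        with pytest.raises(ValueError, match="unknown connection"):
            run(net, {"visual_input": EventStream()}, 0.1,
                enabled={"nope->nada"})

    def test_refractory_bound_on_output_streams(self):
        net = two_layer_net(w_scale=4e-3)
        stream = random_grid_stream(np.random.default_rng(2), 8, 5000, 2.0)
        out = run(net, {"visual_input": stream}, 2.0)
        spikes = out["abstraction"]
        t_ref_us = int(GEN.t_ref * 1e6)
        for u in np.unique(spikes.unit):
            t = spikes.t_us[spikes.unit == u]
            assert np.all(np.diff(t) >= t_ref_us)

    def test_determinism(self):
        net = two_layer_net()
        stream = random_grid_stream(np.random.default_rng(3), 8, 3000, 1.0)
        a = run(net, {"visual_input": stream}, 1.0)
        b = run(net, {"visual_input": stream}, 1.0)
        assert a["abstraction"] == b["abstraction"]

    def test_weights_retained_verbatim(self):
        net = two_layer_net(seed=5)
        w_model = net.model.connection("visual_input", "abstraction").weights
        assert net.weights[("visual_input", "abstraction")] is w_model

    def test_neuron_count(self):
        assert two_layer_net().n_neurons == 13

    def test_untrained_model_rejected(self):
        model = DbnModel(layers=[LayerSpec("visual_input", 4,
                                           "visual-input-up")],
                         connections=[])
        with pytest.raises(ValueError, match="no trained connections"):
            convert_to_spiking(model)


class TestEventClockEquivalence:
    def test_identical_spike_trains_on_random_input(self):
        # event-driven and clock-driven (dt = 0.01 ms) runs must agree
        # spike for spike when inputs sit on the clock grid
        net = two_layer_net(seed=7, w_scale=3e-3)
        rng = np.random.default_rng(11)
        stream = random_grid_stream(rng, 8, 4000, 2.0)
        ev = run(net, {"visual_input": stream}, 2.0)
        ck = clock_driven_reference(net, {"visual_input": stream}, 2.0,
                                    dt_s=1e-5)
        for layer in ("visual_input", "abstraction"):
            assert ev[layer] == ck[layer], layer

    def test_reference_rejects_coarse_dt(self):
        net = two_layer_net()
        with pytest.raises(ValueError):
            clock_driven_reference(net, {}, 0.1, dt_s=1e-3)

    def test_off_grid_event_rejected(self):
        net = two_layer_net()
        s = EventStream([15], [0], "visual_input")  # not on 10 us grid
        with pytest.raises(ValueError, match="grid"):
            clock_driven_reference(net, {"visual_input": s}, 0.1, dt_s=1e-5)


class TestRateFidelity:
    def test_converted_neuron_fires_at_siegert_prediction(self):
        # one neuron, Poisson drive: engine rate within Monte-Carlo error
        # of the closed-form rate (ties the engine to the rate model)
        rate, w = 3000.0, 1e-4
        lif = GEN
        layers = [LayerSpec("visual_input", 1, "visual-input-up"),
                  LayerSpec("abstraction", 1, "hidden")]
        conns = [ConnectionSpec("visual_input", "abstraction",
                                np.array([[w]]), "bottom-up")]
        net = convert_to_spiking(
            DbnModel(layers=layers, connections=conns, neuron=lif,
                     biases={"abstraction": np.zeros(1)}))
        pred = siegert_rate(lif, RateInputs([rate], [w]))
        dur = 20.0
        stream = poisson_unit_stream("visual_input", 0, rate, dur,
                                     np.random.default_rng(0))
        out = run(net, {"visual_input": stream}, dur)
        measured = len(out["abstraction"]) / dur
        assert measured == pytest.approx(pred, rel=0.05)


class TestBiasDrive:
    def test_positive_bias_alone_fires_neurons(self):
        net = two_layer_net()
        net.biases["abstraction"][:] = 3 * GEN.v_th  # strong bias drive
        out = run(net, {"visual_input": EventStream()}, 1.0)
        assert len(out["abstraction"]) > 0

    def test_bias_rate_preserves_mean_current(self):
        # halving the bias event rate doubles per-event weight: mean drive
        # (and hence the firing rate) stays approximately constant
        net = two_layer_net()
        net.biases["abstraction"][:] = 3 * GEN.v_th
        out1 = run(net, {"visual_input": EventStream()}, 2.0, bias_rate=500.0)
        out2 = run(net, {"visual_input": EventStream()}, 2.0, bias_rate=1000.0)
        r1, r2 = len(out1["abstraction"]), len(out2["abstraction"])
        assert r1 > 0 and abs(r1 - r2) / max(r1, r2) < 0.2
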