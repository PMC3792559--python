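# Methods

`spikedbn` trains deep belief networks whose unit activations are the
firing rates of leaky integrate-and-fire (LIF) neurons, and then runs the
trained weights unchanged as an event-driven spiking network.  This note
records the model, the numerical choices, and what the synthetic benchmark
does and does not establish.

## The rate model

An LIF neuron has membrane potential V that decays exponentially with time
constant τ_m toward rest, jumps by the synaptic weight w on each input
spike, fires deterministically when V ≥ V_th, resets to V_reset, and
ignores inputs for an absolute refractory period t_ref.  Under constant
input drive the mean rate is the threshold-linear form

    ρ(s) = [ t_ref − τ_m ln(1 − V_th/s) ]⁻¹      for s > V_th, else 0,

where s is the asymptotic membrane potential of the drive.  Under Poisson
input spike trains with rates ρ_e, ρ_i and weights w_e, w_i, the mean and
variance of the free membrane potential are

    μ_Q = τ_m Σ(w_e ρ_e + w_i ρ_i),   σ_Q² = (τ_m/2) Σ(w_e² ρ_e + w_i² ρ_i),

and the mean output rate is the Siegert transform — the first-passage-time
result for the Ornstein–Uhlenbeck membrane with threshold:

    ρ_out = [ t_ref + (τ_m/σ_Q)·√(π/2) · ∫ exp((u−ϒ)²/2σ_Q²)(1+erf((u−ϒ)/σ_Q√2)) du ]⁻¹

integrated from V_reset + kγσ_Q to V_th + kγσ_Q, with ϒ = V_rest + μ_Q,
k = √(τ_syn/τ_m) and γ = |ζ(1/2)| (evaluated from the zeta function at
import, not hard-coded).  τ_syn defaults to 0.

Dividing by the ceiling 1/t_ref gives a number in [0, 1]: the **normalized
Siegert activation**, used in place of the logistic function as the
conditional "probability" of a restricted Boltzmann machine (RBM) unit.
Because the same transform *is* the LIF input-rate/output-rate curve, the
trained weights transfer to a spiking network verbatim.

### Numerical evaluation

* The integrand `exp(z²)(1+erf(z))` overflows for moderate z; it is
  evaluated as `erfcx(−z)`, stable for all z.  When the upper integration
  bound is more than 25 noise units above ϒ the rate is below double
  precision and 0 is returned.
* `siegert_rate` uses adaptive quadrature (relative tolerance 1e−6);
  `siegert_rate_batch` — the training path — uses composite Gauss–Legendre
  (2 panels × 12 nodes), which agrees with the adaptive path to ~1e−9
  relative in the operating range.
* σ_Q < 1e−12 falls back to the threshold-linear rate at s = V_rest + μ_Q,
  which is the analytic σ→0 limit of the integral (verified numerically to
  1%).
* The *bias* of a unit is treated as a constant, zero-variance current
  offset added to μ_Q.  Its spiking realization is a clock-like periodic
  event stream (below), which carries no Poisson variance; giving the bias
  a Poisson variance term would smear every conditional by a noise level
  comparable to V_th and demonstrably degrades both learning and the
  match between the rate and event-driven regimes.

### Validity limit

The Siegert transform is a diffusion approximation: it assumes many small
synaptic increments per threshold crossing.  At w = V_th/5 (five spikes to
threshold) it overestimates the true LIF rate by ~17%; at w ≤ V_th/25 it
agrees with clock-driven Monte-Carlo simulation to better than 3%
everywhere we measured.  Trained networks operate with weights one to two
orders below V_th, inside the valid regime.  The Monte-Carlo oracle
(`lif_poisson_monte_carlo`, dt = 0.01 ms, Bernoulli-thinned arrivals,
numba-compiled) shares no code with the closed forms.

## RBM training

The energy model, joint distribution, and conditional update rules are the
classic binary-RBM forms; `joint_probability_exact` enumerates them for
≤ 20 units as the sampling oracle.  Training is persistent contrastive
divergence (PCD):

* **Data term**: visible units clamped to real-valued data in [0, 1],
  hidden activation probabilities computed under the regular weights.
* **Model term**: persistent Markov chains advanced one Gibbs sweep per
  update.  Chains are *sampled* with the fast weights (w + w_fast) added,
  so the transient depression pushes them out of whatever mode they
  occupy, but the gradient's model statistic is evaluated under the
  regular weights.  Evaluating it under w + w_fast leaks the depression
  into the learned model and at realistic amplitudes makes training
  diverge; this separation is the single most consequential implementation
  choice in the trainer.
* **Fast weights**: w_fast ← λ·w_fast − α·⟨v h⟩_model with λ = 0.9 and
  α = η/50 by default.  The rule is depression-only, so its stationary
  offset α⟨vh⟩/(1−λ) must remain small against the learned weights;
  α = η/50 keeps the mixing benefit measurable without the offset
  mattering.
* **Unit convention by activation**: with the logistic rule both layers
  are sampled binary (classic Gibbs).  With the Siegert rule the units are
  *continuous rates*: the visible reconstruction stays graded while hidden
  chain states are still sampled binary so the chains keep mixing.
  Binarizing the visible reconstruction creates a systematic drive
  mismatch between the graded data term and the binary model term under
  the convex Siegert curve, and costs roughly ten accuracy points on the
  benchmark task.
* **Bias gradients**: the weight rule is Δw = η(⟨vh⟩_data − ⟨vh⟩_model);
  biases use the analogous first moments.  Under the Siegert rule bias
  steps are scaled by τ_m/t_ref, because a weight enters the membrane mean
  as (τ_m/t_ref)·w while a bias enters directly — without the scaling the
  bias effectively does not learn.
* **Optimization**: heavy-ball momentum (0.5) and linear learning-rate
  annealing to 10% over the run.  Learning rates are expressed relative to
  the natural weight unit V_th·t_ref/τ_m, the weight whose mean current at
  the maximal rate equals the threshold.
* **Sparsity**: hidden biases are nudged by strength·(target − mean
  activation).  This stabilizes *feature* learning (it keeps Siegert units
  from drifting into the silent dead zone, where the gradient vanishes)
  and is applied to the first RBM only; applied to the top RBM it
  throttles the association capacity available to the label joint and
  costs ~20 accuracy points.

## Working points

Two LIF parameter sets appear:

| parameter | training/recognition | generation |
|-----------|---------------------|------------|
| τ_m       | 10 ms               | 800 ms     |
| V_th      | 0.005               | 0.005      |
| V_reset = V_rest | 0            | 0          |
| t_ref     | 2 ms                | 2 ms       |

The generation point (long membrane memory) is the regime in which a
converted network sustains recurrent activity without external input; it
is unusable for training because the normalized activation's midpoint then
sits at ~400·V_th of drive, far beyond any reachable input.  The training
point places the activation's responsive range over the drive the encoders
actually deliver.  t_ref = 2 ms (rate ceiling 500 Hz) is used throughout.

## Architecture and stacking

The chain model is visual input (256) → abstraction (100) → association
(100), with a 4-unit label layer joined into the top RBM's visible layer.
Greedy training: RBM 1 on rate-normalized images; RBM 2 on [abstraction
activation probabilities, one-hot labels].  The label units are 4 of 104
visible units, so the top RBM gets 4× the epochs of the feature RBM by
default.  In the converted network each abstraction neuron keeps RBM 1's
hidden bias — its bottom-up recognition role; RBM 2's visible bias for
that block only shapes the generative model during training.

**Input normalization.** Every image is scaled so its summed intensity
equals `rate_mass` = total input rate × t_ref.  The Poisson encoder emits
a constant total rate over the image, so this makes the drive seen during
rate training identical (in expectation) to the drive the spiking network
receives — the property that keeps spiking accuracy within a couple of
points of rate accuracy.  The toy benchmark operating point is a total
input rate of 10 000 spikes/s over 256 pixels (rate_mass = 20): strong
enough for feature learning, and low enough that label-neuron firing
stays below the 500 Hz refractory ceiling — at higher drive several label
units saturate at the ceiling, their spike counts tie, and the spiking
decision degenerates.

**Split input.** After training, the visual input layer is duplicated
into a top-down copy driven by the transpose of the bottom-up weights, so
generation can paint images while recognition still projects upward.

**Fusion.** The top RBM is retrained with visible layer [abstraction,
labels, auditory rate vector] (warm-started from the visual model), which
leaves the 100-unit auditory input layer bidirectionally connected to the
association layer.

## Event-driven engine

Time is integer microseconds.  An event delivered to a neuron outside its
refractory window decays the membrane by exp(−Δt/τ_m), adds the synaptic
weight, and fires at the same timestamp on threshold crossing (zero
propagation delay); refractory arrivals are discarded outright.
Simultaneous events are processed in a fixed order (external streams,
then bias ticks, then internally generated spikes in creation order), so
runs are bit-reproducible.  Input events *are* spikes of the input layer's
units and are routed along all enabled connection groups.

* **Biases** are delivered as periodic "virtual bias channel" events with
  per-neuron weight b/(τ_m·f_bias), making the mean bias current exactly
  b — the same convention the Siegert activation assumes.  The periodic
  approximation leaves a membrane ripple of about 1/(f_bias·τ_m); the
  default rate max(1/t_ref, 50/τ_m) caps the ripple at 2%, which is the
  level below which the ripple no longer perturbs the rate/spiking
  classification correspondence (at a 20% ripple the spiking accuracy
  measurably detaches from the rate model's prediction).
* **Short-term depression** (generation mode): a pre/post spike pair with
  timing difference Δt transiently depresses the synapse by
  A·exp(−|Δt|/τ_stdp), relaxing with τ_rec.  Only each neuron's most
  recent spike time is stored; the depression applied on a delivery is
  computed on demand from the pre and post traces, with the most recent
  pairing dominating.  Defaults: A = 30% of the mean |w| of the model's
  connection groups, τ_stdp = 50 ms, τ_rec = 2 s.  The kernel's shape is
  the modeled commitment; the constants were chosen so that the pairing
  window covers the inter-spike intervals of a reverberating assembly at
  the generation working point (tens of ms) and the recovery outlasts a
  sampled state.  Much narrower windows catch no pairings at those rates
  and the kernel does nothing.
* **Clock-driven reference**: an independent simulator advances all
  membranes on a fixed grid (default dt = 0.01 ms) with identical firing
  semantics; when event timestamps sit on the grid the two simulators
  agree spike for spike, which is the engine's correctness oracle.

## Generation-mode protocol

Free-running LIF dynamics are deterministic, and at toy scale the four
class assemblies the top RBM learns are nearly disjoint and mutually
inhibitory (with one assembly active, competing label units sit tens of
V_th below threshold).  Two ingredients make the generative wandering of
the full-scale system reproducible here, both modeled on the source
setup:

* **Spontaneous background** (`add_generation_noise`): 64 background
  units sparsely connected (p = 0.25) to the abstraction, association and
  label layers with balanced ±0.4·V_th weights, driven by seeded 20 Hz
  Poisson trains.  This stands in for the ongoing variability a live
  event-sensor system provides; without any noise source a deterministic
  attractor network cannot "drift randomly".
* **Raster protocol**: three label units are stimulated in sequence
  (500 Hz, 2 s total), then the network runs free for the remaining
  duration.  Visits are counted as classes that emit any self-generated
  label spike in the free phase.

With the depression kernel enabled the free-running network visits three
of the four classes in 20 s; with it disabled, strictly fewer — the
kernel, not the noise, is what dislodges the network from the state it
samples.  The free-running trajectories are chaotic: tiny changes to the
kernel amplitude reorder which classes appear and for how long, so only
coarse statistics (number of classes visited) are stable quantities.

## Fusion experiment

The cue-integration experiment mixes the Poisson streams of two class
images per-spike (probability p from one, 1−p from the other) and mixes
two classes' auditory ISI streams at a 4:1 spike ratio, with the auditory
stream contributing a fixed share of all input spikes.  Recognition runs
with the recurrent top-RBM groups enabled and label spikes are tallied
over trials.  At a 10% auditory share, with vision ambiguous between the
ring and zed classes and audition favoring the "one" tone 4:1 over the
zed tone, the network selects zed — the only class consistent with both
cues — and largely suppresses the cue-inconsistent classes.  The visual
pair is chosen to share strokes (ring/zed share their horizontal bars) so
the mixed spike stream stays inside the pair's territory; mixing
non-overlapping glyphs produces an image no class explains and the
decision decouples from the intended ambiguity.

## Synthetic data

`make_toy_digits` renders one stroke glyph per class (up to 10) and
augments with random translations (±15% of image size), rotations (±3°)
and scalings (±10%).  The four benchmark glyphs (ring, one, zed, vee) use
distinct stroke orientations so the classes are separable; ambiguity in
the fusion experiments comes from per-spike stream mixing, not from glyph
similarity.  The synthetic cochlea emits one spike per
waveform period on channels near the tone's best frequency, phase-aligned
across channels with Gaussian jitter (σ = 50 µs default); pooled
inter-spike intervals are histogrammed into 100 logarithmic bins between
0.833 and 2.85 ms, and sliding 100 ms windows (30 ms stride, window-max
normalized) give the auditory rate vectors used in fusion training.

What the toy benchmark shows: that Siegert-trained weights transfer to the
event-driven network with small accuracy loss, that generative sampling
wanders under the depression kernel, and that audio-visual evidence
combines toward the consistent class.  What it does not show: performance
on natural handwriting variability (stroke glyphs are far more regular
than handwriting), realistic sensor noise (the cochlea model is
phase-perfect up to Gaussian jitter; no DVS noise model), or scaling
behavior beyond a few hundred units per layer.

## Known limitations

* The Siegert conditional is not the exact conditional of any energy
  model, so CD under it is a heuristic gradient; its small-scale label
  readout is measurably weaker than a logistic RBM's on identical
  features.
* The diffusion approximation fails for synapses stronger than ~V_th/10;
  nothing in the trainer prevents weights from growing there, though in
  practice they do not.
* Generation-mode dynamics are deterministic given the stimulus seed;
  variability across runs comes only from the stimulation stream.
* The engine is single-threaded by design; its contract is the ordered
  event queue, not wall-clock speed.
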