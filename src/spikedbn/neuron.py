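"""Firing-rate models of leaky integrate-and-fire (LIF) neurons.

The central object is the Siegert transform: the mean output rate of an LIF
neuron receiving Poisson spike trains through excitatory and inhibitory
synapses.  Because this transfer function is exactly the input-rate/output-rate
curve of the spiking neuron, a Boltzmann machine trained with Siegert
activations can be converted into a spiking network without changing a single
weight.  The module also provides the simpler threshold-linear rate for a
constant input current (the deterministic, zero-noise limit) and a
Monte-Carlo clock-driven LIF simulator used as an independent check of the
closed-form rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import quad
from scipy.special import erfcx, zeta

__all__ = [
    "LifParams",
    "RateInputs",
    "sigmoid_activation",
    "threshold_linear_rate",
    "siegert_rate",
    "siegert_rate_batch",
    "normalized_activation",
    "lif_poisson_monte_carlo",
    "QuadratureError",
]

#: |zeta(1/2)|, the constant coupling the synaptic time constant into the
#: integration bounds.  Evaluated from the zeta function, not hard-coded.
GAMMA_ZETA = float(abs(zeta(0.5)))

#: Below this membrane-potential noise level the diffusion integral is
#: degenerate and the deterministic threshold-linear rate is used instead.
SIGMA_EPS = 1e-12


class QuadratureError(FloatingPointError):
    """Raised when the Siegert integrand produces non-finite values."""


#: Neuron constants for self-sustained generation mode (long membrane
#: memory); weights trained at the default working point are retained.
GENERATION_WORKING_POINT = None  # assigned after LifParams is defined


@dataclass(frozen=True)
class LifParams:
    """Constants of a leaky integrate-and-fire neuron.

    Potentials are in dimensionless model units, times in seconds.  The
    default (tau_m = 10 ms, v_th = 0.005, v_reset = 0, t_ref = 2 ms) is the
    training/recognition working point: the normalized Siegert activation
    then saturates within a physically reachable input range.  For
    self-sustained generative sampling use GENERATION_WORKING_POINT
    (tau_m = 800 ms), the regime in which a converted network keeps itself
    active; 1/t_ref = 500 Hz is the rate ceiling in both.
    """

    v_rest: float = 0.0
    v_reset: float = 0.0
    v_th: float = 0.005
    tau_m: float = 0.010
    t_ref: float = 0.002
    tau_syn: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_th > self.v_reset:
            raise ValueError("v_th must exceed v_reset")
        if self.tau_m <= 0 or self.t_ref <= 0:
            raise ValueError("tau_m and t_ref must be positive")
        if self.tau_syn < 0:
            raise ValueError("tau_syn must be non-negative")

    @property
    def max_rate(self) -> float:
        """Refractory-limited firing-rate ceiling, 1/t_ref (Hz)."""
        return 1.0 / self.t_ref


@dataclass
class RateInputs:
    """Poisson input description: per-channel rates (Hz) and synaptic weights.

    Weights are membrane-potential increments per spike; excitatory weights
    are non-negative, inhibitory non-positive.
    """

    exc_rates: np.ndarray = field(default_factory=lambda: np.zeros(0))
    exc_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))
    inh_rates: np.ndarray = field(default_factory=lambda: np.zeros(0))
    inh_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.exc_rates = np.atleast_1d(np.asarray(self.exc_rates, dtype=float))
        self.exc_weights = np.atleast_1d(np.asarray(self.exc_weights, dtype=float))
        self.inh_rates = np.atleast_1d(np.asarray(self.inh_rates, dtype=float))
        self.inh_weights = np.atleast_1d(np.asarray(self.inh_weights, dtype=float))
        if self.exc_rates.shape != self.exc_weights.shape:
            raise ValueError("excitatory rates/weights length mismatch")
        if self.inh_rates.shape != self.inh_weights.shape:
            raise ValueError("inhibitory rates/weights length mismatch")
        if np.any(self.exc_rates < 0) or np.any(self.inh_rates < 0):
            raise ValueError("rates must be non-negative")
        if np.any(self.exc_weights < 0):
            raise ValueError("excitatory weights must be non-negative")
        if np.any(self.inh_weights > 0):
            raise ValueError("inhibitory weights must be non-positive")


def sigmoid_activation(x):
    """Logistic function 1/(1+exp(-x)), the classic binary-unit activation."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def threshold_linear_rate(params: LifParams, s) -> float:
    """Mean rate of an LIF neuron under a constant input potential drive.

    ``s`` is the asymptotic membrane potential the constant input would
    produce.  The rate is ``1/(t_ref - tau_m*log(1 - v_th/s))`` for
    ``s > v_th`` and 0 otherwise (at ``s == v_th`` the charging time
    diverges, so the strict branch returns 0).
    """
    s = np.asarray(s, dtype=float)
    rate = np.zeros_like(s)
    above = s > params.v_th
    if np.any(above):
        sa = s[above]
        rate[above] = 1.0 / (params.t_ref - params.tau_m * np.log1p(-params.v_th / sa))
    return rate if rate.ndim else float(rate)


def _siegert_moments(params: LifParams, inputs: RateInputs):
    """Mean and variance of the free membrane potential (diffusion limit)."""
    mu = params.tau_m * (
        np.sum(inputs.exc_weights * inputs.exc_rates)
        + np.sum(inputs.inh_weights * inputs.inh_rates)
    )
    var = (params.tau_m / 2.0) * (
        np.sum(inputs.exc_weights**2 * inputs.exc_rates)
        + np.sum(inputs.inh_weights**2 * inputs.inh_rates)
    )
    return mu, var


# Arguments beyond this make exp(z^2) overflow; the integral is then
# effectively infinite and the output rate is numerically zero.
_Z_OVERFLOW = 25.0


def siegert_rate(params: LifParams, inputs: RateInputs) -> float:
    """Mean firing rate (Hz) of an LIF neuron under Poisson input.

    Computes the Siegert transform: with free-membrane mean mu_Q and
    variance sigma_Q^2,

        rho = [ t_ref + (tau_m/sigma_Q) sqrt(pi/2)
                * int_{V_reset+k*gamma*sigma_Q}^{V_th+k*gamma*sigma_Q}
                  exp((u-Y)^2 / 2 sigma_Q^2) (1+erf((u-Y)/(sigma_Q sqrt 2))) du ]^-1

    with Y = v_rest + mu_Q, k = sqrt(tau_syn/tau_m) and gamma = |zeta(1/2)|.
    The integrand is evaluated through the scaled complementary error
    function, erfcx(-z) = exp(z^2)(1+erf(z)), which is stable for all z.
    When sigma_Q vanishes the result reduces to ``threshold_linear_rate``
    evaluated at Y.
    """
    mu, var = _siegert_moments(params, inputs)
    if not (np.isfinite(mu) and np.isfinite(var)):
        raise QuadratureError(f"non-finite input moments (mu={mu}, var={var})")
    ups = params.v_rest + mu
    if var < SIGMA_EPS**2:
        return threshold_linear_rate(params, ups)
    sigma = np.sqrt(var)
    k = np.sqrt(params.tau_syn / params.tau_m)
    shift = k * GAMMA_ZETA * sigma
    lo = params.v_reset + shift
    hi = params.v_th + shift
    inv_s2 = 1.0 / (sigma * np.sqrt(2.0))

    zmax = (hi - ups) * inv_s2
    if zmax > _Z_OVERFLOW:
        # Sub-threshold regime so deep that the escape integral overflows:
        # the output rate is zero to double precision.
        return 0.0

    def integrand(u):
        return erfcx(-(u - ups) * inv_s2)

    val, _ = quad(integrand, lo, hi, epsrel=1e-6, limit=200)
    if not np.isfinite(val):
        raise QuadratureError(
            f"Siegert quadrature diverged (mu={mu}, sigma={sigma}, "
            f"bounds=({lo}, {hi}))"
        )
    rate = 1.0 / (params.t_ref + (params.tau_m / sigma) * np.sqrt(np.pi / 2.0) * val)
    return float(rate)


# Gauss-Legendre nodes/weights reused by the vectorized evaluator.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)
_N_PANELS = 2


def siegert_rate_batch(params: LifParams, mu, var):
    """Vectorized Siegert transform from precomputed membrane moments.

    ``mu`` and ``var`` are arrays of the free-membrane mean and variance
    (same meaning as in :func:`siegert_rate`).  Uses composite Gauss-Legendre
    quadrature (8 panels x 24 nodes); agrees with the adaptive scalar path to
    well below the Monte-Carlo tolerance.  Used by the training loop, where a
    scalar adaptive call per unit would dominate the run time.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    out = np.zeros(mu.shape)
    ups = params.v_rest + mu
    sigma = np.sqrt(np.maximum(var, 0.0))

    det = sigma < SIGMA_EPS
    if np.any(det):
        out[det] = threshold_linear_rate(params, ups[det])

    sto = ~det
    if np.any(sto):
        s = sigma[sto]
        y = ups[sto]
        k = np.sqrt(params.tau_syn / params.tau_m)
        shift = k * GAMMA_ZETA * s
        lo = params.v_reset + shift
        hi = params.v_th + shift
        inv_s2 = 1.0 / (s * np.sqrt(2.0))
        zmax = (hi - y) * inv_s2
        ok = zmax <= _Z_OVERFLOW

        # panel edges: (n_cfg, n_panels+1)
        edges = lo[:, None] + (hi - lo)[:, None] * np.linspace(0.0, 1.0, _N_PANELS + 1)
        mid = 0.5 * (edges[:, :-1] + edges[:, 1:])
        half = 0.5 * (edges[:, 1:] - edges[:, :-1])
        # evaluation points: (n_cfg, n_panels, n_nodes)
        u = mid[:, :, None] + half[:, :, None] * _GL_NODES
        z = -(u - y[:, None, None]) * inv_s2[:, None, None]
        z = np.where(ok[:, None, None], z, 0.0)  # masked configs: dummy args
        f = erfcx(z)
        integral = np.sum(f * _GL_WEIGHTS * half[:, :, None], axis=(1, 2))
        rate = 1.0 / (params.t_ref + (params.tau_m / s) * np.sqrt(np.pi / 2.0) * integral)
        out[sto] = np.where(ok, rate, 0.0)
    return out


def normalized_activation(params: LifParams, inputs: RateInputs) -> float:
    """Siegert rate normalized by the maximum rate 1/t_ref, in [0, 1].

    This is the activation probability used in place of the sigmoid when
    training Boltzmann machines destined for spiking conversion.
    """
    return siegert_rate(params, inputs) * params.t_ref


@njit(cache=True)
def _lif_clock_sim(v_rest, v_reset, v_th, tau_m, t_ref, rates, weights,
                   dt, duration, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_steps = int(duration / dt)
    decay = np.exp(-dt / tau_m)
    n_ch = rates.shape[0]
    p_spike = rates * dt  # per-step Poisson thinning (dt << 1/rate)
    v = v_rest
    ref_until = -1.0
    n_out = 0
    for step in range(n_steps):
        t = step * dt
        v = v_rest + (v - v_rest) * decay
        if t < ref_until:
            # inputs during refractoriness are discarded
            for c in range(n_ch):
                if np.random.random() < p_spike[c]:
                    pass
            continue
        for c in range(n_ch):
            if np.random.random() < p_spike[c]:
                v += weights[c]
        if v >= v_th:
            n_out += 1
            v = v_reset
            ref_until = t + t_ref
    return n_out


def lif_poisson_monte_carlo(
    params: LifParams,
    inputs: RateInputs,
    duration: float = 10.0,
    n_runs: int = 20,
    dt: float = 1e-5,
    seed: int = 0,
) -> float:
    """Empirical LIF firing rate under Poisson input (clock-driven, Hz).

    Independent of the closed-form rates: simulates the membrane equation on
    a fixed grid (default dt = 0.01 ms) with Bernoulli-thinned Poisson
    arrivals, averaging spike counts over ``n_runs`` independent runs.
    """
    rates = np.concatenate([inputs.exc_rates, inputs.inh_rates])
    weights = np.concatenate([inputs.exc_weights, inputs.inh_weights])
    total = 0
    for r in range(n_runs):
        total += _lif_clock_sim(
            params.v_rest, params.v_reset, params.v_th, params.tau_m,
            params.t_ref, rates, weights, dt, duration,
            np.uint32((seed + 77003 * r) % (2**31 - 1)),
        )
    return total / (n_runs * duration)


GENERATION_WORKING_POINT = LifParams(tau_m=0.8)
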