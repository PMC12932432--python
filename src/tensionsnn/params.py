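"""Model parameter containers.

Defaults are the standard operating point of the model: a leaky
integrate-and-fire network whose synapses release vesicles with
tension-dependent baseline efficacy and recovery speed, and whose weights
follow trace-based STDP with continuous forgetting.

Units: time in ms, voltages in mV, rates in Hz, positions in um. Tension
``eps`` is a dimensionless strain-like quantity with resting value
``eps0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a parameter set or run configuration is invalid."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters of the leaky integrate-and-fire neuron.

    The membrane potential relaxes toward ``v_rest`` with time constant
    ``tau_membrane``; a threshold crossing emits a spike and resets the
    potential to ``v_reset``.
    """

    v_rest: float = -74.0       # mV
    v_reset: float = -60.0      # mV
    v_threshold: float = -54.0  # mV
    tau_membrane: float = 10.0  # ms
    dt: float = 0.1             # ms

    def __post_init__(self) -> None:
        if self.v_reset >= self.v_threshold:
            raise ConfigurationError("v_reset must be below v_threshold")
        if self.tau_membrane <= 0:
            raise ConfigurationError("tau_membrane must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Vesicle-dynamics and transmission parameters.

    ``j_base`` is the baseline release potential at resting tension;
    ``c1``/``c2`` shape its tension dependence. ``u0`` is the resting
    vesicle release probability (facilitated by each presynaptic spike,
    relaxing back with ``tau_u``); ``r0`` the resting releasable pool,
    replenished with tension-dependent time constant ``tau0`` at rest.
    ``gamma`` scales inhibitory transmission (the excitatory:inhibitory
    count ratio of the reference network). ``w_max`` bounds plastic
    weights and ``eps0`` is the resting tension.
    """

    j_base: float = 0.01   # mV
    c1: float = 0.1        # mV
    c2: float = 0.01       # dimensionless
    u0: float = 0.2        # probability
    tau_u: float = 1000.0  # ms
    r0: float = 1.0        # vesicle volume (normalized)
    tau0: float = 100.0    # ms
    gamma: float = 4.0     # inhibitory scale
    w_max: float = 5.0     # dimensionless
    eps0: float = 0.001    # resting tension
    delay_ms: float = 0.1  # minimum synaptic transmission latency
    delay_jitter_ms: float = 0.0  # per-synapse extra latency, U[0, jitter]

    def __post_init__(self) -> None:
        if not (0.0 < self.u0 <= 1.0):
            raise ConfigurationError("u0 must be in (0, 1]")
        if self.r0 <= 0:
            raise ConfigurationError("r0 must be positive")
        if self.gamma < 0:
            raise ConfigurationError("gamma must be non-negative")
        if self.w_max <= 0:
            raise ConfigurationError("w_max must be positive")
        if self.eps0 <= 0:
            raise ConfigurationError("eps0 must be positive")
        if self.tau_u <= 0 or self.tau0 <= 0:
            raise ConfigurationError("tau_u and tau0 must be positive")
        if self.delay_ms <= 0:
            raise ConfigurationError("delay_ms must be positive")
        if self.delay_jitter_ms < 0:
            raise ConfigurationError("delay_jitter_ms must be non-negative")


@dataclass(frozen=True)
class PlasticityParams:
    """Trace-STDP and forgetting parameters.

    Each spike bumps the neuron's own trace by ``f_w`` (positive
    presynaptic trace, negative postsynaptic trace); traces decay with
    ``tau_w``. Weight updates read the partner trace at spike times.
    All weights decay continuously at forgetting rate ``alpha``.
    ``plastic_inhibitory`` controls whether synapses with an inhibitory
    presynaptic neuron undergo STDP.
    """

    f_w: float = 0.05        # trace increment
    tau_w: float = 20.0      # ms
    alpha: float = 0.25      # Hz (continuous forgetting rate)
    w_max: float = 5.0       # dimensionless
    plastic_inhibitory: bool = True

    def __post_init__(self) -> None:
        if self.f_w <= 0:
            raise ConfigurationError("f_w must be positive")
        if self.tau_w <= 0:
            raise ConfigurationError("tau_w must be positive")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be non-negative")
        if self.w_max <= 0:
            raise ConfigurationError("w_max must be positive")


@dataclass(frozen=True)
class ExternalDriveParams:
    """Stochastic background drive: a fixed random subset of network
    neurons emits spikes with exponentially distributed inter-spike
    intervals (a Poisson process at ``rate`` per neuron)."""

    n_external: int = 1000  # number of driven neurons
    rate: float = 13.0      # Hz per driven neuron

    def __post_init__(self) -> None:
        if self.n_external < 0:
            raise ConfigurationError("n_external must be non-negative")
        if self.rate < 0:
            raise ConfigurationError("rate must be non-negative")


def params_to_dict(p) -> dict:
    """Flatten a params dataclass into a plain dict (for config echo)."""
    return {f.name: getattr(p, f.name) for f in fields(p)}
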