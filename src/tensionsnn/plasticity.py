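"""Trace-based STDP with continuous forgetting.

Every neuron carries two exponentially decaying spike traces: a
presynaptic trace ``A_pre`` that jumps by ``+f_w`` when the neuron
fires, and a postsynaptic trace ``A_post`` that jumps by ``-f_w``. At a
presynaptic spike each outgoing weight is incremented by the target's
(non-positive) ``A_post`` -- depression when the target fired recently.
At a postsynaptic spike each incoming weight is incremented by the
source's (non-negative) ``A_pre`` -- potentiation when the source fired
recently. Weights additionally decay at a continuous forgetting rate
``alpha`` and are clamped to ``[0, w_max]`` after every update.

Order of operations inside one time step: (1) decay traces and weights,
(2) bump the traces of all neurons spiking this step, (3) apply the
pre-spike then post-spike weight updates using the bumped traces,
(4) clamp. With that order a simultaneous pre+post spike pair yields a
potentiation and depression of equal magnitude ``f_w`` -- net zero.
"""

from __future__ import annotations

from math import exp

import numpy as np

from .params import PlasticityParams


def trace_decay_factor(dt: float, params: PlasticityParams) -> float:
    return exp(-dt / params.tau_w)


def forget_factor(dt_ms: float, params: PlasticityParams) -> float:
    """Per-step multiplicative forgetting, exp(-alpha * dt). ``alpha``
    is a rate in Hz, dt in ms."""
    return exp(-params.alpha * dt_ms * 1e-3)


def forget(w_values: np.ndarray, dt_ms: float,
           params: PlasticityParams) -> np.ndarray:
    """Continuous forgetting over an interval: w <- w * exp(-alpha dt)."""
    return np.asarray(w_values, dtype=float) * forget_factor(dt_ms, params)


def on_pre_spike(a_pre_j: float, a_post_i_values: np.ndarray,
                 w_ji_values: np.ndarray, params: PlasticityParams):
    """Presynaptic spike of neuron j: bump its trace, depress outgoing
    weights by the targets' postsynaptic traces. Returns
    ``(a_pre_j, w)`` after clamping."""
    a_pre_j = a_pre_j + params.f_w
    w = np.asarray(w_ji_values, dtype=float) + np.asarray(a_post_i_values, dtype=float)
    np.clip(w, 0.0, params.w_max, out=w)
    return a_pre_j, w


def on_post_spike(a_post_i: float, a_pre_j_values: np.ndarray,
                  w_ji_values: np.ndarray, params: PlasticityParams):
    """Postsynaptic spike of neuron i: drop its trace, potentiate
    incoming weights by the sources' presynaptic traces. Returns
    ``(a_post_i, w)`` after clamping."""
    a_post_i = a_post_i - params.f_w
    w = np.asarray(w_ji_values, dtype=float) + np.asarray(a_pre_j_values, dtype=float)
    np.clip(w, 0.0, params.w_max, out=w)
    return a_post_i, w
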