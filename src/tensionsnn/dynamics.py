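"""Coupled membrane / synapse dynamics.

The engine advances a leaky integrate-and-fire network in fixed steps
``dt``. Synaptic transmission is event-based: when presynaptic neuron j
fires, every postsynaptic target i receives an instantaneous potential
increment ``J(eps) + s_j * w_ji`` (scaled by ``-gamma`` for inhibitory
presynaptic neurons), applied at the *next* integration step (one-dt
transmission latency). ``s_j = u_j * R_j`` is the expected released
vesicle volume of the presynaptic terminal: the release probability
``u`` facilitates with each spike and relaxes to ``u0`` with ``tau_u``;
the releasable pool ``R`` is depleted by release and recovers toward
``R0`` with the tension-dependent time constant ``tau_R(eps)``. One
``(u, R)`` pair is kept per presynaptic neuron, shared across its
outgoing synapses; the plastic weight ``w`` is per synapse.

Update order within one step at time t (mirrored exactly by the scalar
reference used in the tests):

1. tension lookup eps(t);
2. exponential decay of the STDP traces, of u toward u0, and of R
   toward R0 (weights decay implicitly at the forgetting rate);
3. membrane leak (forward Euler), then application of the synaptic
   increments delivered by spikes of the previous step, then external
   stimulus increments scheduled for this step;
4. spike determination: threshold crossings plus forced background
   events; spiking neurons are logged and reset to ``v_reset``;
5. vesicle release for spiking neurons: u jumps by ``u0 (1 - u)``,
   ``s = u_after * R``, R drops by s;
6. synaptic delivery into the next step's increment buffer;
7. STDP: trace jumps (+f_w presynaptic, -f_w postsynaptic) for all
   spiking neurons, then pre-spike (depression) and post-spike
   (potentiation) weight updates using the bumped traces, then a single
   clamp to [0, w_max].

Decays use exact per-step exponential factors by default so the bound
invariants (u in [0,1], R in [0,R0], w in [0,w_max]) hold to machine
precision; plain forward-Euler decay is available for convergence
studies via ``exact_decay=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp
from typing import Optional

import numpy as np

from .geometry import NetworkGeometry
from .params import (ConfigurationError, ExternalDriveParams, NeuronParams,
                     PlasticityParams, SynapseParams)
from .tension import TensionSchedule, baseline_release, recovery_tau

SOURCE_INTRINSIC = 0
SOURCE_EXTERNAL = 1
SOURCE_STIMULUS = 2
SOURCE_NAMES = {SOURCE_INTRINSIC: "intrinsic",
                SOURCE_EXTERNAL: "external",
                SOURCE_STIMULUS: "forced-stimulus"}
SOURCE_CODES = {v: k for k, v in SOURCE_NAMES.items()}


class NumericalError(RuntimeError):
    """Raised when the membrane state becomes non-finite."""


# ---------------------------------------------------------------------------
# spike record


@dataclass
class SpikeRecord:
    """Time-stamped spike events (neuron id, time in ms, source)."""

    neuron_ids: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int32))
    times_ms: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.float64))
    sources: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self):
        if not (len(self.neuron_ids) == len(self.times_ms) == len(self.sources)):
            raise ConfigurationError("spike record arrays must share length")
        if len(self.times_ms) > 1 and np.any(np.diff(self.times_ms) < 0):
            raise ConfigurationError("spike times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times_ms)

    def window(self, t0_ms: float, t1_ms: float) -> "SpikeRecord":
        """Events with t0 <= t < t1."""
        m = (self.times_ms >= t0_ms) & (self.times_ms < t1_ms)
        return SpikeRecord(self.neuron_ids[m], self.times_ms[m], self.sources[m])

    def restrict(self, member_ids) -> "SpikeRecord":
        m = np.isin(self.neuron_ids, np.asarray(member_ids))
        return SpikeRecord(self.neuron_ids[m], self.times_ms[m], self.sources[m])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "neuron_id": self.neuron_ids,
            "t_ms": self.times_ms,
            "source": [SOURCE_NAMES[s] for s in self.sources],
        })

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        # 0.1 ms grid -> one decimal is exact
        df["t_ms"] = df["t_ms"].map(lambda t: f"{t:.1f}")
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SpikeRecord":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(df["neuron_id"].to_numpy(np.int32),
                   df["t_ms"].to_numpy(np.float64),
                   np.array([SOURCE_CODES[s] for s in df["source"]], dtype=np.int8))

    def write_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("neuron_id", data=self.neuron_ids)
            f.create_dataset("t_ms", data=self.times_ms)
            f.create_dataset("source", data=self.sources)

    @classmethod
    def read_hdf5(cls, path) -> "SpikeRecord":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(f["neuron_id"][:], f["t_ms"][:], f["source"][:])


# ---------------------------------------------------------------------------
# stateless kernels (the definitional single-variable updates)


def membrane_step(v: np.ndarray, synaptic_input_mv, external_input_mv,
                  params: NeuronParams):
    """One forward-Euler membrane update with instantaneous inputs.

    Returns ``(v_next, spiked)``; spiking entries are reset to
    ``v_reset`` in the same step.
    """
    v = np.asarray(v, dtype=float)
    lam = params.dt / params.tau_membrane
    v_next = v + lam * (params.v_rest - v)
    v_next = v_next + synaptic_input_mv + external_input_mv
    if not np.all(np.isfinite(v_next)):
        raise NumericalError("non-finite membrane potential")
    spiked = v_next >= params.v_threshold
    v_next = np.where(spiked, params.v_reset, v_next)
    return v_next, spiked


def update_u_on_spike(u_now, params: SynapseParams):
    """Facilitation jump at a presynaptic spike: u <- u + u0 (1 - u)."""
    return u_now + params.u0 * (1.0 - u_now)


def decay_u(u_now, dt_ms: float, params: SynapseParams, exact: bool = True):
    """Relaxation of u toward u0 over ``dt_ms`` without spikes."""
    if exact:
        f = exp(-dt_ms / params.tau_u)
        return params.u0 + (u_now - params.u0) * f
    return u_now + (dt_ms / params.tau_u) * (params.u0 - u_now)


def release_and_recover_R(r_now, u_after, spiked: bool, eps: float,
                          dt_ms: float, params: SynapseParams,
                          exact: bool = True):
    """Vesicle release (if ``spiked``) followed by recovery toward R0.

    Returns ``(r_next, s)`` with ``s`` the released volume
    ``u_after * r_now`` (zero without a spike).
    """
    s = u_after * r_now if spiked else 0.0
    r = r_now - s
    tau_r = recovery_tau(eps, params)
    if exact:
        f = exp(-dt_ms / tau_r)
        r = params.r0 + (r - params.r0) * f
    else:
        r = r + (dt_ms / tau_r) * (params.r0 - r)
    return r, s


def baseline_J(eps: float, params: SynapseParams) -> float:
    """Tension-dependent history-independent release potential (mV)."""
    return baseline_release(eps, params)


def deliver_spike(s_pre: float, w_out: np.ndarray, pre_is_inhibitory: bool,
                  eps: float, params: SynapseParams) -> np.ndarray:
    """Potential increments to the postsynaptic targets of one spike:
    ``+(J(eps) + s w)`` for an excitatory source, ``-gamma (J(eps) + s w)``
    for an inhibitory one."""
    base = baseline_release(eps, params) + s_pre * np.asarray(w_out, dtype=float)
    return -params.gamma * base if pre_is_inhibitory else base


def external_poisson_drive(rng: np.random.Generator, selected_ids: np.ndarray,
                           rate_hz: float, t_start_ms: float, t_stop_ms: float,
                           dt_ms: float):
    """Forced-spike event times for a Poisson background drive.

    Each selected neuron carries an independent spike train with
    exponential inter-spike intervals at mean rate ``rate_hz``. Events
    are snapped to the step grid. Returns ``(steps, ids)`` sorted by
    step.
    """
    if rate_hz < 0:
        raise ConfigurationError("rate must be non-negative")
    if rate_hz == 0 or len(selected_ids) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int32)
    mean_isi_ms = 1000.0 / rate_hz
    steps_all, ids_all = [], []
    span = t_stop_ms - t_start_ms
    for nid in selected_ids:
        t = t_start_ms
        times = []
        # draw in blocks for speed
        while t < t_stop_ms:
            block = rng.exponential(mean_isi_ms, size=max(4, int(span / mean_isi_ms) + 4))
            for isi in block:
                t += isi
                if t >= t_stop_ms:
                    break
                times.append(t)
        if times:
            st = np.floor(np.asarray(times) / dt_ms).astype(np.int64)
            steps_all.append(st)
            ids_all.append(np.full(len(st), nid, dtype=np.int32))
    if not steps_all:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int32)
    steps = np.concatenate(steps_all)
    ids = np.concatenate(ids_all)
    order = np.argsort(steps, kind="stable")
    return steps[order], ids[order]


def _gather_slices(indptr: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Concatenated index ranges ``indptr[r]:indptr[r+1]`` for rows."""
    counts = indptr[rows + 1] - indptr[rows]
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0, dtype=np.int64)
    starts = np.repeat(indptr[rows], counts)
    offs = np.arange(total, dtype=np.int64) - np.repeat(
        np.cumsum(counts) - counts, counts)
    return starts + offs


# ---------------------------------------------------------------------------
# vectorized engine


class Simulator:
    """Event-driven vectorized simulator for one network realization.

    Stimulus pulses are supplied as pre-compiled event arrays
    (``add_stimulus_events``); the Poisson background drive is enabled
    with ``enable_external`` and extended lazily as the simulation
    advances. ``run(t_stop_ms)`` may be called repeatedly; state and the
    spike log persist across calls.
    """

    def __init__(self, geometry: NetworkGeometry,
                 neuron: Optional[NeuronParams] = None,
                 synapse: Optional[SynapseParams] = None,
                 plasticity: Optional[PlasticityParams] = None,
                 schedule: Optional[TensionSchedule] = None,
                 seed: int = 0, exact_decay: bool = True,
                 debug: bool = False):
        self.geometry = geometry
        self.neuron = neuron or NeuronParams()
        self.synapse = synapse or SynapseParams()
        self.plasticity = plasticity or PlasticityParams()
        self.schedule = schedule  # None -> constant resting tension
        self.seed = seed
        self.exact_decay = exact_decay
        self.debug = debug

        n = geometry.n_neurons
        syn = geometry.synapses
        pre, post = syn[:, 0].astype(np.int64), syn[:, 1].astype(np.int64)
        # CSR by presynaptic neuron (synapses are pre-sorted lexicographically)
        self._out_ptr = np.searchsorted(pre, np.arange(n + 1))
        self._out_post = post
        # CSC by postsynaptic neuron, with positions into the CSR arrays
        perm = np.lexsort((pre, post))
        self._in_ptr = np.searchsorted(post[perm], np.arange(n + 1))
        self._in_pos = perm            # csc slot -> csr synapse index
        self._in_pre = pre[perm]
        self._inh = geometry.is_inhibitory.copy()
        self._pre_factor = np.where(self._inh, -self.synapse.gamma, 1.0)
        if self.plasticity.plastic_inhibitory:
            self._plastic = np.ones(len(pre), dtype=bool)
        else:
            self._plastic = ~self._inh[pre]

        # state
        self.k = 0                     # current step index; t = k * dt
        self.v = np.full(n, self.neuron.v_rest)
        self.u = np.full(n, self.synapse.u0)
        self.r = np.full(n, self.synapse.r0)
        self.a_pre = np.zeros(n)
        self.a_post = np.zeros(n)
        # forgetting-compensated weights: w_true = _wtil * exp(-alpha t)
        self._wtil = np.zeros(len(pre))
        # delivery ring buffer: a spike at step k lands at step
        # k + delay(synapse); per-synapse latencies are drawn once,
        # uniformly over [delay_ms, delay_ms + delay_jitter_ms]
        dt = self.neuron.dt
        d_lo = max(1, int(round(self.synapse.delay_ms / dt)))
        if self.synapse.delay_jitter_ms > 0:
            # latencies are a property of the wiring: seed from geometry
            d_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=abs(int(geometry.seed)),
                                       spawn_key=(41,)))
            extra = d_rng.integers(
                0, int(round(self.synapse.delay_jitter_ms / dt)) + 1,
                size=len(pre))
            self._syn_delay = (d_lo + extra).astype(np.int64)
        else:
            self._syn_delay = np.full(len(pre), d_lo, dtype=np.int64)
        self._delay_steps = int(self._syn_delay.max()) + 1
        self._pending = np.zeros((self._delay_steps, n))

        self._spk_ids, self._spk_steps, self._spk_src = [], [], []

        # stimulus events
        self._stim_step = np.zeros(0, dtype=np.int64)
        self._stim_id = np.zeros(0, dtype=np.int32)
        self._stim_amp = np.zeros(0, dtype=np.float64)
        self._stim_sorted = True

        # external drive
        self._ext = None               # ExternalDriveParams
        self._ext_ids = np.zeros(0, dtype=np.int32)
        self._ext_rng = None
        self._ext_step = np.zeros(0, dtype=np.int64)
        self._ext_id = np.zeros(0, dtype=np.int32)
        self._ext_generated_until = 0.0

    # -- configuration ------------------------------------------------------

    @property
    def t_ms(self) -> float:
        return self.k * self.neuron.dt

    @property
    def weights(self) -> np.ndarray:
        """Current true weights, aligned with ``geometry.synapses``."""
        return self._wtil * exp(-self.plasticity.alpha * self.t_ms * 1e-3)

    @weights.setter
    def weights(self, w: np.ndarray) -> None:
        self._wtil = np.asarray(w, dtype=float) * exp(
            self.plasticity.alpha * self.t_ms * 1e-3)

    def add_stimulus_events(self, steps: np.ndarray, ids: np.ndarray,
                            amps: np.ndarray) -> None:
        """Register voltage-pulse events (absolute step, neuron, mV)."""
        self._stim_step = np.concatenate([self._stim_step, np.asarray(steps, np.int64)])
        self._stim_id = np.concatenate([self._stim_id, np.asarray(ids, np.int32)])
        self._stim_amp = np.concatenate([self._stim_amp, np.asarray(amps, float)])
        self._stim_sorted = False

    def enable_external(self, params: Optional[ExternalDriveParams] = None,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Enable the Poisson background drive; returns the driven ids."""
        params = params or ExternalDriveParams()
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(17,))
        rng = rng or np.random.default_rng(ss)
        n_sel = min(params.n_external, self.geometry.n_neurons)
        self._ext_ids = np.sort(rng.permutation(self.geometry.n_neurons)[:n_sel]
                                ).astype(np.int32)
        self._ext = params
        self._ext_rng = rng
        self._ext_generated_until = self.t_ms
        return self._ext_ids

    def _extend_external(self, t_stop: float) -> None:
        if self._ext is None or self._ext.rate == 0:
            return
        t0 = self._ext_generated_until
        if t_stop <= t0:
            return
        steps, ids = external_poisson_drive(
            self._ext_rng, self._ext_ids, self._ext.rate, t0, t_stop,
            self.neuron.dt)
        keep = self._ext_step >= self.k  # drop consumed history
        self._ext_step = np.concatenate([self._ext_step[keep], steps])
        self._ext_id = np.concatenate([self._ext_id[keep], ids])
        order = np.argsort(self._ext_step, kind="stable")
        self._ext_step = self._ext_step[order]
        self._ext_id = self._ext_id[order]
        self._ext_generated_until = t_stop

    # -- main loop ----------------------------------------------------------

    def run(self, t_stop_ms: float) -> "Simulator":
        nrn, syn_p, pl = self.neuron, self.synapse, self.plasticity
        dt = nrn.dt
        k_stop = int(round(t_stop_ms / dt))
        if k_stop <= self.k:
            return self

        self._extend_external(t_stop_ms)
        if not self._stim_sorted:
            order = np.argsort(self._stim_step, kind="stable")
            self._stim_step = self._stim_step[order]
            self._stim_id = self._stim_id[order]
            self._stim_amp = self._stim_amp[order]
            self._stim_sorted = True
        stim_lo = int(np.searchsorted(self._stim_step, self.k))
        ext_lo = int(np.searchsorted(self._ext_step, self.k))

        # scalar per-step factors
        lam = dt / nrn.tau_membrane
        d_tr = exp(-dt / pl.tau_w)
        if self.exact_decay:
            d_u = exp(-dt / syn_p.tau_u)
        else:
            d_u = 1.0 - dt / syn_p.tau_u
        alpha_ms = pl.alpha * 1e-3

        eps = np.nan
        d_r = j_eps = 0.0
        gexp = exp(alpha_ms * self.k * dt)   # forgetting compensation e^{+alpha t}

        v, u, r = self.v, self.u, self.r
        a_pre, a_post = self.a_pre, self.a_post
        wtil, pending = self._wtil, self._pending
        n_delay = self._delay_steps
        syn_delay = self._syn_delay
        pending_flat = pending.reshape(-1)
        out_ptr, out_post = self._out_ptr, self._out_post
        in_ptr, in_pos, in_pre = self._in_ptr, self._in_pos, self._in_pre
        pre_factor, plastic = self._pre_factor, self._plastic
        all_plastic = bool(self._plastic.all())
        n = len(v)

        for k in range(self.k, k_stop):
            t = k * dt
            e = self.schedule.eps_at(t) if self.schedule is not None else syn_p.eps0
            if e != eps:
                eps = e
                tau_r = recovery_tau(eps, syn_p)
                d_r = exp(-dt / tau_r) if self.exact_decay else 1.0 - dt / tau_r
                j_eps = baseline_release(eps, syn_p)

            # 2. decays
            a_pre *= d_tr
            a_post *= d_tr
            u *= d_u
            u += syn_p.u0 * (1.0 - d_u)
            r *= d_r
            r += syn_p.r0 * (1.0 - d_r)

            # 3. membrane leak + queued synaptic input + stimulus pulses
            v *= (1.0 - lam)
            v += lam * nrn.v_rest
            row = k % n_delay
            v += pending[row]
            pending[row] = 0.0
            got_stim = None
            if stim_lo < len(self._stim_step) and self._stim_step[stim_lo] == k:
                hi = stim_lo
                while hi < len(self._stim_step) and self._stim_step[hi] == k:
                    hi += 1
                sid = self._stim_id[stim_lo:hi]
                np.add.at(v, sid, self._stim_amp[stim_lo:hi])
                got_stim = sid
                stim_lo = hi

            # 4. spikes: threshold crossings + forced background events
            spk_mask = v >= nrn.v_threshold
            forced = None
            if ext_lo < len(self._ext_step) and self._ext_step[ext_lo] == k:
                hi = ext_lo
                while hi < len(self._ext_step) and self._ext_step[hi] == k:
                    hi += 1
                forced = self._ext_id[ext_lo:hi]
                ext_lo = hi
            if forced is not None:
                spk_mask[forced] = True
            spk = np.nonzero(spk_mask)[0]
            if len(spk):
                src = np.zeros(len(spk), dtype=np.int8)
                if got_stim is not None and len(got_stim):
                    src[np.isin(spk, got_stim)] = SOURCE_STIMULUS
                if forced is not None and len(forced):
                    src[np.isin(spk, forced)] = SOURCE_EXTERNAL
                self._spk_ids.append(spk.astype(np.int32))
                self._spk_steps.append(np.full(len(spk), k, dtype=np.int64))
                self._spk_src.append(src)
                v[spk] = nrn.v_reset

                # 5. vesicle release
                u_spk = u[spk] + syn_p.u0 * (1.0 - u[spk])
                s_spk = u_spk * r[spk]
                u[spk] = u_spk
                r[spk] -= s_spk

                # 6. delivery into next-step buffer
                gexp = exp(alpha_ms * t)
                idx = _gather_slices(out_ptr, spk)
                if len(idx):
                    counts = out_ptr[spk + 1] - out_ptr[spk]
                    s_rep = np.repeat(s_spk, counts)
                    f_rep = np.repeat(pre_factor[spk], counts)
                    contrib = f_rep * (j_eps + s_rep * (wtil[idx] / gexp))
                    rows = (k + syn_delay[idx]) % n_delay
                    pending_flat += np.bincount(rows * n + out_post[idx],
                                                weights=contrib,
                                                minlength=n_delay * n)

                # 7. STDP
                a_pre[spk] += pl.f_w
                a_post[spk] -= pl.f_w
                if len(idx):
                    oidx = idx if all_plastic else idx[plastic[idx]]
                    # synapse indices are unique within a step
                    wtil[oidx] += a_post[out_post[oidx]] * gexp
                iidx = _gather_slices(in_ptr, spk)
                if len(iidx):
                    if not all_plastic:
                        iidx = iidx[plastic[in_pos[iidx]]]
                    wtil[in_pos[iidx]] += a_pre[in_pre[iidx]] * gexp
                touched = idx if not len(iidx) else (
                    in_pos[iidx] if not len(idx) else
                    np.concatenate([idx, in_pos[iidx]]))
                if len(touched):
                    wtil[touched] = np.clip(wtil[touched], 0.0, pl.w_max * gexp)

            if self.debug:
                if not np.all(np.isfinite(v)):
                    raise NumericalError(f"non-finite V at step {k}")
                assert u.min() >= 0.0 and u.max() <= 1.0 + 1e-12
                assert r.min() >= -1e-12 and r.max() <= syn_p.r0 + 1e-12
                wt = wtil / exp(alpha_ms * t)
                assert wt.min() >= -1e-9 and wt.max() <= pl.w_max + 1e-9
            elif k % 500 == 0 and not np.all(np.isfinite(v)):
                raise NumericalError(f"non-finite V at step {k}")

        self.k = k_stop
        return self

    def snapshot(self) -> dict:
        """Copy of the dynamical state (for branching recall phases)."""
        return {"k": self.k, "v": self.v.copy(), "u": self.u.copy(),
                "r": self.r.copy(), "a_pre": self.a_pre.copy(),
                "a_post": self.a_post.copy(), "wtil": self._wtil.copy(),
                "pending": self._pending.copy()}

    def restore(self, snap: dict) -> "Simulator":
        """Restore a snapshot taken from a simulator over the same
        geometry/parameters. The spike log is not restored."""
        self.k = snap["k"]
        self.v[:] = snap["v"]
        self.u[:] = snap["u"]
        self.r[:] = snap["r"]
        self.a_pre[:] = snap["a_pre"]
        self.a_post[:] = snap["a_post"]
        self._wtil[:] = snap["wtil"]
        self._pending[:] = snap["pending"]
        if self._ext is not None:
            self._ext_generated_until = max(self._ext_generated_until, self.t_ms)
        return self

    # -- results ------------------------------------------------------------

    def spike_record(self) -> SpikeRecord:
        if not self._spk_ids:
            return SpikeRecord()
        ids = np.concatenate(self._spk_ids)
        steps = np.concatenate(self._spk_steps)
        src = np.concatenate(self._spk_src)
        return SpikeRecord(ids, steps * self.neuron.dt, src)

    def weight_triplets(self):
        """(pre, post, w) arrays for nonzero current weights."""
        w = self.weights
        nz = w > 0
        syn = self.geometry.synapses
        return syn[nz, 0], syn[nz, 1], w[nz]
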