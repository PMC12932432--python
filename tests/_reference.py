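"""Independent scalar reference implementation of the network dynamics.

A deliberately slow, dictionary-and-loop transcription of the model's
documented update order, written without numpy vectorization or the
engine's forgetting-compensation trick. It serves as the oracle for
step-by-step equivalence tests on tiny networks.
"""

from math import exp


class ReferenceSimulator:
    """Pure-Python per-step simulator for a handful of neurons.

    ``synapses`` is a list of (pre, post) tuples; ``delays`` optional
    per-synapse latencies in steps (default 1).
    """

    def __init__(self, n, inhibitory, synapses, neuron, synapse, plasticity,
                 eps=None, delays=None):
        self.n = n
        self.inh = list(inhibitory)
        self.syn = list(synapses)
        self.np_ = neuron
        self.sp = synapse
        self.pp = plasticity
        self.eps = eps if eps is not None else synapse.eps0
        self.delays = list(delays) if delays is not None else [1] * len(synapses)
        self.max_delay = max(self.delays, default=1) + 1

        self.k = 0
        self.v = [neuron.v_rest] * n
        self.u = [synapse.u0] * n
        self.r = [synapse.r0] * n
        self.a_pre = [0.0] * n
        self.a_post = [0.0] * n
        self.w = [0.0] * len(synapses)
        self.pending = [[0.0] * n for _ in range(self.max_delay)]
        self.spikes = []  # (step, neuron)

        # stimulus / forced events: {step: [(neuron, amp)]}, {step: [ids]}
        self.stim = {}
        self.forced = {}

    def add_stim(self, step, neuron, amp):
        self.stim.setdefault(step, []).append((neuron, amp))

    def add_forced(self, step, neuron):
        self.forced.setdefault(step, []).append(neuron)

    def step(self):
        np_, sp, pp = self.np_, self.sp, self.pp
        dt = np_.dt
        k = self.k
        d_tr = exp(-dt / pp.tau_w)
        d_u = exp(-dt / sp.tau_u)
        x = (self.eps - sp.eps0) / sp.eps0
        tau_r = sp.tau0 * exp(-x)
        d_r = exp(-dt / tau_r)
        j_eps = sp.j_base + sp.c1 * (1.0 - exp(-sp.c2 * x))
        f_forget = exp(-pp.alpha * dt * 1e-3)

        # 2. decays (weights decay by the forgetting rate)
        for i in range(self.n):
            self.a_pre[i] *= d_tr
            self.a_post[i] *= d_tr
            self.u[i] = sp.u0 + (self.u[i] - sp.u0) * d_u
            self.r[i] = sp.r0 + (self.r[i] - sp.r0) * d_r
        for m in range(len(self.w)):
            self.w[m] *= f_forget

        # 3. leak + queued input + stimulus
        lam = dt / np_.tau_membrane
        row = self.pending[k % self.max_delay]
        for i in range(self.n):
            self.v[i] = self.v[i] * (1.0 - lam) + lam * np_.v_rest + row[i]
            row[i] = 0.0
        for (i, amp) in self.stim.get(k, []):
            self.v[i] += amp

        # 4. spikes
        spiked = [i for i in range(self.n) if self.v[i] >= np_.v_threshold]
        for i in self.forced.get(k, []):
            if i not in spiked:
                spiked.append(i)
        spiked.sort()
        s_val = {}
        for i in spiked:
            self.spikes.append((k, i))
            self.v[i] = np_.v_reset
            # 5. vesicle release
            u_after = self.u[i] + sp.u0 * (1.0 - self.u[i])
            s_val[i] = u_after * self.r[i]
            self.u[i] = u_after
            self.r[i] -= s_val[i]

        # 6. delivery
        for m, (j, i) in enumerate(self.syn):
            if j in s_val:
                inc = j_eps + s_val[j] * self.w[m]
                if self.inh[j]:
                    inc = -sp.gamma * inc
                self.pending[(k + self.delays[m]) % self.max_delay][i] += inc

        # 7. STDP
        touched = set()
        for i in spiked:
            self.a_pre[i] += pp.f_w
            self.a_post[i] -= pp.f_w
        for m, (j, i) in enumerate(self.syn):
            if not pp.plastic_inhibitory and self.inh[j]:
                continue
            if j in s_val:  # presynaptic spike -> depression
                self.w[m] += self.a_post[i]
                touched.add(m)
        for m, (j, i) in enumerate(self.syn):
            if not pp.plastic_inhibitory and self.inh[j]:
                continue
            if i in s_val:  # postsynaptic spike -> potentiation
                self.w[m] += self.a_pre[j]
                touched.add(m)
        for m in touched:
            self.w[m] = min(max(self.w[m], 0.0), pp.w_max)

        self.k += 1

    def run(self, n_steps):
        for _ in range(n_steps):
            self.step()
        return self
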