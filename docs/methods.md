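# Methods

`tensionsnn` simulates a spatially embedded spiking neural network whose
synaptic efficacy is modulated by a global mechanical-tension variable,
and reproduces four assembly-level memory experiments on top of it:
pattern completion, an excitatory/inhibitory balance sweep, projection
between two assemblies, and associative recall. This note records the
model, the choices made where the design was genuinely open, and what
the simulations do and do not show.

## Network substrate

`build_network` places `n_exc + n_inh` neurons uniformly at random in a
bounded rectangle (default 4,000 excitatory + 1,000 inhibitory in
1,000 x 1,000 um, i.e. 5,000 cells/mm^2; a four-fold larger network at
the same density reaches 20,000 neurons on 4 mm^2). Each neuron carries
one effective neurite length drawn from a normal distribution
(mean 200 um, SD 40 um, truncated at zero by resampling). An ordered
pair (j, i) is *eligible* if the Euclidean distance is strictly below
the combined neurite lengths; each eligible ordered pair independently
receives a synapse with probability 0.1. Self-connections are excluded
and an ordered pair carries at most one synapse; the two orientations of
a pair are sampled independently. Excitatory/inhibitory labels are
assigned by a random permutation, independent of position.

## Dynamics

Membrane potentials follow a leaky integrate-and-fire rule integrated by
forward Euler at dt = 0.1 ms:

    tau_m dV_i/dt = -(V_i - V_rest) + V_syn(t) + V_ext(t)

with V_rest = -74 mV, threshold -54 mV, reset -60 mV, tau_m = 10 ms.
Synaptic input is event-based: a spike of presynaptic neuron j delivers
an instantaneous increment `J(eps) + s_j * w_ji` to each target i
(scaled by `-gamma`, gamma = 4, when j is inhibitory).

* `J(eps) = J + c1 (1 - exp(-c2 x))`, `x = (eps - eps0)/eps0`, is the
  history-independent release potential (J = 0.01 mV, c1 = 0.1 mV,
  c2 = 0.01); it grows with tension.
* `s_j = u_j * R_j` is the expected released vesicle volume of terminal
  j. The release probability jumps at each spike of j,
  `u <- u + u0 (1 - u)` (u0 = 0.2), and relaxes to u0 with
  tau_u = 1,000 ms. The releasable pool is depleted by the released
  volume and recovers toward R0 = 1 with the tension-dependent constant
  `tau_R(eps) = tau_0 exp(-x)` (tau_0 = 100 ms): tension accelerates
  replenishment.
* One (u, R) pair is kept per presynaptic neuron and shared by all its
  outgoing synapses; the plastic weight w is per synapse.

Plasticity is trace-based STDP with continuous forgetting. Each neuron
carries a presynaptic trace (jump +F_w at its spikes) and a postsynaptic
trace (jump -F_w), both decaying with tau_w = 20 ms (F_w = 0.05). At a
presynaptic spike every outgoing weight is incremented by the target's
postsynaptic trace (depression); at a postsynaptic spike every incoming
weight is incremented by the source's presynaptic trace (potentiation).
Weights start at zero, decay continuously at alpha = 0.25 Hz, and are
clamped to [0, w_max] (w_max = 5) after each step's updates. With the
documented update order a simultaneous pre+post pair contributes +F_w
and -F_w in the same step - net zero. STDP applies to all synapses by
default; `plastic_inhibitory=False` restricts it to excitatory
presynapses.

Tension `eps(t)` is a single spatially uniform scalar given by a
piecewise-constant schedule (half-open segments); the resting value is
eps0 = 0.001. Tension changes are treated as instantaneous condition
switches. In the experiments the recall-phase tension level applies from
the end of training (the rest gap is part of the recall phase), so the
vesicle pools re-equilibrate under the recall tension before the first
cue - this is what makes first-cue release tension-dependent.

A fixed random subset of 1,000 network neurons carries a Poisson
background (13 Hz per neuron, exponential inter-spike intervals). These
events are forced spikes: they reset the membrane, release vesicles,
propagate synaptically and drive the plasticity traces like any other
spike.

### Numerical choices

* Decays of u, R and the STDP traces use exact per-step exponential
  factors so the bound invariants hold to machine precision; a forward
  Euler mode (`exact_decay=False`) exists for convergence checks.
  Membrane integration is forward Euler (first order in dt).
* Forgetting is folded into the weight storage (weights are kept
  premultiplied by exp(+alpha t)) so that continuous decay of ~10^6
  synapses costs nothing per step; all reads rescale exactly.
* Synaptic transmission uses a per-synapse latency ring buffer. The
  minimal latency is one time step; the experiments draw per-synapse
  latencies uniformly from [0.5, 6.5] ms (seeded by the geometry), a
  standard representation of axonal/synaptic delay heterogeneity. The
  delay spread is what stretches cue-evoked avalanches to the ~10 ms
  propagation scale of the recall maps; with single-step transmission
  avalanches complete within ~1 ms and every recall statistic
  saturates.
* Update order within a step: tension lookup; decays; membrane leak +
  queued synaptic input + stimulus pulses; spike determination (plus
  forced background events), logging and reset; vesicle release;
  delivery into the ring buffer; trace jumps, then depression and
  potentiation updates, then one clamp. A scalar pure-Python reference
  implementation of exactly this order backs the equivalence tests.
* One spike per neuron per step, no refractory period beyond the reset.

## Stimulation protocols

A protocol delivers periodic voltage pulses over a polygonal region
mask: training at 50 Hz, recall cues at 10 Hz, with a configurable
amplitude per pulse (one time step wide). Partial protocols target a
fixed random subset of the member neurons (e.g. 40%), identical for
every pulse; delayed protocols shift every onset by a fixed lag (2 ms
for the projection's downstream region).

The literal pulse of the model description (+2 mV for one step) can
never fire a neuron from rest: the rest-to-threshold gap is 20 mV and at
50 Hz the accumulated depolarization peaks below 2.4 mV. Since every
phenomenon of interest requires stimulated neurons to spike, the
experiment driver uses suprathreshold pulses (25 mV default) and models
the response of a stimulated population explicitly:

* a fixed per-neuron response latency, uniform on [0, 1] ms;
* a per-pulse response jitter, uniform on [0, 3] ms, redrawn each pulse
  (seeded) - this randomizes the spike order across pulses so that
  trace STDP potentiates both orientations of co-activated pairs
  instead of building a one-way latency hierarchy;
* inhibitory neurons respond 2 ms later (feedforward-inhibition lag).
  Because the depression side of the trace rule reads the *fresh*
  postsynaptic trace while potentiation of the lagged population reads
  a decayed one, this systematically keeps trained inhibitory weights
  well below excitatory ones (about 0.2x). Without the lag, gamma = 4
  at a 20% inhibitory fraction makes trained inhibition cancel trained
  excitation exactly and no recall is possible;
* each *training* pulse evokes a short burst (7 spikes at 1 ms
  spacing), the response of a tetanically driven cell; recall cues
  evoke single spikes. Bursts let the traces accumulate across the
  burst, which is what brings pairwise weight growth to a level where
  0.5-1 s of 50 Hz training forms a functional assembly; without them
  the maximum per-pulse weight change (~0.05) cannot reach recall
  threshold within the stated training durations.

These response constants are package parameters (`ExperimentConfig`),
calibrated once so that the model operates in the regime the
experiments describe - assemblies form within 0.5-1 s, cues ignite
recall that spreads over ~10 ms, and recall strength is graded in
training duration and tension - and then held fixed for every
experiment and every replicate.

## Region fixtures

All regions are parametric shapely polygons relative to the substrate
rectangle: a face (elliptical head spanning ~0.56 x 0.66 of the
substrate, with eye/nose/mouth openings), three cue rectangles placed
at seeded random interior positions and scaled to jointly cover
20% +- 1% of the face, a square (A) and triangle (B) for projection
(nearest edges ~20-40 um apart so that cross-region synapses exist
within neurite reach), an uninvolved control square (C), two
association rectangles (0.26 x 0.36 of the substrate, 120 um apart),
and a circular partial cue inside the face. Region membership is exact
point-in-polygon; rasters (10 um cells) are used only for IoU. The
face was sized so that a member's intra-region synaptic in-degree
(~100) gives cue volleys enough margin over threshold that replicate
geometry fluctuations do not tip recall across the ignition boundary.

## Analysis statistics

* **Population rate**: distinct spiking members per 1 ms window,
  divided by region size and window (Hz); the recall peak rate is the
  maximum over the recall window.
* **Activation time**: time until 70% of a region's members have fired
  after cue onset; censored at the 500 ms recall window if never
  reached (censored comparisons use the window bound).
* **Assembly events**: maximal chains of member spikes with gaps below
  0.5 ms, kept when the spike count in a 1 ms window centred at the
  chain midpoint, normalized by member count, exceeds 100 Hz. The
  normalization is per member: an event-level count can never fall
  below 100 Hz for any chain (a single spike in 1 ms is already
  1,000 Hz), so only the per-member reading makes the threshold a real
  filter.
* **Synchrony index**: all events of both assemblies are merged into
  slots (events overlapping within +-0.5 ms share a slot); chi is the
  normalized cross-correlation of the binary participation vectors,
  1 for perfect synchrony, 0 for none (or when either side has no
  events). The association experiment reports chi per consecutive
  recall window and their mean.
* **DBSCAN / IoU**: neurons spiking within a 5 ms window contribute
  their positions; DBSCAN with eps = 120 um and 20 minimum *neighbors*
  (sklearn `min_samples = 21`) labels them; the leak footprint is the
  union of 60 um discs around clustered points, rasterized at 10 um,
  and IoU compares it with the trained region's raster.

## Experiment layouts

Common timeline: 100 ms settling, training (50 Hz), a 250 ms rest gap,
then recall (10 Hz cues, 500 ms unless stated). Recall phases branch
from a snapshot of the trained state so that every tension condition
sees the identical trained network; each branch gets its own derived
background stream. n = 4 seeded replicates throughout, with every
random stream derived from one master seed via labelled 31-bit
`SeedSequence` children.

* **Pattern completion**: face trained 0/0.5/1 s, cued with the
  rectangles; peak rate and activation time per condition. The tension
  sweep (0.5x / 1x / 1.5x resting tension during the recall phase) runs
  on the 1 s-trained network.
* **Inhibition sweep**: total size fixed at 5,000 while the inhibitory
  fraction varies; 1 s face training, circular partial cue; encoding
  IoU uses the 5 ms window at the last training pulse, recall IoU the
  5 ms window after the first cue.
* **Projection**: A trained fully, B delayed 2 ms at 40% participation;
  at recall A alone is cued for 1 s (the acceptance runs use 0.5 s)
  under each tension level; chi(A, B) from detected events plus the
  control-region rate.
* **Association**: both rectangles co-trained; only the right one cued
  during recall while tension is baseline, reduced by 20%, or reduced
  and then restored. The full-length protocol follows the 25 s recall
  with five windows and restoration after 20 s; the shipped defaults
  run a proportionally scaled 5 s span (five 1 s windows, restoration
  after 3 s), which preserves every comparison while keeping a full
  four-replicate run in minutes.

`summarize_stats` adds condition means +- SEM, percent changes against
a reference condition, one-way ANOVA and Tukey HSD from standard scipy
routines - a reporting layer only.

## What the simulations show - and what they cannot

The background drive and response-latency model emulate a cultured
2D network under patterned suprathreshold stimulation; they do not
reproduce intrinsic bursting, ripple oscillations, conductance-based
synapses, distance-dependent delays, or any offline consolidation.
Three known divergences from the reported phenomenology, all rooted in
the printed parameter set rather than in implementation detail:

* **Untrained activation time is censored.** Untrained networks show no
  propagation beyond the cue (as described); since the cue plus
  background covers at most ~36% of the trained region, the 70%
  activation criterion is unreachable and the untrained/trained
  activation-time contrast is reported against the censoring bound,
  far above the reported +81%.
* **No runaway at 0% inhibition.** With a baseline release potential of
  0.01 mV, untrained out-of-region synapses cannot carry regenerative
  activity, and out-of-region weight growth during training is held
  down by the depression term; activity therefore stays
  region-confined even without inhibition, and the recall-IoU optimum
  at 20% inhibition does not emerge (encoding/recall contrasts at 20%
  and 100% do).
* **Relaxation effects are steeper than reported.** Avalanche ignition
  is a collective threshold: reducing tension by 50% lowers release
  enough that some replicates lose ignition outright, so
  low-tension declines in rate and synchrony tend to overshoot the
  reported ~8-19% while high-tension gains are capped by recruitment
  saturation.

Within those limits the headline effects reproduce: longer training
raises recall peak rate and speeds activation; higher tension
strengthens and speeds recall and tightens projection synchrony;
reduced tension reversibly suppresses associative recall with full
recovery on restoration; full inhibition encodes sharply but cannot
recall.
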