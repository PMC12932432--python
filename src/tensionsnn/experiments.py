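"""The four in-silico memory experiments.

Each experiment builds seeded network replicates, runs a training phase
(50 Hz suprathreshold pulse trains over the experiment's regions), a
short rest gap, and one or more recall phases (10 Hz cues) under
controlled global-tension conditions, then reduces the spike records to
the assembly-level statistics:

* pattern completion -- train a face-shaped region, cue with rectangles
  covering 20% of it; peak population rate and 70%-activation time of
  the trained region versus training duration and recall tension;
* inhibition sweep -- vary the inhibitory fraction at fixed total size;
  encoding and recall IoU between the trained region and the DBSCAN
  cluster footprint of spiking activity;
* projection -- train region A fully and region B 2 ms later at 40%
  participation; reactivate A alone and measure the A-B synchrony index
  versus recall tension;
* association -- co-train two separated rectangles, cue only the right
  one, and track the left-right synchrony index over recall time under
  baseline, reduced (-20%) and restored tension.

Results are returned as tidy metric tables: one row per
(replicate, condition, metric, value).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import (activation_time, dbscan_cluster, detect_assembly_events,
                       population_rate, region_iou, synchrony_index)
from .dynamics import Simulator
from .geometry import build_network
from .params import ExternalDriveParams, SynapseParams
from .runio import derive_seed
from .stimulation import (StimulusProtocol, compile_protocol, draw_latencies,
                          make_fixture_mask)
from .tension import TensionSchedule


@dataclass(frozen=True)
class ExperimentConfig:
    """Common settings of the in-silico experiments.

    The defaults are the standard study conditions: a 5,000-neuron
    network (20% inhibitory) in 1 x 1 mm, 50 Hz training / 10 Hz recall
    pulse trains of suprathreshold amplitude with a small fixed
    per-neuron response latency, and a 1,000-neuron 13 Hz Poisson
    background.
    """

    n_total: int = 5000
    inhibitory_fraction: float = 0.2
    area: tuple = (1000.0, 1000.0)
    neurite_mean: float = 200.0
    neurite_sd: float = 40.0
    p_syn: float = 0.1
    # stimulation
    stim_amplitude: float = 25.0      # mV; clears the 20 mV rest-to-threshold gap
    latency_jitter_ms: float = 1.0    # fixed per-neuron stimulus-response latency
    pulse_jitter_ms: float = 3.0      # per-pulse response jitter
    n_burst: int = 7                  # response spikes per tetanic training pulse
    recall_n_burst: int = 1           # response spikes per recall cue pulse
    burst_isi_ms: float = 1.0
    inh_latency_offset_ms: float = 2.0  # feedforward-inhibition response lag
    synapse_delay_ms: float = 0.5     # minimum transmission latency
    synapse_delay_jitter_ms: float = 6.0  # per-synapse latency spread
    train_rate_hz: float = 50.0
    recall_rate_hz: float = 10.0
    settle_ms: float = 100.0
    gap_ms: float = 250.0
    recall_ms: float = 500.0
    # background drive
    n_external: int = 1000
    external_rate_hz: float = 13.0
    # replication
    n_replicates: int = 4
    base_seed: int = 0
    # analysis
    rate_window_ms: float = 1.0
    activation_fraction: float = 0.7
    dbscan_window_ms: float = 5.0

    @property
    def n_inh(self) -> int:
        return int(round(self.n_total * self.inhibitory_fraction))

    @property
    def n_exc(self) -> int:
        return self.n_total - self.n_inh

    def scaled(self, factor: float) -> "ExperimentConfig":
        """Smaller network at identical density (for smoke runs)."""
        side = np.sqrt(factor)
        return replace(self, n_total=int(round(self.n_total * factor)),
                       n_external=int(round(self.n_external * factor)),
                       area=(self.area[0] * side, self.area[1] * side))

    def replicate_seeds(self) -> list:
        return [derive_seed(self.base_seed, f"replicate-{r}")
                for r in range(self.n_replicates)]


_GEOM_CACHE: dict = {}


def _geometry(cfg: ExperimentConfig, seed: int):
    key = (cfg.n_exc, cfg.n_inh, cfg.area, cfg.neurite_mean, cfg.neurite_sd,
           cfg.p_syn, seed)
    if key not in _GEOM_CACHE:
        if len(_GEOM_CACHE) > 12:
            _GEOM_CACHE.clear()
        _GEOM_CACHE[key] = build_network(
            n_exc=cfg.n_exc, n_inh=cfg.n_inh, area=cfg.area,
            neurite_mean=cfg.neurite_mean, neurite_sd=cfg.neurite_sd,
            p_syn=cfg.p_syn, seed=seed)
    return _GEOM_CACHE[key]


def _simulator(geom, cfg: ExperimentConfig, schedule, seed: int) -> Simulator:
    sim = Simulator(geom, synapse=SynapseParams(
        delay_ms=cfg.synapse_delay_ms,
        delay_jitter_ms=cfg.synapse_delay_jitter_ms),
                    schedule=schedule, seed=seed)
    sim.enable_external(ExternalDriveParams(
        n_external=min(cfg.n_external, geom.n_neurons),
        rate=cfg.external_rate_hz))
    return sim


def _add_protocol(sim: Simulator, proto: StimulusProtocol,
                  latencies: np.ndarray) -> None:
    steps, ids, amps = compile_protocol(proto, sim.geometry,
                                        sim.neuron.dt, latencies)
    sim.add_stimulus_events(steps, ids, amps)


def _latencies(geom, cfg: ExperimentConfig, seed: int) -> np.ndarray:
    """Fixed per-neuron response latencies; inhibitory neurons respond
    with an additional feedforward lag."""
    lat = draw_latencies(geom.n_neurons, cfg.latency_jitter_ms, seed)
    return lat + cfg.inh_latency_offset_ms * geom.is_inhibitory


def _proto_kwargs(cfg: ExperimentConfig, recall: bool = False) -> dict:
    nb = cfg.recall_n_burst if recall else cfg.n_burst
    return dict(amplitude=cfg.stim_amplitude, n_burst=nb,
                burst_isi_ms=cfg.burst_isi_ms,
                pulse_jitter_ms=cfg.pulse_jitter_ms)


def _schedule(eps_rel_recall: float, t_recall: float, t_end: float,
              eps0: float = 0.001) -> TensionSchedule:
    """Baseline tension during training, then the recall level from the
    start of the recall phase (rest gap included)."""
    if eps_rel_recall == 1.0:
        return TensionSchedule.constant(eps0, t_end)
    return TensionSchedule.from_relative(
        [(0.0, t_recall, 1.0), (t_recall, t_end, eps_rel_recall)], eps0=eps0)


# ---------------------------------------------------------------------------
# pattern completion


def run_pattern_completion(cfg: ExperimentConfig,
                           train_durations_ms: Sequence[float] = (0.0, 500.0, 1000.0),
                           recall_tensions: Sequence[float] = (0.5, 1.0, 1.5),
                           tension_train_ms: float = 1000.0) -> pd.DataFrame:
    """Face training + rectangular partial cues.

    Conditions ``train_<d>s`` sweep training duration at baseline
    tension; conditions ``tension_<r>x`` sweep recall tension at a fixed
    training duration. Metrics: ``peak_rate_hz``, ``activation_time_ms``
    (censored at the recall window length, flagged by
    ``activation_censored``).
    """
    rows = []
    for rep, seed in enumerate(cfg.replicate_seeds()):
        geom = _geometry(cfg, seed)
        face = make_fixture_mask("face", geom)
        cues = make_fixture_mask("cue_rectangles", geom, seed=seed)
        members = face.members(geom)
        lat = _latencies(geom, cfg, seed)

        snaps = {}
        t_train_end = {}
        durations = sorted(set(float(d) for d in train_durations_ms)
                           | {float(tension_train_ms)})
        d_max = max(durations)
        sim = _simulator(geom, cfg, None, derive_seed(seed, "train"))
        if d_max > 0:
            _add_protocol(sim, StimulusProtocol(
                mask=face, pulse_rate=cfg.train_rate_hz,
                t_start=cfg.settle_ms, t_end=cfg.settle_ms + d_max,
                seed=seed, **_proto_kwargs(cfg)), lat)
        for d in durations:
            sim.run(cfg.settle_ms + d)
            snaps[d] = sim.snapshot()
            t_train_end[d] = cfg.settle_ms + d

        def recall(d_train, eps_rel, tag):
            t0 = t_train_end[d_train]
            t_cue = t0 + cfg.gap_ms
            t_end = t_cue + cfg.recall_ms
            rsim = _simulator(geom, cfg,
                              _schedule(eps_rel, t0, t_end),
                              derive_seed(seed, f"recall-{tag}"))
            rsim.restore(snaps[d_train])
            _add_protocol(rsim, StimulusProtocol(
                mask=cues, pulse_rate=cfg.recall_rate_hz,
                t_start=t_cue, t_end=t_end, seed=seed,
                **_proto_kwargs(cfg, recall=True)), lat)
            rsim.run(t_end)
            spikes = rsim.spike_record()
            _, rates = population_rate(spikes, members, cfg.rate_window_ms,
                                       t_cue, t_end)
            at = activation_time(spikes, members, t_cue,
                                 cfg.activation_fraction,
                                 window_ms=cfg.recall_ms)
            return {"peak_rate_hz": float(rates.max()),
                    "activation_time_ms": cfg.recall_ms if at is None else at,
                    "activation_censored": float(at is None)}

        results = {}
        for d in train_durations_ms:
            results[f"train_{d / 1000:g}s"] = recall(float(d), 1.0, f"d{d}")
        for r in recall_tensions:
            tag = f"tension_{r:g}x"
            if r == 1.0 and float(tension_train_ms) in snaps and \
                    f"train_{tension_train_ms / 1000:g}s" in results:
                results[tag] = results[f"train_{tension_train_ms / 1000:g}s"]
            else:
                results[tag] = recall(float(tension_train_ms), float(r), tag)
        for cond, metrics in results.items():
            for m, v in metrics.items():
                rows.append((rep, cond, m, v))
    return pd.DataFrame(rows, columns=["replicate", "condition",
                                       "metric", "value"])


# ---------------------------------------------------------------------------
# inhibition sweep


def run_inhibition_sweep(cfg: ExperimentConfig,
                         inhibitory_fractions: Sequence[float] =
                         (0.0, 0.1, 0.2, 0.4, 0.7, 1.0),
                         train_ms: float = 1000.0) -> pd.DataFrame:
    """Encoding vs recall spatial fidelity across inhibitory fractions.

    Metrics per condition ``inh_<f>``: ``encoding_iou`` (DBSCAN cluster
    footprint in a 5 ms window at the last training pulse vs the
    trained region) and ``recall_iou`` (same window after the circular
    partial cue).
    """
    rows = []
    for rep, seed in enumerate(cfg.replicate_seeds()):
        for f in inhibitory_fractions:
            fcfg = replace(cfg, inhibitory_fraction=float(f))
            geom = _geometry(fcfg, seed)
            face = make_fixture_mask("face", geom)
            circle = make_fixture_mask("circle_cue", geom, seed=seed)
            lat = _latencies(geom, fcfg, seed)

            t_cue = cfg.settle_ms + train_ms + cfg.gap_ms
            t_end = t_cue + cfg.recall_ms
            sim = _simulator(geom, fcfg, None, derive_seed(seed, f"inh-{f}"))
            _add_protocol(sim, StimulusProtocol(
                mask=face, pulse_rate=cfg.train_rate_hz,
                t_start=cfg.settle_ms, t_end=cfg.settle_ms + train_ms,
                seed=seed, **_proto_kwargs(cfg)), lat)
            _add_protocol(sim, StimulusProtocol(
                mask=circle, pulse_rate=cfg.recall_rate_hz,
                t_start=t_cue, t_end=t_end, seed=seed,
                **_proto_kwargs(cfg, recall=True)), lat)
            sim.run(t_end)
            spikes = sim.spike_record()

            period = 1000.0 / cfg.train_rate_hz
            last_onset = cfg.settle_ms + (
                np.floor((train_ms - 1e-9) / period)) * period
            enc = dbscan_cluster(spikes, geom, last_onset,
                                 window_ms=cfg.dbscan_window_ms)
            rec = dbscan_cluster(spikes, geom, t_cue,
                                 window_ms=cfg.dbscan_window_ms)
            cond = f"inh_{f:g}"
            rows.append((rep, cond, "encoding_iou",
                         region_iou(face, enc, geom.area)))
            rows.append((rep, cond, "recall_iou",
                         region_iou(face, rec, geom.area)))
    return pd.DataFrame(rows, columns=["replicate", "condition",
                                       "metric", "value"])


# ---------------------------------------------------------------------------
# projection


def run_projection(cfg: ExperimentConfig,
                   recall_tensions: Sequence[float] =
                   (0.5, 0.75, 1.0, 1.25, 1.5),
                   train_ms: float = 1000.0,
                   b_delay_ms: float = 2.0,
                   b_fraction: float = 0.4,
                   recall_ms: Optional[float] = 1000.0,
                   include_untrained: bool = True) -> pd.DataFrame:
    """A->B projection under recall-tension conditions.

    Metrics per condition (``tension_<r>x`` or ``untrained``):
    ``chi_ab`` (synchrony of A/B assembly events during recall) and
    ``rate_c_hz`` (mean population rate of the uninvolved control
    region C).
    """
    rows = []
    for rep, seed in enumerate(cfg.replicate_seeds()):
        geom = _geometry(cfg, seed)
        mask_a = make_fixture_mask("square", geom)
        mask_b = make_fixture_mask("triangle", geom)
        mask_c = make_fixture_mask("control", geom)
        mem_a, mem_b, mem_c = (m.members(geom) for m in
                               (mask_a, mask_b, mask_c))
        lat = _latencies(geom, cfg, seed)

        def trained_snapshot(amplitude):
            sim = _simulator(geom, cfg, None,
                             derive_seed(seed, f"proj-train-{amplitude}"))
            if amplitude > 0:
                kw = dict(_proto_kwargs(cfg), amplitude=amplitude)
                _add_protocol(sim, StimulusProtocol(
                    mask=mask_a, pulse_rate=cfg.train_rate_hz,
                    t_start=cfg.settle_ms, t_end=cfg.settle_ms + train_ms,
                    seed=seed, **kw), lat)
                _add_protocol(sim, StimulusProtocol(
                    mask=mask_b, pulse_rate=cfg.train_rate_hz,
                    t_start=cfg.settle_ms, t_end=cfg.settle_ms + train_ms,
                    delay=b_delay_ms, subset_fraction=b_fraction,
                    seed=seed, **kw), lat)
            sim.run(cfg.settle_ms + train_ms)
            return sim.snapshot()

        snap = trained_snapshot(cfg.stim_amplitude)
        snap0 = trained_snapshot(0.0) if include_untrained else None

        span = cfg.recall_ms if recall_ms is None else recall_ms

        def recall(snapshot, eps_rel, tag):
            t0 = cfg.settle_ms + train_ms
            t_cue = t0 + cfg.gap_ms
            t_end = t_cue + span
            rsim = _simulator(geom, cfg, _schedule(eps_rel, t0, t_end),
                              derive_seed(seed, f"proj-recall-{tag}"))
            rsim.restore(snapshot)
            _add_protocol(rsim, StimulusProtocol(
                mask=mask_a, pulse_rate=cfg.recall_rate_hz,
                t_start=t_cue, t_end=t_end, seed=seed,
                **_proto_kwargs(cfg, recall=True)), lat)
            rsim.run(t_end)
            spikes = rsim.spike_record().window(t_cue, t_end)
            ev_a = detect_assembly_events(spikes, mem_a)
            ev_b = detect_assembly_events(spikes, mem_b)
            _, rc = population_rate(spikes, mem_c, cfg.rate_window_ms,
                                    t_cue, t_end)
            return {"chi_ab": synchrony_index(ev_a, ev_b),
                    "rate_c_hz": float(rc.mean()),
                    "n_events_a": float(len(ev_a)),
                    "n_events_b": float(len(ev_b))}

        for r in recall_tensions:
            for m, v in recall(snap, float(r), f"t{r}").items():
                rows.append((rep, f"tension_{r:g}x", m, v))
        if include_untrained:
            for m, v in recall(snap0, 1.0, "untrained").items():
                rows.append((rep, "untrained", m, v))
    return pd.DataFrame(rows, columns=["replicate", "condition",
                                       "metric", "value"])


# ---------------------------------------------------------------------------
# association


def run_association(cfg: ExperimentConfig,
                    train_durations_ms: Sequence[float] = (0.0, 1000.0, 2000.0),
                    tension_train_ms: float = 1000.0,
                    recall_span_ms: float = 25000.0,
                    n_time_points: int = 5,
                    restore_after_ms: float = 20000.0,
                    tension_conditions: Sequence[str] =
                    ("baseline", "reduced", "restored"),
                    reduced_rel: float = 0.8) -> pd.DataFrame:
    """Associative recall between two co-trained rectangles.

    The right rectangle is cued at 10 Hz throughout the recall span;
    the synchrony index between the regions is computed in
    ``n_time_points`` consecutive windows (metrics ``chi_t<i>`` and
    their mean ``chi_mean``; ``chi_t0`` is the early-recall value).
    Tension conditions (at ``tension_train_ms`` training): ``baseline``;
    ``reduced`` (eps = 0.8 eps0 throughout recall); ``restored``
    (reduced, returning to baseline after ``restore_after_ms``).
    """
    rows = []
    win = recall_span_ms / n_time_points
    for rep, seed in enumerate(cfg.replicate_seeds()):
        geom = _geometry(cfg, seed)
        left = make_fixture_mask("rect_pair_left", geom)
        right = make_fixture_mask("rect_pair_right", geom)
        mem_l, mem_r = left.members(geom), right.members(geom)
        lat = _latencies(geom, cfg, seed)

        durations = sorted(set(float(d) for d in train_durations_ms)
                           | {float(tension_train_ms)})
        d_max = max(durations)
        sim = _simulator(geom, cfg, None, derive_seed(seed, "assoc-train"))
        if d_max > 0:
            for mask in (left, right):
                _add_protocol(sim, StimulusProtocol(
                    mask=mask, pulse_rate=cfg.train_rate_hz,
                    t_start=cfg.settle_ms, t_end=cfg.settle_ms + d_max,
                    seed=seed, **_proto_kwargs(cfg)), lat)
        snaps = {}
        for d in durations:
            sim.run(cfg.settle_ms + d)
            snaps[d] = sim.snapshot()

        def recall(d_train, tension_mode, tag):
            t0 = cfg.settle_ms + d_train
            t_cue = t0 + cfg.gap_ms
            t_end = t_cue + recall_span_ms
            eps0 = SynapseParams().eps0
            if tension_mode == "baseline":
                sched = TensionSchedule.constant(eps0, t_end)
            elif tension_mode == "reduced":
                sched = TensionSchedule.from_relative(
                    [(0.0, t0, 1.0), (t0, t_end, reduced_rel)], eps0)
            elif tension_mode == "restored":
                t_rst = t_cue + restore_after_ms
                sched = TensionSchedule.from_relative(
                    [(0.0, t0, 1.0), (t0, t_rst, reduced_rel),
                     (t_rst, t_end, 1.0)], eps0)
            else:
                raise ValueError(tension_mode)
            rsim = _simulator(geom, cfg, sched,
                              derive_seed(seed, f"assoc-recall-{tag}"))
            rsim.restore(snaps[d_train])
            _add_protocol(rsim, StimulusProtocol(
                mask=right, pulse_rate=cfg.recall_rate_hz,
                t_start=t_cue, t_end=t_end, seed=seed,
                **_proto_kwargs(cfg, recall=True)), lat)
            rsim.run(t_end)
            spikes = rsim.spike_record()
            chis = []
            for i in range(n_time_points):
                wsp = spikes.window(t_cue + i * win, t_cue + (i + 1) * win)
                ev_l = detect_assembly_events(wsp, mem_l)
                ev_r = detect_assembly_events(wsp, mem_r)
                chis.append(synchrony_index(ev_l, ev_r))
            out = {f"chi_t{i}": c for i, c in enumerate(chis)}
            out["chi_mean"] = float(np.mean(chis))
            return out

        for d in train_durations_ms:
            cond = f"train_{d / 1000:g}s"
            for m, v in recall(float(d), "baseline", cond).items():
                rows.append((rep, cond, m, v))
        for mode in tension_conditions:
            if mode == "baseline" and \
                    float(tension_train_ms) in [float(d) for d in train_durations_ms]:
                continue  # identical to the train-duration run
            cond = f"tension_{mode}"
            for m, v in recall(float(tension_train_ms), mode, cond).items():
                rows.append((rep, cond, m, v))
    return pd.DataFrame(rows, columns=["replicate", "condition",
                                       "metric", "value"])


# ---------------------------------------------------------------------------
# statistics reporting


def summarize_stats(table: pd.DataFrame, metric: str,
                    reference_condition: str) -> dict:
    """Condition means +- SEM, percent change vs a reference condition,
    one-way ANOVA and Tukey HSD across conditions (reporting layer over
    standard routines)."""
    from scipy import stats as sps

    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not in table")
    groups = {c: g["value"].to_numpy(float)
              for c, g in sub.groupby("condition")}
    if reference_condition not in groups:
        raise ValueError(f"reference condition {reference_condition!r} missing")
    ref_mean = groups[reference_condition].mean()
    summary = {}
    for c, v in groups.items():
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        pct = float((v.mean() - ref_mean) / ref_mean * 100.0) \
            if ref_mean != 0 else np.nan
        summary[c] = {"mean": float(v.mean()), "sem": sem, "n": len(v),
                      "pct_change_vs_ref": pct}
    out = {"metric": metric, "reference": reference_condition,
           "conditions": summary}
    vals = list(groups.values())
    if len(vals) > 1 and all(len(v) > 1 for v in vals) and \
            any(np.ptp(np.concatenate(vals)) > 0 for _ in [0]):
        try:
            f, p = sps.f_oneway(*vals)
            out["anova"] = {"F": float(f), "p": float(p),
                            "df_between": len(vals) - 1,
                            "df_within": sum(len(v) for v in vals) - len(vals)}
            tk = sps.tukey_hsd(*vals)
            names = list(groups)
            out["tukey"] = {f"{names[i]} vs {names[j]}":
                            float(tk.pvalue[i, j])
                            for i in range(len(names))
                            for j in range(i + 1, len(names))}
        except Exception:
            pass
    return out


def percent_change(table: pd.DataFrame, metric: str, condition: str,
                   reference: str, per_replicate: bool = True) -> float:
    """Mean percent change of ``metric`` in ``condition`` relative to
    ``reference`` (averaged over per-replicate percent changes)."""
    sub = table[table["metric"] == metric]
    a = sub[sub["condition"] == condition].set_index("replicate")["value"]
    b = sub[sub["condition"] == reference].set_index("replicate")["value"]
    if per_replicate:
        common = a.index.intersection(b.index)
        vals = (a.loc[common] - b.loc[common]) / b.loc[common] * 100.0
        vals = vals[np.isfinite(vals)]  # drop zero-reference replicates
        if len(vals):
            return float(vals.mean())
    return float((a.mean() - b.mean()) / b.mean() * 100.0)
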