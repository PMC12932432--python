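import math

import numpy as np
import pytest

from _reference import ReferenceSimulator
from conftest import make_geometry
from tensionsnn.dynamics import (NumericalError, Simulator, SpikeRecord,
                                 decay_u, deliver_spike,
                                 external_poisson_drive, membrane_step,
                                 release_and_recover_R, update_u_on_spike)
from tensionsnn.params import (ExternalDriveParams, NeuronParams,
                               PlasticityParams, SynapseParams)


class TestMembrane:
    def test_rest_is_fixed_point(self, neuron_params):
        v = np.full(5, neuron_params.v_rest)
        for _ in range(200):
            v, spiked = membrane_step(v, 0.0, 0.0, neuron_params)
            assert not spiked.any()
        assert np.allclose(v, -74.0)

    def test_exponential_decay_matches_closed_form(self, neuron_params):
        """10 mV deviation decays to 10/e after one tau (first-order in dt)."""
        v = np.array([neuron_params.v_rest + 10.0])
        for _ in range(100):  # 10 ms at dt = 0.1
            v, _ = membrane_step(v, 0.0, 0.0, neuron_params)
        assert v[0] - neuron_params.v_rest == \
            pytest.approx(10 * math.exp(-1), rel=0.01)

    def test_euler_error_halves_with_dt(self):
        errs = []
        for dt in (0.1, 0.05):
            p = NeuronParams(dt=dt)
            v = np.array([p.v_rest + 10.0])
            for _ in range(int(round(10.0 / dt))):
                v, _ = membrane_step(v, 0.0, 0.0, p)
            errs.append(abs(v[0] - p.v_rest - 10 * math.exp(-1)))
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.1)

    def test_suprathreshold_input_spikes_and_resets(self, neuron_params):
        v = np.array([neuron_params.v_rest])
        v, spiked = membrane_step(v, 0.0, 25.0, neuron_params)
        assert spiked[0]
        assert v[0] == -60.0

    def test_subthreshold_input_does_not_spike(self, neuron_params):
        v = np.array([neuron_params.v_rest])
        v, spiked = membrane_step(v, 0.0, 19.0, neuron_params)
        assert not spiked[0]

    def test_nonfinite_input_raises(self, neuron_params):
        with pytest.raises(NumericalError):
            membrane_step(np.array([-74.0]), np.inf, 0.0, neuron_params)


class TestVesicles:
    def test_facilitation_jump_from_baseline(self, synapse_params):
        assert update_u_on_spike(0.2, synapse_params) == \
            pytest.approx(0.36)  # 2 u0 - u0^2

    def test_facilitation_saturates_at_one(self, synapse_params):
        assert update_u_on_spike(1.0, synapse_params) == pytest.approx(1.0)

    def test_two_immediate_spikes(self, synapse_params):
        u = update_u_on_spike(synapse_params.u0, synapse_params)
        assert update_u_on_spike(u, synapse_params) == pytest.approx(0.488)

    def test_u_decay_fixed_point(self, synapse_params):
        assert decay_u(0.2, 5.0, synapse_params) == pytest.approx(0.2)

    def test_u_decay_closed_form(self, synapse_params):
        u = 0.36
        for _ in range(10000):  # 1000 ms at dt = 0.1
            u = decay_u(u, 0.1, synapse_params)
        assert u == pytest.approx(0.2 + 0.16 * math.exp(-1), rel=1e-9)

    def test_u_decay_monotone_from_both_sides(self, synapse_params):
        assert 0.2 < decay_u(0.5, 1.0, synapse_params) < 0.5
        assert 0.1 < decay_u(0.1, 1.0, synapse_params) < 0.2

    def test_euler_u_error_halves_with_dt(self, synapse_params):
        errs = []
        exact = 0.2 + 0.16 * math.exp(-1)
        for dt in (1.0, 0.5):
            u = 0.36
            for _ in range(int(round(1000 / dt))):
                u = decay_u(u, dt, synapse_params, exact=False)
            errs.append(abs(u - exact))
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.05)

    def test_release_depletes_pool(self, synapse_params):
        r, s = release_and_recover_R(1.0, 0.36, True, synapse_params.eps0,
                                     0.0, synapse_params)
        assert s == pytest.approx(0.36)
        assert r == pytest.approx(0.64)

    def test_no_release_without_spike(self, synapse_params):
        r, s = release_and_recover_R(0.8, 0.36, False, synapse_params.eps0,
                                     0.1, synapse_params)
        assert s == 0.0
        assert r > 0.8  # recovery toward R0

    def test_recovery_follows_tension_dependent_tau(self, synapse_params):
        # after one tau_R(eps), the deficit shrinks by e
        for f in (0.5, 1.0, 1.5):
            eps = f * synapse_params.eps0
            tau = 100 * math.exp(-(f - 1.0))
            r = 0.5
            n = int(round(tau / 0.1))
            for _ in range(n):
                r, _ = release_and_recover_R(r, 0.0, False, eps, 0.1,
                                             synapse_params)
            assert 1.0 - r == pytest.approx(0.5 * math.exp(-1), rel=1e-3)


class TestDelivery:
    def test_untrained_excitatory_delivers_baseline_only(self, synapse_params):
        inc = deliver_spike(0.36, np.zeros(4), False, synapse_params.eps0,
                            synapse_params)
        assert np.allclose(inc, 0.01)

    def test_inhibitory_scaled_by_gamma(self, synapse_params):
        inc = deliver_spike(0.36, np.zeros(3), True, synapse_params.eps0,
                            synapse_params)
        assert np.allclose(inc, -0.04)

    def test_trained_synapse_adds_weighted_release(self, synapse_params):
        inc = deliver_spike(0.36, np.array([5.0]), False, synapse_params.eps0,
                            synapse_params)
        assert inc[0] == pytest.approx(1.81)


class TestExternalDrive:
    def test_zero_rate_produces_no_events(self, rng):
        steps, ids = external_poisson_drive(rng, np.arange(10), 0.0,
                                            0.0, 1000.0, 0.1)
        assert len(steps) == 0

    def test_poisson_count_statistics(self, rng):
        """Per-neuron counts over 10 s at 13 Hz: mean 130 within 3 SE,
        and variance consistent with Poisson (CV of counts ~ 1/sqrt(130))."""
        ids = np.arange(300)
        steps, nid = external_poisson_drive(rng, ids, 13.0, 0.0, 10000.0, 0.1)
        counts = np.bincount(nid, minlength=300).astype(float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 130.0) < 3 * se
        cv = counts.std(ddof=1) / counts.mean()
        assert cv == pytest.approx(1 / math.sqrt(130), rel=0.25)

    def test_determinism_for_equal_seeds(self):
        a = external_poisson_drive(np.random.default_rng(7), np.arange(20),
                                   13.0, 0.0, 2000.0, 0.1)
        b = external_poisson_drive(np.random.default_rng(7), np.arange(20),
                                   13.0, 0.0, 2000.0, 0.1)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def _two_neuron_geometry(inhibitory=(False, False)):
    return make_geometry(
        positions=[(100.0, 100.0), (200.0, 100.0)],
        inhibitory=inhibitory,
        lengths=[200.0, 200.0],
        synapses=[(0, 1), (1, 0)],
        area=(300.0, 200.0))


class TestEngineAgainstScalarReference:
    """The vectorized engine must match an independent scalar
    transcription of the update rules step for step."""

    @pytest.mark.parametrize("inhibitory,eps_rel", [
        ((False, False), 1.0),
        ((False, True), 1.0),
        ((False, False), 1.5),
        ((False, True), 0.5),
    ])
    def test_two_neurons_with_stimulation(self, inhibitory, eps_rel):
        geom = _two_neuron_geometry(inhibitory)
        syn = SynapseParams()
        from tensionsnn.tension import TensionSchedule
        eps = eps_rel * syn.eps0
        sched = TensionSchedule.constant(eps, 2000.0, eps0=syn.eps0)
        sim = Simulator(geom, schedule=sched, seed=5, debug=True)
        ref = ReferenceSimulator(2, inhibitory,
                                 [tuple(s) for s in geom.synapses],
                                 NeuronParams(), syn, PlasticityParams(),
                                 eps=eps)
        rng = np.random.default_rng(99)
        steps, ids, amps = [], [], []
        for k in sorted(rng.integers(0, 10000, size=400).tolist()):
            i = int(rng.integers(0, 2))
            steps.append(k)
            ids.append(i)
            amps.append(25.0)
            ref.add_stim(k, i, 25.0)
        sim.add_stimulus_events(np.array(steps), np.array(ids),
                                np.array(amps))
        sim.run(1000.0)  # 10,000 steps
        ref.run(10000)

        rec = sim.spike_record()
        got = sorted(zip((rec.times_ms / 0.1).round().astype(int),
                         rec.neuron_ids))
        assert got == sorted(ref.spikes)
        assert np.allclose(sim.v, ref.v, atol=1e-9)
        assert np.allclose(sim.u, ref.u, atol=1e-12)
        assert np.allclose(sim.r, ref.r, atol=1e-12)
        # the engine reports weights at t_stop, one forgetting step after
        # the reference's final update
        f = math.exp(-0.25 * 0.1 * 1e-3)
        assert np.allclose(sim.weights, np.array(ref.w) * f, atol=1e-9)

    def test_three_neurons_with_forced_background_and_delays(self):
        geom = make_geometry(
            positions=[(100, 100), (220, 100), (160, 180)],
            inhibitory=[False, False, True],
            lengths=[200, 200, 200],
            synapses=[(0, 1), (1, 0), (0, 2), (2, 1), (1, 2)],
            area=(400, 300), seed=17)
        syn = SynapseParams(delay_ms=0.3, delay_jitter_ms=1.2)
        sim = Simulator(geom, synapse=syn, seed=21, debug=True)
        ref = ReferenceSimulator(3, geom.is_inhibitory.tolist(),
                                 [tuple(s) for s in geom.synapses],
                                 NeuronParams(), syn, PlasticityParams(),
                                 delays=sim._syn_delay.tolist())
        rng = np.random.default_rng(4)
        steps, ids, amps = [], [], []
        for k in sorted(rng.integers(0, 12000, size=500).tolist()):
            i = int(rng.integers(0, 3))
            steps.append(k)
            ids.append(i)
            amps.append(float(rng.choice([2.0, 21.0, 25.0])))
            ref.add_stim(k, i, amps[-1])
        sim.add_stimulus_events(np.array(steps), np.array(ids),
                                np.array(amps))
        # forced background events, mirrored in both simulators
        fsteps = sorted(rng.integers(0, 12000, size=60).tolist())
        fids = rng.integers(0, 3, size=60)
        sim._ext_step = np.array(fsteps, dtype=np.int64)
        sim._ext_id = np.array(fids, dtype=np.int32)
        sim._ext = ExternalDriveParams(n_external=0, rate=0.0)
        sim._ext_generated_until = 1e18
        for k, i in zip(fsteps, fids):
            ref.add_forced(int(k), int(i))
        sim.run(1200.0)
        ref.run(12000)
        rec = sim.spike_record()
        got = sorted(zip((rec.times_ms / 0.1).round().astype(int),
                         rec.neuron_ids))
        assert got == sorted(set(ref.spikes))
        assert np.allclose(sim.v, ref.v, atol=1e-9)
        f = math.exp(-0.25 * 0.1 * 1e-3)
        assert np.allclose(sim.weights, np.array(ref.w) * f, atol=1e-9)


class TestSimulatorBehaviour:
    def test_state_bounds_hold_under_drive(self):
        from tensionsnn.geometry import build_network
        net = build_network(n_exc=40, n_inh=10, area=(300, 300), seed=2)
        sim = Simulator(net, seed=3, debug=True)  # debug asserts bounds
        sim.enable_external(ExternalDriveParams(n_external=20, rate=50.0))
        sim.run(500.0)
        assert sim.u.min() >= 0 and sim.u.max() <= 1
        assert sim.r.min() >= 0 and sim.r.max() <= 1
        assert sim.weights.min() >= 0 and sim.weights.max() <= 5

    def test_run_determinism(self):
        from tensionsnn.geometry import build_network
        net = build_network(n_exc=40, n_inh=10, area=(300, 300), seed=2)
        recs = []
        for _ in range(2):
            sim = Simulator(net, seed=9)
            sim.enable_external(ExternalDriveParams(n_external=25, rate=30.0))
            sim.run(400.0)
            recs.append(sim.spike_record())
        assert np.array_equal(recs[0].neuron_ids, recs[1].neuron_ids)
        assert np.array_equal(recs[0].times_ms, recs[1].times_ms)
        assert np.array_equal(recs[0].sources, recs[1].sources)

    def test_snapshot_restore_branches_identically(self):
        from tensionsnn.geometry import build_network
        net = build_network(n_exc=30, n_inh=8, area=(250, 250), seed=5)
        sim = Simulator(net, seed=11)
        sim.enable_external(ExternalDriveParams(n_external=15, rate=40.0))
        sim.run(200.0)
        snap = sim.snapshot()
        branches = []
        for _ in range(2):
            b = Simulator(net, seed=77)
            b.enable_external(ExternalDriveParams(n_external=15, rate=40.0))
            b.restore(snap)
            b.run(400.0)
            branches.append(b.spike_record())
        assert np.array_equal(branches[0].neuron_ids, branches[1].neuron_ids)
        assert np.array_equal(branches[0].times_ms, branches[1].times_ms)


class TestSpikeRecord:
    def _record(self):
        return SpikeRecord(np.array([3, 1, 2], dtype=np.int32),
                           np.array([0.1, 0.5, 12.3]),
                           np.array([0, 1, 2], dtype=np.int8))

    def test_csv_round_trip(self, tmp_path):
        rec = self._record()
        rec.write_csv(tmp_path / "spikes.csv")
        back = SpikeRecord.read_csv(tmp_path / "spikes.csv")
        assert np.array_equal(back.neuron_ids, rec.neuron_ids)
        assert np.allclose(back.times_ms, rec.times_ms)
        assert np.array_equal(back.sources, rec.sources)

    def test_hdf5_round_trip(self, tmp_path):
        rec = self._record()
        rec.write_hdf5(tmp_path / "spikes.h5")
        back = SpikeRecord.read_hdf5(tmp_path / "spikes.h5")
        assert np.array_equal(back.neuron_ids, rec.neuron_ids)
        assert np.array_equal(back.times_ms, rec.times_ms)

    def test_windows_are_half_open(self):
        rec = self._record()
        w = rec.window(0.5, 12.3)
        assert list(w.neuron_ids) == [1]
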