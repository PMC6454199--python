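"""LIF integration, delayed delivery, target lookup, allocation invariance."""

import numpy as np
import pytest

import snncomm as sc
from _oracles import lif_closed_form, lif_period
from conftest import assignment
from snncomm.engine import (
    NeuronState,
    SimulationConfig,
    build_target_lookup,
    lif_step,
    mean_firing_rate,
    run_simulation,
)
from snncomm.models import NeuronParams


def _state(v, i_syn=0.0, ref=0):
    return NeuronState(np.array([v]), np.array([i_syn]),
                       np.array([ref], dtype=np.int64))


QUIET = NeuronParams(v_rest=-65.0, v_thresh=-50.0, v_reset=-65.0,
                     tau_m=10.0, r_m=1.0, t_ref=2.0, i_ext=0.0)


class TestLifStep:
    def test_rest_is_a_fixed_point_without_input(self):
        st, fired = lif_step(_state(QUIET.v_rest), QUIET, np.zeros(1), dt=0.1)
        assert st.v[0] == pytest.approx(QUIET.v_rest)
        assert not fired[0]

    def test_relaxation_matches_closed_form(self):
        # threshold disabled: Euler trajectory vs analytic relaxation
        p = NeuronParams(v_rest=-65.0, v_thresh=1e9, v_reset=-65.0,
                         tau_m=10.0, r_m=2.0, t_ref=0.0, i_ext=3.0)
        dt, t_end = 0.05, 20.0
        st = _state(p.v_rest)
        steps = int(t_end / dt)
        for _ in range(steps):
            st, _ = lif_step(st, p, np.zeros(1), dt=dt)
        expect = lif_closed_form(t_end, p.v_rest, p.v_rest, p.r_m, p.i_ext, p.tau_m)
        assert st.v[0] == pytest.approx(expect, abs=0.05)

    def test_euler_error_scales_linearly_with_dt(self):
        p = NeuronParams(v_rest=-65.0, v_thresh=1e9, v_reset=-65.0,
                         tau_m=10.0, r_m=2.0, t_ref=0.0, i_ext=3.0)
        t_end = 10.0
        errs = []
        for dt in (0.2, 0.1, 0.05):
            st = _state(p.v_rest)
            for _ in range(int(round(t_end / dt))):
                st, _ = lif_step(st, p, np.zeros(1), dt=dt)
            expect = lif_closed_form(t_end, p.v_rest, p.v_rest, p.r_m,
                                     p.i_ext, p.tau_m)
            errs.append(abs(st.v[0] - expect))
        # halving dt about halves the error: observed order ~1
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.25)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.25)

    def test_suprathreshold_interval_matches_first_passage_time(self):
        p = NeuronParams(v_rest=-50.0, v_thresh=-50.5, v_reset=-65.0,
                         tau_m=10.0, r_m=1.0, t_ref=2.0, i_ext=4.0)
        dt = 0.01
        st = _state(p.v_reset)
        spikes = []
        for step in range(int(60.0 / dt)):
            st, fired = lif_step(st, p, np.zeros(1), dt=dt)
            if fired[0]:
                spikes.append(step * dt)
        isis = np.diff(spikes)
        expect = lif_period(p.v_reset, p.v_thresh, p.v_rest, p.r_m,
                            p.i_ext, p.tau_m, p.t_ref)
        assert len(isis) >= 2
        assert np.allclose(isis, expect, atol=3 * dt + 0.05)

    def test_refractory_neuron_neither_integrates_nor_fires(self):
        st, fired = lif_step(_state(-40.0, ref=5), QUIET, np.zeros(1), dt=0.1)
        assert not fired[0]
        assert st.refractory_steps_left[0] == 4
        assert st.v[0] == -40.0


class TestTargetLookup:
    def test_all_targets_local_gives_empty_sets(self, chain_net):
        lk = build_target_lookup(chain_net, assignment([0, 0, 0], 1))
        assert lk.set_sizes().sum() == 0

    def test_remote_processes_deduplicated(self, edge_net_factory):
        # neuron 0 on process 0 targets neurons on processes {2, 2, 5}
        net = edge_net_factory(4, [(0, 1), (0, 2), (0, 3)])
        parts = assignment([0, 2, 2, 5], 6)
        lk = build_target_lookup(net, parts)
        assert list(lk.targets(0)) == [2, 5]

    def test_sizes_match_distinct_neuron_process_pairs(self, small_cm_net):
        a = assignment(np.arange(small_cm_net.n_neurons) % 5, 5)
        lk = build_target_lookup(small_cm_net, a)
        pre = small_cm_net.pre_ids()
        src = a.parts[pre]
        dst = a.parts[small_cm_net.post_ids]
        remote = src != dst
        pairs = set(zip(pre[remote].tolist(),
                        dst[remote].tolist()))
        assert int(lk.set_sizes().sum()) == len(pairs)


class TestRunSimulation:
    def test_subthreshold_network_is_silent_with_zero_traffic(self, edge_net_factory):
        net = edge_net_factory(10, [(0, 1), (2, 3)], params=QUIET)
        cfg = SimulationConfig(duration=20.0, init="rest", seed=0)
        res = run_simulation(net, assignment(np.arange(10) % 2, 2), cfg)
        assert res.n_spikes == 0
        assert res.comm_stats.payload_bytes == 0

    def test_raster_invariant_across_allocation_and_pattern(self, small_cm_net):
        hg = sc.network_to_hypergraph(small_cm_net)
        cfg = dict(duration=20.0, seed=3)
        base = run_simulation(small_cm_net, assignment(
            np.zeros(small_cm_net.n_neurons), 1),
            SimulationConfig(comm_pattern="pex", **cfg))
        alt = run_simulation(
            small_cm_net, sc.allocate_random_balanced(hg, 8, seed=0),
            SimulationConfig(comm_pattern="nbx", **cfg))
        assert np.array_equal(base.raster_steps, alt.raster_steps)
        assert np.array_equal(base.raster_neurons, alt.raster_neurons)

    def test_determinism(self, small_cm_net):
        cfg = SimulationConfig(duration=10.0, seed=5)
        a = sc.allocate_round_robin(small_cm_net.n_neurons, 4)
        r1 = run_simulation(small_cm_net, a, cfg)
        r2 = run_simulation(small_cm_net, a, cfg)
        assert np.array_equal(r1.raster_steps, r2.raster_steps)
        assert np.array_equal(r1.raster_neurons, r2.raster_neurons)
        assert r1.comm_stats.to_dict() == r2.comm_stats.to_dict()

    def test_delivered_events_equal_out_degrees_of_spikes(self, small_cm_net):
        cfg = SimulationConfig(duration=20.0, seed=1)
        a = sc.allocate_round_robin(small_cm_net.n_neurons, 6)
        res = run_simulation(small_cm_net, a, cfg)
        out_deg = small_cm_net.out_degree()
        assert int(res.synaptic_events.sum()) == int(
            out_deg[res.raster_neurons].sum())

    def test_spike_arrives_exactly_after_its_delay(self, edge_net_factory):
        # a single strong synapse with a 7-step delay: the postsynaptic
        # current must jump exactly 7 steps after the presynaptic spike
        drive = NeuronParams(v_rest=-40.0, v_thresh=-50.0, v_reset=-65.0,
                             tau_m=10.0, r_m=1.0, t_ref=5.0, i_ext=0.0)
        net = edge_net_factory(2, [(0, 1)], weights=[50.0], delays=[7],
                               params=drive)
        cfg = SimulationConfig(duration=30.0, init="rest", seed=0)
        res = run_simulation(net, assignment([0, 1], 2), cfg)
        # both start at v_rest above threshold: both fire at step 0; the
        # delayed excitatory kick shortens neuron 1's second passage
        spikes1 = res.raster_steps[res.raster_neurons == 1]
        spikes0 = res.raster_steps[res.raster_neurons == 0]
        assert spikes0[0] == 0 and spikes1[0] == 0
        assert spikes1[1] < spikes0[1]  # the kick arrived

    def test_neuron_update_counters_sum_to_n_times_steps(self, small_cm_net):
        cfg = SimulationConfig(duration=5.0, seed=0)
        a = sc.allocate_round_robin(small_cm_net.n_neurons, 8)
        res = run_simulation(small_cm_net, a, cfg)
        assert int(res.neuron_updates.sum()) == small_cm_net.n_neurons * res.n_steps

    def test_dt_mismatch_with_delay_grid_rejected(self, small_cm_net):
        cfg = SimulationConfig(duration=5.0, dt=0.2)
        a = sc.allocate_round_robin(small_cm_net.n_neurons, 2)
        with pytest.raises(ValueError, match="grid"):
            run_simulation(small_cm_net, a, cfg)

    def test_raster_sorted_by_step_then_neuron(self, small_cm_net):
        cfg = SimulationConfig(duration=10.0, seed=2)
        res = run_simulation(
            small_cm_net, sc.allocate_round_robin(small_cm_net.n_neurons, 2), cfg)
        order = np.lexsort((res.raster_neurons, res.raster_steps))
        assert np.array_equal(order, np.arange(res.n_spikes))


class TestMeanFiringRate:
    def test_silent_network_rate_is_zero(self, edge_net_factory):
        net = edge_net_factory(5, [], params=QUIET)
        cfg = SimulationConfig(duration=10.0, init="rest")
        res = run_simulation(net, assignment(np.zeros(5), 1), cfg)
        assert mean_firing_rate(res, net, cfg) == 0.0

    def test_periodic_firing_rate(self, edge_net_factory):
        # a tonic neuron with analytic period T fires ~ duration/T times
        p = NeuronParams(v_rest=-50.0, v_thresh=-50.5, v_reset=-65.0,
                         tau_m=10.0, r_m=1.0, t_ref=2.0, i_ext=4.0)
        net = edge_net_factory(1, [], params=p)
        cfg = SimulationConfig(duration=1000.0, init="rest", seed=0)
        res = run_simulation(net, assignment([0], 1), cfg)
        expect = 1000.0 / lif_period(p.v_reset, p.v_thresh, p.v_rest,
                                     p.r_m, p.i_ext, p.tau_m, p.t_ref)
        assert mean_firing_rate(res, net, cfg) == pytest.approx(expect, rel=0.05)

    def test_zero_duration_rejected(self, edge_net_factory):
        net = edge_net_factory(1, [], params=QUIET)
        cfg = SimulationConfig(duration=10.0)
        res = run_simulation(net, assignment([0], 1), cfg)
        bad = SimulationConfig(duration=0.0)
        with pytest.raises(ValueError):
            mean_firing_rate(res, net, bad)
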