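import numpy as np
import pandas as pd
import pytest

from neopatch import netgen, parallel, workbench
from neopatch.errors import (
    PartitionError,
    RoutingError,
    UndefinedFractionError,
)
from neopatch.parallel import (
    PartitionMap,
    PhasePerf,
    barrier_fraction,
    build_routing_table,
    exchange_spikes,
    modeled_memory,
    modeled_timing,
    partition_by_location,
    simulate_partitioned,
)


def line_net(n):
    neurons = pd.DataFrame({
        "id": np.arange(n), "cell_class": "SPYR",
        "x_um": np.arange(n) * 5.0, "y_um": np.zeros(n)})
    edges = pd.DataFrame(
        columns=["pre_id", "post_id", "delay_ms", "weight", "kind"])
    return netgen.Network(neurons=neurons, edges=edges)


class TestPartitioning:
    def test_single_rank_owns_everything(self, small_network):
        pm = partition_by_location(small_network, 1)
        assert pm.P == 1 and set(pm.assignment) == {0}

    def test_line_of_100_in_four_balanced_stripes(self):
        pm = partition_by_location(line_net(100), 4, "stripe_x")
        counts = np.bincount(pm.assignment)
        assert list(counts) == [25, 25, 25, 25]
        # stripes are spatially contiguous along x
        assert np.all(np.diff(pm.assignment) >= 0)

    def test_deterministic(self, small_network):
        a = partition_by_location(small_network, 8)
        b = partition_by_location(small_network, 8)
        assert np.array_equal(a.assignment, b.assignment)

    def test_balance_within_one_neuron(self, small_network):
        for p in (3, 7, 16):
            for scheme in ("stripe_x", "block_2d"):
                counts = np.bincount(
                    partition_by_location(small_network, p,
                                          scheme).assignment,
                    minlength=p)
                assert counts.max() - counts.min() <= 1

    def test_block_2d_spatial_contiguity(self, small_network):
        pm = partition_by_location(small_network, 4, "block_2d")
        # 4 = 2 x 2: each rank's bounding box must not contain another
        # rank's centroid (coarse contiguity check)
        xs = small_network.neurons["x_um"].to_numpy()
        ys = small_network.neurons["y_um"].to_numpy()
        cent = [(xs[pm.assignment == r].mean(), ys[pm.assignment == r].mean())
                for r in range(4)]
        assert len({(round(c[0], 3), round(c[1], 3)) for c in cent}) == 4

    def test_more_ranks_than_neurons_rejected(self):
        with pytest.raises(PartitionError):
            partition_by_location(line_net(5), 6)


class TestExchange:
    def _toy(self):
        neurons = pd.DataFrame({
            "id": np.arange(6), "cell_class": "SPYR",
            "x_um": np.arange(6) * 5.0, "y_um": np.zeros(6)})
        edges = pd.DataFrame({
            "pre_id": [0, 0, 0, 3, 5],
            "post_id": [1, 2, 4, 4, 0],
            "delay_ms": 0.5, "weight": 1.0, "kind": "alpha_excitatory"})
        return netgen.Network(neurons=neurons, edges=edges)

    def test_single_rank_inbox_equals_outbox(self):
        net = self._toy()
        pm = partition_by_location(net, 1)
        rt = build_routing_table(net, pm)
        inboxes = exchange_spikes([np.array([0, 3])], pm, rt)
        assert np.array_equal(inboxes[0], [0, 3])

    def test_spike_delivered_to_exactly_target_ranks(self):
        net = self._toy()
        # 3 ranks over 6 neurons on a line: {0,1}, {2,3}, {4,5}
        pm = partition_by_location(net, 3)
        rt = build_routing_table(net, pm)
        # neuron 0 targets 1 (rank 0), 2 (rank 1) and 4 (rank 2)
        inboxes = exchange_spikes(
            [np.array([0]), np.array([]), np.array([])], pm, rt)
        assert [list(b) for b in inboxes] == [[0], [0], [0]]

    def test_empty_outboxes_give_empty_inboxes(self):
        net = self._toy()
        pm = partition_by_location(net, 2)
        rt = build_routing_table(net, pm)
        inboxes = exchange_spikes([np.array([]), np.array([])], pm, rt)
        assert all(b.size == 0 for b in inboxes)

    def test_unassigned_spike_rejected(self):
        net = self._toy()
        pm = partition_by_location(net, 2)
        rt = build_routing_table(net, pm)
        with pytest.raises(RoutingError):
            exchange_spikes([np.array([99]), np.array([])], pm, rt)


class TestPartitionInvariance:
    def test_rasters_and_eeg_identical_across_partitions(
            self, small_network, small_stimulus):
        base = simulate_partitioned(
            small_network, small_stimulus, 100.0, 0.05, 0,
            partition_by_location(small_network, 1))
        assert len(base.spikes) > 0
        for p in (2, 3, 4, 8):
            res = simulate_partitioned(
                small_network, small_stimulus, 100.0, 0.05, 0,
                partition_by_location(small_network, p))
            assert res.spikes.equals(base.spikes)
            assert np.array_equal(res.eeg["value"].to_numpy(),
                                  base.eeg["value"].to_numpy())

    def test_block_scheme_also_invariant(self, small_network,
                                         small_stimulus):
        base = simulate_partitioned(
            small_network, small_stimulus, 50.0, 0.05, 0,
            partition_by_location(small_network, 1))
        res = simulate_partitioned(
            small_network, small_stimulus, 50.0, 0.05, 0,
            partition_by_location(small_network, 4, "block_2d"))
        assert res.spikes.equals(base.spikes)
        assert np.array_equal(res.eeg["value"].to_numpy(),
                              base.eeg["value"].to_numpy())

    def test_spike_conservation_each_step(self, small_network,
                                          small_stimulus):
        res = simulate_partitioned(
            small_network, small_stimulus, 60.0, 0.05, 0,
            partition_by_location(small_network, 4))
        sent = res.perf.spikes_sent.sum(axis=0)
        recv = res.perf.spikes_received.sum(axis=0)
        assert np.array_equal(sent, recv)
        assert sent.sum() > 0  # traffic actually crossed ranks

    def test_advance_work_tracks_neuron_count(self, small_network):
        # quiescent run: modeled advance cost is compartment work only
        res = simulate_partitioned(
            small_network, None, 20.0, 0.05, 0,
            partition_by_location(small_network, 4))
        mt = modeled_timing(res.perf)
        per_neuron = (mt.advance_seconds.sum(axis=1)
                      / mt.local_neurons)
        assert per_neuron.max() / per_neuron.min() < 1.10


class TestBarrierAccounting:
    def test_single_rank_fraction_zero(self, small_network, small_stimulus):
        res = simulate_partitioned(
            small_network, small_stimulus, 20.0, 0.05, 0,
            partition_by_location(small_network, 1))
        mt = modeled_timing(res.perf)
        assert barrier_fraction(mt, pooled=True) == 0.0

    def test_constructed_half_idle_rank(self):
        perf = PhasePerf(
            advance_seconds=np.array([[1.0], [1.0]]),
            exchange_seconds=np.zeros((2, 1)),
            barrier_wait_seconds=np.array([[0.0], [1.0]]),
            spikes_sent=np.zeros((2, 1), dtype=int),
            spikes_received=np.zeros((2, 1), dtype=int),
            deliveries=np.zeros((2, 1), dtype=int),
            local_neurons=np.array([1, 1]),
            local_compartments=np.array([1, 1]),
            resident_bytes=np.zeros(2),
        )
        fr = barrier_fraction(perf)
        assert fr[0] == 0.0 and fr[1] == pytest.approx(0.5)

    def test_zero_total_time_rejected(self):
        perf = PhasePerf(
            advance_seconds=np.zeros((1, 1)),
            exchange_seconds=np.zeros((1, 1)),
            barrier_wait_seconds=np.zeros((1, 1)),
            spikes_sent=np.zeros((1, 1), dtype=int),
            spikes_received=np.zeros((1, 1), dtype=int),
            deliveries=np.zeros((1, 1), dtype=int),
            local_neurons=np.array([1]),
            local_compartments=np.array([1]),
            resident_bytes=np.zeros(1),
        )
        with pytest.raises(UndefinedFractionError):
            barrier_fraction(perf)

    def test_pooled_fraction_nondecreasing_with_ranks(self):
        """Modeled barrier waiting grows with the partition count on a fixed
        fixture with spatially localized activity (load imbalance grows as
        stripes narrow)."""
        spec = workbench.FixtureSpec(name="bar", n_neurons=1024,
                                     target_edges=60000, seed=3)
        network, cfg = workbench.make_network_fixture(spec)
        stim = workbench.build_stimulus(cfg, network)
        fracs = []
        for p in (1, 2, 4, 8):
            res = simulate_partitioned(
                network, stim, 60.0, 0.05, 0,
                partition_by_location(network, p))
            fracs.append(barrier_fraction(modeled_timing(res.perf),
                                          pooled=True))
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]


class TestModeledMemory:
    def test_total_constant_up_to_per_rank_overhead(self, small_network):
        m1 = modeled_memory(small_network,
                            partition_by_location(small_network, 1))
        m4 = modeled_memory(small_network,
                            partition_by_location(small_network, 4))
        overhead = parallel.RANK_OVERHEAD_BYTES
        assert m4.sum() - m1.sum() == pytest.approx(3 * overhead)

    def test_empty_network_is_overhead_only(self):
        net = netgen.Network(
            neurons=pd.DataFrame(columns=["id", "cell_class", "x_um",
                                          "y_um"]),
            edges=pd.DataFrame(columns=["pre_id", "post_id", "delay_ms",
                                        "weight", "kind"]))
        pm = PartitionMap(assignment=np.empty(0, dtype=np.int64), P=1,
                          scheme="stripe_x")
        assert modeled_memory(net, pm)[0] == parallel.RANK_OVERHEAD_BYTES

    def test_edge_bytes_linear(self, small_network):
        pm = partition_by_location(small_network, 2)
        base = modeled_memory(small_network, pm).sum()
        doubled = netgen.Network(
            neurons=small_network.neurons,
            edges=pd.concat([small_network.edges, small_network.edges],
                            ignore_index=True))
        more = modeled_memory(doubled, pm).sum()
        assert more - base == pytest.approx(
            parallel.BYTES_PER_EDGE * small_network.M)

    def test_jsonl_emission(self, small_network, small_stimulus, tmp_path):
        res = simulate_partitioned(
            small_network, small_stimulus, 10.0, 0.05, 0,
            partition_by_location(small_network, 2))
        path = tmp_path / "perf.jsonl"
        res.perf.to_jsonl(path, window=50)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2 * 4  # 2 ranks x ceil(200 steps / 50)
        import json
        rec = json.loads(lines[0])
        assert {"rank", "advance_seconds", "barrier_wait_seconds",
                "spikes_sent"} <= set(rec)
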