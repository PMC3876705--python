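import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from neopatch import cells, netgen, workbench
from neopatch.dynamics import SynapseSpec
from neopatch.errors import CalibrationError, ConfigurationError
from neopatch.netgen import (
    ConnectionRule,
    MemoryModelParams,
    assign_delay,
    calibrate_density,
    connection_probability,
    expected_connection_count,
    generate_network,
    predict_memory_bytes,
)

EXC = SynapseSpec(kind="alpha_excitatory")


def spyr_only(n, seed=0, jitter=0.1):
    cls = [c for c in cells.build_cell_classes() if c.name == "SPYR"]
    return cells.place_neurons_for_count(n, cls, jitter=jitter, seed=seed)


def rule(**kw):
    kw.setdefault("pre_class", "SPYR")
    kw.setdefault("post_class", "SPYR")
    kw.setdefault("synapse", EXC)
    return ConnectionRule(**kw)


class TestConnectionProbability:
    def test_beyond_cutoff_is_zero(self):
        r = rule(kernel="uniform_disc", cutoff_um=500.0, base_probability=0.1)
        assert connection_probability(r, 600.0) == 0.0

    def test_kernel_normalized_at_zero_distance(self):
        for kernel in ("uniform_disc", "gaussian"):
            r = rule(kernel=kernel, cutoff_um=400.0, base_probability=0.37)
            assert connection_probability(r, 0.0) == pytest.approx(0.37)

    def test_gaussian_value_at_half_cutoff(self):
        r = rule(kernel="gaussian", cutoff_um=600.0, base_probability=0.2)
        # sigma defaults to cutoff/2, so d = sigma gives base * exp(-1/2)
        assert connection_probability(r, 300.0) == pytest.approx(
            0.2 * math.exp(-0.5), rel=1e-12)

    def test_long_range_beyond_one_mm(self):
        r = rule(cutoff_um=500.0, base_probability=0.1,
                 long_range_probability=0.01)
        assert connection_probability(r, 800.0) == 0.0
        assert connection_probability(r, 1500.0) == 0.01

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            connection_probability(rule(), -1.0)

    def test_rule_validation(self):
        with pytest.raises(ConfigurationError):
            rule(cutoff_um=50.0)  # below the 100 µm model minimum
        with pytest.raises(ConfigurationError):
            rule(base_probability=1.5)


class TestGeneration:
    def test_certain_connection_gives_both_directed_edges(self):
        neurons = pd.DataFrame({
            "id": [0, 1], "cell_class": "SPYR",
            "x_um": [0.0, 50.0], "y_um": [0.0, 0.0]})
        net = generate_network(neurons, [rule(base_probability=1.0,
                                              cutoff_um=100.0)], seed=0)
        got = set(zip(net.edges["pre_id"], net.edges["post_id"]))
        assert got == {(0, 1), (1, 0)}

    def test_zero_probability_gives_no_edges(self):
        neurons = spyr_only(50)
        net = generate_network(neurons, [rule(base_probability=0.0)], seed=0)
        assert net.M == 0

    def test_no_self_edges_and_cutoff_respected(self, small_network):
        edges = small_network.edges
        assert (edges["pre_id"] != edges["post_id"]).all()
        pos = small_network.neurons[["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(pos[edges["pre_id"]] - pos[edges["post_id"]],
                           axis=1)
        assert d.max() <= 500.0  # largest configured cutoff

    def test_bitwise_reproducible_given_seed(self):
        neurons = spyr_only(300, seed=2)
        r = [rule(base_probability=0.05, cutoff_um=150.0)]
        a = generate_network(neurons, r, seed=9).edges
        b = generate_network(neurons, r, seed=9).edges
        assert a.equals(b)
        c = generate_network(neurons, r, seed=10).edges
        assert not a.equals(c)

    def test_missing_rule_raises(self):
        neurons = cells.place_neurons_for_count(50, jitter=0.0, seed=0)
        with pytest.raises(ConfigurationError):
            generate_network(neurons, [rule()], seed=0)

    def test_edge_counts_match_binomial_oracle_over_seeds(self):
        neurons = spyr_only(1000, seed=4)
        p = 0.05
        r = [rule(base_probability=p, cutoff_um=100.0)]
        expected = expected_connection_count(neurons, r)
        sigma = math.sqrt(expected * (1.0 - p))
        for seed in range(20):
            m = generate_network(neurons, r, seed=seed).M
            assert abs(m - expected) < 4.0 * sigma

    def test_delays_positive_and_velocity_consistent(self, small_network):
        delays = small_network.edges["delay_ms"]
        assert (delays > 0).all()
        # worst case: longest allowed distance at the slowest jittered speed
        assert delays.max() <= 500.0 / (200.0 * 0.8) + 1e-9


class TestExpectedCount:
    def test_all_within_cutoff_quadratic(self):
        neurons = pd.DataFrame({
            "id": range(10), "cell_class": "SPYR",
            "x_um": np.linspace(0, 20, 10), "y_um": 0.0})
        r = [rule(base_probability=0.3, cutoff_um=100.0)]
        assert expected_connection_count(neurons, r) == pytest.approx(
            0.3 * 10 * 9)

    def test_two_isolated_neurons(self):
        neurons = pd.DataFrame({
            "id": [0, 1], "cell_class": "SPYR",
            "x_um": [0.0, 700.0], "y_um": [0.0, 0.0]})
        assert expected_connection_count(
            neurons, [rule(cutoff_um=500.0, base_probability=0.5)]) == 0.0

    def test_linear_growth_at_fixed_density_and_cutoff(self):
        r = [rule(base_probability=0.02, cutoff_um=100.0)]
        per_neuron = []
        for n in (8000, 32000, 128000):
            neurons = spyr_only(n, seed=6)
            per_neuron.append(expected_connection_count(neurons, r) / n)
        # expectation per neuron converges (linear total regime): the
        # remaining growth is the shrinking patch-boundary correction
        assert per_neuron[1] / per_neuron[0] > per_neuron[2] / per_neuron[1]
        assert per_neuron[2] / per_neuron[1] < 1.1
        # and approaches the unbounded-plane value p * rho * pi * r^2
        assert per_neuron[2] < 0.02 * 0.04 * np.pi * 100.0 ** 2


class TestCalibration:
    def test_fixed_point(self):
        neurons = spyr_only(200, seed=1)
        rules = [rule(base_probability=0.05, cutoff_um=150.0)]
        target = expected_connection_count(neurons, rules)
        out = calibrate_density(rules, neurons, target)
        assert out[0].base_probability == pytest.approx(0.05, rel=1e-6)

    def test_linear_in_target_below_saturation(self):
        neurons = spyr_only(200, seed=1)
        rules = [rule(base_probability=0.05, cutoff_um=150.0)]
        base = expected_connection_count(neurons, rules)
        half = calibrate_density(rules, neurons, base / 2.0)
        assert half[0].base_probability == pytest.approx(0.025, rel=1e-6)

    def test_unreachable_target_raises(self):
        neurons = spyr_only(50, seed=1)
        rules = [rule(base_probability=0.05, cutoff_um=150.0)]
        with pytest.raises(CalibrationError):
            calibrate_density(rules, neurons, 1e9)

    def test_saturation_warns_and_clips(self):
        neurons = spyr_only(50, seed=1)
        rules = [
            rule(base_probability=0.9, cutoff_um=100.0),
            rule(post_class="DPYR", base_probability=0.01, cutoff_um=100.0),
        ]
        neurons2 = pd.concat([
            neurons,
            spyr_only(50, seed=2).assign(cell_class="DPYR",
                                         id=lambda d: d["id"] + 50),
        ], ignore_index=True)
        n_pairs_ee = cKDTree(
            neurons[["x_um", "y_um"]].to_numpy()).count_neighbors(
            cKDTree(neurons[["x_um", "y_um"]].to_numpy()), r=100.0) - 50
        target = n_pairs_ee * 1.0 + 100  # forces the first rule past 1
        rules_full = rules + [
            rule(pre_class="DPYR", post_class="SPYR", base_probability=0.01,
                 cutoff_um=100.0),
            rule(pre_class="DPYR", post_class="DPYR", base_probability=0.01,
                 cutoff_um=100.0),
        ]
        with pytest.warns(UserWarning, match="saturated"):
            out = calibrate_density(rules_full, neurons2, target)
        assert out[0].base_probability == 1.0


class TestDelays:
    def test_jitter_free_ratio(self):
        r = rule(velocity_um_per_ms=500.0, velocity_jitter=0.0)
        rng = np.random.default_rng(0)
        assert assign_delay(r, 500.0, rng) == pytest.approx(1.0)

    def test_jitter_bounds(self):
        r = rule(velocity_um_per_ms=500.0, velocity_jitter=0.2)
        rng = np.random.default_rng(0)
        d = assign_delay(r, np.full(2000, 500.0), rng)
        assert d.min() >= 0.8 - 1e-12 and d.max() <= 1.2 + 1e-12

    def test_zero_distance_floors_at_one_step(self):
        r = rule(velocity_um_per_ms=500.0, velocity_jitter=0.2)
        rng = np.random.default_rng(0)
        assert assign_delay(r, 0.0, rng, dt_ms=0.05) == 0.05


class TestMemoryModel:
    def test_small_volume_quadratic_regime(self):
        p = MemoryModelParams(bytes_per_edge=24.0, n_saturation=1e6,
                              bytes_per_neuron=100.0, probability=0.1)
        n = 1000  # << saturation
        expected = 24.0 * 0.1 * n * (n - 1) + 100.0 * n
        assert predict_memory_bytes(p, n) == pytest.approx(expected, rel=1e-3)

    def test_asymptotic_slope_approaches_one(self):
        p = MemoryModelParams(n_saturation=1e4, probability=0.05,
                              bytes_per_neuron=0.0)
        slope = netgen.effective_exponent(p, 1e8, 1e9)
        assert slope == pytest.approx(1.0, abs=1e-3)

    def test_single_neuron_no_connection_bytes(self):
        p = MemoryModelParams(bytes_per_neuron=0.0)
        assert predict_memory_bytes(p, 1) == 0.0

    def test_effective_exponent_decreases_monotonically(self):
        p = MemoryModelParams(n_saturation=1e4, probability=0.05)
        sizes = [1e2, 1e3, 1e4, 1e5, 1e6]
        exps = [netgen.effective_exponent(p, a, b)
                for a, b in zip(sizes, sizes[1:])]
        assert all(e1 > e2 for e1, e2 in zip(exps, exps[1:]))
        assert 1.0 < exps[-1] < exps[0] <= 2.0


class TestInterchange:
    def test_edge_table_round_trip(self, small_network, tmp_path):
        path = tmp_path / "edges.tsv"
        netgen.write_edge_table(small_network, path)
        back = netgen.read_edge_table(small_network.neurons, path)
        assert back.M == small_network.M
        assert np.array_equal(back.edges["pre_id"],
                              small_network.edges["pre_id"])
        assert np.allclose(back.edges["delay_ms"],
                           small_network.edges["delay_ms"])
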