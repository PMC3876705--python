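"""Synaptic wiring generation with distance kernels, and the connection
memory model.

Connections are sampled independently per ordered neuron pair from a
class-pair rule: within a cutoff distance (100-900 µm depending on the
connection type, 500 µm for the dominant excitatory-excitatory type) the
probability follows a distance kernel scaled by a base probability; between
the cutoff and 1 mm it is zero; beyond 1 mm an optional flat long-range
probability applies (disabled by default, matching patches below ~100 K
cells).  Conduction delays are distance over a partially randomized
velocity.

The module also provides the analytic expectation of the edge count (the
oracle used to test the sampler and to calibrate densities) and the
crossover memory model: connection storage grows quadratically with neuron
count while a patch is smaller than the connection radius and linearly once
the in-range neighborhood saturates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .cells import CLASS_NAMES
from .dynamics import SynapseSpec
from .errors import CalibrationError, ConfigurationError

__all__ = [
    "ConnectionRule",
    "Network",
    "MemoryModelParams",
    "connection_probability",
    "generate_network",
    "expected_connection_count",
    "calibrate_density",
    "assign_delay",
    "predict_memory_bytes",
    "effective_exponent",
    "write_edge_table",
    "read_edge_table",
]

LONG_RANGE_THRESHOLD_UM = 1000.0

_KIND_OF_SIGN = {
    "excitatory": "alpha_excitatory",
    "inhibitory": "dualexp_inhibitory",
}


@dataclass(frozen=True)
class ConnectionRule:
    """Wiring rule for one ordered (pre-class, post-class) pair."""

    pre_class: str
    post_class: str
    kernel: str = "uniform_disc"  # or "gaussian"
    cutoff_um: float = 300.0
    base_probability: float = 0.1
    tuning_multiplier: float = 1.0
    synapse: SynapseSpec = SynapseSpec(kind="alpha_excitatory")
    velocity_um_per_ms: float = 200.0
    velocity_jitter: float = 0.2
    long_range_probability: float = 0.0
    sigma_um: float | None = None  # gaussian width; default cutoff/2

    def __post_init__(self) -> None:
        if self.kernel not in ("uniform_disc", "gaussian"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")
        if not (100.0 <= self.cutoff_um <= 900.0):
            raise ConfigurationError(
                f"cutoff must lie in [100, 900] µm, got {self.cutoff_um}"
            )
        for p in (self.base_probability, self.long_range_probability):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.velocity_um_per_ms <= 0:
            raise ConfigurationError("conduction velocity must be positive")
        if not (0.0 <= self.velocity_jitter < 1.0):
            raise ConfigurationError("velocity jitter must lie in [0, 1)")

    @property
    def sigma(self) -> float:
        return self.sigma_um if self.sigma_um is not None else self.cutoff_um / 2.0


@dataclass
class Network:
    """A generated patch: neuron table plus directed edge table.

    ``neurons`` columns: id, cell_class, x_um, y_um.
    ``edges`` columns: pre_id, post_id, delay_ms, weight, kind.
    """

    neurons: pd.DataFrame
    edges: pd.DataFrame

    @property
    def N(self) -> int:
        return len(self.neurons)

    @property
    def M(self) -> int:
        return len(self.edges)


def _rules_by_pair(rules: Iterable[ConnectionRule]) -> dict:
    out = {}
    for r in rules:
        key = (r.pre_class, r.post_class)
        if key in out:
            raise ConfigurationError(f"duplicate rule for pair {key}")
        out[key] = r
    return out


def connection_probability(rule: ConnectionRule, distance_um):
    """Probability of a directed connection at the given somatic distance.

    Zero between the cutoff and 1 mm; the flat long-range probability
    beyond 1 mm; base probability times the distance kernel (normalized to
    one at zero distance) within the cutoff.  Accepts scalars or arrays.
    """
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    if rule.kernel == "uniform_disc":
        k = np.ones_like(d)
    else:
        k = np.exp(-(d ** 2) / (2.0 * rule.sigma ** 2))
    p = np.clip(rule.base_probability * k, 0.0, 1.0)
    p = np.where(d > rule.cutoff_um, 0.0, p)
    p = np.where(d > LONG_RANGE_THRESHOLD_UM, rule.long_range_probability, p)
    return p if p.ndim else float(p)


def assign_delay(rule: ConnectionRule, distance_um, rng: np.random.Generator,
                 dt_ms: float = 0.05):
    """Conduction delay: distance over a velocity randomized per edge by a
    uniform fractional jitter, floored at one integration step."""
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    u = rng.uniform(-rule.velocity_jitter, rule.velocity_jitter, size=d.shape)
    delay = (d / rule.velocity_um_per_ms) * (1.0 + u)
    delay = np.maximum(delay, dt_ms)
    return delay if delay.ndim else float(delay)


_CHUNK = 1024  # pre-neuron rows handled per block during sampling


def _iter_rule_candidates(
    pre_pos: np.ndarray, post_pos: np.ndarray, post_tree: cKDTree,
    cutoff: float, same_class: bool, pre_ids: np.ndarray, post_ids: np.ndarray,
):
    """Yield (pre_id, post_id, distance) arrays for within-cutoff candidate
    pairs, in deterministic (pre, post) order, chunked to bound memory."""
    if same_class:
        # C-level pair enumeration; expand the i<j pairs to both directions
        pairs = post_tree.query_pairs(r=cutoff, output_type="ndarray")
        pi = np.concatenate([pairs[:, 0], pairs[:, 1]])
        pj = np.concatenate([pairs[:, 1], pairs[:, 0]])
        order = np.lexsort((pj, pi))
        pi, pj = pi[order], pj[order]
        for lo in range(0, pi.size, _CHUNK * 256):
            hi = min(lo + _CHUNK * 256, pi.size)
            dist = np.linalg.norm(pre_pos[pi[lo:hi]] - post_pos[pj[lo:hi]],
                                  axis=1)
            yield pre_ids[pi[lo:hi]], post_ids[pj[lo:hi]], dist
        return
    for lo in range(0, len(pre_pos), _CHUNK):
        hi = min(lo + _CHUNK, len(pre_pos))
        neigh = post_tree.query_ball_point(pre_pos[lo:hi], r=cutoff)
        pre_list, post_list = [], []
        for i, js in enumerate(neigh):
            js = np.sort(np.asarray(js, dtype=np.int64))
            pre_list.append(np.full(js.size, lo + i, dtype=np.int64))
            post_list.append(js)
        if not pre_list:
            continue
        pi = np.concatenate(pre_list)
        pj = np.concatenate(post_list)
        if pi.size == 0:
            continue
        dist = np.linalg.norm(pre_pos[pi] - post_pos[pj], axis=1)
        yield pre_ids[pi], post_ids[pj], dist


def _sorted_rules(rules: Sequence[ConnectionRule]) -> list[ConnectionRule]:
    order = {name: i for i, name in enumerate(CLASS_NAMES)}
    return sorted(rules, key=lambda r: (order.get(r.pre_class, 99),
                                        order.get(r.post_class, 99)))


def generate_network(
    neurons: pd.DataFrame,
    rules: Sequence[ConnectionRule],
    seed: int = 0,
    dt_ms: float = 0.05,
) -> Network:
    """Sample the directed edge list.

    Every ordered pair covered by a rule is an independent Bernoulli draw at
    :func:`connection_probability`; self-edges are excluded and at most one
    edge exists per ordered pair.  Deterministic given the seed and neuron
    ordering: rules are visited in canonical class order, each with its own
    child random stream, and candidate pairs are enumerated in (pre, post)
    order.
    """
    by_pair = _rules_by_pair(rules)
    present = list(dict.fromkeys(neurons["cell_class"]))
    for a in present:
        for b in present:
            if (a, b) not in by_pair:
                raise ConfigurationError(f"no connection rule for pair ({a}, {b})")

    groups = {
        name: neurons[neurons["cell_class"] == name] for name in present
    }
    pos = {n: np.column_stack([g["x_um"], g["y_um"]]) for n, g in groups.items()}
    ids = {n: g["id"].to_numpy() for n, g in groups.items()}
    trees = {n: cKDTree(pos[n]) for n in present}

    ss = np.random.SeedSequence(seed)
    ordered = [r for r in _sorted_rules(rules)
               if r.pre_class in groups and r.post_class in groups]
    children = ss.spawn(len(ordered))

    pre_all, post_all, delay_all, w_all, kind_all = [], [], [], [], []
    for rule, child in zip(ordered, children):
        rng = np.random.default_rng(child)
        a, b = rule.pre_class, rule.post_class
        for pre_id, post_id, dist in _iter_rule_candidates(
            pos[a], pos[b], trees[b], rule.cutoff_um, a == b, ids[a], ids[b]
        ):
            p = connection_probability(rule, dist)
            keep = rng.uniform(size=dist.size) < p
            if not np.any(keep):
                continue
            pre_all.append(pre_id[keep])
            post_all.append(post_id[keep])
            delay_all.append(assign_delay(rule, dist[keep], rng, dt_ms))
            w_all.append(np.full(keep.sum(), rule.tuning_multiplier))
            kind_all.append(np.full(keep.sum(), rule.synapse.kind, dtype=object))
        if rule.long_range_probability > 0:
            _sample_long_range(rule, pos, ids, a, b, rng, dt_ms,
                               pre_all, post_all, delay_all, w_all, kind_all)

    if pre_all:
        edges = pd.DataFrame({
            "pre_id": np.concatenate(pre_all),
            "post_id": np.concatenate(post_all),
            "delay_ms": np.concatenate(delay_all),
            "weight": np.concatenate(w_all),
            "kind": np.concatenate(kind_all),
        })
        edges = edges.sort_values(["pre_id", "post_id"],
                                  kind="stable").reset_index(drop=True)
    else:
        edges = pd.DataFrame(
            columns=["pre_id", "post_id", "delay_ms", "weight", "kind"]
        )
    return Network(neurons=neurons.reset_index(drop=True), edges=edges)


def _sample_long_range(rule, pos, ids, a, b, rng, dt_ms,
                       pre_all, post_all, delay_all, w_all, kind_all):
    """Flat-probability sampling of pairs beyond the 1 mm threshold."""
    pa, pb = pos[a], pos[b]
    for lo in range(0, len(pa), _CHUNK):
        hi = min(lo + _CHUNK, len(pa))
        d = np.linalg.norm(pa[lo:hi, None, :] - pb[None, :, :], axis=2)
        ii, jj = np.nonzero(d > LONG_RANGE_THRESHOLD_UM)
        if ii.size == 0:
            continue
        keep = rng.uniform(size=ii.size) < rule.long_range_probability
        ii, jj = ii[keep], jj[keep]
        if ii.size == 0:
            continue
        dist = d[ii, jj]
        pre_all.append(ids[a][lo + ii])
        post_all.append(ids[b][jj])
        delay_all.append(assign_delay(rule, dist, rng, dt_ms))
        w_all.append(np.full(ii.size, rule.tuning_multiplier))
        kind_all.append(np.full(ii.size, rule.synapse.kind, dtype=object))


def expected_connection_count(
    neurons: pd.DataFrame,
    rules: Sequence[ConnectionRule],
    factor: float = 1.0,
) -> float:
    """Exact expectation of the generated edge count: the sum of
    :func:`connection_probability` over all ordered pairs, with every base
    probability scaled by ``factor`` (and clipped at one)."""
    present = list(dict.fromkeys(neurons["cell_class"]))
    by_pair = _rules_by_pair(rules)
    groups = {n: neurons[neurons["cell_class"] == n] for n in present}
    pos = {n: np.column_stack([g["x_um"], g["y_um"]]) for n, g in groups.items()}
    ids = {n: g["id"].to_numpy() for n, g in groups.items()}
    trees = {n: cKDTree(pos[n]) for n in present}

    total = 0.0
    for a in present:
        for b in present:
            rule = by_pair.get((a, b))
            if rule is None:
                continue
            p_eff = min(factor * rule.base_probability, 1.0)
            if rule.kernel == "uniform_disc":
                n_pairs = trees[a].count_neighbors(trees[b], r=rule.cutoff_um)
                if a == b:
                    n_pairs -= len(groups[a])  # self pairs at distance 0
                total += p_eff * n_pairs
            else:
                for _, _, dist in _iter_rule_candidates(
                    pos[a], pos[b], trees[b], rule.cutoff_um, a == b,
                    ids[a], ids[b],
                ):
                    total += np.minimum(
                        factor * rule.base_probability
                        * np.exp(-(dist ** 2) / (2.0 * rule.sigma ** 2)),
                        1.0,
                    ).sum()
            if rule.long_range_probability > 0:
                n_far = _count_pairs_beyond(pos[a], pos[b],
                                            LONG_RANGE_THRESHOLD_UM)
                total += rule.long_range_probability * n_far
    return float(total)


def _count_pairs_beyond(pa: np.ndarray, pb: np.ndarray, r: float) -> int:
    within = cKDTree(pa).count_neighbors(cKDTree(pb), r=r)
    return pa.shape[0] * pb.shape[0] - int(within)


def calibrate_density(
    rules: Sequence[ConnectionRule],
    neurons: pd.DataFrame,
    target_edge_count: float,
    tol: float = 1e-3,
) -> list[ConnectionRule]:
    """Scale all base probabilities by one common factor so the expected
    edge count matches the target within ``tol`` (relative).

    Saturated probabilities are clipped at one with a warning; a target
    above the all-clipped maximum raises :class:`CalibrationError`.
    """
    if target_edge_count <= 0:
        raise CalibrationError("target edge count must be positive")
    base = expected_connection_count(neurons, rules, factor=1.0)
    if base == 0:
        raise CalibrationError("no reachable pairs: expectation is zero")
    max_p = max(r.base_probability for r in rules if r.base_probability > 0)
    f_sat = 1.0 / max_p  # smallest factor at which clipping can start
    factor = target_edge_count / base
    if factor > f_sat:  # linear solution invalid once any rule clips
        f_hi = f_sat
        while (expected_connection_count(neurons, rules, f_hi)
               < target_edge_count):
            if f_hi > 1e12:
                raise CalibrationError(
                    f"target {target_edge_count:g} unreachable even with all "
                    f"probabilities clipped at 1"
                )
            f_hi *= 2.0
        factor = brentq(
            lambda f: expected_connection_count(neurons, rules, f)
            - target_edge_count,
            f_sat / 2.0, f_hi, xtol=1e-12, rtol=1e-12,
        )
    achieved = expected_connection_count(neurons, rules, factor)
    if abs(achieved - target_edge_count) > tol * target_edge_count:
        raise CalibrationError(
            f"calibration reached {achieved:g}, target {target_edge_count:g}"
        )
    out = []
    clipped = False
    for r in rules:
        p = factor * r.base_probability
        if p > 1.0:
            clipped = True
            p = 1.0
        out.append(replace(r, base_probability=p))
    if clipped:
        warnings.warn(
            "density calibration saturated: some base probabilities clipped "
            "at 1", stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# memory-occupation model

@dataclass(frozen=True)
class MemoryModelParams:
    """Crossover model for simulator memory.

    Connection storage is ``k`` bytes per edge; the expected edge count per
    neuron is ``p`` times the number of in-range partners, which grows with
    the patch until it saturates at ``n_saturation`` (the population inside
    one connection disc at fixed density).  Neuron state adds ``c3`` bytes
    per neuron.  The connection term therefore behaves as
    ``c1(N) * N**c2(N)`` with an effective exponent falling from 2 toward 1.
    """

    bytes_per_edge: float = 24.0
    n_saturation: float = 1e4
    bytes_per_neuron: float = 1024.0
    probability: float = 0.05

    def __post_init__(self) -> None:
        if self.n_saturation <= 0 or self.bytes_per_edge < 0:
            raise ConfigurationError("invalid memory-model parameters")


def _expected_edges(params: MemoryModelParams, n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    partners = (n - 1.0) * params.n_saturation / (n - 1.0 + params.n_saturation)
    return params.probability * n * partners


def predict_memory_bytes(params: MemoryModelParams, n) -> float | np.ndarray:
    """Modeled simulator memory in bytes at network size ``n``.

    Quadratic in the small-volume regime (all pairs in range), linear once
    the in-range neighborhood saturates, plus the linear per-neuron state
    term.
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ConfigurationError("network size must be >= 1")
    out = (params.bytes_per_edge * _expected_edges(params, n_arr)
           + params.bytes_per_neuron * n_arr)
    return out if out.ndim else float(out)


def effective_exponent(params: MemoryModelParams, n1: float, n2: float,
                       connection_term_only: bool = True) -> float:
    """Log-log slope of the (connection) memory between two sizes."""
    f = (_expected_edges(params, np.array([n1, n2]))
         if connection_term_only
         else np.asarray(predict_memory_bytes(params, np.array([n1, n2]))))
    return float(np.log(f[1] / f[0]) / np.log(n2 / n1))


# ---------------------------------------------------------------------------
# interchange

def write_edge_table(network: Network, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_edge_table(neurons: pd.DataFrame, path) -> Network:
    edges = pd.read_csv(path, sep="\t")
    return Network(neurons=neurons, edges=edges)
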