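"""Spatial partitioning, spike exchange and instrumentation.

The network is divided among ``P`` logical processes ("ranks") by spatial
location.  Each simulation step is phase-structured: every rank advances its
own neurons, all ranks rendezvous at a barrier, spikes are exchanged (a
spike travels only to ranks that own at least one of its targets; spikes
whose targets are all local never cross rank boundaries), and a second
barrier closes the step.

Parallelism is logical: the rank loops execute sequentially in rank order
inside one process.  That choice makes the central contract — bit-identical
spike rasters and pseudo-EEG for every partition count — directly testable,
because the per-neuron arithmetic is unchanged by how neurons are grouped.
Wall-clock instrumentation on the rank loops is indicative only; a
deterministic cost model (:func:`modeled_timing`) maps the collected
counters onto modeled phase times for load-balance and barrier analyses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import (
    PartitionError,
    RoutingError,
    UndefinedFractionError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import StimulusSpec
    from .netgen import Network

__all__ = [
    "PartitionMap",
    "PhasePerf",
    "SimResult",
    "partition_by_location",
    "build_routing_table",
    "exchange_spikes",
    "simulate_partitioned",
    "barrier_fraction",
    "modeled_memory",
    "modeled_timing",
    "write_partition_table",
]


@dataclass(frozen=True)
class PartitionMap:
    """Assignment of every neuron id to a rank in ``[0, P)``."""

    assignment: np.ndarray  # rank per neuron id
    P: int
    scheme: str

    def __post_init__(self) -> None:
        ranks = np.asarray(self.assignment)
        if ranks.min(initial=0) < 0 or (ranks.size and ranks.max() >= self.P):
            raise PartitionError("ranks must lie in [0, P)")

    def neurons_of(self, rank: int) -> np.ndarray:
        return np.nonzero(self.assignment == rank)[0]


def _balanced_split_sizes(n: int, parts: int) -> np.ndarray:
    """Contiguous chunk sizes differing by at most one."""
    base = n // parts
    sizes = np.full(parts, base, dtype=np.int64)
    sizes[: n - base * parts] += 1
    return sizes


def partition_by_location(network: "Network", P: int,
                          scheme: str = "stripe_x") -> PartitionMap:
    """Partition neurons into P spatially contiguous, balanced ranks.

    ``stripe_x`` sorts by (x, y, id) and cuts into P contiguous stripes;
    ``block_2d`` first stripes along x and then cuts each stripe along y,
    using the most square factorization of P.  Rank sizes differ by at most
    one neuron and the map is deterministic.
    """
    n = network.N
    if P < 1:
        raise PartitionError("P must be >= 1")
    if P > n:
        raise PartitionError(f"P = {P} exceeds neuron count {n}")
    neurons = network.neurons
    x = neurons["x_um"].to_numpy()
    y = neurons["y_um"].to_numpy()
    ids = neurons["id"].to_numpy()
    assignment = np.empty(n, dtype=np.int64)

    if scheme == "stripe_x":
        order = np.lexsort((ids, y, x))
        sizes = _balanced_split_sizes(n, P)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        for r in range(P):
            assignment[ids[order[bounds[r]: bounds[r + 1]]]] = r
    elif scheme == "block_2d":
        px = max(d for d in range(1, int(math.isqrt(P)) + 1) if P % d == 0)
        py = P // px
        order = np.lexsort((ids, y, x))
        xs = _balanced_split_sizes(n, px)
        xb = np.concatenate([[0], np.cumsum(xs)])
        for sx in range(px):
            stripe = order[xb[sx]: xb[sx + 1]]
            sorder = stripe[np.lexsort((ids[stripe], x[stripe], y[stripe]))]
            ys = _balanced_split_sizes(sorder.size, py)
            yb = np.concatenate([[0], np.cumsum(ys)])
            for sy in range(py):
                assignment[ids[sorder[yb[sy]: yb[sy + 1]]]] = sx * py + sy
    else:
        raise PartitionError(f"unknown scheme {scheme!r}")
    return PartitionMap(assignment=assignment, P=P, scheme=scheme)


# ---------------------------------------------------------------------------
# spike routing

@dataclass
class RoutingTable:
    """CSR map from presynaptic neuron id to the sorted set of ranks owning
    at least one of its targets."""

    indptr: np.ndarray
    target_ranks: np.ndarray
    P: int


def build_routing_table(network: "Network", pmap: PartitionMap) -> RoutingTable:
    n = network.N
    pre = network.edges["pre_id"].to_numpy(dtype=np.int64)
    post = network.edges["post_id"].to_numpy(dtype=np.int64)
    tr = pmap.assignment[post]
    # unique (pre, rank) pairs, sorted
    key = pre * pmap.P + tr
    uniq = np.unique(key)
    upre = uniq // pmap.P
    uranks = uniq % pmap.P
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, upre + 1, 1)
    np.cumsum(indptr, out=indptr)
    return RoutingTable(indptr=indptr, target_ranks=uranks, P=pmap.P)


def exchange_spikes(
    outboxes: Sequence[np.ndarray],
    pmap: PartitionMap,
    routing: RoutingTable,
) -> list[np.ndarray]:
    """Route each rank's emitted spikes to the inboxes of every rank owning
    at least one target of the spike.  A spike with local targets appears in
    the emitting rank's own inbox, but only the copies destined for *other*
    ranks constitute exchange traffic (intra-rank spikes bypass the wire;
    with P = 1 the inbox is simply the outbox).  Returns per-rank inboxes of
    presynaptic neuron ids, sorted.
    """
    n = pmap.assignment.size
    inboxes: list[list] = [[] for _ in range(pmap.P)]
    for rank, out in enumerate(outboxes):
        out = np.asarray(out, dtype=np.int64)
        if out.size == 0:
            continue
        if out.min() < 0 or out.max() >= n:
            bad = out[(out < 0) | (out >= n)][0]
            raise RoutingError(f"spike from unassigned neuron id {bad}")
        for nid in out:
            ranks = routing.target_ranks[
                routing.indptr[nid]: routing.indptr[nid + 1]
            ]
            for q in ranks:
                inboxes[int(q)].append(nid)
    return [np.sort(np.array(b, dtype=np.int64)) for b in inboxes]


# ---------------------------------------------------------------------------
# instrumentation

@dataclass
class PhasePerf:
    """Per-rank, per-step phase instrumentation.

    ``*_seconds`` arrays have shape (P, steps).  ``spikes_sent`` counts
    (spike, destination-rank) messages leaving each rank per step;
    ``spikes_received`` the matching arrivals, so the two totals agree at
    every step.  ``deliveries`` counts synaptic events enqueued per rank.
    ``resident_bytes`` is the modeled per-rank memory, not process RSS.
    """

    advance_seconds: np.ndarray
    exchange_seconds: np.ndarray
    barrier_wait_seconds: np.ndarray
    spikes_sent: np.ndarray
    spikes_received: np.ndarray
    deliveries: np.ndarray
    local_neurons: np.ndarray      # (P,)
    local_compartments: np.ndarray  # (P,)
    resident_bytes: np.ndarray      # (P,)

    @property
    def P(self) -> int:
        return self.advance_seconds.shape[0]

    @property
    def steps(self) -> int:
        return self.advance_seconds.shape[1]

    def to_jsonl(self, path, window: int = 100) -> None:
        """Write one JSON record per (rank, step-window)."""
        with open(path, "w") as fh:
            for r in range(self.P):
                for lo in range(0, self.steps, window):
                    hi = min(lo + window, self.steps)
                    rec = {
                        "rank": r,
                        "step_start": lo,
                        "step_stop": hi,
                        "advance_seconds": float(
                            self.advance_seconds[r, lo:hi].sum()),
                        "exchange_seconds": float(
                            self.exchange_seconds[r, lo:hi].sum()),
                        "barrier_wait_seconds": float(
                            self.barrier_wait_seconds[r, lo:hi].sum()),
                        "spikes_sent": int(self.spikes_sent[r, lo:hi].sum()),
                        "spikes_received": int(
                            self.spikes_received[r, lo:hi].sum()),
                        "deliveries": int(self.deliveries[r, lo:hi].sum()),
                        "resident_bytes": int(self.resident_bytes[r]),
                    }
                    fh.write(json.dumps(rec) + "\n")


@dataclass
class SimResult:
    """Output of a simulation run: spike raster, pseudo-EEG trace and
    per-rank instrumentation."""

    spikes: pd.DataFrame   # time_ms, neuron_id, cell_class
    eeg: pd.DataFrame      # time_ms, value
    perf: PhasePerf


def simulate_partitioned(
    network: "Network",
    stimulus: "StimulusSpec | None",
    duration_ms: float,
    dt_ms: float,
    seed: int,
    pmap: PartitionMap,
    **kwargs,
) -> SimResult:
    """Run the phase-structured partitioned simulation.

    The defining contract: the spike list and pseudo-EEG are bit-identical
    to the single-rank run of the same configuration and seed.
    """
    from ._engine import simulate

    return simulate(network, stimulus, duration_ms, dt_ms, seed, pmap,
                    **kwargs)


def barrier_fraction(perf: PhasePerf, pooled: bool = False):
    """Fraction of each rank's time spent waiting at barriers.

    With ``pooled=True`` returns the single all-rank fraction instead of the
    per-rank vector.
    """
    per_rank_total = (
        perf.advance_seconds + perf.exchange_seconds
        + perf.barrier_wait_seconds
    ).sum(axis=1)
    wait = perf.barrier_wait_seconds.sum(axis=1)
    if pooled:
        tot = per_rank_total.sum()
        if tot <= 0:
            raise UndefinedFractionError("zero total time")
        return float(wait.sum() / tot)
    if np.any(per_rank_total <= 0):
        raise UndefinedFractionError("zero total time for some rank")
    return wait / per_rank_total


# deterministic per-unit costs of the logical cost model (arbitrary units)
_COST_PER_COMPARTMENT_STEP = 1.0
_COST_PER_DELIVERY = 0.2
_COST_PER_MESSAGE = 0.5
_COST_EXCHANGE_FIXED = 1.0


def modeled_timing(perf: PhasePerf) -> PhasePerf:
    """Replace measured phase times with a deterministic cost model.

    Advance cost is proportional to local compartment updates plus local
    synaptic event deliveries; exchange cost to cross-rank message traffic.
    Barrier waits are the rendezvous residuals (slowest rank minus own time,
    per phase, per step).  Used for load-balance and barrier-trend analyses,
    which must not depend on wall-clock noise.
    """
    adv = (
        _COST_PER_COMPARTMENT_STEP
        * perf.local_compartments[:, None]
        * np.ones_like(perf.advance_seconds)
        + _COST_PER_DELIVERY * perf.deliveries
    )
    exch = (
        _COST_EXCHANGE_FIXED
        + _COST_PER_MESSAGE * (perf.spikes_sent + perf.spikes_received)
    )
    barrier = (adv.max(axis=0)[None, :] - adv) + (
        exch.max(axis=0)[None, :] - exch
    )
    return PhasePerf(
        advance_seconds=adv,
        exchange_seconds=exch,
        barrier_wait_seconds=barrier,
        spikes_sent=perf.spikes_sent,
        spikes_received=perf.spikes_received,
        deliveries=perf.deliveries,
        local_neurons=perf.local_neurons,
        local_compartments=perf.local_compartments,
        resident_bytes=perf.resident_bytes,
    )


# modeled memory accounting (bytes); ratios matter, absolute values are
# documented model constants
BYTES_PER_NEURON = 1024.0
BYTES_PER_EDGE = 24.0
RANK_OVERHEAD_BYTES = 8.0 * 2 ** 20


def modeled_memory(
    network: "Network",
    pmap: PartitionMap,
    bytes_per_neuron: float = BYTES_PER_NEURON,
    bytes_per_edge: float = BYTES_PER_EDGE,
    overhead_bytes: float = RANK_OVERHEAD_BYTES,
) -> np.ndarray:
    """Modeled resident bytes per rank.

    Neuron state is charged to the owning rank and connection data to the
    rank owning the postsynaptic neuron, so the total across ranks equals
    the single-rank total plus one fixed overhead per rank.
    """
    per_rank = np.full(pmap.P, overhead_bytes, dtype=float)
    counts = np.bincount(pmap.assignment, minlength=pmap.P)
    per_rank += bytes_per_neuron * counts
    if network.M:
        post = network.edges["post_id"].to_numpy(dtype=np.int64)
        edge_counts = np.bincount(pmap.assignment[post], minlength=pmap.P)
        per_rank += bytes_per_edge * edge_counts
    return per_rank


def write_partition_table(pmap: PartitionMap, path) -> None:
    pd.DataFrame({
        "neuron_id": np.arange(pmap.assignment.size),
        "rank": pmap.assignment,
    }).to_csv(path, sep="\t", index=False)
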