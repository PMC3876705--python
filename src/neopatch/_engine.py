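"""Phase-structured network integration engine.

One simulation step is: (advance) every rank integrates the membrane and
synaptic-kernel states of its own neurons for one dt; (barrier) ranks
rendezvous; (exchange) the step's spikes are routed to the ranks owning
their targets and enqueued into per-rank delay ring buffers; (barrier).

Bit-identical partition invariance rests on three properties of the advance
and exchange arithmetic:

* membrane updates are elementwise per compartment, with scatter-adds that
  never cross a neuron boundary, so grouping neurons into ranks cannot
  change any neuron's trajectory;
* spikes are always processed in global presynaptic-id order, and each
  rank's edge list is a mask (order-preserving) of the globally sorted edge
  list, so the floating-point accumulation order into any delay-buffer cell
  is the same for every partition count;
* the pseudo-EEG is reduced from a globally ordered soma-voltage vector,
  never from per-rank partial sums.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cells import PYRAMIDAL_CLASSES, build_cell_classes
from .dynamics import (
    DEFAULT_CHANNELS,
    REFRACTORY_MS,
    SPIKE_THRESHOLD_MV,
    ChannelParams,
    CompiledMembrane,
    StimulusSpec,
    SynapseSpec,
    advance_compartments,
    compile_class,
    dualexp_norm,
    steady_state_gating,
)
from .errors import ConfigurationError, IntegrationError
from .parallel import (
    PartitionMap,
    PhasePerf,
    SimResult,
    build_routing_table,
    modeled_memory,
)

DEFAULT_SYNAPSES: dict[str, SynapseSpec] = {
    "alpha_excitatory": SynapseSpec(
        kind="alpha_excitatory", tau_ms=2.0, gmax_nS=0.4, reversal_mV=0.0),
    "dualexp_inhibitory": SynapseSpec(
        kind="dualexp_inhibitory", tau_rise_ms=1.0, tau_decay_ms=7.0,
        gmax_nS=1.2, reversal_mV=-75.0),
}

_SIGN_OF_KIND = {"alpha_excitatory": "excitatory",
                 "dualexp_inhibitory": "inhibitory"}


@dataclass
class _Rank:
    neuron_ids: np.ndarray        # global ids, ascending
    mem: CompiledMembrane         # gathered per-compartment constants
    soma_local: np.ndarray        # local compartment index of each soma
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    prev_soma_v: np.ndarray
    last_spike: np.ndarray
    # synaptic kernel states, one value per local neuron
    ae: np.ndarray
    ge: np.ndarray
    ri: np.ndarray
    di: np.ndarray
    ring_e: np.ndarray            # (ring_len, n_local)
    ring_i: np.ndarray
    # edges terminating on this rank, CSR over global presynaptic id
    indptr: np.ndarray
    post_local: np.ndarray
    delay_steps: np.ndarray
    amp: np.ndarray
    is_exc: np.ndarray
    stim_soma_local: np.ndarray   # local soma comp indices under stimulus


def _gather_membrane(mem_templates, class_idx,
                     neuron_ids) -> tuple[CompiledMembrane, np.ndarray]:
    """Concatenate class templates for the given neurons into one
    CompiledMembrane with locally remapped parent links."""
    cm, gl, el, gna, gk, ch, pa, gax = [], [], [], [], [], [], [], []
    soma_local = np.empty(neuron_ids.size, dtype=np.int64)
    off = 0
    for k, nid in enumerate(neuron_ids):
        t = mem_templates[class_idx[nid]]
        nc = t.n_compartments
        cm.append(t.cm_pF)
        gl.append(t.g_leak_nS)
        el.append(t.e_leak_mV)
        gna.append(t.g_na_nS)
        gk.append(t.g_k_nS)
        ch.append(t.child_idx + off)
        pa.append(t.parent_idx + off)
        gax.append(t.g_axial_nS)
        soma_local[k] = off
        off += nc
    t0 = mem_templates[0]
    mem = CompiledMembrane(
        cm_pF=np.concatenate(cm),
        g_leak_nS=np.concatenate(gl),
        e_leak_mV=np.concatenate(el),
        g_na_nS=np.concatenate(gna),
        g_k_nS=np.concatenate(gk),
        e_na=t0.e_na,
        e_k=t0.e_k,
        child_idx=np.concatenate(ch) if ch else np.empty(0, dtype=np.int64),
        parent_idx=np.concatenate(pa) if pa else np.empty(0, dtype=np.int64),
        g_axial_nS=np.concatenate(gax) if gax else np.empty(0),
        v_rest=t0.v_rest,
    )
    return mem, soma_local


def simulate(
    network,
    stimulus: StimulusSpec | None,
    duration_ms: float,
    dt_ms: float,
    seed: int,
    pmap: PartitionMap,
    channel_params: ChannelParams = DEFAULT_CHANNELS,
    tuning: Mapping[str, Mapping[str, float]] | None = None,
    synapse_specs: Mapping[str, SynapseSpec] | None = None,
    threshold_mV: float = SPIKE_THRESHOLD_MV,
    refractory_ms: float = REFRACTORY_MS,
) -> SimResult:
    """Run the partitioned fixed-step simulation (see module docstring)."""
    if duration_ms <= 0 or dt_ms <= 0:
        raise ConfigurationError("duration and dt must be positive")
    del seed  # reserved; the dynamics themselves are deterministic
    specs = dict(DEFAULT_SYNAPSES)
    if synapse_specs:
        specs.update(synapse_specs)
    exc, inh = specs["alpha_excitatory"], specs["dualexp_inhibitory"]

    neurons = network.neurons
    n_neurons = network.N
    class_names = neurons["cell_class"].to_numpy()
    classes = {c.name: c for c in build_cell_classes()}
    name_list = list(dict.fromkeys(class_names))
    name_to_slot = {nm: i for i, nm in enumerate(name_list)}
    class_idx = np.array([name_to_slot[nm] for nm in class_names])
    templates = [compile_class(classes[nm], channel_params)
                 for nm in name_list]

    steps = int(round(duration_ms / dt_ms))

    # --- edges, globally sorted by (pre, post); per-edge delivery data
    edges = network.edges
    pre = edges["pre_id"].to_numpy(dtype=np.int64)
    post = edges["post_id"].to_numpy(dtype=np.int64)
    kind = edges["kind"].to_numpy()
    weight = edges["weight"].to_numpy(dtype=float)
    is_exc = kind == "alpha_excitatory"
    delay_steps = np.maximum(
        np.rint(edges["delay_ms"].to_numpy(dtype=float) / dt_ms), 1
    ).astype(np.int64)
    gmax_edge = np.where(is_exc, exc.gmax_nS, inh.gmax_nS)
    tune = np.ones(len(edges))
    if tuning:
        post_class = class_names[post]
        for cname, per_sign in tuning.items():
            in_class = post_class == cname
            for sign, val in per_sign.items():
                sign_mask = is_exc if sign == "excitatory" else ~is_exc
                tune[in_class & sign_mask] = val
    amp_edge = gmax_edge * weight * tune

    ring_len = int(delay_steps.max(initial=1)) + 2

    # kernel propagation constants
    dec_e = np.exp(-dt_ms / exc.tau_ms)
    fe = dt_ms * np.e / exc.tau_ms
    dec_r = np.exp(-dt_ms / inh.tau_rise_ms)
    dec_d = np.exp(-dt_ms / inh.tau_decay_ms)
    norm_i = dualexp_norm(inh.tau_rise_ms, inh.tau_decay_ms)

    # --- stimulus
    stim_ids = (np.array(sorted(stimulus.target_ids), dtype=np.int64)
                if stimulus else np.empty(0, dtype=np.int64))
    stim_pA = stimulus.amplitude_nA * 1000.0 if stimulus else 0.0

    # --- per-rank compilation
    post_rank = pmap.assignment[post] if len(edges) else np.empty(0, int)
    ranks: list[_Rank] = []
    for r in range(pmap.P):
        nids = pmap.neurons_of(r)
        mem, soma_local = _gather_membrane(templates, class_idx, nids)
        g2l = np.full(n_neurons, -1, dtype=np.int64)
        g2l[nids] = np.arange(nids.size)
        v = np.full(mem.n_compartments, mem.v_rest)
        m0, h0, n0 = steady_state_gating(v)
        emask = post_rank == r
        pre_r = pre[emask]
        indptr = np.searchsorted(pre_r, np.arange(n_neurons + 1))
        sl = np.intersect1d(stim_ids, nids)
        ranks.append(_Rank(
            neuron_ids=nids,
            mem=mem,
            soma_local=soma_local,
            v=v, m=np.asarray(m0), h=np.asarray(h0), n=np.asarray(n0),
            prev_soma_v=np.full(nids.size, mem.v_rest),
            last_spike=np.full(nids.size, -np.inf),
            ae=np.zeros(nids.size), ge=np.zeros(nids.size),
            ri=np.zeros(nids.size), di=np.zeros(nids.size),
            ring_e=np.zeros((ring_len, nids.size)),
            ring_i=np.zeros((ring_len, nids.size)),
            indptr=indptr,
            post_local=g2l[post[emask]],
            delay_steps=delay_steps[emask],
            amp=amp_edge[emask],
            is_exc=is_exc[emask],
            stim_soma_local=soma_local[g2l[sl]],
        ))

    routing = build_routing_table(network, pmap)

    # --- instrumentation
    P = pmap.P
    adv_s = np.zeros((P, steps))
    exch_s = np.zeros((P, steps))
    sent = np.zeros((P, steps), dtype=np.int64)
    recv = np.zeros((P, steps), dtype=np.int64)
    deliv = np.zeros((P, steps), dtype=np.int64)

    # --- pseudo-EEG bookkeeping (global order, partition independent)
    pyr_mask = np.isin(class_names, PYRAMIDAL_CLASSES)
    pyr_ids = np.nonzero(pyr_mask)[0]
    eeg_w = (np.full(pyr_ids.size, 1.0 / pyr_ids.size)
             if pyr_ids.size else np.empty(0))
    soma_v_global = np.full(n_neurons, templates[0].v_rest)
    eeg_raw = np.zeros(steps)

    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    for k in range(steps):
        t = k * dt_ms
        t_new = (k + 1) * dt_ms
        slot = k % ring_len
        stim_on = (stimulus is not None
                   and stimulus.onset_ms <= t < stimulus.offset_ms)
        step_spikes: list[np.ndarray] = []
        for r, rk in enumerate(ranks):
            t0 = time.perf_counter()
            # consume due synaptic impulses
            rk.ae += rk.ring_e[slot]
            rk.ring_e[slot] = 0.0
            imp = rk.ring_i[slot]
            rk.ri += imp
            rk.di += imp
            rk.ring_i[slot] = 0.0
            g_e_now = rk.ge
            g_i_now = norm_i * (rk.di - rk.ri)
            nc = rk.mem.n_compartments
            g_add = np.zeros(nc)
            ge_add = np.zeros(nc)
            i_add = np.zeros(nc)
            g_add[rk.soma_local] = g_e_now + g_i_now
            ge_add[rk.soma_local] = (g_e_now * exc.reversal_mV
                                     + g_i_now * inh.reversal_mV)
            if stim_on and rk.stim_soma_local.size:
                i_add[rk.stim_soma_local] += stim_pA
            v_new, rk.m, rk.h, rk.n = advance_compartments(
                rk.v, rk.m, rk.h, rk.n, rk.mem, g_add, ge_add, i_add, dt_ms
            )
            if not np.all(np.isfinite(v_new)):
                bad_comp = int(np.nonzero(~np.isfinite(v_new))[0][0])
                bad_neuron = int(
                    rk.neuron_ids[np.searchsorted(
                        rk.soma_local, bad_comp, side="right") - 1]
                )
                raise IntegrationError(
                    f"non-finite membrane potential for neuron {bad_neuron} "
                    f"at step {k}", neuron_id=bad_neuron, step=k,
                )
            rk.v = v_new
            vs = v_new[rk.soma_local]
            crossed = (
                (rk.prev_soma_v < threshold_mV)
                & (vs >= threshold_mV)
                & (t_new - rk.last_spike >= refractory_ms)
            )
            local_spikes = rk.neuron_ids[crossed]
            rk.last_spike[crossed] = t_new
            rk.prev_soma_v = vs
            # propagate kernel states to the next step boundary
            rk.ge = dec_e * (rk.ge + fe * rk.ae)
            rk.ae *= dec_e
            rk.ri *= dec_r
            rk.di *= dec_d
            step_spikes.append(local_spikes)
            adv_s[r, k] = time.perf_counter() - t0

        # barrier 1 (rendezvous), then exchange phase
        ids = np.sort(np.concatenate(step_spikes))
        if ids.size:
            spike_steps.append(np.full(ids.size, k, dtype=np.int64))
            spike_ids.append(ids)
            owners = pmap.assignment[ids]
            cnt = routing.indptr[ids + 1] - routing.indptr[ids]
            tot = int(cnt.sum())
            if tot:
                starts = routing.indptr[ids]
                idx = np.repeat(starts, cnt) + (
                    np.arange(tot)
                    - np.repeat(np.cumsum(cnt) - cnt, cnt)
                )
                tr = routing.target_ranks[idx]
                own_rep = np.repeat(owners, cnt)
                cross = tr != own_rep
                sent[:, k] = np.bincount(own_rep[cross], minlength=P)
                recv[:, k] = np.bincount(tr[cross], minlength=P)
        for r, rk in enumerate(ranks):
            t0 = time.perf_counter()
            if ids.size:
                cnt = rk.indptr[ids + 1] - rk.indptr[ids]
                tot = int(cnt.sum())
                if tot:
                    starts = rk.indptr[ids]
                    eidx = np.repeat(starts, cnt) + (
                        np.arange(tot)
                        - np.repeat(np.cumsum(cnt) - cnt, cnt)
                    )
                    slots = (k + 1 + rk.delay_steps[eidx]) % ring_len
                    posts = rk.post_local[eidx]
                    em = rk.is_exc[eidx]
                    a = rk.amp[eidx]
                    np.add.at(rk.ring_e, (slots[em], posts[em]), a[em])
                    np.add.at(rk.ring_i, (slots[~em], posts[~em]), a[~em])
                    deliv[r, k] = tot
            exch_s[r, k] = time.perf_counter() - t0
        # barrier 2; then the global EEG reduction
        for rk in ranks:
            soma_v_global[rk.neuron_ids] = rk.v[rk.soma_local]
        if pyr_ids.size:
            eeg_raw[k] = soma_v_global[pyr_ids] @ eeg_w

    barrier = (adv_s.max(axis=0)[None, :] - adv_s) + (
        exch_s.max(axis=0)[None, :] - exch_s
    )
    perf = PhasePerf(
        advance_seconds=adv_s,
        exchange_seconds=exch_s,
        barrier_wait_seconds=barrier,
        spikes_sent=sent,
        spikes_received=recv,
        deliveries=deliv,
        local_neurons=np.array([rk.neuron_ids.size for rk in ranks]),
        local_compartments=np.array(
            [rk.mem.n_compartments for rk in ranks]),
        resident_bytes=modeled_memory(network, pmap),
    )

    if spike_ids:
        all_steps = np.concatenate(spike_steps)
        all_ids = np.concatenate(spike_ids)
    else:
        all_steps = np.empty(0, dtype=np.int64)
        all_ids = np.empty(0, dtype=np.int64)
    spikes = pd.DataFrame({
        "time_ms": (all_steps + 1) * dt_ms,
        "neuron_id": all_ids,
        "cell_class": class_names[all_ids] if all_ids.size else
        np.empty(0, dtype=object),
    })
    eeg = pd.DataFrame({
        "time_ms": (np.arange(steps) + 1) * dt_ms,
        "value": eeg_raw - eeg_raw.mean(),
    })
    return SimResult(spikes=spikes, eeg=eeg, perf=perf)
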