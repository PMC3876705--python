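"""Neuron and synapse dynamics.

Each neuron is a tree of cylindrical compartments coupled by axial
conductances.  Membrane kinetics are a documented standard conductance-based
model: transient sodium and delayed-rectifier potassium currents with
conventional voltage-dependent rate functions, plus leak, on the soma and
axon initial segment; the remaining compartments are passive cable.  This
stand-in preserves the engineering surface of the simulators being modeled
(multicompartment stepping, spike threshold at the soma, synaptic kernels
driven by delayed spikes) while keeping every downstream contract —
partition invariance, event conservation, scaling behavior — independent of
the exact channel kinetics.

Synaptic conductances follow the two kernel families used throughout:

* excitatory: alpha function ``g(t) = gmax (t/tau) exp(1 - t/tau)``,
  peak-normalized so the maximum is ``gmax`` at ``t = tau`` (tau 1-3 ms);
* inhibitory: dual exponential
  ``g(t) = gmax A (exp(-t/tau_d) - exp(-t/tau_r))`` with ``A`` chosen so the
  peak equals ``gmax`` (time constants 1-7 ms, rise < decay).

Both kernels are integrated as linear state updates with exact per-step
decay factors, so the ODE form reproduces the closed forms at step times to
machine precision.

Units: mV, ms, nS, nA (stimuli), pA (internal currents), pF, µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .cells import CellClass, CompartmentRole, compartment_area
from .errors import ConfigurationError, IntegrationError

if TYPE_CHECKING:  # pragma: no cover
    from .netgen import Network
    from .parallel import PhasePerf

__all__ = [
    "SynapseSpec",
    "SpikeEvent",
    "StimulusSpec",
    "NeuronState",
    "ChannelParams",
    "DEFAULT_CHANNELS",
    "alpha_conductance",
    "dualexp_conductance",
    "dualexp_peak_time",
    "rest_potential",
    "make_initial_state",
    "step_neuron",
    "detect_spike",
    "run_simulation",
    "pseudo_eeg",
    "SPIKE_THRESHOLD_MV",
    "REFRACTORY_MS",
]

# Soma spike threshold and refractory window for spike *detection*
# (bookkeeping only; the membrane equations are not reset).
SPIKE_THRESHOLD_MV = -20.0
REFRACTORY_MS = 2.0

# unit conversions for densities given per cm^2 and areas in µm^2
_NS_PER_UM2 = 0.01  # 1 mS/cm^2
_PF_PER_UM2 = 0.01  # 1 µF/cm^2


# ---------------------------------------------------------------------------
# synaptic kernels

@dataclass(frozen=True)
class SynapseSpec:
    """Kernel family and parameters for one synapse population.

    ``alpha_excitatory`` uses ``tau_ms``; ``dualexp_inhibitory`` uses
    ``tau_rise_ms``/``tau_decay_ms``.  ``gmax_nS`` is the peak conductance
    of a unit-weight synapse and ``reversal_mV`` its driving reversal.
    """

    kind: str  # "alpha_excitatory" | "dualexp_inhibitory"
    gmax_nS: float = 1.0
    reversal_mV: float = 0.0
    tau_ms: float = 2.0
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 7.0

    def __post_init__(self) -> None:
        if self.kind not in ("alpha_excitatory", "dualexp_inhibitory"):
            raise ConfigurationError(f"unknown synapse kind {self.kind!r}")
        if self.gmax_nS < 0:
            raise ConfigurationError("gmax must be nonnegative")
        if self.kind == "alpha_excitatory":
            if not (1.0 <= self.tau_ms <= 3.0):
                raise ConfigurationError(
                    f"alpha synapse tau must lie in [1, 3] ms, got {self.tau_ms}"
                )
        else:
            if not (0 < self.tau_rise_ms < self.tau_decay_ms):
                raise ConfigurationError("need 0 < tau_rise < tau_decay")
            if not (1.0 <= self.tau_rise_ms and self.tau_decay_ms <= 7.0):
                raise ConfigurationError(
                    "dual-exponential time constants must lie in [1, 7] ms"
                )


def alpha_conductance(t_ms, tau_ms: float, gmax_nS: float):
    """Alpha-function conductance, zero for t < 0, peaking at gmax at t=tau."""
    if tau_ms <= 0:
        raise ConfigurationError("tau must be positive")
    t = np.asarray(t_ms, dtype=float)
    g = gmax_nS * (t / tau_ms) * np.exp(1.0 - t / tau_ms)
    g = np.where(t < 0, 0.0, g)
    return g if g.ndim else float(g)


def dualexp_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Time of the dual-exponential maximum."""
    if not 0 < tau_rise_ms < tau_decay_ms:
        raise ConfigurationError("need 0 < tau_rise < tau_decay")
    return (
        tau_rise_ms * tau_decay_ms / (tau_decay_ms - tau_rise_ms)
        * math.log(tau_decay_ms / tau_rise_ms)
    )


def dualexp_norm(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Amplitude A making the dual-exponential difference peak at 1."""
    tp = dualexp_peak_time(tau_rise_ms, tau_decay_ms)
    return 1.0 / (
        math.exp(-tp / tau_decay_ms) - math.exp(-tp / tau_rise_ms)
    )


def dualexp_conductance(t_ms, tau_rise_ms: float, tau_decay_ms: float,
                        gmax_nS: float):
    """Dual-exponential conductance, zero for t < 0, peak-normalized."""
    a = dualexp_norm(tau_rise_ms, tau_decay_ms)
    t = np.asarray(t_ms, dtype=float)
    g = gmax_nS * a * (np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms))
    g = np.where(t < 0, 0.0, g)
    return g if g.ndim else float(g)


# ---------------------------------------------------------------------------
# membrane model

@dataclass(frozen=True)
class ChannelParams:
    """Densities (mS/cm²), reversals (mV) and cable constants of the
    conductance-based membrane stand-in."""

    g_na: float = 120.0
    g_k: float = 36.0
    g_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.4
    ra_ohm_cm: float = 100.0
    cm_uf_cm2: float = 1.0
    # compartment roles carrying active channels
    active_roles: tuple[CompartmentRole, ...] = (
        CompartmentRole.SOMA,
        CompartmentRole.IS,
    )


DEFAULT_CHANNELS = ChannelParams()


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    r = x / y
    small = np.abs(r) < 1e-7
    safe = np.where(small, 1.0, r)
    return np.where(small, y * (1.0 - r / 2.0), x / np.expm1(safe))


def _rates(v):
    """Voltage-dependent opening/closing rates (1/ms) of m, h, n."""
    am = 0.1 * _vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def steady_state_gating(v):
    am, bm, ah, bh, an, bn = _rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def rest_potential(params: ChannelParams = DEFAULT_CHANNELS) -> float:
    """Resting potential of an active compartment (zero net current)."""

    def balance(v):
        m, h, n = steady_state_gating(v)
        return (
            params.g_leak * (v - params.e_leak)
            + params.g_na * m ** 3 * h * (v - params.e_na)
            + params.g_k * n ** 4 * (v - params.e_k)
        )

    return float(brentq(balance, -80.0, -50.0, xtol=1e-12))


@dataclass
class CompiledMembrane:
    """Per-compartment constant arrays for a set of neurons (one class
    template or a whole network slice)."""

    cm_pF: np.ndarray
    g_leak_nS: np.ndarray
    e_leak_mV: np.ndarray
    g_na_nS: np.ndarray
    g_k_nS: np.ndarray
    e_na: float
    e_k: float
    child_idx: np.ndarray   # compartments that have a parent
    parent_idx: np.ndarray  # their parents (same length)
    g_axial_nS: np.ndarray  # coupling conductance child<->parent
    v_rest: float

    @property
    def n_compartments(self) -> int:
        return self.cm_pF.size


_PARENT_ROLE = {
    CompartmentRole.SOMA: None,
    CompartmentRole.D1: CompartmentRole.SOMA,
    CompartmentRole.D2: CompartmentRole.D1,
    CompartmentRole.D3: CompartmentRole.D2,
    CompartmentRole.D4: CompartmentRole.D3,
    CompartmentRole.BD: CompartmentRole.SOMA,
    CompartmentRole.IS: CompartmentRole.SOMA,
}

_template_cache: dict = {}


def compile_class(cell_class: CellClass,
                  params: ChannelParams = DEFAULT_CHANNELS) -> CompiledMembrane:
    """Build the constant per-compartment arrays for one cell class.

    Passive compartments get their leak reversal pinned to the active-side
    resting potential so a whole cell at rest carries no axial current.
    """
    key = (cell_class, params)
    if key in _template_cache:
        return _template_cache[key]
    v_rest = rest_potential(params)
    comps = cell_class.compartments
    roles = [c.role for c in comps]
    areas = np.array([compartment_area(c) for c in comps])
    active = np.array([c.role in params.active_roles for c in comps])
    cm = params.cm_uf_cm2 * _PF_PER_UM2 * areas
    g_leak = params.g_leak * _NS_PER_UM2 * areas
    g_na = np.where(active, params.g_na * _NS_PER_UM2 * areas, 0.0)
    g_k = np.where(active, params.g_k * _NS_PER_UM2 * areas, 0.0)
    e_leak = np.where(active, params.e_leak, v_rest)

    child, parent, g_ax = [], [], []
    ra_mohm_um = params.ra_ohm_cm * 1e-2  # MΩ·µm
    for i, c in enumerate(comps):
        prole = _PARENT_ROLE[c.role]
        if prole is None:
            continue
        j = roles.index(prole)
        p = comps[j]
        r_mohm = ra_mohm_um * (
            c.length_um / 2.0 / (math.pi * c.diameter_um ** 2 / 4.0)
            + p.length_um / 2.0 / (math.pi * p.diameter_um ** 2 / 4.0)
        )
        child.append(i)
        parent.append(j)
        g_ax.append(1000.0 / r_mohm)  # µS -> nS
    out = CompiledMembrane(
        cm_pF=cm,
        g_leak_nS=g_leak,
        e_leak_mV=e_leak,
        g_na_nS=g_na,
        g_k_nS=g_k,
        e_na=params.e_na,
        e_k=params.e_k,
        child_idx=np.array(child, dtype=np.int64),
        parent_idx=np.array(parent, dtype=np.int64),
        g_axial_nS=np.array(g_ax),
        v_rest=v_rest,
    )
    _template_cache[key] = out
    return out


def advance_compartments(
    v: np.ndarray,
    m: np.ndarray,
    h: np.ndarray,
    n: np.ndarray,
    mem: CompiledMembrane,
    g_add_nS: np.ndarray,
    ge_add: np.ndarray,
    i_add_pA: np.ndarray,
    dt_ms: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One exponential-Euler step of the capacitive current balance.

    ``g_add_nS``/``ge_add`` carry extra (synaptic) conductance and its
    conductance-weighted reversal per compartment; ``i_add_pA`` injected
    current.  Axial coupling uses neighbor voltages from the step start.
    All operations are elementwise per compartment or scatter-adds confined
    within a neuron, which is what makes partitioned execution bit-identical
    to the serial run.
    """
    am, bm, ah, bh, an, bn = _rates(v)
    m = am / (am + bm) + (m - am / (am + bm)) * np.exp(-dt_ms * (am + bm))
    h = ah / (ah + bh) + (h - ah / (ah + bh)) * np.exp(-dt_ms * (ah + bh))
    n = an / (an + bn) + (n - an / (an + bn)) * np.exp(-dt_ms * (an + bn))

    g_na = mem.g_na_nS * m ** 3 * h
    g_k = mem.g_k_nS * n ** 4
    g_tot = mem.g_leak_nS + g_na + g_k + g_add_nS
    num = (
        mem.g_leak_nS * mem.e_leak_mV
        + g_na * mem.e_na
        + g_k * mem.e_k
        + ge_add
        + i_add_pA
    )
    ci, pi, gax = mem.child_idx, mem.parent_idx, mem.g_axial_nS
    if ci.size:
        g_tot[ci] += gax
        num[ci] += gax * v[pi]
        np.add.at(g_tot, pi, gax)
        np.add.at(num, pi, gax * v[ci])
    v_inf = num / g_tot
    v_new = v_inf + (v - v_inf) * np.exp(-dt_ms * g_tot / mem.cm_pF)
    return v_new, m, h, n


# ---------------------------------------------------------------------------
# single-neuron surface

@dataclass
class NeuronState:
    """State of one neuron: per-compartment voltages and gating, the
    per-kind synaptic kernel state pairs, and spike bookkeeping."""

    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    syn_exc: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (drive, g)
    syn_inh: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (rise, decay)
    v_soma_prev: float = 0.0
    last_spike_time: float | None = None


@dataclass(frozen=True)
class SpikeEvent:
    neuron_id: int
    time_ms: float


@dataclass(frozen=True)
class StimulusSpec:
    """Step current injection into a set of target somata."""

    target_ids: tuple[int, ...]
    amplitude_nA: float
    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ConfigurationError("stimulus onset must precede offset")


def make_initial_state(cell_class: CellClass,
                       params: ChannelParams = DEFAULT_CHANNELS) -> NeuronState:
    """Neuron at its resting equilibrium (uniform potential, zero current)."""
    mem = compile_class(cell_class, params)
    v = np.full(mem.n_compartments, mem.v_rest)
    m, h, n = steady_state_gating(v)
    return NeuronState(v=v, m=np.asarray(m), h=np.asarray(h),
                       n=np.asarray(n), v_soma_prev=mem.v_rest)


def step_neuron(
    state: NeuronState,
    cell_class: CellClass,
    synaptic_inputs: Sequence[tuple[float, float]] = (),
    injected_current_nA: float = 0.0,
    dt_ms: float = 0.05,
    params: ChannelParams = DEFAULT_CHANNELS,
) -> NeuronState:
    """Advance one neuron by ``dt``.

    ``synaptic_inputs`` is a sequence of ``(conductance_nS, reversal_mV)``
    pairs applied at the soma during this step.
    """
    if dt_ms <= 0:
        raise ConfigurationError("dt must be positive")
    mem = compile_class(cell_class, params)
    nc = mem.n_compartments
    g_add = np.zeros(nc)
    ge_add = np.zeros(nc)
    i_add = np.zeros(nc)
    for g, erev in synaptic_inputs:
        g_add[0] += g
        ge_add[0] += g * erev
    i_add[0] += injected_current_nA * 1000.0  # nA -> pA
    state.v_soma_prev = float(state.v[0])
    v, m, h, n = advance_compartments(
        state.v, state.m, state.h, state.n, mem, g_add, ge_add, i_add, dt_ms
    )
    if not np.all(np.isfinite(v)):
        raise IntegrationError("non-finite membrane potential in step_neuron")
    state.v, state.m, state.h, state.n = v, m, h, n
    return state


def detect_spike(
    state: NeuronState,
    threshold_mV: float = SPIKE_THRESHOLD_MV,
    refractory_ms: float = REFRACTORY_MS,
    t_ms: float = 0.0,
    neuron_id: int = 0,
) -> SpikeEvent | None:
    """Report an upward soma threshold crossing outside the refractory
    window, updating ``last_spike_time`` when one occurs."""
    v_now = float(state.v[0])
    crossed = state.v_soma_prev < threshold_mV <= v_now
    if not crossed:
        return None
    if (state.last_spike_time is not None
            and t_ms - state.last_spike_time < refractory_ms):
        return None
    state.last_spike_time = t_ms
    return SpikeEvent(neuron_id=neuron_id, time_ms=t_ms)


# ---------------------------------------------------------------------------
# population-level operations

def pseudo_eeg(voltage_history: np.ndarray,
               weights: np.ndarray | None = None) -> np.ndarray:
    """Aggregate population signal: weighted sum over pyramidal somatic
    membrane potentials, mean-subtracted.

    ``voltage_history`` has shape (steps, cells).  This weighted-voltage-sum
    form is a stand-in for an extracellular forward model; see the methods
    note for what it does and does not represent.
    """
    vh = np.asarray(voltage_history, dtype=float)
    if vh.ndim == 1:
        vh = vh[:, None]
    if weights is None:
        weights = np.ones(vh.shape[1])
    raw = vh @ np.asarray(weights, dtype=float)
    return raw - raw.mean()


def run_simulation(
    network: "Network",
    stimulus: StimulusSpec | None,
    duration_ms: float,
    dt_ms: float = 0.05,
    seed: int = 0,
    partitions: int = 1,
    scheme: str = "stripe_x",
    channel_params: ChannelParams = DEFAULT_CHANNELS,
    tuning: Mapping[str, Mapping[str, float]] | None = None,
):
    """Run the fixed-step network simulation.

    Returns a :class:`neopatch.parallel.SimResult` with the spike raster,
    the pseudo-EEG trace and per-rank instrumentation.  Output is identical
    for every value of ``partitions`` (the partition-invariance contract);
    see :mod:`neopatch.parallel` for the partitioned execution model.
    """
    from .parallel import partition_by_location
    from ._engine import simulate

    pmap = partition_by_location(network, partitions, scheme)
    return simulate(
        network, stimulus, duration_ms, dt_ms, seed, pmap,
        channel_params=channel_params, tuning=tuning,
    )
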