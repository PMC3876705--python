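"""Run configuration, deterministic fixtures and batch helpers.

Everything here exists so the other modules are exercised without any
external data: network fixtures are generated from a handful of numbers
(neuron count, target edge count, stimulus recipe, seed) and performance
fixtures are sampled from the named generative models that the fitting
routines invert.

A single 64-bit master seed is expanded into independent per-purpose
streams (placement, wiring, dynamics) through ``numpy.random.SeedSequence``
spawning, so each module can be tested in isolation while a full run stays
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cells, netgen, perfmodel
from .cells import CLASS_NAMES, build_cell_classes
from .dynamics import StimulusSpec, SynapseSpec
from .errors import ConfigurationError
from .netgen import ConnectionRule, Network

__all__ = [
    "RunConfig",
    "FixtureSpec",
    "default_rules",
    "make_network_fixture",
    "make_perf_fixture",
    "build_network",
    "build_stimulus",
    "load_config",
    "save_config",
]

# default kernel parameters per (pre sign, post sign): the dominant
# excitatory-excitatory connections reach 500 µm, everything else 300 µm
DEFAULT_CUTOFFS_UM = {
    ("excitatory", "excitatory"): 500.0,
    ("excitatory", "inhibitory"): 300.0,
    ("inhibitory", "excitatory"): 300.0,
    ("inhibitory", "inhibitory"): 300.0,
}

DEFAULT_EXC_SYNAPSE = SynapseSpec(
    kind="alpha_excitatory", tau_ms=2.0, gmax_nS=0.4, reversal_mV=0.0)
DEFAULT_INH_SYNAPSE = SynapseSpec(
    kind="dualexp_inhibitory", tau_rise_ms=1.0, tau_decay_ms=7.0,
    gmax_nS=1.2, reversal_mV=-75.0)


def default_rules(
    class_names: Sequence[str] = CLASS_NAMES,
    base_probability: float = 0.1,
    velocity_um_per_ms: float = 200.0,
    velocity_jitter: float = 0.2,
    long_range_probability: float = 0.0,
) -> list[ConnectionRule]:
    """One uniform-disc rule per ordered class pair with the default
    cutoffs; densities are meant to be rescaled by
    :func:`neopatch.netgen.calibrate_density` against a target edge count."""
    signs = {c.name: c.sign for c in build_cell_classes()}
    rules = []
    for a in class_names:
        for b in class_names:
            syn = (DEFAULT_EXC_SYNAPSE if signs[a] == "excitatory"
                   else DEFAULT_INH_SYNAPSE)
            rules.append(ConnectionRule(
                pre_class=a,
                post_class=b,
                kernel="uniform_disc",
                cutoff_um=DEFAULT_CUTOFFS_UM[(signs[a], signs[b])],
                base_probability=base_probability,
                synapse=syn,
                velocity_um_per_ms=velocity_um_per_ms,
                velocity_jitter=velocity_jitter,
                long_range_probability=long_range_probability,
            ))
    return rules


# ---------------------------------------------------------------------------
# run configuration

def _dict_of(obj) -> dict:
    return dataclasses.asdict(obj)


@dataclass
class StimulusConfig:
    """Startup current injection emulating a focal drive: the given fraction
    of the target class (or of both pyramidal classes) nearest the patch
    center receives a sustained step current."""

    target_class: str = "pyramidal"
    fraction: float = 0.05
    amplitude_nA: float = 0.6
    onset_ms: float = 10.0
    offset_ms: float = 500.0

    def __post_init__(self):
        if self.target_class not in CLASS_NAMES + ("pyramidal",):
            raise ConfigurationError(
                f"unknown stimulus class {self.target_class!r}")
        if not 0 < self.fraction <= 1:
            raise ConfigurationError("stimulus fraction must lie in (0, 1]")


@dataclass
class NetworkConfig:
    n_neurons: int = 1000
    classes: tuple[str, ...] = CLASS_NAMES
    jitter: float = 0.1
    target_edges: float | None = None
    base_probability: float = 0.1
    velocity_um_per_ms: float = 200.0
    velocity_jitter: float = 0.2
    long_range_probability: float = 0.0
    seed: int = 0


@dataclass
class DynamicsConfig:
    dt_ms: float = 0.05
    duration_ms: float = 100.0
    threshold_mV: float = -20.0
    refractory_ms: float = 2.0
    exc_gmax_nS: float = 0.4
    exc_tau_ms: float = 2.0
    inh_gmax_nS: float = 1.2
    inh_tau_rise_ms: float = 1.0
    inh_tau_decay_ms: float = 7.0
    tuning: dict = field(default_factory=dict)
    stimulus: StimulusConfig | None = field(default_factory=StimulusConfig)


@dataclass
class ParallelConfig:
    partitions: int = 1
    scheme: str = "stripe_x"


@dataclass
class OutputConfig:
    directory: str = "out"


@dataclass
class RunConfig:
    """Schema-validated run description; every default is explicit in the
    resolved form written next to each run's outputs."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    parallel: ParallelConfig = field(default_factory=ParallelConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def resolved(self) -> dict:
        d = {
            "network": _dict_of(self.network),
            "dynamics": _dict_of(self.dynamics),
            "parallel": _dict_of(self.parallel),
            "output": _dict_of(self.output),
        }
        d["network"]["classes"] = list(self.network.classes)
        return d

    def synapse_specs(self) -> dict[str, SynapseSpec]:
        dy = self.dynamics
        return {
            "alpha_excitatory": SynapseSpec(
                kind="alpha_excitatory", tau_ms=dy.exc_tau_ms,
                gmax_nS=dy.exc_gmax_nS, reversal_mV=0.0),
            "dualexp_inhibitory": SynapseSpec(
                kind="dualexp_inhibitory", tau_rise_ms=dy.inh_tau_rise_ms,
                tau_decay_ms=dy.inh_tau_decay_ms, gmax_nS=dy.inh_gmax_nS,
                reversal_mV=-75.0),
        }


def _build_section(cls, data: Mapping[str, Any], path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config section '{path}'")
    return cls(**data)


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    if not isinstance(data, Mapping):
        raise ConfigurationError("config root must be a mapping")
    allowed = {"network", "dynamics", "parallel", "output"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    net = _build_section(NetworkConfig, data.get("network", {}), "network")
    dyn_data = dict(data.get("dynamics", {}))
    stim = dyn_data.pop("stimulus", "default")
    if stim == "default":
        stim_cfg = StimulusConfig()
    elif stim is None:
        stim_cfg = None
    else:
        stim_cfg = _build_section(StimulusConfig, stim, "dynamics.stimulus")
    dyn = _build_section(DynamicsConfig,
                         {**dyn_data, "stimulus": stim_cfg}, "dynamics")
    par = _build_section(ParallelConfig, data.get("parallel", {}), "parallel")
    out = _build_section(OutputConfig, data.get("output", {}), "output")
    if isinstance(net.classes, list):
        net.classes = tuple(net.classes)
    return RunConfig(network=net, dynamics=dyn, parallel=par, output=out)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    YAML syntax errors propagate with their line-numbered marks; schema
    errors raise :class:`ConfigurationError`.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# network construction from a config

def _spawn_seeds(master: int, count: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master).spawn(count)


def build_network(cfg: RunConfig) -> Network:
    """Place neurons and wire them according to the configuration."""
    net = cfg.network
    place_ss, wire_ss = _spawn_seeds(net.seed, 2)
    place_seed = int(place_ss.generate_state(1)[0] % 2 ** 31)
    wire_seed = int(wire_ss.generate_state(1)[0] % 2 ** 31)
    classes = [c for c in build_cell_classes() if c.name in net.classes]
    neurons = cells.place_neurons_for_count(
        net.n_neurons, classes, jitter=net.jitter, seed=place_seed)
    rules = default_rules(
        tuple(net.classes),
        base_probability=net.base_probability,
        velocity_um_per_ms=net.velocity_um_per_ms,
        velocity_jitter=net.velocity_jitter,
        long_range_probability=net.long_range_probability,
    )
    if net.target_edges:
        rules = netgen.calibrate_density(rules, neurons, net.target_edges)
    return netgen.generate_network(neurons, rules, seed=wire_seed,
                                   dt_ms=cfg.dynamics.dt_ms)


def build_stimulus(cfg: RunConfig, network: Network) -> StimulusSpec | None:
    """Resolve the stimulus recipe to concrete target ids: the requested
    fraction of the target class closest to the patch center."""
    sc = cfg.dynamics.stimulus
    if sc is None:
        return None
    neurons = network.neurons
    targets = (list(cells.PYRAMIDAL_CLASSES)
               if sc.target_class == "pyramidal" else [sc.target_class])
    cx = neurons["x_um"].mean()
    cy = neurons["y_um"].mean()
    chosen: list[int] = []
    for cls in targets:
        sub = neurons[neurons["cell_class"] == cls]
        if sub.empty:
            continue
        d2 = (sub["x_um"] - cx) ** 2 + (sub["y_um"] - cy) ** 2
        k = max(1, int(round(sc.fraction * len(sub))))
        chosen.extend(int(i) for i in sub.loc[d2.nsmallest(k).index, "id"])
    if not chosen:
        raise ConfigurationError(
            f"stimulus class {sc.target_class} absent from network")
    return StimulusSpec(
        target_ids=tuple(sorted(chosen)),
        amplitude_nA=sc.amplitude_nA,
        onset_ms=sc.onset_ms,
        offset_ms=sc.offset_ms,
    )


# ---------------------------------------------------------------------------
# fixtures

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic desk-scale network fixture."""

    name: str
    n_neurons: int
    target_edges: float
    seed: int = 0
    duration_ms: float = 100.0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)

    def __post_init__(self):
        if self.n_neurons > 5000:
            raise ConfigurationError(
                "fixtures are capped at 5000 neurons; build larger networks "
                "through build_network directly")
        if self.target_edges <= 0:
            raise ConfigurationError("target_edges must be positive")


def make_network_fixture(spec: FixtureSpec) -> tuple[Network, RunConfig]:
    """Deterministic all-class network calibrated to the target edge count,
    plus the RunConfig that reproduces it."""
    cfg = RunConfig(
        network=NetworkConfig(
            n_neurons=spec.n_neurons,
            target_edges=spec.target_edges,
            seed=spec.seed,
        ),
        dynamics=DynamicsConfig(
            duration_ms=spec.duration_ms,
            stimulus=spec.stimulus,
        ),
        output=OutputConfig(directory=f"out-{spec.name}"),
    )
    return build_network(cfg), cfg


def make_perf_fixture(kind: str, params: Mapping[str, Any],
                      noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic samples from the generative models the fitters invert.

    ``power_law``: params alpha, beta, sizes -> (n_neurons, memory_gb);
    ``amdahl``: params serial_fraction, t1_seconds, threads ->
    (threads, total_cpu_seconds); ``weak_scaling``: params n_ref, pool_ref,
    sizes -> (n_neurons, pool).  ``noise`` is the sigma of multiplicative
    lognormal noise on the dependent variable.
    """
    rng = np.random.default_rng(seed)
    if kind == "power_law":
        sizes = np.asarray(params["sizes"], dtype=float)
        mem = params["alpha"] * sizes ** params["beta"]
        if noise > 0:
            mem = mem * np.exp(rng.normal(0.0, noise, sizes.size))
        return pd.DataFrame({"n_neurons": sizes, "memory_gb": mem})
    if kind == "amdahl":
        th = np.asarray(params["threads"], dtype=float)
        s = params["serial_fraction"]
        total = params["t1_seconds"] * (s * th + (1.0 - s))
        if noise > 0:
            total = total * np.exp(rng.normal(0.0, noise, th.size))
        return pd.DataFrame({"threads": th, "total_cpu_seconds": total})
    if kind == "weak_scaling":
        sizes = np.asarray(params["sizes"], dtype=float)
        pools = [perfmodel.weak_scaling_pool(
            params["n_ref"], params["pool_ref"], n) for n in sizes]
        return pd.DataFrame({"n_neurons": sizes, "pool": pools})
    raise ConfigurationError(f"unknown perf fixture kind {kind!r}")
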