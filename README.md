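# neopatch

Desk-scale simulator of epileptiform activity in a patch of neocortex,
together with the performance-scaling mathematics used to plan such
simulations on parallel machines.

Understanding how seizures emerge requires networks that are both large
(population signals such as the EEG aggregate millions of cells) and
detailed (multicompartment neurons, several interneuron classes, realistic
wiring).  Production runs of such models are distributed over many MPI
processes; before committing supercomputer time one wants to know (a) that
the partitioned program computes exactly the same network trajectory as a
serial run, and (b) how memory and run time scale with network size,
process count and thread count.  `neopatch` packages both concerns at a
size that runs on a laptop:

* **a full simulation pipeline** — six cortical cell classes (superficial
  and deep pyramidal cells, three basket-cell types, chandelier cells) as
  cylinder-compartment neurons on per-class lattices (5 µm pyramidal,
  15 µm interneuron pitch), distance-kernel wiring with class-pair cutoffs
  (100–900 µm; 500 µm for the dominant excitatory–excitatory type),
  alpha-function excitatory and dual-exponential inhibitory synapses,
  fixed-step conductance-based dynamics, spatial partitioning with
  phase-structured spike exchange, and a pseudo-EEG readout;
* **the scaling models** — log–log power-law memory fits
  *Memory = α·N^β*, weak-scaling process-pool estimation at constant cells
  per process, and Amdahl serial-fraction fits to thread-scaling data.

## The core contracts

**Partition invariance.**  Neurons are assigned to `P` logical ranks by
spatial location.  Each step is *advance → barrier → exchange → barrier*;
spikes cross rank boundaries only when a target lives on another rank.
Because the membrane update is elementwise per compartment and synaptic
events are always accumulated in global presynaptic order, the spike
raster and pseudo-EEG are **bit-identical for every P** — the package's
central correctness property, asserted up to P = 16 on a 2,600-neuron,
0.5 M-connection, 500 ms reference fixture.

**Analytic wiring oracle.**  The expected edge count
`Σ_pairs p(rule, distance)` is computed exactly and used both to calibrate
densities to a target connection count and to test the sampler (binomial
4σ bounds).  At fixed density and cutoff the generated connection count
crosses over from ~N² (patch smaller than the connection disc) toward ~N,
the regime where simulator memory becomes linear in N.

**Scaling laws.**  `Total(n) = T1·(s·n + (1 − s))` is fitted to
total-CPU-versus-threads data; with serial fraction `s = 1/3` the wall
clock speedup `1/(s + (1 − s)/n)` is 2.25 at 6 threads and ~2.77 at 24.
The weak-scaling pool `n = N_target · n_ref / N_ref` reproduces, from the
4-process baselines, the per-size pools 49 / 45 / 16 and the
two-significant-figure extrapolations 450 / 4.5 K and 1.5 K / 15 K
processes for 10⁶ / 10⁷-cell networks.

## Worked example

```bash
cat > run.yaml <<'YAML'
network:
  n_neurons: 1024
  target_edges: 60000
  seed: 42
dynamics:
  duration_ms: 200.0
  dt_ms: 0.05
parallel:
  partitions: 4
output:
  directory: out
YAML
neopatch simulate --config run.yaml
```

prints `359 spikes -> out` and writes `spikes.tsv`, `eeg.csv`,
`perf.jsonl`, `partition.tsv` and a `resolved_config.yaml` that reproduces
the run bit-for-bit.  The raster contains all six cell classes
(`{'SPYR': 294, 'BASK1': 24, 'DPYR': 21, 'BASK2': 9, 'CHAN': 8,
'BASK3': 3}`) and the pseudo-EEG oscillates at ~70 Hz — a focal sustained
current injection drives the patch into a seizure-like rhythm.  Re-running
with `--partitions 1` (or 16) yields byte-identical `spikes.tsv` and
`eeg.csv`.

The scaling side, on synthetic thread-scaling data with 5 % noise around a
serial fraction of 1/3:

```bash
neopatch fixture perf --kind amdahl \
  --params '{"serial_fraction": 0.3333, "t1_seconds": 300, "threads": [1,2,4,8,12,24]}' \
  --noise 0.05 --seed 3 --out amdahl.csv
neopatch perffit amdahl --input amdahl.csv --speedup-at 6 --speedup-at 24
```

```json
{
  "serial_fraction": 0.3338976638024689,
  "t1_seconds": 295.344129284788,
  "speedup": {"6": 2.247621747309191, "24": 2.7650896431096403}
}
```

and the weak-scaling extrapolation to a million cells from an 8,800-cell,
4-process baseline:

```bash
neopatch perffit weak-scaling --nref 8800 --pref 4 --ntarget 1000000 \
  --rounding two_significant
# -> 450
```

Everything is also available as a library (`neopatch.cells`,
`neopatch.netgen`, `neopatch.dynamics`, `neopatch.parallel`,
`neopatch.perfmodel`, `neopatch.workbench`); see `docs/methods.md` for the
model description and the numerical choices.

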