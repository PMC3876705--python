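# Methods

This note documents the model implemented by `neopatch`, the parameters
that matter, the numerical choices, and what the desk-scale tests do and do
not establish.

## Cell classes and geometry

Six classes populate the patch: superficial pyramidal (SPYR, 5
compartments), deep pyramidal (DPYR, 7), three basket types (BASK1–3) and
chandelier cells (CHAN), each with 2 compartments.  Every compartment is a
cylinder with a fixed (diameter, length) in µm held in
`cells.COMPARTMENT_TABLE`; e.g. the pyramidal soma is 16.1 × 22 µm and the
chandelier cell is a 4.0 × 5.5 µm soma with a single 2.0 × 150 µm
dendrite.  Compartments form a tree: the apical chain D1→D2(→D3→D4) hangs
off the soma, and the basal dendrite (BD) and axon initial segment (IS)
attach directly to it.

Placement is lattice-based.  Each class owns a full square lattice over the
same two-dimensional patch — 5 µm pitch for the two pyramidal classes,
15 µm for the four interneuron classes — so pyramidal sites outnumber each
interneuron class 9:1.  Depth is collapsed: the two pyramidal classes
occupy separate lattices on the same plane rather than separate laminae,
which reproduces the stated pitches without inventing an unquantified 3-D
geometry.  A per-axis uniform jitter of ±(j·pitch), default j = 0.1,
perturbs sites; below j = 0.5 each neuron remains attributable to its
lattice site.  When a network is requested by neuron count N, the smallest
square patch whose lattices hold ≥ N sites is used and the surplus is
trimmed per class by largest-remainder apportionment, so all classes stay
represented at their lattice proportions; ids are dense, 0-based, row-major
per class in canonical class order (determinism matters for partition
tests).  The relative abundance of the three basket types is not otherwise
constrained; equal lattices are assumed.

## Wiring

Connections are directed and sampled independently per ordered neuron pair
from a per-class-pair rule.  Within the rule's cutoff the probability is
`base_probability × kernel(d)` with the kernel normalized to 1 at d = 0;
between the cutoff and 1 mm it is zero; beyond 1 mm an optional flat
long-range probability applies (off by default — the desk-scale patches are
far smaller than 1 mm).  Two kernels are provided: `uniform_disc` (default)
and a truncated Gaussian with σ = cutoff/2 unless overridden.  The paper
trail behind the in-range profile is literature data not reproduced here,
so the kernel shape is deliberately the simplest distance-dependent,
cutoff-subject family.  Cutoffs default to 500 µm for
excitatory→excitatory rules and 300 µm otherwise, inside the model's
100–900 µm range; self-connections are excluded and at most one edge
exists per ordered pair per rule.

Absolute densities are anchored by calibration rather than by literature
tables: `calibrate_density` scales all base probabilities by one common
factor so the analytic expectation `Σ_pairs p(d)` hits a target edge count
(0.1 % tolerance), clipping at probability 1 with a warning.  The
reference fixture (2,600 neurons, 0.5 M connections) then has a mean
out-degree of ≈ 192.

Delays are `distance / velocity × (1 + u)` with `u` uniform in
±velocity_jitter (defaults 200 µm/ms and 0.2 — partially randomized
conduction velocities compensate the lattice regularity), floored at one
integration step.

The connection-memory model `predict_memory_bytes` charges k bytes per
expected edge (default 24; only ratios matter) plus c₃ bytes per neuron of
state, with the expected in-range partner count interpolating smoothly
between N − 1 (small patch, quadratic total) and a saturation count
(population of one connection disc, linear total).  Its effective log–log
exponent falls monotonically from 2 toward 1, the crossover that makes
large-network memory linear in N.

## Dynamics

Membrane kinetics are a documented standard conductance-based stand-in:
transient Na⁺ and delayed-rectifier K⁺ currents with the conventional
voltage-dependent rate functions (rest ≈ −65 mV), plus leak, on the soma
and axon initial segment; other compartments are passive cable.  The
original simulators' exact channel repertoires live in prior model papers
and are not reproduced; every contract tested here (partition invariance,
event conservation, calibration, scaling) is independent of the specific
kinetics.  Constants: Cₘ = 1 µF/cm², axial resistivity 100 Ω·cm,
ḡ_Na = 120, ḡ_K = 36, g_L = 0.3 mS/cm².  Passive compartments have their
leak reversal pinned to the active resting potential so a cell at rest is
isopotential and carries no axial current — the rest state is then a true
fixed point of the integrator.

Integration is exponential Euler on voltages and gating with fixed
dt = 0.05 ms by default; axial and synaptic terms enter the per-compartment
balance with step-start neighbor voltages.  Spikes are detected as upward
soma crossings of −20 mV outside a 2 ms refractory window (bookkeeping
only; the membrane is never reset).  The integrator is first order:
halving dt roughly halves evoked-spike timing errors and inter-spike
-interval errors (Richardson ratio ≈ 2 in the tests), but near rheobase the
error constant exceeds one step, so individual tonic spike times should not
be read at single-step precision.

Synapses: excitatory inputs follow the alpha kernel
g(t) = gmax·(t/τ)·e^(1−t/τ) (τ = 2 ms, range 1–3 ms) and inhibitory inputs
the peak-normalized dual exponential with τ_rise = 1 ms, τ_decay = 7 ms
(range 1–7 ms); reversals 0 and −75 mV.  Both kernels are integrated as
linear per-neuron state recurrences with *exact* per-step decay factors,
so the ODE form equals the closed forms at step times to machine precision
and costs O(1) per synapse per step.  A consequence of aggregating kernel
state per neuron is that time constants are global per kind; per-edge
variation enters through the delivered amplitude
gmax × edge weight × tuning.  Tuning multipliers scale that amplitude per
(presynaptic sign → postsynaptic class), constant over a run.  Delays are
rounded to the nearest step and simultaneous deliveries superpose linearly.

Default synaptic peaks (gmax 0.4 nS excitatory, 1.2 nS inhibitory) and the
default stimulus — 5 % of each pyramidal class nearest the patch center,
0.6 nA sustained from 10 ms — were chosen once so the reference patch
enters a sustained oscillatory, seizure-like regime (~60 Hz pseudo-EEG,
all six classes firing).  A single-cell sweep showed the stand-in fires
tonically for 0.5–0.8 nA and enters depolarization block above ~1 nA,
which fixed the amplitude.  With the stimulus off the network is exactly
quiescent (no background noise is modeled).

The pseudo-EEG is the mean-subtracted, weighted sum of pyramidal somatic
potentials (uniform weights by default).  This is a stand-in for an
extracellular forward model — no electrode geometry, distance weighting or
current-source calculation is attempted — and is intended as a population
synchrony readout, not a quantitative EEG prediction.

## Partitioned execution

`partition_by_location` assigns neurons to P ranks by spatial stripes
along x (default) or 2-D blocks, balanced to within one neuron and
deterministic.  A step is phase-structured: every rank advances its
neurons; ranks rendezvous at a barrier; the step's spikes are routed to the
ranks owning their targets (spikes whose targets are all local never cross
the wire); a second barrier closes the step.  Parallelism is logical —
rank loops execute sequentially in rank order inside one process — which is
what makes the defining contract directly testable: spike rasters and
pseudo-EEG are **bit-identical for every P**.  The arithmetic guarantees
are (i) elementwise membrane updates with scatter-adds confined within a
neuron, (ii) synaptic accumulation always in global presynaptic-id order
through order-preserving masks of the globally sorted edge list, and
(iii) an EEG reduction over a globally ordered vector rather than per-rank
partial sums.

Instrumentation records, per rank and step, measured phase seconds
(indicative only — the ranks are sequential), message counts (Σ sent =
Σ received every step), delivery counts and modeled resident bytes
(neuron state charged to the owner, connection data to the target's rank,
plus a fixed per-rank overhead, so the total is constant up to P×overhead).
Load-balance and barrier-trend analyses use `modeled_timing`, a
deterministic cost model (advance ∝ local compartment updates + local
deliveries; exchange ∝ cross-rank messages; barrier wait = slowest rank
minus own time per phase), under which the pooled barrier fraction grows
with P on a fixture with focal activity — the qualitative signature of
synchronization cost — without depending on wall-clock noise.

## Scaling models

*Power law.*  `fit_power_law` is OLS on (log₁₀ N, log₁₀ memory):
α = 10^intercept, β = slope, adjusted r² with n − 2 degrees of freedom.
Noiseless data are inverted exactly; under 5 % multiplicative lognormal
noise at the four benchmark network sizes (8.8 K–390 K) the mean recovered
β over 100 draws is within ±0.05.

*Weak scaling.*  `weak_scaling_pool` returns N_target·pool_ref/N_ref,
rounded to the nearest integer for per-size tables or to two significant
figures (half away from zero) for headline extrapolations; it is invariant
under common rescaling of the two network sizes.

*Amdahl.*  `fit_amdahl` fits Total(n) = T1·(s·n + (1 − s)) by unweighted
least squares on *total CPU time* (which is linear in n; wall time is not),
mapping slope/intercept to (s, T1) and clipping s to [0, 1] with a flag.
`speedup(n) = 1/(s + (1 − s)/n)` is nondecreasing and bounded by 1/s.
`tradeoff_curve` combines near-ideal distributed scaling (1/P, optionally
degraded per doubling) with the thread-level Amdahl factor; moving one
core-doubling from ranks to threads at s = 1/3 costs the canonical ×4/3 in
wall time at the T = 1→2 step.

## Fixture sizes and what the tests show

Tests run at deliberately small sizes chosen as representative work
points: the partition-invariance sweep uses 2,600 neurons / 0.5 M
connections / 500 ms (the smallest benchmark scale), connectivity
statistics use 256–20,000 neurons, and Monte-Carlo fits use 100 draws.
The synthetic generators emulate the *form* of real measurements
(power-law memory growth, linear total-CPU growth, Bernoulli wiring); they
do not emulate hardware effects — interconnect latency, cache contention,
RSS fragmentation, I/O — so passing tests certify the mathematics and the
software contracts, not the absolute performance of any machine.  Measured
phase timings are likewise indicative; only modeled quantities are
asserted.

## Known limitations

* Channel kinetics are a stand-in; quantitative single-cell behavior
  (rheobase, f–I curve) is not matched to the original models.
* No gap junctions, no synaptic plasticity, no columnar structure, no 3-D
  laminar geometry — consistent with the modeled system's own scope.
* Synaptic input attaches at the soma; dendritic synapse placement and
  per-edge time constants are not supported.
* The long-range (> 1 mm) pathway uses a flat probability and brute-force
  pair enumeration; it is intended for small demonstration patches, not
  for 100 K+-neuron networks.
* The pseudo-EEG is a weighted voltage sum, not a forward-modeled field
  potential.
* First-order integration: spike times converge as O(dt) with an error
  constant of a few steps near threshold.
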