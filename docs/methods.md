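# Methods

## Scope and design stance

`snncomm` studies the *communication* side of distributed time-step SNN
simulation.  Everything hardware-bound (wall-clock phase timings, MPI
collective behavior, interconnect contention) is deliberately out of scope:
the engine runs on a single machine over P **virtual processes**, keeping
strict per-process accounting at an explicit exchange boundary each step,
so every communication metric is an exact, reproducible count rather than
a noisy measurement.  Dynamics are computed once, globally; the contract —
enforced by tests and by the experiment harness at run time — is that the
spike raster is bit-identical across allocation strategies, exchange
patterns and process counts.

## Network model and generators

Neurons are leaky integrate-and-fire with exponential current synapses:

    dv/dt = (−(v − v_rest) + R·(I_ext + I_syn)) / τ_m
    I_syn ← I_syn·exp(−dt/τ_syn) + Σ arriving weights

integrated by forward Euler at dt = 0.1 ms (the integrator's first-order
convergence is verified against the closed-form relaxation).  A spike
resets v to v_reset and opens a refractory window t_ref during which the
neuron neither integrates nor fires.  Synaptic delays are independent per
synapse, uniform on {1, …, 15} grid steps by default; a minimum of one step
is enforced, which is what forces an exchange at every step (no message
packing across steps is modeled, matching the worst-case regime).

Two generator presets define the study conditions:

* **Layered preset** (`cm_like_spec`): eight populations — L2/3e,i; L4e,i;
  L5e,i; L6e,i — with sizes in the usual layered-cortex proportions and a
  probability table in which within-layer connections (0.10 base) dominate
  adjacent-layer (0.025) and distant-layer (0.008) ones; inhibitory axons
  stay within their layer.  The whole table is rescaled so the expected
  mean in-degree hits a requested value (50 for the headline experiments).
  The table is deliberately labeled *CM-like*: it preserves the clustered
  topology of microcircuit models without reprinting any published
  parameterization; a user table can be loaded from YAML.  Constant drive
  0.95 mA; inhibitory weight multiplier −4.
* **Modular preset** (`multiarea_like_spec`): 32 areas, each a small dense
  layered circuit (intra-area mean in-degree 100 — local probabilities of
  order 0.1 are realistic for ~1k-neuron circuits), with a *fixed*
  probability 10⁻⁴ from excitatory cells to any cell of another area
  (≈ 3 long-range targets per neuron).  Constant drive 0.38 mA; inhibitory
  multiplier −15, which strengthens recurrent inhibition enough to hold
  the population near the 20–25 spikes/s operating range.

A deliberate oddity is kept as printed in the source material these presets
emulate: the resting potential (−45 mV) sits *above* the spiking threshold
(−50 mV).  With the leak pulling v toward rest, every neuron is tonically
suprathreshold and fires periodically at rates set by t_ref, τ_m and the
reset depth (tens of Hz here) rather than by a balanced-network mechanism.
The inversion is flagged, configurable, and harmless for the questions the
package asks — all headline metrics are *ratios* between allocation
strategies under identical dynamics — but it means the presets do not
reproduce biological firing statistics, which is an explicit non-goal.

Initial membrane potentials default to a uniform draw on [v_reset,
v_thresh), seeded and taken in ascending global id so the draw cannot
depend on the allocation.  Starting every neuron exactly at rest (available
as `init="rest"`) makes all neurons of a population fire on identical
steps — a degenerate, fully synchronous traffic pattern that stresses
nothing — so the jittered start is the default.

Generation uses three named RNG streams (structure, weights, delays)
derived from one seed, so changing a weight distribution cannot rewire the
topology.  Connectivity is Gilbert sampling per (pre-population,
post-population) block: the synapse count is Binomial(pairs, p) and the
pairs are a uniform random subset, with the diagonal excluded (no
autapses).  Neuron ids are contiguous, area-major.

## Hypergraph model and partitioner

One hyperedge per presynaptic neuron with out-degree ≥ 1, containing the
neuron and the *distinct set* of its targets (synapse multiplicity does not
multiply messages).  Vertex weight = in-degree + 1; zero-out-degree neurons
produce no hyperedge but keep their workload weight.  The cut metric is
connectivity-1: Σ_e (parts touched by e − 1).  Imbalance is max part load
over mean part load, with empty parts allowed by the metric (they lower
the average) but forbidden in every assignment the partitioner emits.

The multilevel pipeline:

* **Coarsening** — agglomerative inner-product matching: visiting vertices
  in a seeded random order, an unmatched vertex pairs with the unmatched
  neighbor maximizing Σ over shared hyperedges of 1/(|e|−1) (ties: smaller
  combined weight, then lower id).  Contraction collapses duplicate pins
  and drops singleton edges; total vertex weight is conserved and any
  coarse assignment, projected down, has exactly the fine-level cut (a
  tested invariant).  Levels stop at 2·P vertices or when a level shrinks
  the count by < 5%.
* **Initial partition** — longest-processing-time greedy on coarse weights
  (heaviest vertex to the lightest part), then one FM sweep.  LPT
  guarantees a load gap of at most one vertex weight, which at the coarsest
  level is absorbed by the granularity-aware working tolerance below.
* **Refinement** — at *every* uncoarsening level (V-cycle): each FM pass
  visits the current boundary in a seeded random order, tentatively moves
  each vertex to its gain-maximal admissible part (admissible: target load
  within the working tolerance and source part left non-empty; single
  vertex moves only), locks it, and rolls back to the best prefix of moves
  at pass end.  Passes stop at 10 (configurable) or on zero net gain.
  Before refining, an explicit rebalance loop shifts the
  connectivity-cheapest vertices off overloaded parts.

**Balance tolerance.**  The default 1.001 presumes ≳10³ vertices of slack
per part; when one vertex weight exceeds the slack (common at desk scale)
the constraint is unattainable at that granularity.  The partitioner then
relaxes stepwise through a declared ladder — 1.01, 1.05, 1.10, and as a
last resort the instance's own granularity bound 1 + 1.05·max w / mean
load — and reports both the working tolerance and the achieved imbalance
in `Assignment.meta`.  Each level's working tolerance is the final
tolerance or the level's granularity bound, whichever is looser, so coarse
levels are never forced into infeasible balance.  An instance that cannot
meet even the last ladder step raises an explicit infeasibility error.

Hot loops (matching, FM passes, rebalance scoring) are numba kernels over
flat CSR arrays; all randomness is decided outside the kernels, so a fixed
(hypergraph, config) yields a bit-identical assignment.

## Communication accounting

Per exchange step, the traffic is the set of (firing neuron, target
process) pairs from the precomputed target lookup (distinct processes
hosting ≥ 1 target of the neuron, minus its own).  Under **PEX** every
process sends one metadata unit to each other process (P·(P−1) units per
step, activity-independent) and then one payload message per flagged pair;
under **NBX** only the payload messages are sent, plus P zero-byte barrier
tokens counted as messages.  Bytes: 4 per neuron id and 4 per metadata
unit (32-bit address-event ids); these units are conventions, stated here
because the source experiments report volumes without units.

Aggregates: **ARN** is the mean over (process, exchange step) of the
number of distinct payload-target processes, silent steps included.  Two
remote-spike statistics are kept because they answer different questions:
`remote_spikes` counts firing events with at least one remote target (how
many spikes need any propagation), while `spike_messages` counts
(spike × target process) pairs (how many propagation messages are paid).
At realistic out-degrees and part sizes, *every* spike has some remote
target under any balanced allocation, so the first statistic saturates and
allocation strategies can only be distinguished by the second; the
acceptance script's message-reduction metric therefore uses
`spike_messages`.  Per-pair message frequencies F_{a,b} (messages per
simulated second) and a theoretical PEX volume table (handshake vs payload
as a function of P and spiking rate, with the crossover point) are also
provided.  No timing is modeled anywhere — all comparisons are in counts.

## Problem sizes and what the tests show

The test suite exercises the full pipeline at sizes chosen to keep the
default run desk-friendly: oracle checks on ≤ 14-vertex hypergraphs against
brute-force and exhaustive enumeration; balance checks on a 12k-neuron
layered network (whose granularity makes the strict 1.001 feasible);
raster-invariance on a 5k-neuron preset across 3 strategies × 2 patterns ×
P ∈ {1, 8, 96}; and directional reduction checks on 8k-neuron presets.
The acceptance script runs the headline configurations in full: 40k
neurons / P = 8 for the balance target, 20k / P = 96 (100 ms, five seeds)
for the layered-network reductions, and 32 areas × 1k / P = 192 (50 ms,
five seeds) for the modular-network reductions.

Passing tests demonstrate correctness of the accounting and the expected
*structural* effects (clustered topology → less communication; sparse
patterns → no quadratic metadata).  They do not demonstrate wall-clock
speedups, biological activity statistics, or behavior under real network
contention — the generator emulates topology and load, not physiology or
hardware.

## Known limitations

* Virtual processes only; a message-passing backend would share the
  interfaces but is not implemented.
* Forward Euler at fixed dt; exact exponential integration is not offered.
* The partitioner is direct k-way with pairwise matching and single-vertex
  FM moves; no recursive bisection comparison, pair swaps, multi-constraint
  balancing, or topology-aware (non-uniform process distance) weighting.
* Hyperedges are unweighted beyond connectivity-1 (no traffic-frequency
  weighting); an extension point, not a feature.
* No plasticity; network structure is static during a run.
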