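"""Time-step LIF simulation over virtual processes.

The engine advances leaky integrate-and-fire neurons with exponential
current synapses on a fixed grid (forward Euler, default dt = 0.1 ms).  The
network is partitioned over P *virtual* processes: dynamics are computed
once, globally and deterministically (neurons updated in ascending global
id), while every exchange step the spikes crossing process boundaries are
pushed through the selected communication pattern (PEX or NBX) for exact
message/byte accounting.  Because delivery is equivalent under both
patterns, the spike raster is bit-identical across allocation strategies and
patterns — only the communication statistics differ.  Synapse objects live
on the postsynaptic side (address-event convention): messages carry
presynaptic ids only and the receiver resolves weights and delays locally,
which is why the target lookup maps each neuron to target *processes*, not
synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import comm
from .hypergraph import Assignment
from .models import Network

__all__ = [
    "SimulationConfig",
    "NeuronState",
    "SpikeEvent",
    "TargetLookup",
    "SimulationResult",
    "lif_step",
    "run_simulation",
    "build_target_lookup",
    "mean_firing_rate",
    "NumericalError",
]


class NumericalError(FloatingPointError):
    """Non-finite neuron state, reported with neuron id and step."""


@dataclass(frozen=True)
class SimulationConfig:
    """dt and duration in ms; ``comm_pattern`` is ``"pex"`` or ``"nbx"``.

    ``exchange_every`` is the number of steps between exchanges (default 1,
    the worst case forced by random per-synapse delays).  ``init`` selects
    the initial membrane potential: ``"uniform"`` (default) draws v0 from
    [v_reset, v_thresh) per neuron using ``seed``, in ascending global id so
    the draw cannot depend on the allocation; ``"rest"`` starts every neuron
    at its resting potential (mass synchrony — useful only for debugging).
    """

    dt: float = 0.1
    duration: float = 100.0
    comm_pattern: str = "pex"
    exchange_every: int = 1
    seed: int = 0
    init: str = "uniform"
    record_raster: bool = True
    keep_records: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.exchange_every < 1:
            raise ValueError("exchange_every must be >= 1")
        if self.comm_pattern not in ("pex", "nbx"):
            raise ValueError("comm_pattern must be 'pex' or 'nbx'")
        if self.init not in ("uniform", "rest"):
            raise ValueError("init must be 'uniform' or 'rest'")


@dataclass
class NeuronState:
    """Per-neuron dynamical state (arrays broadcast over neurons)."""

    v: np.ndarray
    i_syn: np.ndarray
    refractory_steps_left: np.ndarray


@dataclass(frozen=True)
class SpikeEvent:
    neuron_id: int
    step: int


@dataclass
class TargetLookup:
    """CSR map neuron → sorted distinct remote target processes."""

    ptr: np.ndarray    # int64, (n_neurons + 1,)
    procs: np.ndarray  # int32

    def targets(self, neuron: int) -> np.ndarray:
        return self.procs[self.ptr[neuron]:self.ptr[neuron + 1]]

    def set_sizes(self) -> np.ndarray:
        return np.diff(self.ptr)


@dataclass
class SimulationResult:
    """Raster, per-process counters and communication statistics."""

    raster_steps: np.ndarray   # int64, sorted by (step, neuron)
    raster_neurons: np.ndarray  # int64
    n_steps: int
    dt: float
    n_neurons: int
    neuron_updates: np.ndarray    # per-process neuron update counts
    synaptic_events: np.ndarray   # per-process delivered synaptic events
    comm_stats: comm.CommStats
    comm_records: list = field(default_factory=list)

    @property
    def n_spikes(self) -> int:
        return int(len(self.raster_steps))

    def raster_times_ms(self) -> np.ndarray:
        return self.raster_steps * self.dt

    def spikes(self) -> list[SpikeEvent]:
        return [SpikeEvent(int(n), int(s))
                for s, n in zip(self.raster_steps, self.raster_neurons)]

    def write_raster(self, path) -> None:
        """gdf-style two-column text: time_ms neuron_id."""
        with open(path, "w") as fh:
            for s, n in zip(self.raster_steps, self.raster_neurons):
                fh.write(f"{s * self.dt:.4f}\t{n}\n")


# ---------------------------------------------------------------------------


def lif_step(state: NeuronState, params, syn_arrivals, dt: float,
             tau_syn: float = 2.0):
    """One forward-Euler step; returns (state, fired mask).

    ``params`` is any object (scalars or per-neuron arrays) exposing v_rest,
    v_thresh, v_reset, tau_m, r_m, t_ref, i_ext.  The synaptic current first
    decays by exp(-dt/tau_syn), then accumulates the weights arriving this
    step (``syn_arrivals``).  Refractory neurons hold v_reset and count
    down.  Fires iff v >= v_thresh and not refractory.
    """
    v = np.asarray(state.v, dtype=np.float64)
    i_syn = (np.asarray(state.i_syn, dtype=np.float64)
             * np.exp(-dt / tau_syn) + syn_arrivals)
    ref = np.asarray(state.refractory_steps_left)
    active = ref == 0
    dv = (dt / params.tau_m) * (-(v - params.v_rest)
                                + params.r_m * (params.i_ext + i_syn))
    v = np.where(active, v + dv, v)
    ref = np.where(active, ref, ref - 1)
    fired = active & (v >= params.v_thresh)
    ref_steps = np.maximum(np.rint(params.t_ref / dt), 0).astype(ref.dtype)
    v = np.where(fired, params.v_reset, v)
    ref = np.where(fired, ref_steps, ref)
    return NeuronState(v, i_syn, ref), fired


def build_target_lookup(net: Network, a: Assignment) -> TargetLookup:
    """For each neuron: distinct processes hosting its targets, minus its own."""
    if len(a.parts) != net.n_neurons:
        raise ValueError("assignment does not cover the network")
    pre = net.pre_ids()
    src_proc = a.parts[pre].astype(np.int64)
    dst_proc = a.parts[net.post_ids].astype(np.int64)
    remote = src_proc != dst_proc
    key = pre[remote] * np.int64(a.n_parts) + dst_proc[remote]
    uniq = np.unique(key)
    neurons = uniq // a.n_parts
    procs = (uniq % a.n_parts).astype(np.int32)
    ptr = np.zeros(net.n_neurons + 1, dtype=np.int64)
    np.cumsum(np.bincount(neurons, minlength=net.n_neurons), out=ptr[1:])
    return TargetLookup(ptr=ptr, procs=procs)


def _expand_params(net: Network):
    """Per-neuron parameter arrays resolved from population specs."""
    fields = ["v_rest", "v_thresh", "v_reset", "tau_m", "r_m", "t_ref", "i_ext"]
    per_pop = {
        f: np.array([getattr(p.neuron_params, f) for p in net.populations])
        for f in fields
    }

    class _P:  # simple namespace with per-neuron arrays
        pass

    out = _P()
    for f in fields:
        setattr(out, f, per_pop[f][net.pop_of])
    return out


def run_simulation(net: Network, a: Assignment, cfg: SimulationConfig) -> SimulationResult:
    """Simulate the network over P virtual processes.

    Per step: synaptic currents decay and absorb arrivals, all neurons are
    updated in ascending global id, spikes are routed locally (delayed
    delivery at step + delay) and, at exchange boundaries, announced to
    remote processes through the configured pattern.  The raster depends
    only on (net, cfg), never on the allocation or the pattern.
    """
    if len(a.parts) != net.n_neurons:
        raise ValueError("assignment does not cover the network")
    if abs(net.dt_ms - cfg.dt) > 1e-12:
        raise ValueError(
            f"network delays are on a {net.dt_ms} ms grid but cfg.dt = "
            f"{cfg.dt} ms: delays would fall off the step grid"
        )
    n = net.n_neurons
    P = a.n_parts
    n_steps = int(round(cfg.duration / cfg.dt))
    params = _expand_params(net)
    tau_syn = net.synapse_params.tau_syn
    decay = float(np.exp(-cfg.dt / tau_syn))
    ref_steps = np.maximum(np.rint(params.t_ref / cfg.dt), 0).astype(np.int64)

    if cfg.init == "uniform":
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
        v = params.v_reset + rng.random(n) * (params.v_thresh - params.v_reset)
    else:
        v = params.v_rest.astype(np.float64).copy()
    i_syn = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)

    max_delay = int(net.delay_steps.max()) if net.n_synapses else 1
    D = max_delay + 1
    buf = np.zeros((D, n))

    lookup = build_target_lookup(net, a)
    lk_sizes = lookup.set_sizes()
    parts64 = a.parts.astype(np.int64)

    raster_steps: list[np.ndarray] = []
    raster_neurons: list[np.ndarray] = []
    records: list[comm.CommRecord] = []
    syn_events = np.zeros(P, dtype=np.int64)

    pattern_fn = comm.pex_exchange if cfg.comm_pattern == "pex" else comm.nbx_exchange

    for step in range(n_steps):
        row = step % D
        arrivals = buf[row].copy()
        buf[row] = 0.0

        i_syn *= decay
        i_syn += arrivals
        active = ref == 0
        dv = (cfg.dt / params.tau_m) * (
            -(v - params.v_rest) + params.r_m * (params.i_ext + i_syn)
        )
        v[active] += dv[active]
        ref[~active] -= 1
        fired_mask = active & (v >= params.v_thresh)
        fired = np.flatnonzero(fired_mask)
        if len(fired):
            v[fired] = params.v_reset[fired]
            ref[fired] = ref_steps[fired]
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise NumericalError(
                f"non-finite membrane potential at neuron {bad}, step {step}"
            )

        if cfg.record_raster and len(fired):
            raster_steps.append(np.full(len(fired), step, dtype=np.int64))
            raster_neurons.append(fired.astype(np.int64))

        # local + delayed delivery of every synapse of every spike
        if len(fired):
            starts = net.out_ptr[fired]
            ends = net.out_ptr[fired + 1]
            counts = ends - starts
            tot = int(counts.sum())
            if tot:
                idx = np.concatenate(
                    [np.arange(s, e) for s, e in zip(starts, ends)]
                )
                posts = net.post_ids[idx]
                rows = (step + net.delay_steps[idx]) % D
                np.add.at(buf, (rows, posts), net.weights[idx])
                syn_events += np.bincount(parts64[posts], minlength=P)

        # exchange boundary: announce spikes to remote processes
        if step % cfg.exchange_every == 0:
            if len(fired):
                k = lk_sizes[fired]
                remote = fired[k > 0]
                kr = lk_sizes[remote]
                dst = np.concatenate(
                    [lookup.targets(int(i)) for i in remote]
                ) if len(remote) else np.empty(0, dtype=np.int32)
                src = np.repeat(parts64[remote], kr).astype(np.int32)
                nid = np.repeat(remote, kr)
            else:
                dst = np.empty(0, dtype=np.int32)
                src = np.empty(0, dtype=np.int32)
                nid = np.empty(0, dtype=np.int64)
            traffic = comm.StepTraffic(P, src, dst, nid)
            rec, _delivered = pattern_fn(traffic, P, step=step)
            records.append(rec)

    duration_s = cfg.duration / 1000.0
    stats = comm.accumulate_stats(records, P, duration_s)
    r_steps = (np.concatenate(raster_steps) if raster_steps
               else np.empty(0, dtype=np.int64))
    r_neur = (np.concatenate(raster_neurons) if raster_neurons
              else np.empty(0, dtype=np.int64))
    return SimulationResult(
        raster_steps=r_steps,
        raster_neurons=r_neur,
        n_steps=n_steps,
        dt=cfg.dt,
        n_neurons=n,
        neuron_updates=a.part_sizes().astype(np.int64) * n_steps,
        synaptic_events=syn_events,
        comm_stats=stats,
        comm_records=records if cfg.keep_records else [],
    )


def mean_firing_rate(result: SimulationResult, net: Network,
                     cfg: SimulationConfig) -> float:
    """Spikes per neuron per second over the whole run."""
    if cfg.duration <= 0:
        raise ValueError("duration must be positive to define a rate")
    return result.n_spikes / (net.n_neurons * cfg.duration / 1000.0)
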