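"""Message-by-message accounting for the two census exchange patterns.

Spike exchange in a distributed step-driven SNN simulation is a *census*:
each process knows which processes must receive its local spikes (via a
precomputed target lookup), but not who will send to it.  Two realizations
are accounted for here:

* **PEX** (personalized exchange): two sequential rounds.  Round one is an
  explicit all-to-all handshake in which every process sends one metadata
  unit to each of the other P−1 processes — whether or not it has anything
  to say — so handshake traffic is exactly P·(P−1) units per exchange and
  grows quadratically with P.  Round two delivers payload only along the
  pairs flagged during the handshake.
* **NBX** (neighborhood exchange, a dynamic sparse data exchange): payload
  is sent immediately to actual targets while an asynchronous barrier
  replaces the handshake.  Barrier tokens carry a payload of zero bytes;
  metadata volume is identically 0.

Both patterns deliver exactly the same id multisets for the same traffic, so
simulation dynamics cannot depend on the pattern — only the accounting
differs.  Bytes: 4 per neuron id and 4 per PEX metadata unit (32-bit
address-event ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BYTES_PER_ID",
    "BYTES_PER_METADATA_UNIT",
    "StepTraffic",
    "CommRecord",
    "CommStats",
    "pex_exchange",
    "nbx_exchange",
    "accumulate_stats",
    "theoretical_pex_curves",
]

BYTES_PER_ID = 4
BYTES_PER_METADATA_UNIT = 4


@dataclass
class StepTraffic:
    """Remote spike traffic of one exchange step.

    Flat triplet arrays: message ``i`` says neuron ``neuron_ids[i]`` hosted
    on ``src[i]`` must be announced to process ``dst[i]``.  Destinations are
    distinct per (neuron, dst) pair and never equal the hosting process.
    """

    n_parts: int
    src: np.ndarray        # int32, source process per (spike, target) pair
    dst: np.ndarray        # int32, destination process
    neuron_ids: np.ndarray  # int64, firing neuron id

    def __post_init__(self):
        self.src = np.asarray(self.src, dtype=np.int32)
        self.dst = np.asarray(self.dst, dtype=np.int32)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if np.any(self.src == self.dst):
            raise ValueError("traffic contains a self-destined message")

    @classmethod
    def from_destinations(cls, n_parts: int, destinations: dict) -> "StepTraffic":
        """Build from {(src, dst): iterable of neuron ids}."""
        srcs, dsts, ids = [], [], []
        for (p, q), neurons in sorted(destinations.items()):
            for nid in neurons:
                srcs.append(p)
                dsts.append(q)
                ids.append(nid)
        return cls(n_parts, np.asarray(srcs, dtype=np.int32),
                   np.asarray(dsts, dtype=np.int32),
                   np.asarray(ids, dtype=np.int64))

    @property
    def n_remote_spikes(self) -> int:
        """Distinct firing neurons with at least one remote target."""
        return len(np.unique(self.neuron_ids)) if len(self.neuron_ids) else 0

    @property
    def n_spike_messages(self) -> int:
        """(spike, target process) pairs — one id per payload entry."""
        return int(len(self.dst))

    def destinations(self) -> dict:
        """{(src, dst): sorted array of neuron ids} — the delivered payload."""
        out: dict[tuple[int, int], np.ndarray] = {}
        if len(self.dst) == 0:
            return out
        key = self.src.astype(np.int64) * self.n_parts + self.dst
        order = np.lexsort((self.neuron_ids, key))
        k_sorted = key[order]
        ids_sorted = self.neuron_ids[order]
        bounds = np.flatnonzero(np.diff(k_sorted)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(k_sorted)]])
        for s, e in zip(starts, ends):
            k = int(k_sorted[s])
            out[(k // self.n_parts, k % self.n_parts)] = ids_sorted[s:e]
        return out


@dataclass
class CommRecord:
    """Accounting of one exchange step under one pattern."""

    step: int
    pattern: str
    n_parts: int
    target_set_sizes: np.ndarray   # |T_p| per process
    n_payload_messages: int
    n_payload_ids: int
    handshake_units: int           # PEX: P*(P-1); NBX: 0
    rounds: int                    # PEX: 2 sequential phases; NBX: 1
    n_remote_spikes: int
    n_spike_messages: int
    pair_src: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    pair_dst: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    pair_id_counts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    n_barrier_messages: int = 0

    @property
    def payload_bytes(self) -> int:
        return BYTES_PER_ID * self.n_payload_ids

    @property
    def metadata_bytes(self) -> int:
        return BYTES_PER_METADATA_UNIT * self.handshake_units

    @property
    def messages_total(self) -> int:
        return self.handshake_units + self.n_payload_messages + self.n_barrier_messages


@dataclass
class CommStats:
    """Aggregate communication metrics of a run.

    ``arn`` — average runtime neighbors: mean over (process, exchange step)
    of the number of distinct payload-target processes, silent steps
    included.  ``remote_spikes`` counts firing events with at least one
    remote target (once per spike); ``spike_messages`` counts them once per
    (spike, target process) — the per-message propagation load.
    """

    n_parts: int
    n_exchange_steps: int
    duration_s: float
    arn: float
    remote_spikes: int
    spike_messages: int
    payload_bytes: int
    metadata_bytes: int
    messages_total: int
    pair_messages: np.ndarray  # (P, P) messages a→b over the run

    @property
    def total_bytes(self) -> int:
        return self.payload_bytes + self.metadata_bytes

    def pair_frequency(self) -> np.ndarray:
        """F_{a,b}: messages a→b per simulated second."""
        if self.duration_s == 0:
            return np.zeros_like(self.pair_messages, dtype=np.float64)
        return self.pair_messages / self.duration_s

    def to_dict(self) -> dict:
        return {
            "n_parts": self.n_parts,
            "n_exchange_steps": self.n_exchange_steps,
            "duration_s": self.duration_s,
            "arn": self.arn,
            "remote_spikes": self.remote_spikes,
            "spike_messages": self.spike_messages,
            "payload_bytes": self.payload_bytes,
            "metadata_bytes": self.metadata_bytes,
            "total_bytes": self.total_bytes,
            "messages_total": self.messages_total,
        }


# ---------------------------------------------------------------------------


def _group_pairs(traffic: StepTraffic):
    """Distinct (src, dst) payload pairs with id counts and |T_p| sizes."""
    P = traffic.n_parts
    if len(traffic.dst) == 0:
        return (np.empty(0, np.int32), np.empty(0, np.int32),
                np.empty(0, np.int64), np.zeros(P, dtype=np.int64))
    key = traffic.src.astype(np.int64) * P + traffic.dst
    uniq, counts = np.unique(key, return_counts=True)
    pair_src = (uniq // P).astype(np.int32)
    pair_dst = (uniq % P).astype(np.int32)
    t_sizes = np.bincount(pair_src, minlength=P).astype(np.int64)
    return pair_src, pair_dst, counts.astype(np.int64), t_sizes


def _exchange(traffic: StepTraffic, n_parts: int, pattern: str, step: int):
    if traffic.n_parts != n_parts:
        raise ValueError("traffic/n_parts mismatch")
    pair_src, pair_dst, pair_counts, t_sizes = _group_pairs(traffic)
    common = dict(
        step=step,
        n_parts=n_parts,
        target_set_sizes=t_sizes,
        n_payload_messages=int(len(pair_src)),
        n_payload_ids=int(pair_counts.sum()),
        n_remote_spikes=traffic.n_remote_spikes,
        n_spike_messages=traffic.n_spike_messages,
        pair_src=pair_src,
        pair_dst=pair_dst,
        pair_id_counts=pair_counts,
    )
    if pattern == "pex":
        rec = CommRecord(pattern="pex", handshake_units=n_parts * (n_parts - 1),
                         rounds=2, **common)
    else:
        rec = CommRecord(pattern="nbx", handshake_units=0, rounds=1,
                         n_barrier_messages=n_parts, **common)
    return rec, traffic.destinations()


def pex_exchange(traffic: StepTraffic, n_parts: int, step: int = 0):
    """Personalized exchange: all-to-all handshake, then payload.

    Returns (CommRecord, delivered) where delivered maps (src, dst) to the
    neuron ids carried by that payload message.  Handshake metadata is
    exactly P·(P−1) units regardless of activity.
    """
    return _exchange(traffic, n_parts, "pex", step)


def nbx_exchange(traffic: StepTraffic, n_parts: int, step: int = 0):
    """Neighborhood exchange: payload to actual targets only, async barrier.

    Zero handshake metadata; P barrier tokens are counted as messages of 0
    bytes.  Delivered id multisets are identical to PEX on the same traffic.
    """
    return _exchange(traffic, n_parts, "nbx", step)


def accumulate_stats(
    records: list[CommRecord],
    n_parts: int,
    duration_s: float,
) -> CommStats:
    """Aggregate per-step records into run-level communication metrics."""
    pair = np.zeros((n_parts, n_parts), dtype=np.int64)
    if not records:
        return CommStats(
            n_parts=n_parts, n_exchange_steps=0, duration_s=duration_s,
            arn=0.0, remote_spikes=0, spike_messages=0, payload_bytes=0,
            metadata_bytes=0, messages_total=0, pair_messages=pair,
        )
    arn_sum = 0
    remote = 0
    messages = 0
    payload = 0
    metadata = 0
    spike_msgs = 0
    for rec in records:
        arn_sum += int(rec.target_set_sizes.sum())
        remote += rec.n_remote_spikes
        spike_msgs += rec.n_spike_messages
        payload += rec.payload_bytes
        metadata += rec.metadata_bytes
        messages += rec.messages_total
        np.add.at(pair, (rec.pair_src, rec.pair_dst), 1)
    n_steps = len(records)
    return CommStats(
        n_parts=n_parts,
        n_exchange_steps=n_steps,
        duration_s=duration_s,
        arn=arn_sum / (n_parts * n_steps),
        remote_spikes=remote,
        spike_messages=spike_msgs,
        payload_bytes=payload,
        metadata_bytes=metadata,
        messages_total=messages,
        pair_messages=pair,
    )


def theoretical_pex_curves(
    process_counts,
    spike_rates_hz=(20.0, 80.0, 160.0),
    neurons_per_process: int = 1000,
    mean_remote_targets: float | None = None,
    mean_remote_synapses: float | None = None,
    dt_ms: float = 0.1,
) -> pd.DataFrame:
    """Theoretical PEX volume per exchange step versus process count.

    Handshake volume is P·(P−1) metadata units; payload volume per step is
    rate × neurons-per-process × P × dt × (mean remote target count) ids.
    By default a remote target count of P−1 capped by ``mean_remote_targets``
    is used (per-process accounting); pass ``mean_remote_synapses`` to also
    emit a per-synapse payload column.  The ``crossover_P`` attribute of the
    result (``df.attrs``) holds, per rate, the first P at which handshake
    volume overtakes payload volume.
    """
    rows = []
    for P in process_counts:
        handshake_units = P * (P - 1)
        for rate in spike_rates_hz:
            spikes_per_step = rate * neurons_per_process * P * (dt_ms / 1000.0)
            targets = (P - 1) if mean_remote_targets is None else min(
                mean_remote_targets, P - 1)
            payload_ids = spikes_per_step * targets
            row = {
                "P": P,
                "rate_hz": rate,
                "handshake_units": handshake_units,
                "handshake_bytes": handshake_units * BYTES_PER_METADATA_UNIT,
                "payload_ids": payload_ids,
                "payload_bytes": payload_ids * BYTES_PER_ID,
            }
            if mean_remote_synapses is not None:
                row["payload_ids_per_synapse"] = spikes_per_step * mean_remote_synapses
                row["payload_bytes_per_synapse"] = (
                    spikes_per_step * mean_remote_synapses * BYTES_PER_ID
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    crossover = {}
    for rate in spike_rates_hz:
        sub = df[df.rate_hz == rate].sort_values("P")
        over = sub[sub.handshake_bytes > sub.payload_bytes]
        crossover[rate] = int(over.P.iloc[0]) if len(over) else None
    df.attrs["crossover_P"] = crossover
    return df
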