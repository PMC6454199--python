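"""Strong-scaling experiment grids: strategy × pattern × process count.

The harness reproduces, at desk scale, the comparative experiments of
communication-bound SNN simulation studies: fix the model, sweep the number
of (virtual) processes, and compare allocation strategies (round robin,
random balanced, hypergraph partitioning) crossed with exchange patterns
(PEX, NBX) on hardware-independent count metrics — connectivity-1 cut,
imbalance, average runtime neighbors, remote spikes, payload and handshake
volume.  Every grid run asserts that the spike raster is identical across
all cells sharing (model, seed): allocation and pattern must never change
the dynamics, only the communication accounting.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .allocation import PartitionerConfig, allocate
from .engine import SimulationConfig, mean_firing_rate, run_simulation
from .hypergraph import network_to_hypergraph, partition_cost, partition_imbalance

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "RasterMismatchError",
    "run_grid",
    "reduction",
    "build_cost_report",
    "MODEL_PRESETS",
]

MODEL_PRESETS = {
    "cm_like": models.cm_like_spec,
    "multiarea_like": models.multiarea_like_spec,
}


class RasterMismatchError(AssertionError):
    """Spike rasters diverged across cells that share (model, seed).

    This is the harness's built-in correctness oracle: a mismatch indicates
    a dynamics bug, never a communication difference.
    """


@dataclass(frozen=True)
class ExperimentConfig:
    """A grid of cells: seeds × process counts × strategies × patterns."""

    model: str = "cm_like"
    model_kwargs: dict = field(default_factory=dict)
    process_counts: tuple[int, ...] = (8,)
    strategies: tuple[str, ...] = ("random_balanced", "hypergraph")
    patterns: tuple[str, ...] = ("pex",)
    duration_ms: float = 50.0
    dt_ms: float = 0.1
    seeds: tuple[int, ...] = (1,)
    partitioner: dict = field(default_factory=dict)
    scale: float = 1.0  # applied to the preset's population sizes

    def __post_init__(self):
        if self.model not in MODEL_PRESETS:
            raise ValueError(f"unknown model preset {self.model!r}")
        if any(p < 1 for p in self.process_counts):
            raise ValueError("process counts must be >= 1")
        if len(self.seeds) < 1:
            raise ValueError("at least one seed (repetition) required")


@dataclass
class ComparisonReport:
    """Per-cell metrics plus percentage reductions against a baseline."""

    table: pd.DataFrame
    config: ExperimentConfig

    METRICS = ("cut_cost", "arn", "remote_spikes", "spike_messages",
               "payload_bytes", "metadata_bytes", "total_bytes")

    def medians(self) -> pd.DataFrame:
        """Median over seeds for every (P, strategy, pattern) cell."""
        return (
            self.table
            .groupby(["P", "strategy", "pattern"], as_index=False)
            .median(numeric_only=True)
        )

    def reductions(self, baseline: tuple[str, str]) -> pd.DataFrame:
        """100·(baseline − candidate)/baseline per metric, medians over seeds.

        ``baseline`` is a (strategy, pattern) pair present in the grid.
        """
        base_s, base_p = baseline
        med = self.medians()
        base = med[(med.strategy == base_s) & (med.pattern == base_p)]
        if base.empty:
            raise ValueError(f"baseline {baseline} not in the grid")
        rows = []
        for _, cand in med.iterrows():
            b = base[base.P == cand.P]
            if b.empty:
                continue
            b = b.iloc[0]
            row = {"P": cand.P, "strategy": cand.strategy,
                   "pattern": cand.pattern}
            for m in self.METRICS:
                row[f"{m}_reduction_pct"] = reduction(b[m], cand[m])
            rows.append(row)
        return pd.DataFrame(rows)


def reduction(baseline: float, candidate: float) -> float:
    """Percentage reduction of candidate relative to baseline.

    Undefined (NaN) when the baseline is not positive.
    """
    if baseline is None or not math.isfinite(baseline) or baseline <= 0:
        return math.nan
    return 100.0 * (baseline - candidate) / baseline


def _raster_key(result) -> tuple:
    return (
        result.n_spikes,
        hash(result.raster_steps.tobytes()),
        hash(result.raster_neurons.tobytes()),
    )


def run_grid(cfg: ExperimentConfig) -> ComparisonReport:
    """Run every cell of the grid; returns the comparison table.

    The network is built once per seed; each (P, strategy) allocation is
    computed once and shared across patterns.  Spike-raster equality across
    all cells of a seed is asserted (RasterMismatchError on violation).
    """
    preset = MODEL_PRESETS[cfg.model]
    rows = []
    for seed in cfg.seeds:
        spec = preset(dt_ms=cfg.dt_ms, **cfg.model_kwargs)
        if cfg.scale != 1.0:
            spec = models.apply_scale(spec, cfg.scale)
        net = models.build_network(spec, seed)
        hg = network_to_hypergraph(net)
        reference_key = None
        for P in cfg.process_counts:
            for strategy in cfg.strategies:
                pcfg = PartitionerConfig(
                    n_parts=P, seed=seed, **cfg.partitioner
                )
                assign = allocate(strategy, hg, P, seed=seed, cfg=pcfg)
                cut = partition_cost(hg, assign)
                imb = partition_imbalance(hg, assign)
                for pattern in cfg.patterns:
                    sim_cfg = SimulationConfig(
                        dt=cfg.dt_ms, duration=cfg.duration_ms,
                        comm_pattern=pattern, seed=seed, keep_records=False,
                    )
                    res = run_simulation(net, assign, sim_cfg)
                    key = _raster_key(res)
                    if reference_key is None:
                        reference_key = key
                    elif key != reference_key:
                        raise RasterMismatchError(
                            f"raster diverged at seed={seed} P={P} "
                            f"strategy={strategy} pattern={pattern}"
                        )
                    st = res.comm_stats
                    rows.append({
                        "seed": seed,
                        "P": P,
                        "strategy": strategy,
                        "pattern": pattern,
                        "cut_cost": cut,
                        "imbalance": imb,
                        "arn": st.arn,
                        "remote_spikes": st.remote_spikes,
                        "spike_messages": st.spike_messages,
                        "payload_bytes": st.payload_bytes,
                        "metadata_bytes": st.metadata_bytes,
                        "total_bytes": st.total_bytes,
                        "messages_total": st.messages_total,
                        "n_spikes": res.n_spikes,
                        "rate_hz": mean_firing_rate(res, net, sim_cfg),
                        "fm_moves": assign.meta.get("fm_moves", 0),
                        "matching_ops": assign.meta.get("matching_ops", 0),
                        "achieved_imbalance": assign.meta.get(
                            "achieved_imbalance", imb),
                    })
    return ComparisonReport(table=pd.DataFrame(rows), config=cfg)


def build_cost_report(report: ComparisonReport,
                      baseline: tuple[str, str] | None = None) -> pd.DataFrame:
    """Partitioner work versus communication savings, per cell.

    Work is expressed in hardware-independent operation counts (matching
    score accumulations during coarsening, accepted FM moves); savings as
    the reduction in total exchanged bytes against the baseline cell (by
    default the first strategy/pattern of the grid).  Savings grow with the
    simulated duration while the partitioning work does not depend on it.
    """
    cfg = report.config
    if baseline is None:
        baseline = (cfg.strategies[0], cfg.patterns[0])
    med = report.medians()
    base = med[(med.strategy == baseline[0]) & (med.pattern == baseline[1])]
    rows = []
    for _, cand in med.iterrows():
        b = base[base.P == cand.P]
        bytes_saved = (
            float(b.iloc[0].total_bytes - cand.total_bytes) if len(b) else math.nan
        )
        rows.append({
            "P": cand.P,
            "strategy": cand.strategy,
            "pattern": cand.pattern,
            "matching_ops": cand.matching_ops,
            "fm_moves": cand.fm_moves,
            "partitioner_work": cand.matching_ops + cand.fm_moves,
            "bytes_saved_vs_baseline": bytes_saved,
        })
    return pd.DataFrame(rows)
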