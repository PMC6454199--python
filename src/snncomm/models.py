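"""Synthetic spiking-network model generation.

Two families of networks are generated, mirroring the structures used in
communication-scaling studies of distributed SNN simulators:

* a *layered* network in the style of a cortical microcircuit: a handful of
  excitatory/inhibitory populations ("layers") with connection probabilities
  that are larger within a layer than between layers;
* a *multi-area* network: many areas, each an independent layered network,
  with a fixed (small) connection probability between cells of different
  areas.

Connectivity is Gilbert-style: every ordered neuron pair covered by a rule is
connected independently with the rule's probability (no autapses unless a rule
asks for them).  Synaptic delays live on the simulation step grid and are at
least one step, which is what forces a spike exchange at every step of the
simulator.  Generation is reproducible: identical (spec, seed) produces a
bit-identical network, and structure, weights and delays are drawn from
separate named RNG streams so that changing the weight draw cannot perturb
the topology.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "PopulationSpec",
    "ConnectivityRule",
    "ModelSpec",
    "Network",
    "ModelConfigError",
    "NetworkParseError",
    "build_layered_network",
    "build_multiarea_network",
    "build_network",
    "apply_scale",
    "network_summary",
    "write_network",
    "read_network",
    "cm_like_spec",
    "multiarea_like_spec",
    "mvc_full_spec",
]


class ModelConfigError(ValueError):
    """A model specification references unknown labels or invalid values."""


class NetworkParseError(ValueError):
    """A serialized network file is malformed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire parameters.

    v_rest/v_thresh/v_reset in mV, tau_m in ms, r_m in MOhm, t_ref in ms,
    i_ext the constant injected current (mA).  Note the default preset keeps
    a resting potential above the spiking threshold; see docs/methods.md.
    """

    v_rest: float = -45.0
    v_thresh: float = -50.0
    v_reset: float = -65.0
    tau_m: float = 10.0
    r_m: float = 1.0
    t_ref: float = 2.0
    i_ext: float = 0.95

    def __post_init__(self):
        vals = dataclasses.astuple(self)
        if not all(math.isfinite(v) for v in vals):
            raise ModelConfigError("neuron parameters must be finite")
        if self.tau_m <= 0:
            raise ModelConfigError("tau_m must be positive")
        if self.t_ref < 0:
            raise ModelConfigError("t_ref must be non-negative")


@dataclass(frozen=True)
class SynapseParams:
    """Network-wide synapse defaults.

    ``tau_syn`` (ms) is the exponential decay constant of the post-synaptic
    current; ``inhibitory_multiplier`` scales the weight of every synapse
    whose presynaptic population is inhibitory (−4 for microcircuit-style
    presets, −15 for the multi-area preset).
    """

    tau_syn: float = 2.0
    inhibitory_multiplier: float = -4.0

    def __post_init__(self):
        if self.tau_syn <= 0:
            raise ModelConfigError("tau_syn must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    excitatory: bool = True
    neuron_params: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self):
        if self.size < 0:
            raise ModelConfigError(f"population {self.name!r} has negative size")


@dataclass(frozen=True)
class ConnectivityRule:
    """Independent pairwise connections from population ``pre`` to ``post``.

    ``post`` (or ``pre``) may be the wildcard ``"*"`` meaning every declared
    population.  ``weight_dist`` is ``("constant", w)``, ``("uniform", lo,
    hi)`` or ``("normal", mu, sigma)``; ``delay_dist`` is ``("uniform_steps",
    lo, hi)`` with inclusive integer bounds on the step grid (lo >= 1).
    """

    pre: str
    post: str
    probability: float
    weight_dist: tuple = ("constant", 0.1)
    delay_dist: tuple = ("uniform_steps", 1, 15)
    allow_autapses: bool = False

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ModelConfigError(
                f"rule {self.pre}->{self.post}: probability {self.probability} "
                "outside [0, 1]"
            )
        kind = self.delay_dist[0]
        if kind != "uniform_steps":
            raise ModelConfigError(f"unknown delay distribution {kind!r}")
        lo, hi = self.delay_dist[1], self.delay_dist[2]
        if lo < 1 or hi < lo:
            raise ModelConfigError("delays must span >= 1 step on the grid")


@dataclass(frozen=True)
class ModelSpec:
    """Full generative description of a network.

    ``populations`` and ``rules`` describe one area; for ``n_areas > 1`` the
    area template is replicated and ``inter_area_rules`` apply between every
    ordered pair of distinct areas with a fixed probability.  ``scale``
    multiplies population sizes (probabilities are left untouched).
    """

    populations: tuple[PopulationSpec, ...]
    rules: tuple[ConnectivityRule, ...]
    n_areas: int = 1
    inter_area_rules: tuple[ConnectivityRule, ...] = ()
    scale: float = 1.0
    synapse_params: SynapseParams = field(default_factory=SynapseParams)
    dt_ms: float = 0.1

    def __post_init__(self):
        if self.n_areas < 1:
            raise ModelConfigError("n_areas must be >= 1")
        if self.scale <= 0:
            raise ModelConfigError("scale must be positive")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ModelConfigError("duplicate population names")

    # -- convenience -------------------------------------------------------
    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise ModelConfigError(f"unknown population label {name!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = [dataclasses.asdict(p) for p in self.populations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        pops = tuple(
            PopulationSpec(
                name=p["name"],
                size=int(p["size"]),
                excitatory=bool(p.get("excitatory", True)),
                neuron_params=NeuronParams(**p.get("neuron_params", {})),
            )
            for p in d["populations"]
        )

        def _rule(r):
            return ConnectivityRule(
                pre=r["pre"],
                post=r["post"],
                probability=float(r["probability"]),
                weight_dist=tuple(r.get("weight_dist", ("constant", 0.1))),
                delay_dist=tuple(r.get("delay_dist", ("uniform_steps", 1, 15))),
                allow_autapses=bool(r.get("allow_autapses", False)),
            )

        return cls(
            populations=pops,
            rules=tuple(_rule(r) for r in d.get("rules", ())),
            n_areas=int(d.get("n_areas", 1)),
            inter_area_rules=tuple(_rule(r) for r in d.get("inter_area_rules", ())),
            scale=float(d.get("scale", 1.0)),
            synapse_params=SynapseParams(**d.get("synapse_params", {})),
            dt_ms=float(d.get("dt_ms", 0.1)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class Network:
    """A generated network in canonical CSR form.

    ``out_ptr``/``post_ids`` index the adjacency of each presynaptic neuron
    (sorted by postsynaptic id within each row); ``weights`` carry the signed
    synaptic efficacy and ``delay_steps`` the transmission delay as an
    integer number of simulation steps (>= 1).  ``pop_of``/``area_of`` map
    each neuron to its population (index into ``populations``) and area.
    """

    n_neurons: int
    out_ptr: np.ndarray      # int64, shape (n_neurons + 1,)
    post_ids: np.ndarray     # int64, shape (n_synapses,)
    weights: np.ndarray      # float64, shape (n_synapses,)
    delay_steps: np.ndarray  # int32,  shape (n_synapses,)
    pop_of: np.ndarray       # int32,  shape (n_neurons,)
    area_of: np.ndarray      # int32,  shape (n_neurons,)
    populations: tuple[PopulationSpec, ...]
    synapse_params: SynapseParams = field(default_factory=SynapseParams)
    dt_ms: float = 0.1

    def __post_init__(self):
        if len(self.post_ids) and (
            self.post_ids.min() < 0 or self.post_ids.max() >= self.n_neurons
        ):
            raise ModelConfigError("postsynaptic id out of range")
        if len(self.delay_steps) and self.delay_steps.min() < 1:
            raise ModelConfigError("delays must be >= one time step")

    @property
    def n_synapses(self) -> int:
        return int(len(self.post_ids))

    def out_degree(self) -> np.ndarray:
        return np.diff(self.out_ptr)

    def in_degree(self) -> np.ndarray:
        return np.bincount(self.post_ids, minlength=self.n_neurons).astype(np.int64)

    def targets_of(self, neuron: int) -> np.ndarray:
        return self.post_ids[self.out_ptr[neuron]:self.out_ptr[neuron + 1]]

    def pre_ids(self) -> np.ndarray:
        """Presynaptic id of every synapse, aligned with ``post_ids``."""
        return np.repeat(np.arange(self.n_neurons, dtype=np.int64), self.out_degree())

    def excitatory_mask(self) -> np.ndarray:
        exc = np.array([p.excitatory for p in self.populations], dtype=bool)
        return exc[self.pop_of]

    def __eq__(self, other) -> bool:  # bit-exact comparison, used by tests
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.n_neurons == other.n_neurons
            and np.array_equal(self.out_ptr, other.out_ptr)
            and np.array_equal(self.post_ids, other.post_ids)
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.delay_steps, other.delay_steps)
            and np.array_equal(self.pop_of, other.pop_of)
            and np.array_equal(self.area_of, other.area_of)
        )


# ---------------------------------------------------------------------------
# random sampling helpers
# ---------------------------------------------------------------------------

def _sample_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct uniform integers from [0, n), unsorted, seed-deterministic."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k > n:
        raise ValueError("k > n")
    if n <= 4 * k or n < 1 << 20:
        return rng.choice(n, size=k, replace=False).astype(np.int64)
    # sparse regime: rejection sampling keeps memory at O(k)
    out = np.unique(rng.integers(0, n, size=int(k * 1.1) + 16, dtype=np.int64))
    while len(out) < k:
        extra = rng.integers(0, n, size=k, dtype=np.int64)
        out = np.unique(np.concatenate([out, extra]))
    return rng.permutation(out)[:k]


def _draw_weights(rng: np.random.Generator, dist: tuple, k: int) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        return np.full(k, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(float(dist[1]), float(dist[2]), size=k)
    if kind == "normal":
        return rng.normal(float(dist[1]), float(dist[2]), size=k)
    raise ModelConfigError(f"unknown weight distribution {kind!r}")


def _sample_block(
    rng: np.random.Generator,
    n_pre: int,
    n_post: int,
    p: float,
    same_block: bool,
    allow_autapses: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Gilbert sample of an n_pre x n_post block of ordered pairs.

    ``same_block`` marks pre and post ranging over the same neurons, in which
    case the diagonal (autapses) is excluded unless explicitly allowed.
    """
    skip_diag = same_block and not allow_autapses
    n_cols = n_post - 1 if skip_diag else n_post
    total = n_pre * n_cols
    if total == 0 or p == 0.0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    k = int(rng.binomial(total, p))
    flat = _sample_distinct(rng, total, k)
    i = flat // n_cols
    j = flat % n_cols
    if skip_diag:
        j = j + (j >= i)
    return i, j


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _expand_rules(spec: ModelSpec, rules) -> list[ConnectivityRule]:
    names = set(spec.pop_names)
    out: list[ConnectivityRule] = []
    for r in rules:
        pres = spec.pop_names if r.pre == "*" else [r.pre]
        posts = spec.pop_names if r.post == "*" else [r.post]
        for pre in pres:
            for post in posts:
                if pre not in names or post not in names:
                    raise ModelConfigError(
                        f"rule references unknown population "
                        f"{pre if pre not in names else post!r}"
                    )
                out.append(dataclasses.replace(r, pre=pre, post=post))
    return out


def _layout(spec: ModelSpec) -> tuple[int, np.ndarray, np.ndarray, dict]:
    """Area-major, population-minor contiguous id layout.

    Returns (n_neurons, pop_of, area_of, offsets) where offsets[(area, pop)]
    is the first id of that block.
    """
    sizes = [p.size for p in spec.populations]
    area_size = int(sum(sizes))
    n = area_size * spec.n_areas
    pop_of = np.empty(n, dtype=np.int32)
    area_of = np.empty(n, dtype=np.int32)
    offsets: dict[tuple[int, str], int] = {}
    cursor = 0
    for a in range(spec.n_areas):
        for pi, p in enumerate(spec.populations):
            offsets[(a, p.name)] = cursor
            pop_of[cursor:cursor + p.size] = pi
            area_of[cursor:cursor + p.size] = a
            cursor += p.size
    return n, pop_of, area_of, offsets


def _build(spec: ModelSpec, seed: int) -> Network:
    n, pop_of, area_of, offsets = _layout(spec)
    rules = _expand_rules(spec, spec.rules)
    inter_rules = _expand_rules(spec, spec.inter_area_rules)

    rng_struct = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    rng_weight = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    rng_delay = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))

    inh_mult = spec.synapse_params.inhibitory_multiplier
    pres, posts, ws, ds = [], [], [], []

    def _emit(rule: ConnectivityRule, pre0: int, post0: int, same: bool):
        n_pre = spec.population(rule.pre).size
        n_post = spec.population(rule.post).size
        i, j = _sample_block(
            rng_struct, n_pre, n_post, rule.probability, same, rule.allow_autapses
        )
        k = len(i)
        if k == 0:
            return
        w = _draw_weights(rng_weight, rule.weight_dist, k)
        if not spec.population(rule.pre).excitatory:
            w = w * inh_mult
        lo, hi = rule.delay_dist[1], rule.delay_dist[2]
        d = rng_delay.integers(lo, hi + 1, size=k, dtype=np.int32)
        pres.append(pre0 + i)
        posts.append(post0 + j)
        ws.append(w)
        ds.append(d)

    # intra-area connectivity: each area is an independent layered network
    for a in range(spec.n_areas):
        for rule in rules:
            _emit(rule, offsets[(a, rule.pre)], offsets[(a, rule.post)],
                  same=rule.pre == rule.post)

    # inter-area connectivity: fixed probability between every ordered pair
    for a in range(spec.n_areas):
        for b in range(spec.n_areas):
            if a == b:
                continue
            for rule in inter_rules:
                _emit(rule, offsets[(a, rule.pre)], offsets[(b, rule.post)],
                      same=False)

    if pres:
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
        w = np.concatenate(ws)
        d = np.concatenate(ds)
        order = np.lexsort((post, pre))
        pre, post, w, d = pre[order], post[order], w[order], d[order]
    else:
        pre = post = np.empty(0, dtype=np.int64)
        w = np.empty(0, dtype=np.float64)
        d = np.empty(0, dtype=np.int32)

    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(pre, minlength=n), out=out_ptr[1:])
    return Network(
        n_neurons=n,
        out_ptr=out_ptr,
        post_ids=post.astype(np.int64),
        weights=w.astype(np.float64),
        delay_steps=d.astype(np.int32),
        pop_of=pop_of,
        area_of=area_of,
        populations=spec.populations,
        synapse_params=spec.synapse_params,
        dt_ms=spec.dt_ms,
    )


def build_layered_network(spec: ModelSpec, seed: int) -> Network:
    """Generate a single-area layered network (``spec.n_areas`` must be 1)."""
    if spec.n_areas != 1:
        raise ModelConfigError("build_layered_network requires n_areas == 1")
    return _build(spec, seed)


def build_multiarea_network(spec: ModelSpec, seed: int) -> Network:
    """Generate a modular multi-area network (``spec.n_areas`` must be >= 2)."""
    if spec.n_areas < 2:
        raise ModelConfigError("build_multiarea_network requires n_areas >= 2")
    return _build(spec, seed)


def build_network(spec: ModelSpec, seed: int) -> Network:
    """Dispatch on ``spec.n_areas``."""
    return _build(spec, seed)


def apply_scale(spec: ModelSpec, scale: float) -> ModelSpec:
    """Scale population sizes (rounded to nearest int); probabilities kept."""
    if scale <= 0:
        raise ModelConfigError("scale must be positive")
    pops = tuple(
        dataclasses.replace(p, size=int(round(p.size * scale)))
        for p in spec.populations
    )
    return dataclasses.replace(spec, populations=pops, scale=spec.scale * scale)


def network_summary(net: Network) -> dict:
    """Counts and degree distributions of a network."""
    out_deg = net.out_degree()
    in_deg = net.in_degree()
    per_pop = {
        p.name: int((net.pop_of == i).sum()) for i, p in enumerate(net.populations)
    }
    n_areas = int(net.area_of.max()) + 1 if net.n_neurons else 0
    per_area = {
        int(a): int((net.area_of == a).sum()) for a in range(n_areas)
    }
    return {
        "n_neurons": net.n_neurons,
        "n_synapses": net.n_synapses,
        "per_population": per_pop,
        "per_area": per_area,
        "mean_in_degree": float(in_deg.mean()) if net.n_neurons else 0.0,
        "mean_out_degree": float(out_deg.mean()) if net.n_neurons else 0.0,
        "max_in_degree": int(in_deg.max()) if net.n_neurons else 0,
        "max_out_degree": int(out_deg.max()) if net.n_neurons else 0,
    }


# ---------------------------------------------------------------------------
# serialization: CSV edge list + JSON metadata sidecar
# ---------------------------------------------------------------------------

def write_network(net: Network, path) -> None:
    """Write ``path`` (CSV edge list) and ``path + '.meta.json'``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("pre_id,post_id,weight,delay\n")
        pre = net.pre_ids()
        for a, b, w, d in zip(pre, net.post_ids, net.weights, net.delay_steps):
            fh.write(f"{a},{b},{float(w)!r},{d}\n")
    meta = {
        "n_neurons": net.n_neurons,
        "dt_ms": net.dt_ms,
        "pop_of": net.pop_of.tolist(),
        "area_of": net.area_of.tolist(),
        "synapse_params": dataclasses.asdict(net.synapse_params),
        "populations": [dataclasses.asdict(p) for p in net.populations],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_network(path) -> Network:
    """Inverse of :func:`write_network`; bit-exact round trip."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    n = int(meta["n_neurons"])
    pres, posts, ws, ds = [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "pre_id,post_id,weight,delay":
            raise NetworkParseError("bad header", line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise NetworkParseError("expected 4 fields", line=lineno)
            try:
                a, b, w, d = int(parts[0]), int(parts[1]), float(parts[2]), int(parts[3])
            except ValueError as exc:
                raise NetworkParseError(str(exc), line=lineno) from None
            if not 0 <= a < n or not 0 <= b < n:
                raise NetworkParseError(
                    f"neuron id out of range [0, {n})", line=lineno
                )
            if d < 1:
                raise NetworkParseError("delay below one step", line=lineno)
            pres.append(a)
            posts.append(b)
            ws.append(w)
            ds.append(d)
    pre = np.asarray(pres, dtype=np.int64)
    post = np.asarray(posts, dtype=np.int64)
    w = np.asarray(ws, dtype=np.float64)
    d = np.asarray(ds, dtype=np.int32)
    order = np.lexsort((post, pre))
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(pre, minlength=n), out=out_ptr[1:])
    pops = tuple(
        PopulationSpec(
            name=p["name"],
            size=int(p["size"]),
            excitatory=bool(p["excitatory"]),
            neuron_params=NeuronParams(**p["neuron_params"]),
        )
        for p in meta["populations"]
    )
    return Network(
        n_neurons=n,
        out_ptr=out_ptr,
        post_ids=post[order],
        weights=w[order],
        delay_steps=d[order],
        pop_of=np.asarray(meta["pop_of"], dtype=np.int32),
        area_of=np.asarray(meta["area_of"], dtype=np.int32),
        populations=pops,
        synapse_params=SynapseParams(**meta["synapse_params"]),
        dt_ms=float(meta["dt_ms"]),
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Eight populations (four layers, excitatory/inhibitory each) with relative
# sizes in the usual proportions of layered cortical models.  The probability
# table is "CM-like", not a reprint of any published parameterization:
# within-layer probabilities exceed cross-layer ones, inhibitory neurons
# project only within their own layer, and the whole table is rescaled to hit
# a requested mean in-degree.
_CM_LAYERS = ["L23", "L4", "L5", "L6"]
_CM_FRACTIONS = {
    "L23e": 0.27, "L23i": 0.08,
    "L4e": 0.28, "L4i": 0.07,
    "L5e": 0.06, "L5i": 0.02,
    "L6e": 0.18, "L6i": 0.04,
}
_P_SAME_LAYER = 0.10
_P_ADJACENT = 0.025
_P_DISTANT = 0.008


def _cm_rule_table() -> list[tuple[str, str, float]]:
    table = []
    for li, lpre in enumerate(_CM_LAYERS):
        for kind_pre in ("e", "i"):
            pre = lpre + kind_pre
            for lj, lpost in enumerate(_CM_LAYERS):
                for kind_post in ("e", "i"):
                    post = lpost + kind_post
                    if kind_pre == "i" and li != lj:
                        continue  # inhibitory axons stay within their layer
                    if li == lj:
                        p = _P_SAME_LAYER
                    elif abs(li - lj) == 1:
                        p = _P_ADJACENT
                    else:
                        p = _P_DISTANT
                    table.append((pre, post, p))
    return table


def _cm_populations(n_neurons: int, params: NeuronParams) -> tuple[PopulationSpec, ...]:
    pops = []
    for name, frac in _CM_FRACTIONS.items():
        pops.append(
            PopulationSpec(
                name=name,
                size=int(round(n_neurons * frac)),
                excitatory=name.endswith("e"),
                neuron_params=params,
            )
        )
    return tuple(pops)


def _rescale_table_to_in_degree(
    table, sizes: dict[str, int], n_neurons: int, mean_in_degree: float
) -> list[tuple[str, str, float]]:
    expected = 0.0
    for pre, post, p in table:
        pairs = sizes[pre] * sizes[post] - (sizes[pre] if pre == post else 0)
        expected += p * pairs
    target = mean_in_degree * n_neurons
    factor = target / expected if expected else 0.0
    out = [(pre, post, min(1.0, p * factor)) for pre, post, p in table]
    return out


def cm_like_spec(
    n_neurons: int = 20_000,
    mean_in_degree: float = 50.0,
    weight: float = 0.1,
    delay_steps: tuple[int, int] = (1, 15),
    dt_ms: float = 0.1,
) -> ModelSpec:
    """Layered cortical-microcircuit-like preset (single area).

    Eight populations, within-layer probabilities above cross-layer ones,
    rescaled so the expected mean in-degree equals ``mean_in_degree``.
    Constant current 0.95 mA, rest −45 mV, threshold −50 mV, inhibitory
    weight multiplier −4.
    """
    params = NeuronParams(v_rest=-45.0, v_thresh=-50.0, v_reset=-65.0,
                          tau_m=10.0, r_m=1.0, t_ref=2.0, i_ext=0.95)
    pops = _cm_populations(n_neurons, params)
    sizes = {p.name: p.size for p in pops}
    total = sum(sizes.values())
    table = _rescale_table_to_in_degree(
        _cm_rule_table(), sizes, total, mean_in_degree
    )
    rules = tuple(
        ConnectivityRule(
            pre=pre, post=post, probability=p,
            weight_dist=("constant", weight),
            delay_dist=("uniform_steps", delay_steps[0], delay_steps[1]),
        )
        for pre, post, p in table
    )
    return ModelSpec(
        populations=pops, rules=rules, n_areas=1,
        synapse_params=SynapseParams(tau_syn=2.0, inhibitory_multiplier=-4.0),
        dt_ms=dt_ms,
    )


def multiarea_like_spec(
    n_areas: int = 32,
    area_neurons: int = 1_000,
    intra_mean_in_degree: float = 100.0,
    inter_area_probability: float = 1e-4,
    weight: float = 0.5,
    delay_steps: tuple[int, int] = (1, 15),
    dt_ms: float = 0.1,
) -> ModelSpec:
    """Modular multi-area preset: each area a small dense layered circuit.

    Inter-area connectivity is a fixed per-pair probability from excitatory
    populations to any population of another area — intra-area connection
    probabilities dominate inter-area ones by orders of magnitude.  Constant
    current 0.38 mA and inhibitory weight multiplier −15.
    """
    params = NeuronParams(v_rest=-45.0, v_thresh=-50.0, v_reset=-65.0,
                          tau_m=10.0, r_m=1.0, t_ref=2.0, i_ext=0.38)
    pops = _cm_populations(area_neurons, params)
    sizes = {p.name: p.size for p in pops}
    total = sum(sizes.values())
    table = _rescale_table_to_in_degree(
        _cm_rule_table(), sizes, total, intra_mean_in_degree
    )
    rules = tuple(
        ConnectivityRule(
            pre=pre, post=post, probability=p,
            weight_dist=("constant", weight),
            delay_dist=("uniform_steps", delay_steps[0], delay_steps[1]),
        )
        for pre, post, p in table
    )
    inter = tuple(
        ConnectivityRule(
            pre=p.name, post="*", probability=inter_area_probability,
            weight_dist=("constant", weight),
            delay_dist=("uniform_steps", delay_steps[0], delay_steps[1]),
        )
        for p in pops
        if p.excitatory
    )
    return ModelSpec(
        populations=pops, rules=rules, n_areas=n_areas, inter_area_rules=inter,
        synapse_params=SynapseParams(tau_syn=2.0, inhibitory_multiplier=-15.0),
        dt_ms=dt_ms,
    )


def mvc_full_spec() -> ModelSpec:
    """Full-size 32-area spec (~4.125 M neurons) for scale arithmetic.

    At 16% scale this comes to ~660 k neurons; the returned ModelSpec is
    meant for :func:`apply_scale` bookkeeping, not generation at full size.
    """
    per_area = 4_125_000 // 32  # 128,906 neurons per area
    return multiarea_like_spec(n_areas=32, area_neurons=per_area)
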