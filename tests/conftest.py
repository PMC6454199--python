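import numpy as np
import pytest

import snncomm as sc
from snncomm.hypergraph import Assignment, Hypergraph


@pytest.fixture(scope="session")
def small_cm_net():
    """2k-neuron layered network shared across read-only tests."""
    spec = sc.cm_like_spec(n_neurons=2000, mean_in_degree=30)
    return sc.build_network(spec, seed=11)


@pytest.fixture(scope="session")
def small_multiarea_net():
    spec = sc.multiarea_like_spec(n_areas=4, area_neurons=250,
                                  intra_mean_in_degree=30)
    return sc.build_network(spec, seed=11)


@pytest.fixture()
def chain_net():
    """3-neuron chain 0 -> 1 -> 2 with unit weights, 1-step delays."""
    return _edge_net(3, [(0, 1), (1, 2)])


def _edge_net(n, edges, weights=None, delays=None, params=None):
    """Hand-built network from an explicit edge list (test helper)."""
    from snncomm.models import Network, NeuronParams, PopulationSpec, SynapseParams

    if params is None:
        params = NeuronParams()
    pre = np.array([e[0] for e in edges], dtype=np.int64)
    post = np.array([e[1] for e in edges], dtype=np.int64)
    w = (np.asarray(weights, dtype=np.float64) if weights is not None
         else np.ones(len(edges)))
    d = (np.asarray(delays, dtype=np.int32) if delays is not None
         else np.ones(len(edges), dtype=np.int32))
    order = np.lexsort((post, pre))
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(pre, minlength=n), out=out_ptr[1:])
    return Network(
        n_neurons=n,
        out_ptr=out_ptr,
        post_ids=post[order],
        weights=w[order],
        delay_steps=d[order],
        pop_of=np.zeros(n, dtype=np.int32),
        area_of=np.zeros(n, dtype=np.int32),
        populations=(PopulationSpec("pop", n, True, params),),
        synapse_params=SynapseParams(),
    )


@pytest.fixture()
def edge_net_factory():
    return _edge_net


def make_hg(n, edges, weights=None):
    return Hypergraph.from_edge_lists(
        n, edges,
        None if weights is None else np.asarray(weights, dtype=np.int64),
    )


def assignment(parts, n_parts=None):
    parts = np.asarray(parts)
    if n_parts is None:
        n_parts = int(parts.max()) + 1 if len(parts) else 1
    return Assignment(parts.astype(np.int32), n_parts)
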