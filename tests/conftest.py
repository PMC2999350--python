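from __future__ import annotations

import itertools

import numpy as np
import pytest

from netonco.interactome import Interactome, InteractionRecord, ProteinSet, build_interactome


def make_net(edges, isolated=()):
    """Interactome from a list of (a, b) pairs plus optional isolated nodes."""
    net = build_interactome([InteractionRecord(a, b) for a, b in edges])
    for v in isolated:
        net.graph.add_node(v)
    return net


def make_set(members, name="s"):
    members = frozenset(members)
    return ProteinSet(name=name, genes=members, mapped=members)


def random_edges(rng, n_nodes, p=0.35):
    """Random simple-graph edge list over string node ids."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = [
        (a, b)
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p
    ]
    return nodes, edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world shared by read-only tests."""
    from netonco.synthetic import generate_world

    return generate_world(
        n=400,
        model="pa",
        model_params={"m_attach": 4},
        set_specs=[
            {"name": "cancer", "size": 60, "alpha": 1.5},
            {"name": "uniform", "size": 60, "alpha": 0.0},
        ],
        catalog_spec={
            "n_pathways": 24,
            "size_range": (8, 30),
            "enriched_in": "cancer",
            "n_enriched": 4,
            "enrichment_factor": 20.0,
        },
        seed=11,
    )
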