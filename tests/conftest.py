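import itertools

import networkx as nx
import numpy as np
import pytest

from chromnet.intervals import GenomicInterval
from chromnet.network import ChromatinNetwork, NetworkEdge, NetworkNode
from chromnet.topology import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_network(edges, labels=None, spacing=10_000, chrom="chr1"):
    """Small test network: nodes placed ``spacing`` bp apart on one chromosome."""
    node_ids = sorted({n for e in edges for n in e[:2]})
    labels = labels or {}
    nodes = [
        NetworkNode(
            i,
            GenomicInterval(chrom, 1000 + i * spacing, 1500 + i * spacing),
            labels.get(i, "unassigned"),
        )
        for i in node_ids
    ]
    es = [NetworkEdge(e[0], e[1], e[2] if len(e) > 2 else 1) for e in edges]
    return ChromatinNetwork(nodes, es)


@pytest.fixture
def toy_network():
    # two components: a path a-b-c and an edge d-e
    return make_network([(0, 1), (1, 2), (3, 4)])


# ---------------------------------------------------------------------------
# independent oracles


def orbit_counts_oracle(g: nx.Graph, catalog):
    """Exhaustive orbit counting: enumerate every vertex subset of size 2-5,
    keep connected induced subgraphs, classify by isomorphism against the
    catalog and read off each vertex's orbit through an explicit mapping."""
    counts = {v: np.zeros(catalog.n_orbits, dtype=int) for v in g.nodes}
    by_shape = {}
    for gl in catalog.graphlets:
        key = (gl.graph.number_of_nodes(), gl.graph.number_of_edges())
        by_shape.setdefault(key, []).append(gl)
    nodes = sorted(g.nodes)
    for k in range(2, 6):
        for subset in itertools.combinations(nodes, k):
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            for gl in by_shape.get((k, sub.number_of_edges()), []):
                matcher = nx.algorithms.isomorphism.GraphMatcher(sub, gl.graph)
                if matcher.is_isomorphic():
                    for v, w in matcher.mapping.items():
                        counts[v][gl.vertex_orbit[w]] += 1
                    break
            else:  # pragma: no cover - catalog is exhaustive
                raise AssertionError("subgraph matched no graphlet")
    return counts


def centralities_oracle(g: nx.Graph):
    """Brute-force closeness/harmonic/betweenness via explicit path enumeration."""
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nodes = sorted(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        # all shortest paths per unordered pair
        paths = {}
        for u, x in itertools.combinations(nodes, 2):
            paths[(u, x)] = list(nx.all_shortest_paths(sub, u, x))
        for v in nodes:
            total = sum(dist[v][u] for u in nodes)
            harm = sum(1.0 / dist[v][u] for u in nodes if u != v)
            btw = 0.0
            for (u, x), ps in paths.items():
                if v in (u, x):
                    continue
                btw += sum(1 for p in ps if v in p) / len(ps)
            out[v] = {
                "closeness": 1.0 / total if total else 0.0,
                "harmonic": harm,
                "betweenness": btw,
                "component_size": len(nodes),
            }
    return out


def components_oracle(edges):
    """Union-find connected components over an edge list."""
    parent = {}

    def find(v):
        parent.setdefault(v, v)
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for v in list(parent):
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=min)
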