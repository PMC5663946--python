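"""Network topology: centrality measures, graphlet orbit signatures, orbit
clustering and per-node cluster scores.

Centralities are computed within each connected component with unweighted
shortest-path distances:

* closeness(v)   = 1 / sum_u nd(u, v)
* harmonic(v)    = sum_{u != v} 1 / nd(u, v)
* betweenness(v) = sum_{u != v != x} |sp(u, x, v)| / |sp(u, x)| over unordered
  pairs {u, x}, where sp(u, x, v) are shortest u-x paths through v

with normalized variants taken with respect to the component size |N_c|.

Graphlets are the 30 connected non-isomorphic graphs on 2-5 vertices; their
vertex automorphism classes give 73 orbits. Per node, the orbit signature
counts, for every induced connected subgraph of size 2-5 containing the node,
the orbit the node occupies. Orbits are clustered by 1 - Spearman correlation
of their per-node scores (average linkage), and each node receives one score
per orbit cluster: the maximum z-score over the cluster's member orbits.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .network import ChromatinNetwork

logger = logging.getLogger(__name__)

N_ORBITS = 73
N_GRAPHLETS = 30

#: Sentinel cluster id for orbits that carry no signal in the data.
DEGENERATE_CLUSTER = 0


# ---------------------------------------------------------------------------
# centralities


@dataclass
class CentralityRecord:
    node_id: int
    degree: int
    closeness: float
    harmonic: float
    betweenness: float
    degree_norm: float
    closeness_norm: float
    harmonic_norm: float
    betweenness_norm: float
    component_size: int


def centralities(net: ChromatinNetwork) -> dict[int, CentralityRecord]:
    """Raw and component-size-normalized centralities for every node."""
    g = net.graph()
    out: dict[int, CentralityRecord] = {}
    for comp in net.components:
        sub = g.subgraph(comp)
        n = len(comp)
        # raw betweenness: unordered pair sum, endpoints excluded
        btw = nx.betweenness_centrality(sub, normalized=False)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        for v in comp:
            total = sum(dist[v].values())
            close = 1.0 / total if total > 0 else 0.0
            harm = sum(1.0 / d for u, d in dist[v].items() if u != v)
            deg = sub.degree(v)
            pair_norm = (n - 1) * (n - 2) / 2.0
            out[v] = CentralityRecord(
                node_id=v,
                degree=deg,
                closeness=close,
                harmonic=harm,
                betweenness=btw[v],
                degree_norm=deg / (n - 1) if n > 1 else 0.0,
                closeness_norm=close * (n - 1),
                harmonic_norm=harm / (n - 1) if n > 1 else 0.0,
                betweenness_norm=btw[v] / pair_norm if pair_norm > 0 else 0.0,
                component_size=n,
            )
    return out


# ---------------------------------------------------------------------------
# orbit catalog


def _edge_order(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def _mask_to_graph(n: int, mask: int) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for b, (i, j) in enumerate(_edge_order(n)):
        if mask >> b & 1:
            g.add_edge(i, j)
    return g


def _graph_to_mask(n: int, g: nx.Graph) -> int:
    mask = 0
    for b, (i, j) in enumerate(_edge_order(n)):
        if g.has_edge(i, j):
            mask |= 1 << b
    return mask


def _perm_bit_weights(n: int) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """For each vertex permutation, the weight vector mapping source edge bits
    to their relabeled bit values, so ``bits @ W[:, p]`` remaps a mask."""
    edges = _edge_order(n)
    bit_of = {e: b for b, e in enumerate(edges)}
    perms = list(itertools.permutations(range(n)))
    W = np.zeros((len(edges), len(perms)), dtype=np.int64)
    for pi, p in enumerate(perms):
        for b, (i, j) in enumerate(edges):
            a, c = p[i], p[j]
            if a > c:
                a, c = c, a
            W[b, pi] = 1 << bit_of[(a, c)]
    return perms, W


def _remap_mask(mask: int, perm: tuple[int, ...], n: int) -> int:
    edges = _edge_order(n)
    bit_of = {e: b for b, e in enumerate(edges)}
    out = 0
    for b, (i, j) in enumerate(edges):
        if mask >> b & 1:
            a, c = perm[i], perm[j]
            if a > c:
                a, c = c, a
            out |= 1 << bit_of[(a, c)]
    return out


@dataclass
class Graphlet:
    graphlet_id: int
    graph: nx.Graph
    #: vertex -> orbit index (global, 0..72)
    vertex_orbit: dict[int, int]
    orbit_ids: list[int]


@dataclass
class OrbitCatalog:
    graphlets: list[Graphlet]
    n_orbits: int
    #: (n, adjacency mask over sorted local vertices) -> per-vertex orbit ids
    _lookup: dict[tuple[int, int], tuple[int, ...]] = field(repr=False, default_factory=dict)


def _automorphism_orbits(n: int, mask: int, perms) -> list[list[int]]:
    """Vertex classes under the automorphism group of the graph ``mask``."""
    parent = list(range(n))

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for p in perms:
        if _remap_mask(mask, p, n) != mask:
            continue
        for a in range(n):
            ra, rb = find(a), find(p[a])
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for v in range(n):
        groups.setdefault(find(v), []).append(v)
    return sorted((sorted(vs) for vs in groups.values()), key=lambda vs: vs[0])


def build_orbit_catalog() -> OrbitCatalog:
    """Enumerate all connected non-isomorphic graphs on 2-5 vertices and their
    automorphism orbits.

    Graphlets are ordered by (vertex count, edge count, canonical adjacency
    form); orbits within a graphlet are ordered by increasing member degree.
    This places the single edge at orbit 0, the 3-path ends/middle at orbits
    1/2, the triangle at orbit 3 and the 5-clique at orbit 72.
    """
    graphlets: list[Graphlet] = []
    orbit_counter = 0
    lookup: dict[tuple[int, int], tuple[int, ...]] = {}
    for n in range(2, 6):
        n_bits = len(_edge_order(n))
        perms, W = _perm_bit_weights(n)
        masks = np.arange(1 << n_bits, dtype=np.int64)
        bits = (masks[:, None] >> np.arange(n_bits)) & 1
        connected = np.array(
            [nx.is_connected(_mask_to_graph(n, int(m))) for m in masks], dtype=bool
        )
        canonical = (bits @ W).min(axis=1)

        def sort_key(canon: int) -> tuple:
            g = _mask_to_graph(n, canon)
            degseq = tuple(sorted((d for _, d in g.degree()), reverse=True))
            return (g.number_of_edges(), degseq, canon)

        canon_set = sorted({int(c) for c, ok in zip(canonical, connected) if ok}, key=sort_key)
        for canon in canon_set:
            g = _mask_to_graph(n, canon)
            orbits = _automorphism_orbits(n, canon, perms)
            # order orbits by the degree of their members (ties by smallest vertex)
            orbits.sort(key=lambda vs: (g.degree(vs[0]), vs[0]))
            vertex_orbit: dict[int, int] = {}
            orbit_ids = []
            for vs in orbits:
                for v in vs:
                    vertex_orbit[v] = orbit_counter
                orbit_ids.append(orbit_counter)
                orbit_counter += 1
            gid = len(graphlets)
            graphlets.append(Graphlet(gid, g, vertex_orbit, orbit_ids))
            # every labeled isomorph of the canonical graph feeds the lookup:
            # position p[v] in the relabeled graph is canonical vertex v
            for p in perms:
                labeled = _remap_mask(canon, p, n)
                if (n, labeled) in lookup:
                    continue
                pos_orbit = [0] * n
                for v in range(n):
                    pos_orbit[p[v]] = vertex_orbit[v]
                lookup[(n, labeled)] = tuple(pos_orbit)
    catalog = OrbitCatalog(graphlets, orbit_counter, lookup)
    if orbit_counter != N_ORBITS or len(graphlets) != N_GRAPHLETS:
        logger.warning(
            "catalog has %d graphlets / %d orbits", len(graphlets), orbit_counter
        )
    return catalog


_CATALOG: OrbitCatalog | None = None


def default_catalog() -> OrbitCatalog:
    """Module-level cached catalog (construction takes a few seconds)."""
    global _CATALOG
    if _CATALOG is None:
        _CATALOG = build_orbit_catalog()
    return _CATALOG


# ---------------------------------------------------------------------------
# orbit counting


@dataclass
class OrbitSignature:
    node_id: int
    counts: np.ndarray  # length 73, int
    proportions: np.ndarray  # length 73, sums to 1 (all zero if no counts)


def _connected_subgraphs(adj: dict[int, set[int]], max_size: int):
    """Yield every connected vertex subset of size 2..max_size exactly once.

    ESU-style enumeration: subsets are grown only with exclusive neighbors
    carrying a larger id than the root, so each subset is produced once.
    """
    for v in sorted(adj):
        sub = [v]
        ext = sorted(u for u in adj[v] if u > v)
        yield from _extend(adj, sub, ext, v, max_size)


def _extend(adj, sub, ext, root, max_size):
    while ext:
        w = ext.pop()
        new_sub = sub + [w]
        if len(new_sub) >= 2:
            yield new_sub
        if len(new_sub) < max_size:
            in_or_near = set(sub)
            for s in sub:
                in_or_near |= adj[s]
            new_ext = ext + [
                u for u in adj[w] if u > root and u not in in_or_near and u != w
            ]
            yield from _extend(adj, new_sub, new_ext, root, max_size)


def count_orbits(
    net: ChromatinNetwork | nx.Graph, catalog: OrbitCatalog | None = None
) -> dict[int, OrbitSignature]:
    """Per-node 73-orbit counts over all induced connected subgraphs of size 2-5."""
    if catalog is None:
        catalog = default_catalog()
    if isinstance(net, ChromatinNetwork):
        adj = {nid: set(nbrs) for nid, nbrs in net.adjacency().items()}
    else:
        adj = {v: set(net.neighbors(v)) for v in net.nodes}
    counts = {v: np.zeros(N_ORBITS, dtype=np.int64) for v in adj}
    lookup = catalog._lookup
    for sub in _connected_subgraphs(adj, 5):
        k = len(sub)
        s = sorted(sub)
        mask = 0
        b = 0
        for ii in range(k):
            si = s[ii]
            nbrs = adj[si]
            for jj in range(ii + 1, k):
                if s[jj] in nbrs:
                    mask |= 1 << b
                b += 1
        orbits = lookup[(k, mask)]
        for pos in range(k):
            counts[s[pos]][orbits[pos]] += 1
    out = {}
    for v, c in counts.items():
        total = c.sum()
        props = c / total if total > 0 else np.zeros(N_ORBITS)
        out[v] = OrbitSignature(v, c, props)
    return out


def signature_matrix(signatures: dict[int, OrbitSignature]) -> tuple[list[int], np.ndarray]:
    """(node ids, nodes x 73 proportion matrix) in ascending node-id order."""
    ids = sorted(signatures)
    mat = np.vstack([signatures[i].proportions for i in ids])
    return ids, mat


# ---------------------------------------------------------------------------
# orbit clustering and cluster scores


@dataclass
class OrbitClustering:
    #: orbit index -> cluster id (1..K); DEGENERATE_CLUSTER for empty orbits
    assignment: dict[int, int]
    cutoff: float | None
    linkage: str = "average"
    excluded: tuple[int, ...] = (0, 1)

    @property
    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for orbit, cid in sorted(self.assignment.items()):
            out.setdefault(cid, []).append(orbit)
        return out

    @property
    def n_clusters(self) -> int:
        return len([c for c in self.clusters if c != DEGENERATE_CLUSTER])


def cluster_orbits(
    signatures: dict[int, OrbitSignature],
    cutoff: float = 0.3,
    n_clusters: int | None = None,
    exclude: tuple[int, ...] = (0, 1),
) -> OrbitClustering:
    """Agglomerative clustering of orbits by Spearman correlation of their
    per-node proportions.

    Orbits 0 and 1 (edge endpoint and path end) are excluded by default: they
    are present with similar scores for essentially every node. Distance is
    1 - Spearman rho, linkage is average; the tree is cut at distance
    ``1 - cutoff``, or into exactly ``n_clusters`` clusters when that is given
    (useful when downstream consumers require a fixed score count). Orbits with
    zero variance across nodes go to the sentinel degenerate cluster 0.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two nodes to cluster orbits")
    _, mat = signature_matrix(signatures)
    retained = [j for j in range(N_ORBITS) if j not in exclude]
    sub = mat[:, retained]
    variable = [
        retained[k] for k in range(len(retained)) if np.ptp(sub[:, k]) > 0
    ]
    degenerate = [j for j in retained if j not in variable]
    if degenerate:
        logger.info("%d orbits carry no signal; assigned to degenerate cluster", len(degenerate))
    assignment = {j: DEGENERATE_CLUSTER for j in degenerate}
    if len(variable) == 0:
        return OrbitClustering(assignment, cutoff, excluded=tuple(exclude))
    if len(variable) == 1:
        assignment[variable[0]] = 1
        return OrbitClustering(assignment, cutoff, excluded=tuple(exclude))

    if len(variable) == 2:
        r = float(spearmanr(mat[:, variable[0]], mat[:, variable[1]]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.atleast_2d(spearmanr(mat[:, variable]).statistic)
    np.fill_diagonal(rho, 1.0)
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(link, t=1.0 - cutoff, criterion="distance")

    # renumber clusters by the first orbit index they contain
    first_orbit: dict[int, int] = {}
    for k, orbit in zip(flat, variable):
        first_orbit.setdefault(int(k), orbit)
    order = sorted(first_orbit, key=lambda k: first_orbit[k])
    renum = {k: i + 1 for i, k in enumerate(order)}
    for k, orbit in zip(flat, variable):
        assignment[orbit] = renum[int(k)]
    return OrbitClustering(assignment, None if n_clusters else cutoff, excluded=tuple(exclude))


def cluster_scores(
    signatures: dict[int, OrbitSignature], clustering: OrbitClustering
) -> dict[int, dict[int, float]]:
    """Per node, the maximum z-score over each cluster's member orbits.

    The z-score of orbit j for node i is (O_ij - mu_j) / sigma_j on the
    normalized proportions, with mu/sigma taken over all nodes (population
    standard deviation). A zero-variance orbit contributes z = 0. The
    degenerate cluster receives no score.
    """
    ids, mat = signature_matrix(signatures)
    mu = mat.mean(axis=0)
    sigma = mat.std(axis=0)  # population SD
    z = np.zeros_like(mat)
    nonzero = sigma > 0
    z[:, nonzero] = (mat[:, nonzero] - mu[nonzero]) / sigma[nonzero]
    out: dict[int, dict[int, float]] = {}
    clusters = clustering.clusters
    for row, nid in enumerate(ids):
        scores = {}
        for cid, orbits in clusters.items():
            if cid == DEGENERATE_CLUSTER:
                continue
            scores[cid] = float(z[row, orbits].max())
        out[nid] = scores
    return out


def write_signatures_tsv(path, signatures: dict[int, OrbitSignature]) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\t" + "\t".join(f"orbit_{j}" for j in range(N_ORBITS)) + "\n")
        for nid in sorted(signatures):
            fh.write(str(nid) + "\t" + "\t".join(map(str, signatures[nid].counts.tolist())) + "\n")


def write_cluster_map_tsv(path, clustering: OrbitClustering) -> None:
    with open(path, "w") as fh:
        fh.write("orbit\tcluster\n")
        for orbit, cid in sorted(clustering.assignment.items()):
            fh.write(f"{orbit}\t{cid}\n")


def read_cluster_map_tsv(path) -> OrbitClustering:
    """Load a fixed orbit -> cluster map (for cross-dataset comparability)."""
    assignment: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("orbit"):
                continue
            orbit, cid = line.split()
            assignment[int(orbit)] = int(cid)
    return OrbitClustering(assignment, cutoff=None)
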