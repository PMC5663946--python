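import math

import networkx as nx
import numpy as np
import pytest

from chromnet.topology import (
    DEGENERATE_CLUSTER,
    OrbitSignature,
    build_orbit_catalog,
    centralities,
    cluster_orbits,
    cluster_scores,
    count_orbits,
    signature_matrix,
)

from conftest import centralities_oracle, make_network, orbit_counts_oracle


class TestCentralities:
    def test_path_of_three_closed_forms(self):
        net = make_network([(0, 1), (1, 2)])
        c = centralities(net)
        assert c[1].closeness == pytest.approx(1 / 2)
        assert c[1].harmonic == pytest.approx(2.0)
        assert c[1].betweenness == pytest.approx(1.0)
        assert c[0].closeness == pytest.approx(1 / 3)
        assert c[0].harmonic == pytest.approx(1.5)
        assert c[0].betweenness == pytest.approx(0.0)

    def test_triangle_symmetry(self):
        net = make_network([(0, 1), (1, 2), (0, 2)])
        c = centralities(net)
        for v in range(3):
            assert c[v].betweenness == 0.0
            assert c[v].harmonic == pytest.approx(2.0)

    def test_normalization(self):
        net = make_network([(0, 1), (1, 2)])
        c = centralities(net)
        assert c[1].degree_norm == pytest.approx(1.0)
        assert c[1].closeness_norm == pytest.approx(1.0)
        assert c[1].harmonic_norm == pytest.approx(1.0)
        assert c[1].betweenness_norm == pytest.approx(1.0)
        # two-node component: betweenness normalization denominator vanishes
        net2 = make_network([(0, 1)])
        assert centralities(net2)[0].betweenness_norm == 0.0

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(12):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            net = make_network(sorted(g.edges))
            got = centralities(net)
            want = centralities_oracle(net.graph())
            for v in want:
                assert got[v].closeness == pytest.approx(want[v]["closeness"])
                assert got[v].harmonic == pytest.approx(want[v]["harmonic"])
                assert got[v].betweenness == pytest.approx(want[v]["betweenness"])
                assert got[v].component_size == want[v]["component_size"]


class TestOrbitCatalog:
    def test_thirty_graphlets_and_73_orbits(self, catalog):
        assert len(catalog.graphlets) == 30
        assert catalog.n_orbits == 73

    def test_orbits_partition_vertices(self, catalog):
        for gl in catalog.graphlets:
            seen = sorted(gl.vertex_orbit.keys())
            assert seen == sorted(gl.graph.nodes)

    def test_anchor_orbits_match_standard_numbering(self, catalog):
        # edge endpoint = orbit 0; path end/mid = 1/2; triangle = 3;
        # 4-path ends/mid = 4/5; 4-star leaf/center = 6/7; 4-cycle = 8;
        # 4-clique = 14; 5-clique = 72
        g0 = catalog.graphlets[0]
        assert set(g0.orbit_ids) == {0}
        g1 = catalog.graphlets[1]  # 3-path
        assert g1.orbit_ids == [1, 2]
        g2 = catalog.graphlets[2]  # triangle
        assert g2.orbit_ids == [3]
        assert catalog.graphlets[8].orbit_ids == [14]  # 4-clique
        assert catalog.graphlets[29].orbit_ids == [72]  # 5-clique

    def test_vertex_transitive_graphlets_have_one_orbit(self, catalog):
        for gl in catalog.graphlets:
            n = gl.graph.number_of_nodes()
            m = gl.graph.number_of_edges()
            if m == n * (n - 1) // 2:  # complete graph
                assert len(gl.orbit_ids) == 1

    def test_deterministic_rebuild(self, catalog):
        again = build_orbit_catalog()
        assert [gl.orbit_ids for gl in again.graphlets] == [
            gl.orbit_ids for gl in catalog.graphlets
        ]


class TestCountOrbits:
    def test_triangle_counts(self, catalog):
        sigs = count_orbits(nx.complete_graph(3), catalog)
        for v in range(3):
            c = sigs[v].counts
            assert c[0] == 2 and c[3] == 1
            assert c[1] == 0 and c[2] == 0  # only induced 3-set is the triangle

    def test_five_clique_counts(self, catalog):
        sigs = count_orbits(nx.complete_graph(5), catalog)
        c = sigs[0].counts
        assert c[72] == 1
        assert c[14] == math.comb(4, 3)  # 4-cliques through a vertex

    def test_star_center_path_middles(self, catalog):
        sigs = count_orbits(nx.star_graph(3), catalog)
        assert sigs[0].counts[2] == math.comb(3, 2)

    def test_counts0_equals_degree(self, catalog):
        g = nx.gnp_random_graph(15, 0.3, seed=5)
        sigs = count_orbits(g, catalog)
        for v, s in sigs.items():
            assert s.counts[0] == g.degree(v)

    def test_matches_exhaustive_oracle(self, catalog):
        rng = np.random.default_rng(1)
        for _ in range(6):
            g = nx.gnp_random_graph(9, float(rng.uniform(0.2, 0.5)), seed=int(rng.integers(1 << 30)))
            sigs = count_orbits(g, catalog)
            want = orbit_counts_oracle(g, catalog)
            for v in g.nodes:
                assert np.array_equal(sigs[v].counts, want[v]), f"node {v}"

    def test_isomorphism_invariance(self, catalog):
        g = nx.gnp_random_graph(10, 0.35, seed=9)
        perm = {v: (v * 7 + 3) % 10 for v in g.nodes}
        h = nx.relabel_nodes(g, perm)
        sg = count_orbits(g, catalog)
        sh = count_orbits(h, catalog)
        for v in g.nodes:
            assert np.array_equal(sg[v].counts, sh[perm[v]].counts)

    def test_graphlet_totals_consistent_across_orbits(self, catalog):
        # summed vertex counts of each orbit, divided by the orbit's vertex
        # multiplicity, give the same total per graphlet
        g = nx.gnp_random_graph(11, 0.35, seed=11)
        sigs = count_orbits(g, catalog)
        totals = {v: s.counts for v, s in sigs.items()}
        summed = np.sum(list(totals.values()), axis=0)
        for gl in catalog.graphlets:
            per_orbit = []
            for oid in gl.orbit_ids:
                members = [v for v, o in gl.vertex_orbit.items() if o == oid]
                per_orbit.append(summed[oid] / len(members))
            assert len(set(per_orbit)) == 1

    def test_proportions_sum_to_one(self, catalog):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        for s in count_orbits(g, catalog).values():
            assert s.proportions.sum() == pytest.approx(1.0)


def _signatures_from_matrix(mat):
    return {
        i: OrbitSignature(i, mat[i].astype(int), mat[i] / max(mat[i].sum(), 1))
        for i in range(mat.shape[0])
    }


class TestClusterOrbits:
    def test_identical_orbits_cluster_together(self):
        rng = np.random.default_rng(0)
        mat = np.zeros((30, 73))
        base = rng.random(30)
        mat[:, 5] = base
        mat[:, 6] = base  # identical profile
        mat[:, 7] = rng.random(30)
        sigs = _signatures_from_matrix((mat * 100).astype(int) + 1)
        clustering = cluster_orbits(sigs, cutoff=0.9)
        assert clustering.assignment[5] == clustering.assignment[6]

    def test_anticorrelated_orbits_split(self):
        n = 40
        up = np.arange(n, dtype=float) + 1
        mat = np.zeros((n, 73))
        mat[:, 10] = up
        mat[:, 11] = up[::-1]  # rho = -1
        sigs = _signatures_from_matrix(mat.astype(int) + 1)
        clustering = cluster_orbits(sigs, cutoff=0.3)
        assert clustering.assignment[10] != clustering.assignment[11]

    def test_degenerate_orbits_flagged(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(1, 50, size=(20, 73)).astype(float)
        mat[:, 40] = 0.0
        sigs = _signatures_from_matrix(mat)
        clustering = cluster_orbits(sigs, cutoff=0.3)
        # proportions of orbit 40 are 0 for all nodes -> degenerate
        assert clustering.assignment[40] == DEGENERATE_CLUSTER

    def test_excluded_orbits_absent(self):
        rng = np.random.default_rng(3)
        sigs = _signatures_from_matrix(rng.integers(1, 50, size=(20, 73)).astype(float))
        clustering = cluster_orbits(sigs, cutoff=0.3)
        assert 0 not in clustering.assignment and 1 not in clustering.assignment

    def test_fixed_cluster_count_cut(self):
        rng = np.random.default_rng(4)
        sigs = _signatures_from_matrix(rng.integers(1, 50, size=(40, 73)).astype(float))
        clustering = cluster_orbits(sigs, n_clusters=7)
        assert clustering.n_clusters == 7


class TestClusterScores:
    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        mat = rng.integers(1, 30, size=(25, 73)).astype(float)
        sigs = _signatures_from_matrix(mat)
        clustering = cluster_orbits(sigs, n_clusters=5)
        scores = cluster_scores(sigs, clustering)
        ids, props = signature_matrix(sigs)
        mu = props.mean(axis=0)
        sd = props.std(axis=0)
        for cid, orbits in clustering.clusters.items():
            if cid == DEGENERATE_CLUSTER:
                continue
            for row, nid in enumerate(ids):
                zs = [
                    (props[row, j] - mu[j]) / sd[j] if sd[j] > 0 else 0.0 for j in orbits
                ]
                assert scores[nid][cid] == pytest.approx(max(zs))

    def test_node_at_population_mean_scores_zero(self):
        mat = np.ones((10, 73)) * 7
        mat[0, 10] = 14  # one deviant node so orbits are not all degenerate
        sigs = _signatures_from_matrix(mat)
        clustering = cluster_orbits(sigs, n_clusters=1)
        scores = cluster_scores(sigs, clustering)
        # every other node sits below the mean of the only varying orbit
        assert scores[0][1] > 0
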