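"""Median-joining network construction vs spanning-network oracles."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from ylineage.network import (
    annotate_clusters,
    build_network,
    derive_weights,
    minimum_spanning_network,
    network_from_dataset,
)


def haps(*vectors):
    """Observed haplotype map with multiplicity 1 each (values in tenths)."""
    return {tuple(v): (1, (f"s{i}",)) for i, v in enumerate(vectors)}


class TestDeriveWeights:
    def test_equal_rates_equal_weights(self):
        w = derive_weights({"a": 0.004, "b": 0.004, "c": 0.004})
        assert set(w.values()) == {99}

    def test_decade_spread_hand_oracle(self):
        w = derive_weights({"slow": 1e-4, "mid": 1e-3, "fast": 1e-2})
        assert (w["slow"], w["mid"], w["fast"]) == (99, 10, 1)

    def test_scale_invariance(self):
        r = {"a": 3.78e-4, "b": 2.3e-3, "c": 1.84e-2}
        assert derive_weights(r) == derive_weights({k: 2 * v for k, v in r.items()})

    def test_anti_monotone_with_rates(self):
        from ylineage.loci import DEFAULT_MUTATION_RATES

        w = derive_weights(DEFAULT_MUTATION_RATES)
        pairs = sorted(DEFAULT_MUTATION_RATES.items(), key=lambda kv: kv[1])
        for (l1, r1), (l2, r2) in zip(pairs, pairs[1:]):
            assert w[l1] >= w[l2]
        assert all(1 <= x <= 99 for x in w.values())

    def test_positive_rates_required(self):
        with pytest.raises(ValueError):
            derive_weights({"a": 0.0})


# brute-force MSN oracle: enumerate every spanning tree, union the minimal ones
def msn_oracle(vectors, weights):
    n = len(vectors)
    def dist(u, v):
        return sum(w * abs(a - b) for w, a, b in zip(weights, u, v))

    all_edges = list(combinations(range(n), 2))
    best = None
    union: set[tuple[int, int]] = set()
    for tree_edges in combinations(all_edges, n - 1):
        g = nx.Graph(tree_edges)
        if g.number_of_nodes() != n or not nx.is_connected(g):
            continue
        total = sum(dist(vectors[i], vectors[j]) for i, j in tree_edges)
        if best is None or total < best:
            best = total
            union = set(tree_edges)
        elif total == best:
            union |= set(tree_edges)
    return union


class TestMinimumSpanningNetwork:
    def test_equals_union_of_all_msts_exhaustive(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(3, 7))
            L = int(rng.integers(1, 4))
            vectors = [tuple(int(x) * 10 for x in rng.integers(10, 14, L)) for _ in range(n)]
            # distinct vectors only: identical haplotypes collapse upstream
            if len(set(vectors)) != n:
                continue
            w = tuple(int(x) for x in rng.integers(1, 5, L))
            got = minimum_spanning_network(vectors, w, epsilon=0)
            want = msn_oracle(vectors, w)
            assert got == want

    def test_epsilon_adds_near_minimal_links(self):
        # path 0 - 10 - 21: direct 0-21 edge is within eps=1 of the 11 link
        vectors = [(0,), (10,), (21,)]
        w = (1,)
        assert minimum_spanning_network(vectors, w, 0) == {(0, 1), (1, 2)}
        relaxed = minimum_spanning_network(vectors, w, 11)
        assert (0, 2) in relaxed

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            minimum_spanning_network([(0,), (1,)], (1,), epsilon=-1)


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        mj = build_network(haps([100], [120]), ("L1",), {"L1": 1})
        assert len(mj.graph) == 2
        assert mj.graph.number_of_edges() == 1
        assert mj.medians == []

    def test_star_median_inferred_for_three_way_split(self):
        # B, C, D pairwise differ at two loci; their coordinatewise median
        # (the unobserved ancestral vector) shortens the connection
        B, C, D = [110, 100, 100], [100, 110, 100], [100, 100, 110]
        loci = ("L1", "L2", "L3")
        w = {"L1": 1, "L2": 1, "L3": 1}
        mj = build_network(haps(B, C, D), loci, w)
        assert (100, 100, 100) in mj.medians
        assert mj.spanning_length() == 30  # 3 spokes of 10 vs MST 40

    def test_observed_center_means_no_median_needed(self):
        A, B, C, D = (
            [100, 100, 100],
            [110, 100, 100],
            [100, 110, 100],
            [100, 100, 110],
        )
        loci = ("L1", "L2", "L3")
        w = {"L1": 1, "L2": 1, "L3": 1}
        mj = build_network(haps(A, B, C, D), loci, w)
        assert mj.medians == []
        center = (100, 100, 100)
        assert all(center in e for e in mj.graph.edges)

    def test_no_cost_reducing_median_gives_msn_exactly(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(3, 7))
            L = int(rng.integers(1, 4))
            vectors = [
                tuple(int(x) * 10 for x in rng.integers(10, 14, L))
                for _ in range(n)
            ]
            if len(set(vectors)) != n:
                continue
            w = {f"L{i}": int(x) for i, x in enumerate(rng.integers(1, 5, L))}
            loci = tuple(sorted(w))
            wt = tuple(w[l] for l in loci)
            mj = build_network(haps(*vectors), loci, w)
            if mj.medians:
                continue  # medians were cost-reducing; covered elsewhere
            got = {frozenset(e) for e in mj.graph.edges}
            vecs_sorted = sorted(set(map(tuple, vectors)))
            oracle = {
                frozenset((vecs_sorted[i], vecs_sorted[j]))
                for i, j in msn_oracle(vecs_sorted, wt)
            }
            assert got == oracle
            checked += 1
        assert checked >= 10

    def test_observed_nodes_never_deleted(self, qr_network):
        ds, _ = qr_network
        mj = network_from_dataset(ds)
        observed_keys = set(mj.observed)
        distinct = set()
        for s in ds:
            vec = tuple(
                a.tenths
                for l in ds.panel
                if l.copy_number == 1
                for a in s.haplotype.calls[l.name].alleles
            )
            distinct.add(vec)
        assert distinct == observed_keys
        assert nx.is_connected(mj.graph)

    def test_spanning_length_not_above_observed_mst(self, qr_network):
        ds, _ = qr_network
        mj = network_from_dataset(ds)
        obs = sorted(mj.observed)
        w = mj.weights
        g = nx.Graph()
        for i, j in combinations(range(len(obs)), 2):
            d = sum(wi * abs(a - b) for wi, a, b in zip(w, obs[i], obs[j]))
            g.add_edge(i, j, weight=d)
        mst_len = sum(
            d["weight"]
            for _, _, d in nx.minimum_spanning_tree(g).edges(data=True)
        )
        assert mj.spanning_length() <= mst_len

    def test_input_order_invariance(self):
        rng = np.random.default_rng(31)
        vectors = [tuple(int(x) * 10 for x in rng.integers(10, 14, 3)) for _ in range(6)]
        vectors = list(dict.fromkeys(vectors))
        w = {"L0": 2, "L1": 1, "L2": 3}
        loci = ("L0", "L1", "L2")
        mj1 = build_network(haps(*vectors), loci, w)
        mj2 = build_network(haps(*reversed(vectors)), loci, w)
        assert set(mj1.graph.nodes) == set(mj2.graph.nodes)
        assert {frozenset(e) for e in mj1.graph.edges} == {
            frozenset(e) for e in mj2.graph.edges
        }

    def test_graph_exports_round_trip(self, tmp_path, qr_network):
        ds, _ = qr_network
        mj = network_from_dataset(ds)
        mj.write_gml(tmp_path / "g.gml")
        mj.write_dot(tmp_path / "g.dot")
        mj.write_tables(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        back = nx.read_gml(tmp_path / "g.gml")
        assert len(back) == len(mj.graph)
        assert back.number_of_edges() == mj.graph.number_of_edges()
        assert "graph mj {" in (tmp_path / "g.dot").read_text()

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            build_network(haps([100]), ("L1",), {"L1": 1})


class TestAnnotateClusters:
    def test_no_carriers_empty(self):
        mj = build_network(haps([100, 100], [120, 100]), ("DYS518", "L2"), {"DYS518": 1, "L2": 1})
        rep = annotate_clusters(mj, "DYS518")
        assert rep.carrier_nodes == () and rep.n_components == 0

    def test_all_carriers_single_component(self):
        mj = build_network(
            haps([102, 100], [122, 100]), ("DYS518", "L2"), {"DYS518": 1, "L2": 1}
        )
        rep = annotate_clusters(mj, "DYS518")
        assert rep.n_components == 1
        assert len(rep.carrier_nodes) == len(mj.graph)
        assert rep.boundary_edges == ()

    def test_unknown_locus_rejected(self):
        mj = build_network(haps([100], [120]), ("L1",), {"L1": 1})
        with pytest.raises(KeyError):
            annotate_clusters(mj, "DYS999")

    def test_single_origin_variant_forms_one_component(self, qr_network):
        ds, truth = qr_network
        mj = network_from_dataset(ds)
        rep = annotate_clusters(mj, "DYS518")
        assert rep.n_components == 1
        carrier_samples = {
            sid
            for node in rep.carrier_nodes
            for sid in mj.graph.nodes[node]["sample_ids"]
        }
        assert carrier_samples == set(truth.variant_carriers)
        assert len(rep.boundary_edges) >= 1
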