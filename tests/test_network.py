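import itertools

import networkx as nx
import numpy as np
import pytest

from unipargen import network as net


def _mst_oracle(haplos, mode="categorical"):
    """Independent MST of observed haplotypes via networkx on raw distances."""
    g = nx.Graph()
    for a, b in itertools.combinations(haplos, 2):
        if mode == "categorical":
            d = sum(x != y for x, y in zip(a, b))
        else:
            d = sum(abs(x - y) for x, y in zip(a, b))
        g.add_edge(a, b, weight=d)
    return nx.minimum_spanning_tree(g)


def _contains_mst(hg, haplos, mode="categorical"):
    """The network is connected, keeps every observed haplotype, and
    contains an independently computed MST of its full node set (the
    epsilon=0 spanning network is the union of all MSTs, so any one MST
    returned by the oracle must be a subgraph)."""
    g = hg.graph
    assert nx.is_connected(g)
    for h in haplos:
        assert tuple(h) in g
    mst = _mst_oracle(list(g.nodes), mode)
    for u, v, data in mst.edges(data=True):
        assert g.has_edge(u, v), (u, v)
        assert g[u][v]["weight"] == pytest.approx(data["weight"])
    # without inferred medians this is an MST of the observed haplotypes
    if not any(d["median"] for _, d in g.nodes(data=True)):
        total_mst = sum(d["weight"] for _, _, d in _mst_oracle(haplos, mode).edges(data=True))
        spanning = nx.minimum_spanning_tree(g, weight="weight")
        total_net = sum(d["weight"] for _, _, d in spanning.edges(data=True))
        assert total_net == pytest.approx(total_mst)
    return True


def _fixture_instances(rng):
    """The small-instance suite: canonical cases plus random <=8-haplotype
    binary and STR instances."""
    instances = [
        ("categorical", [(0, 0, 0), (1, 1, 0), (1, 0, 1)]),
        ("categorical", [(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0)]),
        ("categorical", [(0, 0), (1, 1)]),
        ("ordinal", [(10, 12), (11, 12), (13, 12), (10, 14)]),
    ]
    for _ in range(12):
        n = int(rng.integers(3, 9))
        sites = int(rng.integers(4, 9))
        rows = {tuple(int(x) for x in rng.integers(0, 2, size=sites)) for _ in range(n)}
        if len(rows) >= 2:
            instances.append(("categorical", sorted(rows)))
    for _ in range(8):
        n = int(rng.integers(3, 9))
        loci = int(rng.integers(3, 7))
        rows = {tuple(int(x) for x in rng.integers(9, 15, size=loci)) for _ in range(n)}
        if len(rows) >= 2:
            instances.append(("ordinal", sorted(rows)))
    return instances


class TestMjNetwork:
    def test_two_haplotypes_single_edge(self):
        hg = net.build_mj_network([(0, 0), (1, 1)])
        assert hg.graph.number_of_nodes() == 2
        ((u, v, data),) = list(hg.graph.edges(data=True))
        assert data["weight"] == 2.0

    def test_three_binary_haplotypes_yield_single_median(self):
        hg = net.build_mj_network([(0, 0, 0), (1, 1, 0), (1, 0, 1)], epsilon=0)
        medians = [n for n, d in hg.graph.nodes(data=True) if d["median"]]
        assert medians == [(1, 0, 0)]
        assert all(
            hg.graph[m][nbr]["weight"] == 1.0
            for m in medians
            for nbr in hg.graph.neighbors(m)
        )

    def test_observed_star_adds_no_medians(self):
        star = [(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)]
        hg = net.build_mj_network(star, epsilon=0)
        assert not any(d["median"] for _, d in hg.graph.nodes(data=True))
        center = (0, 0, 0, 0)
        assert hg.graph.degree[center] == 4

    def test_network_contains_mst_on_fixture_suite(self, rng):
        for mode, haplos in _fixture_instances(rng):
            hg = net.build_mj_network(haplos, epsilon=0, mode=mode)
            assert _contains_mst(hg, haplos, mode)

    def test_node_set_stable_under_input_permutation(self, rng):
        haplos = [(0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
        hg1 = net.build_mj_network(haplos)
        for _ in range(3):
            perm = list(haplos)
            rng.shuffle(perm)
            hg2 = net.build_mj_network(perm)
            assert set(hg1.graph.nodes) == set(hg2.graph.nodes)
            assert {frozenset(e) for e in hg1.graph.edges} == {
                frozenset(e) for e in hg2.graph.edges
            }

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            net.build_mj_network([(0, 0), (1, 1, 1)])

    def test_str_ordinal_distances_and_medians(self):
        hg = net.build_mj_network(
            [(10, 10), (12, 10), (10, 12)], mode="ordinal", epsilon=0
        )
        # the observed (10,10) haplotype is itself the coordinatewise median
        assert not any(d["median"] for _, d in hg.graph.nodes(data=True))
        assert hg.graph[(10, 10)][(12, 10)]["steps"] == 2


class TestWeights:
    def _genome(self, sid, labels, kinds, reference):
        from unipargen.mtdna import MtGenome, parse_variant_label

        variants = []
        for lab, kind in zip(labels, kinds):
            v = parse_variant_label(lab)
            object.__setattr__(v, "kind", kind)
            variants.append(v)
        return MtGenome(sid, "", variants, variants)

    def test_transition_only_dataset_all_unit_weights(self, reference):
        g1 = self._genome("a", ["100G"], ["transition"], reference)
        g2 = self._genome("b", ["200T"], ["transition"], reference)
        w = net.default_mtdna_weights([g1, g2], ["100G", "200T"])
        assert list(w) == [1.0, 1.0]

    def test_transversion_site_weighted_three(self, reference):
        g1 = self._genome("a", ["100C"], ["transversion"], reference)
        g2 = self._genome("b", ["200T"], ["transition"], reference)
        w = net.default_mtdna_weights([g1, g2], ["100C", "200T"])
        assert list(w) == [3.0, 1.0]

    def test_recurrent_transition_floored_at_one(self, reference):
        genomes = [
            self._genome(f"s{i}", ["100G", f"{200+i}T"], ["transition", "transition"], reference)
            for i in range(4)
        ]
        labels = ["100G"] + [f"{200+i}T" for i in range(4)]
        w = net.default_mtdna_weights(genomes, labels)
        assert w[0] == 1.0  # recurrent in 4 distinct haplotype classes, floored


class TestAnnotate:
    def test_annotation_counts_and_round_trip(self, tmp_path):
        haplos = [(0, 0), (0, 0), (0, 0), (1, 1)]
        hg = net.build_mj_network(haplos)
        annotated = net.annotate_network(hg, haplos, ["Tsachila"] * 3 + ["Pasto"])
        counts = {n: d["count"] for n, d in annotated.nodes(data=True)}
        assert sorted(counts.values()) == [1, 3]
        node = [n for n, d in annotated.nodes(data=True) if d["count"] == 3][0]
        assert annotated.nodes[node]["n_Tsachila"] == 3
        from unipargen.io import read_network_graphml, write_network_graphml

        path = tmp_path / "net.graphml"
        write_network_graphml(annotated, path)
        back = read_network_graphml(path)
        assert set(back.nodes) == set(annotated.nodes)
        assert {frozenset(e) for e in back.edges} == {
            frozenset(e) for e in annotated.edges
        }
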