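"""Median-joining networks, minimum spanning networks, MP pruning."""

import itertools

import networkx as nx
import numpy as np
import pytest
from networkx.algorithms.tree.mst import SpanningTreeIterator

from mitopop import (
    collapse_haplotypes,
    median_joining,
    minimum_spanning_network,
    mp_prune,
    pairwise_distance_matrix,
    segregating_sites,
)
from mitopop.coalsim import Demography, simulate_alignment
from mitopop.errors import InputError, SizeError
from mitopop.network import MJNetwork
from mitopop.seq_io import Alignment, HaplotypeTable

from conftest import random_alignment


def ht_from_seqs(*seqs):
    return HaplotypeTable(
        ids=tuple(f"H{i + 1:03d}" for i in range(len(seqs))),
        seqs=tuple(seqs),
        counts=tuple(1 for _ in seqs),
        members=tuple((f"s{i}",) for i in range(len(seqs))),
    )


def all_min_spanning_trees(g: nx.Graph):
    """All spanning trees of minimum total weight (exhaustive oracle)."""
    trees = []
    best = None
    for t in SpanningTreeIterator(g, weight="weight"):
        w = t.size(weight="weight")
        if best is None:
            best = w
        if w > best + 1e-9:
            break
        trees.append(t)
    return best, trees


class TestMSN:
    def test_two_haplotypes_single_edge(self):
        ht = ht_from_seqs("AAAA", "AATT")
        dm = pairwise_distance_matrix(ht)
        assert minimum_spanning_network(dm) == [("H001", "H002", 2)]

    def test_triangle_longest_edge_excluded(self):
        ht = ht_from_seqs("AAA", "AAT", "ATT")  # d = 1, 1, 2
        edges = minimum_spanning_network(pairwise_distance_matrix(ht))
        assert sorted((u, v) for u, v, _ in edges) == [
            ("H001", "H002"), ("H002", "H003")
        ]

    def test_tied_edges_all_kept(self):
        ht = ht_from_seqs("AA", "AT", "TA")  # equilateral: d = 1, 1, 2? no: 1,1,2
        edges = minimum_spanning_network(pairwise_distance_matrix(ht))
        assert len(edges) == 2

    def test_equals_union_of_all_msts(self, rng):
        """At epsilon = 0 the MSN is exactly the union of every minimum
        spanning tree, checked by exhaustive enumeration."""
        for _ in range(5):
            aln = random_alignment(rng, 8, 6)
            ht = collapse_haplotypes(aln)
            dm = pairwise_distance_matrix(ht)
            msn = {frozenset((u, v)) for u, v, _ in minimum_spanning_network(dm)}
            g = nx.Graph()
            for i, a in enumerate(dm.ids):
                for j in range(i + 1, len(dm.ids)):
                    g.add_edge(a, dm.ids[j], weight=int(dm.d[i, j]))
            _, trees = all_min_spanning_trees(g)
            union = {frozenset(e) for t in trees for e in t.edges}
            assert msn == union

    def test_epsilon_relaxation_is_superset(self, rng):
        aln = random_alignment(rng, 6, 8)
        dm = pairwise_distance_matrix(collapse_haplotypes(aln))
        e0 = {frozenset((u, v)) for u, v, _ in minimum_spanning_network(dm, 0)}
        e2 = {frozenset((u, v)) for u, v, _ in minimum_spanning_network(dm, 2)}
        assert e0 <= e2


class TestMedianJoining:
    def test_three_haplotype_star(self):
        """The classic {000, 110, 101} instance: one median vector (100)
        completes a star of three unit edges."""
        net = median_joining(ht_from_seqs("AAA", "TTA", "TAT"))
        assert net.n_medians == 1
        mv = [i for i, m in zip(net.node_ids, net.is_median) if m][0]
        assert net.node_seqs[net.node_ids.index(mv)] == "TAA"
        assert sorted(w for _, _, w in net.edges) == [1, 1, 1]
        assert all(mv in (u, v) for u, v, _ in net.edges)

    def test_two_haplotypes_no_medians(self):
        net = median_joining(ht_from_seqs("AAAA", "ATTA"))
        assert net.n_medians == 0 and len(net.edges) == 1

    def test_chain_adds_no_median(self):
        net = median_joining(ht_from_seqs("AAA", "AAT", "ATT"))
        assert net.n_medians == 0
        assert len(net.edges) == 2

    def test_connected_and_spans_observed(self, rng):
        for _ in range(5):
            aln = random_alignment(rng, 10, 8)
            ht = collapse_haplotypes(aln)
            if ht.k < 2:
                continue
            net = median_joining(ht)
            g = net.to_networkx()
            assert nx.is_connected(g)
            assert set(ht.ids) <= set(net.node_ids)
            # edge lengths equal Hamming distance between endpoint sequences
            seq = dict(zip(net.node_ids, net.node_seqs))
            for u, v, w in net.edges:
                assert w == sum(a != b for a, b in zip(seq[u], seq[v]))

    def test_relabeling_gives_isomorphic_network(self, rng):
        # binary state space avoids three-way ties, making the result unique
        aln = random_alignment(rng, 10, 8, alphabet="AT")
        ht = collapse_haplotypes(aln)
        relabeled = HaplotypeTable(
            ids=tuple(f"X{i}" for i in range(ht.k)),
            seqs=ht.seqs, counts=ht.counts, members=ht.members,
        )
        a, b = median_joining(ht), median_joining(relabeled)
        assert nx.is_isomorphic(
            a.to_networkx(), b.to_networkx(),
            edge_match=lambda x, y: x["weight"] == y["weight"],
            node_match=lambda x, y: x["count"] == y["count"]
            and x["is_median"] == y["is_median"],
        )

    def test_infinite_sites_network_is_reticulation_free(self, rng):
        """Homoplasy-free data always give a cycle-free network; direct links
        can stand in for unproposed interior nodes, so total length is
        bounded below by the segregating-site count."""
        found = 0
        for _ in range(8):
            s = simulate_alignment(
                15, 300, Demography.constant(3.0), rng, infinite_sites=True
            )
            ht = collapse_haplotypes(s.alignment)
            if ht.k < 3:
                continue
            found += 1
            net = median_joining(ht)
            assert len(net.edges) == len(net.node_ids) - 1  # tree: no cycles
            hap_aln = Alignment(ht.ids, ht.seqs)
            assert net.total_length >= segregating_sites(hap_aln)
        assert found >= 3

    def test_infinite_sites_star_data_recover_true_genealogy(self, rng):
        """In the star-like expansion regime the network is the true
        genealogy: a tree of length S whose path metric reproduces every
        pairwise Hamming distance between observed haplotypes."""
        demog = Demography.sudden_expansion(theta0=0.3, theta1=500.0, tau=2.0)
        found = 0
        for _ in range(8):
            s = simulate_alignment(15, 400, demog, rng, infinite_sites=True)
            ht = collapse_haplotypes(s.alignment)
            if ht.k < 3:
                continue
            found += 1
            net = median_joining(ht)
            assert len(net.edges) == len(net.node_ids) - 1
            assert net.total_length == segregating_sites(Alignment(ht.ids, ht.seqs))
            g = net.to_networkx()
            seqs = dict(zip(net.node_ids, net.node_seqs))
            sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
            for i, a in enumerate(ht.ids):
                for b in ht.ids[i + 1 :]:
                    hamming = sum(x != y for x, y in zip(seqs[a], seqs[b]))
                    assert sp[a][b] == hamming
        assert found >= 3


def steiner_union_oracle(net: MJNetwork):
    """Union of all minimum-length trees spanning the observed haplotypes,
    by exhaustive enumeration over median subsets and spanning trees."""
    g = net.to_networkx()
    terminals = [n for n, m in zip(net.node_ids, net.is_median) if not m]
    medians = [n for n, m in zip(net.node_ids, net.is_median) if m]
    best = None
    all_trees = []
    for r in range(len(medians) + 1):
        for sub in itertools.combinations(medians, r):
            sg = g.subgraph(terminals + list(sub))
            if not nx.is_connected(sg):
                continue
            w, trees = all_min_spanning_trees(nx.Graph(sg))
            if best is None or w < best - 1e-9:
                best, all_trees = w, list(trees)
            elif abs(w - best) < 1e-9:
                all_trees.extend(trees)
    nodes = {n for t in all_trees for n in t.nodes}
    edges = {frozenset(e) for t in all_trees for e in t.edges}
    return nodes, edges


class TestMPPrune:
    def test_tree_is_identity(self):
        net = median_joining(ht_from_seqs("AAA", "AAT", "ATT"))
        pruned = mp_prune(net)
        assert set(pruned.edges) == set(net.edges)
        assert pruned.node_ids == net.node_ids

    def test_redundant_median_removed(self):
        # a 4-cycle of observed haplotypes plus a central median shortcut:
        # the centre lies on every shortest tree, the cycle does not survive
        net = MJNetwork(
            node_ids=("H001", "H002", "H003", "H004", "mv1"),
            node_seqs=("AA", "AT", "TT", "TA", "NN"),
            node_counts=(1, 1, 1, 1, 0),
            is_median=(False, False, False, False, True),
            edges=(
                ("H001", "H002", 1), ("H002", "H003", 1),
                ("H003", "H004", 1), ("H004", "H001", 1),
                ("H001", "mv1", 2),
            ),
            epsilon=0,
        )
        pruned = mp_prune(net)
        assert "mv1" not in pruned.node_ids
        assert len(pruned.edges) >= 3

    def test_observed_haplotypes_never_removed(self, rng):
        for _ in range(5):
            aln = random_alignment(rng, 8, 6)
            ht = collapse_haplotypes(aln)
            if ht.k < 2:
                continue
            net = median_joining(ht)
            if len(net.node_ids) > 20:
                continue
            pruned = mp_prune(net)
            assert set(ht.ids) <= set(pruned.node_ids)
            assert pruned.total_length <= net.total_length

    def test_matches_exhaustive_steiner_oracle(self, rng):
        checked = 0
        for _ in range(8):
            aln = random_alignment(rng, 8, 5)
            ht = collapse_haplotypes(aln)
            if ht.k < 3:
                continue
            net = median_joining(ht)
            if len(net.node_ids) > 12:
                continue
            checked += 1
            pruned = mp_prune(net)
            nodes, edges = steiner_union_oracle(net)
            assert set(pruned.node_ids) == nodes
            assert {frozenset((u, v)) for u, v, _ in pruned.edges} == edges
        assert checked >= 3

    def test_node_guard(self):
        net = median_joining(ht_from_seqs("AAA", "AAT", "ATT"))
        with pytest.raises(SizeError):
            mp_prune(net, node_guard=2)

    def test_needs_at_least_two_haplotypes(self):
        with pytest.raises(InputError):
            median_joining(ht_from_seqs("AAAA"))
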