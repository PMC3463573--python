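"""Median-joining haplotype networks with MP (shortest-tree) post-processing.

The construction follows the classical algorithm: build the epsilon-relaxed
minimum spanning network (the union of all minimum spanning trees when
epsilon = 0), then repeatedly propose median vectors — per-column majority
consensus sequences of mutually linked triplets — admitting those whose
connection cost is within epsilon of the iteration's minimum, until no new
vector is added.  MP post-processing keeps exactly the nodes and links
that occur in at least one minimum-total-length tree spanning all observed
haplotypes (a Steiner-tree union, found here by exhaustive search over
median subsets, which is exact at the node counts produced by per-lineage
datasets).

Different but equally optimal reticulations can exist; ties are broken by
haplotype-ID order so results are reproducible run to run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InputError, MitopopError, SizeError
from .seq_io import DistanceMatrix, HaplotypeTable, retained_columns


@dataclass(frozen=True)
class MJNetwork:
    """Observed haplotypes plus inferred median vectors, with integer edges."""

    node_ids: tuple[str, ...]
    node_seqs: tuple[str, ...]
    node_counts: tuple[int, ...]  # 0 for median vectors
    is_median: tuple[bool, ...]
    edges: tuple[tuple[str, str, int], ...]
    epsilon: int

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, nid in enumerate(self.node_ids):
            g.add_node(
                nid,
                sequence=self.node_seqs[i],
                count=self.node_counts[i],
                is_median=self.is_median[i],
            )
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    @property
    def total_length(self) -> int:
        return sum(w for _, _, w in self.edges)

    @property
    def n_medians(self) -> int:
        return sum(self.is_median)


class _DSU:
    def __init__(self, n: int) -> None:
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.p[self.find(a)] = self.find(b)


def _msn_edges(d: np.ndarray, epsilon: int) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum spanning network over a distance matrix.

    An edge of weight w is admitted iff its endpoints are not yet connected
    by admitted edges of weight <= w - epsilon - 1; at epsilon = 0 this is
    the union of all minimum spanning trees.
    """
    m = d.shape[0]
    if m == 0:
        raise InputError("empty distance matrix")
    if m == 1:
        return []
    all_edges = [
        (int(d[i, j]), i, j) for i in range(m) for j in range(i + 1, m)
    ]
    all_edges.sort()
    admitted: list[tuple[int, int, int]] = []
    weights = sorted({w for w, _, _ in all_edges})
    for w in weights:
        dsu = _DSU(m)
        for ww, i, j in admitted:
            if ww <= w - epsilon - 1:
                dsu.union(i, j)
        batch = [(ww, i, j) for ww, i, j in all_edges if ww == w]
        for ww, i, j in batch:
            if dsu.find(i) != dsu.find(j):
                admitted.append((ww, i, j))
        # stop once everything is connected at a strictly cheaper level
        full = _DSU(m)
        for ww, i, j in admitted:
            if ww <= w - epsilon:
                full.union(i, j)
        if len({full.find(i) for i in range(m)}) == 1:
            break
    return [(i, j, w) for w, i, j in admitted]


def minimum_spanning_network(
    dm: DistanceMatrix, epsilon: int = 0
) -> list[tuple[str, str, int]]:
    """Edges (id1, id2, length) of the epsilon-relaxed MSN."""
    edges = _msn_edges(np.asarray(dm.d), epsilon)
    return [(dm.ids[i], dm.ids[j], w) for i, j, w in edges]


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def median_joining(
    ht: HaplotypeTable, epsilon: int = 0, max_iter: int = 100
) -> MJNetwork:
    """Median-joining network over the haplotypes of ``ht``."""
    if ht.k < 2:
        raise InputError("median-joining needs at least 2 haplotypes")
    cols = retained_columns(ht.seqs)
    full = {hid: seq for hid, seq in zip(ht.ids, ht.seqs)}
    enc = {
        hid: np.frombuffer(seq.encode(), dtype=np.uint8)[cols]
        for hid, seq in zip(ht.ids, ht.seqs)
    }
    node_ids: list[str] = list(ht.ids)
    seen_keys = {enc[h].tobytes() for h in node_ids}
    mv_counter = itertools.count(1)

    def distance_matrix() -> np.ndarray:
        mat = np.stack([enc[h] for h in node_ids])
        return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)

    for _ in range(max_iter):
        d = distance_matrix()
        edges = _msn_edges(d, epsilon)
        adj = {i: set() for i in range(len(node_ids))}
        for i, j, _w in edges:
            adj[i].add(j)
            adj[j].add(i)
        # candidate medians from mutually linked triplets
        candidates: list[tuple[int, bytes, np.ndarray]] = []
        for u in range(len(node_ids)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                if u < v < w and w in adj[v]:
                    med = _median_sequence(enc[node_ids[u]], enc[node_ids[v]], enc[node_ids[w]])
                    key = med.tobytes()
                    if key in seen_keys:
                        continue
                    cost = (
                        _hamming(med, enc[node_ids[u]])
                        + _hamming(med, enc[node_ids[v]])
                        + _hamming(med, enc[node_ids[w]])
                    )
                    candidates.append((cost, key, med))
        if not candidates:
            break
        min_cost = min(c for c, _, _ in candidates)
        added = False
        for cost, key, med in sorted(candidates, key=lambda c: c[0]):
            if cost > min_cost + epsilon:
                break
            if key in seen_keys:
                continue
            mv_id = f"mv{next(mv_counter)}"
            node_ids.append(mv_id)
            enc[mv_id] = med
            full[mv_id] = _expand_median(med, cols, full[node_ids[0]])
            seen_keys.add(key)
            added = True
        if not added:
            break
    else:
        raise MitopopError("median-joining failed to stabilise (iteration cap hit)")

    # drop median vectors the final network does not need (degree <= 2 and
    # removal does not lengthen the MSN)
    observed = set(ht.ids)
    while True:
        d = distance_matrix()
        edges = _msn_edges(d, epsilon)
        deg = {i: 0 for i in range(len(node_ids))}
        for i, j, _w in edges:
            deg[i] += 1
            deg[j] += 1
        total = sum(w for _, _, w in edges)
        removable = None
        for i, nid in enumerate(node_ids):
            if nid in observed or deg[i] > 2:
                continue
            trial = [h for h in node_ids if h != nid]
            mat = np.stack([enc[h] for h in trial])
            dt = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
            if sum(w for _, _, w in _msn_edges(dt, epsilon)) <= total:
                removable = nid
                break
        if removable is None:
            break
        node_ids.remove(removable)

    d = distance_matrix()
    edges = _msn_edges(d, epsilon)
    count_of = dict(zip(ht.ids, ht.counts))
    return MJNetwork(
        node_ids=tuple(node_ids),
        node_seqs=tuple(full[h] for h in node_ids),
        node_counts=tuple(count_of.get(h, 0) for h in node_ids),
        is_median=tuple(h not in observed for h in node_ids),
        edges=tuple(
            (node_ids[i], node_ids[j], int(w)) for i, j, w in edges
        ),
        epsilon=epsilon,
    )


def _median_sequence(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-column majority of three sequences; three-way ties go to the first
    node in ID order (a deterministic resolution the algorithm leaves open)."""
    med = a.copy()  # three-way ties and a-b/a-c agreements resolve to a
    bc = b == c
    med[bc] = b[bc]
    return med


def _expand_median(med: np.ndarray, cols: np.ndarray, template: str) -> str:
    out = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    out[cols] = med
    return out.tobytes().decode()


MP_NODE_GUARD = 25


def mp_prune(net: MJNetwork, node_guard: int = MP_NODE_GUARD) -> MJNetwork:
    """Keep only nodes/links on at least one shortest tree spanning all
    observed haplotypes (exhaustive Steiner search over median subsets)."""
    n_nodes = len(net.node_ids)
    if n_nodes > node_guard:
        raise SizeError(
            f"{n_nodes} nodes exceeds the exhaustive-search guard ({node_guard}); "
            "use epsilon=0 or analyse a subset"
        )
    g = net.to_networkx()
    terminals = [nid for nid, m in zip(net.node_ids, net.is_median) if not m]
    medians = [nid for nid, m in zip(net.node_ids, net.is_median) if m]

    best_weight = None
    optima: list[nx.Graph] = []
    for r in range(len(medians) + 1):
        for subset in itertools.combinations(medians, r):
            nodes = terminals + list(subset)
            sub = g.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            mst = nx.minimum_spanning_tree(sub, weight="weight")
            w = int(mst.size(weight="weight"))
            if best_weight is None or w < best_weight:
                best_weight = w
                optima = [sub]
            elif w == best_weight:
                optima.append(sub)
    if best_weight is None:
        raise InputError("network does not connect the observed haplotypes")

    keep_nodes: set[str] = set()
    keep_edges: set[tuple[str, str]] = set()
    for sub in optima:
        keep_nodes.update(sub.nodes)
        for u, v, w in sub.edges(data="weight"):
            # edge is in some MST of `sub` iff u,v are not joined by strictly
            # lighter edges (cycle rule)
            lighter = nx.Graph(
                (a, b) for a, b, ww in sub.edges(data="weight") if ww < w
            )
            lighter.add_nodes_from(sub.nodes)
            if not nx.has_path(lighter, u, v):
                keep_edges.add((u, v) if u <= v else (v, u))

    idx = {nid: i for i, nid in enumerate(net.node_ids)}
    kept = [nid for nid in net.node_ids if nid in keep_nodes]
    return MJNetwork(
        node_ids=tuple(kept),
        node_seqs=tuple(net.node_seqs[idx[h]] for h in kept),
        node_counts=tuple(net.node_counts[idx[h]] for h in kept),
        is_median=tuple(net.is_median[idx[h]] for h in kept),
        edges=tuple(
            (u, v, w)
            for u, v, w in net.edges
            if ((u, v) if u <= v else (v, u)) in keep_edges
        ),
        epsilon=net.epsilon,
    )
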