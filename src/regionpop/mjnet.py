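"""Median-joining haplotype networks (Bandelt-style) over binary characters.

The network starts from the minimum spanning network (the union of all
minimum spanning trees, optionally relaxed by a tolerance epsilon) over the
distinct observed haplotypes.  Quasi-medians — majority-consensus vectors of
node triplets — are then proposed and admitted whenever they strictly lower
the total (MST) cost of connecting all nodes, to a fixpoint; inferred median
vectors that end up unobserved with degree < 3 are pruned.  With binary
characters the quasi-median of a triplet is the site-wise majority vector,
so the procedure is a pure Steiner-point search under Hamming distance.

Tie-breaking is everywhere lexicographic on haplotype strings, so the
result is independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HaploNetwork", "median_joining", "cluster_report", "msn_edges",
           "mst_cost"]


@dataclass
class HaploNetwork:
    haplotypes: list[str]                   # node id -> binary string
    counts: dict[str, np.ndarray]           # group label -> per-node counts
    observed: np.ndarray                    # bool per node; medians are False
    edges: list[tuple[int, int, tuple[int, ...]]]  # (a, b, differing site indices)
    epsilon: int = 0
    positions: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.haplotypes)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def total_cost(self) -> int:
        return sum(len(d) for _, _, d in self.edges)

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for i, h in enumerate(self.haplotypes):
            g.add_node(i, haplotype=h, observed=bool(self.observed[i]))
        for a, b, diff in self.edges:
            g.add_edge(a, b, weight=len(diff), sites=diff)
        return g


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra
            return True
        return False


def _sorted_edges(vecs: list[np.ndarray]):
    n = len(vecs)
    edges = [(_hamming(vecs[a], vecs[b]), a, b)
             for a in range(n) for b in range(a + 1, n)]
    edges.sort()
    return edges


def mst_cost(vecs: list[np.ndarray]) -> int:
    """Total weight of a minimum spanning tree under Hamming distance."""
    uf = _UnionFind(len(vecs))
    cost = 0
    for w, a, b in _sorted_edges(vecs):
        if uf.union(a, b):
            cost += w
    return cost


def msn_edges(vecs: list[np.ndarray], epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Minimum spanning network: edges of every MST, plus (for epsilon > 0)
    edges whose weight is within epsilon of the connection level of their
    components.  Returns (a, b, weight) triples."""
    edges = _sorted_edges(vecs)
    out = []
    uf = _UnionFind(len(vecs))
    pending_unions: list[tuple[int, int]] = []
    i = 0
    while i < len(edges):
        w = edges[i][0]
        # commit unions for all strictly lighter levels beyond tolerance
        still: list[tuple[int, int]] = []
        for uw, pair in pending_unions:
            if uw < w - epsilon:
                uf.union(*pair)
            else:
                still.append((uw, pair))
        pending_unions = still
        j = i
        while j < len(edges) and edges[j][0] == w:
            _, a, b = edges[j]
            if uf.find(a) != uf.find(b):
                out.append((a, b, w))
                pending_unions.append((w, (a, b)))
            j += 1
        i = j
    return out


def _majority(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return ((a.astype(int) + b + c) >= 2).astype(np.uint8)


def median_joining(haplotypes, counts=None, groups: dict[str, np.ndarray] | None = None,
                   epsilon: int = 0, positions=None, max_medians: int = 1000) -> HaploNetwork:
    """Median-joining network over distinct binary haplotypes.

    ``haplotypes``: iterable of equal-length binary strings (or 0/1 arrays);
    duplicates collapse with summed counts. ``counts``: pooled counts (default
    1 each); ``groups``: optional per-group count vectors for pie-chart-style
    annotation.  ``epsilon=0`` gives the most parsimonious network.
    """
    vec_list = []
    for h in haplotypes:
        v = np.asarray([int(x) for x in h] if isinstance(h, str) else h,
                       dtype=np.uint8)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("haplotype characters must be binary 0/1")
        vec_list.append(v)
    if not vec_list:
        raise ValueError("need at least one haplotype")
    if counts is None:
        counts = np.ones(len(vec_list), dtype=int)
    counts = np.asarray(counts)
    # collapse duplicates, order lexicographically for determinism
    keyed: dict[str, np.ndarray] = {}
    pooled: dict[str, int] = {}
    grp_counts: dict[str, dict[str, float]] = {}
    for i, v in enumerate(vec_list):
        key = "".join(map(str, v))
        keyed[key] = v
        pooled[key] = pooled.get(key, 0) + int(counts[i])
        if groups:
            for gname, gvec in groups.items():
                grp_counts.setdefault(gname, {})
                grp_counts[gname][key] = grp_counts[gname].get(key, 0) + gvec[i]
    keys = sorted(keyed)
    vecs = [keyed[k] for k in keys]
    observed = [True] * len(vecs)

    cur_cost = mst_cost(vecs)
    while True:
        n = len(vecs)
        best = None  # (new_cost, key, vec)
        seen = set("".join(map(str, v)) for v in vecs)
        for a in range(n):
            for b in range(a + 1, n):
                for c in range(b + 1, n):
                    m = _majority(vecs[a], vecs[b], vecs[c])
                    key = "".join(map(str, m))
                    if key in seen:
                        continue
                    seen.add(key)
                    new_cost = mst_cost(vecs + [m])
                    if new_cost < cur_cost and (best is None or
                                                (new_cost, key) < best[:2]):
                        best = (new_cost, key, m)
        if best is None or len(vecs) >= len(keys) + max_medians:
            break
        cur_cost = best[0]
        vecs.append(best[2])
        observed.append(False)

    # prune obsolete medians: unobserved nodes of degree < 3 in the MSN
    while True:
        edges = msn_edges(vecs, epsilon)
        deg = np.zeros(len(vecs), dtype=int)
        for a, b, _ in edges:
            deg[a] += 1
            deg[b] += 1
        drop = [i for i in range(len(vecs)) if not observed[i] and deg[i] < 3]
        if not drop:
            break
        for i in sorted(drop, reverse=True):
            del vecs[i]
            del observed[i]

    strings = ["".join(map(str, v)) for v in vecs]
    order = sorted(range(len(vecs)), key=lambda i: (not observed[i], strings[i]))
    vecs = [vecs[i] for i in order]
    observed_arr = np.array([observed[i] for i in order])
    strings = [strings[i] for i in order]
    edges_final = []
    for a, b, _ in msn_edges(vecs, epsilon):
        diff = tuple(int(x) for x in np.nonzero(vecs[a] != vecs[b])[0])
        edges_final.append((min(a, b), max(a, b), diff))
    edges_final.sort()

    group_arrays = {}
    pooled_arr = np.array([pooled.get(s, 0) for s in strings])
    group_arrays["pooled"] = pooled_arr
    if groups:
        for gname in groups:
            group_arrays[gname] = np.array(
                [grp_counts[gname].get(s, 0) for s in strings])
    return HaploNetwork(haplotypes=strings, counts=group_arrays,
                        observed=observed_arr, edges=edges_final,
                        epsilon=epsilon,
                        positions=None if positions is None else np.asarray(positions))


def cluster_report(network: HaploNetwork) -> dict:
    """Node frequency table plus connectivity summary.

    Reticulation count is edges - nodes + components (the network's cycle
    rank); a strict tree has 0.
    """
    import networkx as nx
    g = network.to_networkx()
    comps = list(nx.connected_components(g))
    table = pd.DataFrame({"haplotype": network.haplotypes,
                          "observed": network.observed})
    for gname, arr in network.counts.items():
        table[f"count_{gname}"] = arr
    comp_of = {}
    for ci, comp in enumerate(sorted(comps, key=min)):
        for node in comp:
            comp_of[node] = ci
    table["component"] = [comp_of[i] for i in range(network.n_nodes)]
    return {
        "nodes": table,
        "n_components": len(comps),
        "reticulations": len(network.edges) - network.n_nodes + len(comps),
    }
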