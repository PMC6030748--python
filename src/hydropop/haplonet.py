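"""mtDNA haplotypes and median-joining networks.

Aligned sequences are collapsed to haplotypes (sites with gaps or N in any
sequence are excluded alignment-wide first), and the haplotype set is turned
into a median-joining network: a relaxed minimum-spanning network augmented
with inferred intermediate (median) haplotypes wherever a majority-consensus
vector of three connected nodes shortens the total connection, then pruned
of unsampled nodes that end up with degree below three.  With epsilon = 0
and homoplasy-free data the result collapses to the minimum spanning tree.

All tie-breaking is lexicographic, so the network is independent of input
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from hydropop.io import SequenceAlignment, ValidationError


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with frequencies and population membership."""

    haplotypes: dict  # id -> sequence (over retained sites)
    freq: dict  # id -> count
    members: dict  # id -> list of sequence names
    pop_counts: dict  # id -> {population: count}
    retained_sites: list  # alignment positions used

    @property
    def n_haplotypes(self):
        return len(self.haplotypes)

    def total(self):
        return sum(self.freq.values())

    def table(self) -> pd.DataFrame:
        """Haplotype frequency table with per-population counts (pie-chart
        data for a geographic haplotype map)."""
        pops = sorted({p for d in self.pop_counts.values() for p in d})
        rows = []
        for h in self.haplotypes:
            row = {"haplotype": h, "count": self.freq[h]}
            for p in pops:
                row[p] = self.pop_counts[h].get(p, 0)
            rows.append(row)
        return pd.DataFrame(rows).set_index("haplotype")


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeSet:
    """Collapse an alignment into distinct haplotypes.

    Sites containing ``N`` or ``-`` in *any* sequence are excluded
    alignment-wide before comparison; haplotypes are numbered ``H1, H2, ...``
    by first occurrence in the alignment.
    """
    if aln.n_sequences == 0:
        raise ValidationError("empty alignment")
    names = list(aln.records)
    seqs = [aln.records[n] for n in names]
    arr = np.array([list(s) for s in seqs])
    ok = ~np.any((arr == "N") | (arr == "-"), axis=0)
    retained = np.where(ok)[0].tolist()
    reduced = ["".join(row) for row in arr[:, ok]]
    haplotypes, freq, members, pop_counts = {}, {}, {}, {}
    seq_to_id = {}
    for name, seq in zip(names, reduced):
        if seq not in seq_to_id:
            hid = f"H{len(seq_to_id) + 1}"
            seq_to_id[seq] = hid
            haplotypes[hid] = seq
            freq[hid] = 0
            members[hid] = []
            pop_counts[hid] = {}
        hid = seq_to_id[seq]
        freq[hid] += 1
        members[hid].append(name)
        pop = aln.population_of.get(name)
        if pop is not None:
            pop_counts[hid][pop] = pop_counts[hid].get(pop, 0) + 1
    return HaplotypeSet(haplotypes, freq, members, pop_counts, retained)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _median_vector(a: str, b: str, c: str) -> str:
    """Majority-consensus sequence of three haplotypes (ties resolved toward
    the lexicographically smallest base for determinism)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min(x, y, z))
    return "".join(out)


def _msn_edges(seq_of: dict, epsilon: int = 0):
    """Edges of the epsilon-relaxed minimum spanning network.

    Edges are grouped by weight; within a weight level, an edge joins the
    network if its endpoints were in different components at the previous
    level (plus ``epsilon`` extra levels of tolerance).
    """
    nodes = sorted(seq_of)
    dists = {}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            dists.setdefault(_hamming(seq_of[u], seq_of[v]), []).append((u, v))
    uf = nx.utils.UnionFind(nodes)
    edges = []
    levels = sorted(dists)
    # component state lags epsilon levels behind, giving relaxed connectivity
    history = []
    for d in levels:
        snapshot = {n: uf[n] for n in nodes}
        history.append(snapshot)
        ref = history[0] if len(history) <= epsilon + 1 else history[-(epsilon + 1)]
        for u, v in sorted(dists[d]):
            if ref[u] != ref[v] or uf[u] != uf[v]:
                # feasible at this level if not yet connected at the lagged state
                if snapshot[u] != snapshot[v]:
                    edges.append((u, v, d))
                    uf.union(u, v)
    return edges


def median_joining(haps: HaplotypeSet, epsilon: int = 0, max_iter: int = 50) -> nx.Graph:
    """Median-joining network of a haplotype set.

    Iteratively rebuilds the epsilon-relaxed minimum-spanning network,
    proposes the consensus (median) vector of every connected triple, and
    keeps those that reduce the connection cost; unsampled median nodes of
    degree < 3 are pruned at the end.  Nodes carry ``freq``, ``median``
    (bool) and ``sequence`` attributes; edges carry ``weight`` =
    substitution count.
    """
    if haps.n_haplotypes < 1:
        raise ValidationError("no haplotypes")
    seq_of = dict(haps.haplotypes)
    sampled = set(seq_of)
    if haps.n_haplotypes == 1:
        g = nx.Graph()
        hid = next(iter(seq_of))
        g.add_node(hid, freq=haps.freq[hid], median=False, sequence=seq_of[hid])
        return g
    n_median = 0
    for _ in range(max_iter):
        edges = _msn_edges(seq_of, epsilon)
        g = nx.Graph()
        g.add_nodes_from(seq_of)
        g.add_weighted_edges_from(edges)
        added = False
        # connected triples: u-v and u-w adjacent in the current network
        candidates = []
        for u in sorted(g.nodes):
            nbrs = sorted(g.neighbors(u))
            for i, v in enumerate(nbrs):
                for w in nbrs[i + 1 :]:
                    m = _median_vector(seq_of[u], seq_of[v], seq_of[w])
                    if m in set(seq_of.values()):
                        continue
                    cost_new = (
                        _hamming(m, seq_of[u])
                        + _hamming(m, seq_of[v])
                        + _hamming(m, seq_of[w])
                    )
                    duv = _hamming(seq_of[u], seq_of[v])
                    duw = _hamming(seq_of[u], seq_of[w])
                    dvw = _hamming(seq_of[v], seq_of[w])
                    cost_cur = duv + duw + dvw - max(duv, duw, dvw)
                    if cost_new < cost_cur:
                        candidates.append((cost_new, m))
        if candidates:
            candidates.sort()
            best_cost = candidates[0][0]
            for cost, m in candidates:
                if cost > best_cost:
                    break
                if m not in set(seq_of.values()):
                    n_median += 1
                    seq_of[f"mv{n_median}"] = m
                    added = True
        if not added:
            break
    # prune obsolete median vectors (degree <= 2, unsampled), iteratively
    while True:
        edges = _msn_edges(seq_of, epsilon)
        g = nx.Graph()
        g.add_nodes_from(seq_of)
        g.add_weighted_edges_from(edges)
        removable = [
            n for n in g.nodes if n not in sampled and g.degree(n) <= 2
        ]
        if not removable:
            break
        for n in removable:
            del seq_of[n]
    edges = _msn_edges(seq_of, epsilon)
    g = nx.Graph()
    for n, s in seq_of.items():
        g.add_node(
            n,
            freq=haps.freq.get(n, 0),
            median=n not in sampled,
            sequence=s,
        )
    g.add_weighted_edges_from(edges)
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node_a": u, "node_b": v, "substitutions": d["weight"]}
        for u, v, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows)


def write_network(g: nx.Graph, tsv_path=None, gml_path=None):
    if tsv_path:
        network_edge_table(g).to_csv(tsv_path, sep="\t", index=False)
    if gml_path:
        nx.write_gml(g, gml_path)
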