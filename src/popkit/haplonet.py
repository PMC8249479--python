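"""Mitochondrial haplotype analysis: collapse aligned sequences to unique
haplotypes, pairwise substitution distances, and a minimum spanning
network (the union of all minimum spanning trees, i.e. an epsilon = 0
MSN as drawn by PopART).

Alignment columns containing a gap in any sequence are excluded from all
distance computations, so indel columns cannot affect the network.
Comparison is case-insensitive; non-ACGT ambiguity codes are compared
literally with a warning.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .genotype_io import PopulationMap

__all__ = [
    "HaplotypeSet",
    "HaplotypeNetwork",
    "collapse_haplotypes",
    "hamming_distance",
    "minimum_spanning_network",
]

_GAPS = frozenset("-.")
_STANDARD = frozenset("ACGT")


def _check_ambiguity(seqs) -> None:
    letters = set().union(*(set(s) for s in seqs)) - _GAPS
    odd = letters - _STANDARD
    if odd:
        warnings.warn(
            f"non-ACGT symbols compared literally: {sorted(odd)}", stacklevel=3
        )


def _ungapped_columns(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    gapped = np.isin(arr, list(_GAPS)).any(axis=0)
    return ~gapped


@dataclass(frozen=True)
class HaplotypeSet:
    """Unique aligned haplotypes with per-population carrier counts."""

    haplotypes: list[str]  # unique sequences, uppercased
    names: list[str]  # one label per unique haplotype
    counts: list[Counter]  # per-haplotype Counter(population -> carriers)
    members: dict[str, int]  # sample id -> haplotype index
    n_segregating: int  # polymorphic ungapped columns

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total_carriers(self) -> int:
        return sum(sum(c.values()) for c in self.counts)


@dataclass(frozen=True)
class HaplotypeNetwork:
    """MSN over unique haplotypes; every edge lies in some minimum
    spanning tree, and ``essential`` edges lie in every one."""

    graph: nx.Graph
    haplotype_set: HaplotypeSet

    def edges(self) -> list[tuple[str, str, int, bool]]:
        return sorted(
            (min(u, v), max(u, v), d["weight"], d["essential"])
            for u, v, d in self.graph.edges(data=True)
        )

    def write_graphml(self, path: str) -> None:
        g = self.graph.copy()
        for node, data in g.nodes(data=True):
            data["pop_counts"] = ";".join(
                f"{p}:{c}" for p, c in sorted(data["pop_counts"].items())
            )
        nx.write_graphml(g, path)

    def to_edge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.edges(), columns=["node1", "node2", "steps", "in_every_mst"]
        )


def collapse_haplotypes(fasta, popmap: PopulationMap) -> HaplotypeSet:
    """Merge identical aligned sequences into unique haplotypes.

    ``fasta`` is a path to an aligned FASTA (or a list of (id, sequence)
    pairs); every id must appear in ``popmap``.  Sequences must share one
    alignment length.  The count of polymorphic ungapped columns is
    reported as ``n_segregating``.
    """
    if isinstance(fasta, (str, bytes)):
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fasta, "fasta")]
    else:
        records = [(name, str(seq)) for name, seq in fasta]
    if not records:
        raise ValueError("no sequences")
    seqs = [s.upper() for _, s in records]
    length = len(seqs[0])
    for name, s in zip((n for n, _ in records), seqs):
        if len(s) != length:
            raise ValueError(f"sequence {name!r} length {len(s)} != {length}")
    for name, _ in records:
        if name not in popmap.assignment:
            raise ValueError(f"sample {name!r} missing from population map")
    _check_ambiguity(seqs)

    uniq: dict[str, int] = {}
    haplotypes: list[str] = []
    counts: list[Counter] = []
    members: dict[str, int] = {}
    for (name, _), seq in zip(records, seqs):
        if seq not in uniq:
            uniq[seq] = len(haplotypes)
            haplotypes.append(seq)
            counts.append(Counter())
        idx = uniq[seq]
        counts[idx][popmap.assignment[name]] += 1
        members[name] = idx

    keep = _ungapped_columns(haplotypes)
    arr = np.array([list(h) for h in haplotypes])[:, keep]
    n_segregating = int(sum(len(set(arr[:, j])) > 1 for j in range(arr.shape[1])))
    names = [f"H{i + 1}" for i in range(len(haplotypes))]
    return HaplotypeSet(
        haplotypes=haplotypes,
        names=names,
        counts=counts,
        members=members,
        n_segregating=n_segregating,
    )


def hamming_distance(h1: str, h2: str) -> int:
    """Substitution count between two aligned sequences.

    Columns where either sequence carries a gap are excluded; comparison
    is case-insensitive.
    """
    if len(h1) != len(h2):
        raise ValueError(f"length mismatch: {len(h1)} vs {len(h2)}")
    a, b = h1.upper(), h2.upper()
    _check_ambiguity([a, b])
    return sum(
        1
        for x, y in zip(a, b)
        if x not in _GAPS and y not in _GAPS and x != y
    )


def _distance_matrix(haps: list[str]) -> np.ndarray:
    keep = _ungapped_columns([h.upper() for h in haps])
    arr = np.array([list(h.upper()) for h in haps])[:, keep]
    n = len(haps)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = int((arr[i] != arr[j]).sum())
    return d


def minimum_spanning_network(hapset: HaplotypeSet) -> HaplotypeNetwork:
    """Union-of-all-MSTs network by Kruskal growth over distance classes.

    Edges are grouped by distance; within each class, every edge joining
    two components that were distinct at the start of the class is
    admitted (so tie alternatives are all kept), then the components are
    merged.  An admitted edge is flagged ``essential`` (in every MST) iff
    it is the only admitted edge of its class joining that component pair.
    """
    names = hapset.names
    n = len(names)
    g = nx.Graph()
    for i, name in enumerate(names):
        g.add_node(
            name,
            count=sum(hapset.counts[i].values()),
            pop_counts=dict(hapset.counts[i]),
        )
    if n <= 1:
        return HaplotypeNetwork(graph=g, haplotype_set=hapset)

    dist = _distance_matrix(hapset.haplotypes)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = [(dist[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    edges.sort()
    k = 0
    while k < len(edges):
        weight = edges[k][0]
        cls = []
        while k < len(edges) and edges[k][0] == weight:
            cls.append(edges[k])
            k += 1
        comp_start = [find(i) for i in range(n)]
        admitted = [
            (w, i, j) for w, i, j in cls if comp_start[i] != comp_start[j]
        ]
        pair_counts = Counter(
            tuple(sorted((comp_start[i], comp_start[j]))) for _, i, j in admitted
        )
        # an edge is in every MST iff, contracting all lighter edges, it is
        # a bridge of its weight class and has no tie between the same pair
        class_graph = nx.Graph(pair_counts.keys())
        bridges = set(frozenset(e) for e in nx.bridges(class_graph)) if class_graph else set()
        for w, i, j in admitted:
            pair = tuple(sorted((comp_start[i], comp_start[j])))
            essential = pair_counts[pair] == 1 and frozenset(pair) in bridges
            g.add_edge(names[i], names[j], weight=int(w), essential=essential)
        for _, i, j in admitted:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    return HaplotypeNetwork(graph=g, haplotype_set=hapset)
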