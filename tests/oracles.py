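"""Independent reference implementations used as test oracles.

These deliberately avoid the package's vectorized code paths: plain
loops, exhaustive enumeration, and direct transcriptions of the
published estimator formulas.  They are slow and only run on tiny
fixtures.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

MISSING = -1


def wc84_two_pop_site(geno1: list[int], geno2: list[int]):
    """Weir & Cockerham (1984) variance components for one biallelic site
    and two populations, transcribed directly from the published formulas
    for r = 2 subpopulations of diploids with observed heterozygosity.

    Genotypes are 0/1/2 dosages; missing entries must be pre-filtered.
    Returns (a, b, c) or None where the estimator is undefined.
    """
    n1, n2 = len(geno1), len(geno2)
    if n1 == 0 or n2 == 0:
        return None
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    if nc == 0:
        return None
    p1 = sum(geno1) / (2 * n1)
    p2 = sum(geno2) / (2 * n2)
    h1 = sum(1 for g in geno1 if g == 1) / n1
    h2 = sum(1 for g in geno2 if g == 1) / n2
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)

    a = (nbar / nc) * (
        s2
        - (1 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def roh_exhaustive(pos, calls, params):
    """Exhaustive-interval ROH oracle.

    Hit status per SNP is computed by brute force over every scanning
    window; then EVERY SNP interval [i, j] is tested against the segment
    rules (all SNPs hits, no internal gap above the limit, maximal,
    minimum length / SNP count / density).  Returns sorted
    (start_pos, end_pos, n_snps) tuples.
    """
    n = len(pos)
    w = params.window_snps
    if n < w:
        return []
    win_ok = []
    for t in range(n - w + 1):
        chunk = calls[t : t + w]
        n_het = sum(1 for g in chunk if g == 1)
        n_mis = sum(1 for g in chunk if g == MISSING)
        win_ok.append(
            n_het <= params.window_het_max and n_mis <= params.window_missing_max
        )
    hit = []
    for i in range(n):
        lo = max(0, i - w + 1)
        hi = min(i, n - w)
        overlapping = win_ok[lo : hi + 1]
        hit.append(sum(overlapping) / len(overlapping) >= params.hit_fraction)

    # prefix sums for O(1) interval checks
    hit_prefix = [0]
    for h in hit:
        hit_prefix.append(hit_prefix[-1] + (1 if h else 0))
    gap_break = [pos[i + 1] - pos[i] > params.gap_kb * 1000 for i in range(n - 1)]
    break_prefix = [0]
    for br in gap_break:
        break_prefix.append(break_prefix[-1] + (1 if br else 0))

    def all_hits(i, j):
        return hit_prefix[j + 1] - hit_prefix[i] == j - i + 1

    def no_break(i, j):
        return break_prefix[j] - break_prefix[i] == 0

    segments = []
    for i in range(n):
        for j in range(i, n):
            if not (all_hits(i, j) and no_break(i, j)):
                continue
            left_max = i == 0 or not hit[i - 1] or gap_break[i - 1]
            right_max = j == n - 1 or not hit[j + 1] or gap_break[j]
            if not (left_max and right_max):
                continue
            length = pos[j] - pos[i] + 1
            n_snps = j - i + 1
            if length < params.min_kb * 1000:
                continue
            if n_snps < params.min_snps:
                continue
            if length / n_snps > params.density_kb_per_snp * 1000:
                continue
            segments.append((int(pos[i]), int(pos[j]), n_snps))
    return sorted(segments)


def all_minimum_spanning_trees(nodes, weighted_edges):
    """Enumerate every spanning tree of a small graph; return
    (min_weight, [edge sets of all minimum spanning trees])."""
    n = len(nodes)
    best = None
    trees = []
    for subset in combinations(weighted_edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((u, v) for u, v, _ in subset)
        if not nx.is_connected(g):
            continue
        weight = sum(w for _, _, w in subset)
        edges = frozenset(frozenset((u, v)) for u, v, _ in subset)
        if best is None or weight < best:
            best = weight
            trees = [edges]
        elif weight == best:
            trees.append(edges)
    return best, trees
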