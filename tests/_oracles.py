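"""Independent brute-force oracles used to validate the implementation.

Each oracle restates the definition literally (pairwise rule checks, path
unions, exhaustive enumerations) and is deliberately written against a
different algorithmic route than the package code it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np


# --- neighborhood rules ----------------------------------------------------


def brute_force_neighborhoods(genes, max_gap=250, div_min=200, div_max=1000):
    """O(n²) pair check + transitive closure, then left-to-right divergent
    merge.  Genes must be sorted; returns a list of member-index tuples."""
    n = len(genes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i, j in combinations(range(n), 2):
        span = genes[i : j + 1]
        if len({g.strand for g in span}) != 1:
            continue
        gaps_ok = all(
            span[k + 1].start - span[k].end <= max_gap for k in range(len(span) - 1)
        )
        if gaps_ok:
            union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = sorted(
        (sorted(members) for members in groups.values()),
        key=lambda m: genes[m[0]].start,
    )
    # divergent merge, applied once left-to-right
    merged = []
    i = 0
    while i < len(clusters):
        if i + 1 < len(clusters):
            left, right = clusters[i], clusters[i + 1]
            left_strands = {genes[k].strand for k in left}
            right_strands = {genes[k].strand for k in right}
            gap = genes[right[0]].start - max(genes[k].end for k in left)
            if (
                left_strands == {"-"}
                and right_strands == {"+"}
                and div_min <= gap <= div_max
            ):
                merged.append(tuple(left + right))
                i += 2
                continue
        merged.append(tuple(clusters[i]))
        i += 1
    return merged


# --- homology --------------------------------------------------------------


def brute_force_components(universe, edges):
    """Union-find over explicit edge list; returns frozenset of frozensets."""
    parent = {p: p for p in universe}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a, b in edges:
        parent[find(a)] = find(b)
    groups: dict[str, set] = {}
    for p in universe:
        groups.setdefault(find(p), set()).add(p)
    return frozenset(frozenset(g) for g in groups.values())


# --- Steiner subtree / phylogenetic diversity ------------------------------


def steiner_length_by_paths(tree, leaf_set):
    """PD as the union of edges on pairwise leaf paths (networkx route)."""
    g = nx.Graph()
    ids = {}

    def node_id(node):
        if id(node) not in ids:
            ids[id(node)] = len(ids)
        return ids[id(node)]

    for node in tree.traverse(include_self=True):
        for child in node.children:
            g.add_edge(
                node_id(node), node_id(child), weight=child.length or 0.0
            )
    leaves = {t.name: node_id(t) for t in tree.tips()}
    s = sorted(leaf_set)
    if len(s) <= 1:
        return 0.0
    edges = set()
    for a, b in combinations(s, 2):
        path = nx.shortest_path(g, leaves[a], leaves[b])
        edges.update(frozenset(e) for e in zip(path, path[1:]))
    return sum(g.edges[tuple(e)]["weight"] for e in edges)


# --- F1max (literal per-protein transcription) -----------------------------


def f1max_literal(truth, scores):
    """Set-based transcription of the protein-centric F1max definition."""
    grid = [round(0.1 * i, 1) for i in range(11)]
    labels = list(scores.columns)
    n = len(scores.index)
    best = 0.0
    for t in grid:
        prs, rcs = [], []
        for pid in scores.index:
            P = {f for f in labels if scores.at[pid, f] >= t}
            T = truth[pid]
            tp = len(P & T)
            if P:
                prs.append(tp / len(P))
            rcs.append(tp / len(T))
        m = len(prs)
        avg_pr = sum(prs) / m if m else 0.0
        avg_rc = sum(rcs) / n
        if m == 0 or avg_pr + avg_rc == 0:
            f1 = 0.0
        else:
            f1 = 2 * avg_pr * avg_rc / (avg_pr + avg_rc)
        best = max(best, f1)
    return best


# --- Wilcoxon signed-rank, exact by sign enumeration -----------------------


def wilcoxon_exact_enumeration(a, b):
    """Two-sided exact p by enumerating all 2^n sign assignments (n ≤ 16)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    assert n <= 16
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        midrank = (pos + (pos + (j - i))) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        pos += j - i + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    stats = []
    for mask in range(2 ** n):
        w = sum(ranks[k] for k in range(n) if mask >> k & 1)
        stats.append(w)
    stats = np.asarray(stats)
    w_min = min(w_obs, total - w_obs)
    p = np.mean(np.minimum(stats, total - stats) <= w_min + 1e-12)
    return min(1.0, float(p))


# --- hypergeometric upper tail by enumeration ------------------------------


def hypergeom_tail_enumeration(x, N, K, n_draw):
    """P(X ≥ x) summed term by term with exact binomial coefficients."""
    denom = comb(N, n_draw)
    total = 0
    for k in range(x, min(K, n_draw) + 1):
        total += comb(K, k) * comb(N - K, n_draw - k)
    return total / denom


# --- RF-ML weights, literal loop -------------------------------------------


def rfml_weights_literal(X, Y, k_nn):
    """Naive per-pair accumulation of the multi-label ReliefF update."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    L = Y.shape[1]
    k = min(k_nn, n - 1)
    n_dy = 0.0
    n_df = np.zeros(p)
    n_dydf = np.zeros(p)
    for i in range(n):
        dists = [sum(abs(X[i] - X[j])) / 3.0 for j in range(n)]
        # Python's sort is stable, mirroring np.argsort(kind="stable")
        order = sorted(range(n), key=lambda j: dists[j])
        neighbors = [j for j in order if j != i][:k]
        for j in neighbors:
            dl = sum(Y[i] != Y[j]) / L
            n_dy += dl
            for f in range(p):
                diff = abs(X[i, f] - X[j, f]) / 3.0
                n_df[f] += diff
                n_dydf[f] += dl * diff
    m_total = n * k
    if n_dy == 0:
        return np.zeros(p)
    hit = m_total - n_dy
    return n_dydf / n_dy - (
        (n_df - n_dydf) / hit if hit > 0 else np.zeros(p)
    )
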