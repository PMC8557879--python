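"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from textbook definitions with explicit loops and
sums, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def average_ranks(values) -> list[float]:
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y) -> float:
    return pearson_brute(average_ranks(x), average_ranks(y))


def correlation_matrix_brute(matrix, method: str):
    """matrix: list of rows (genes); returns dense list-of-lists correlation."""
    n = len(matrix)
    fn = pearson_brute if method == "pearson" else spearman_brute
    out = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            r = fn(matrix[i], matrix[j])
            out[i][j] = out[j][i] = r
    return out


def rank_lists_brute(corr, gene_ids):
    """Rank table by descending correlation, ties by ascending gene id."""
    n = len(gene_ids)
    ranks = [[0] * n for _ in range(n)]
    for i in range(n):
        others = [j for j in range(n) if j != i]
        others.sort(key=lambda j: (-corr[i][j], gene_ids[j]))
        for pos, j in enumerate(others, start=1):
            ranks[i][j] = pos
    return ranks


def mutual_rank_brute(corr, gene_ids):
    r = rank_lists_brute(corr, gene_ids)
    n = len(gene_ids)
    mr = [[float("nan")] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                mr[i][j] = math.sqrt(r[i][j] * r[j][i])
    return mr


def decay_weight_brute(mr: float, x: float) -> float:
    return math.exp(-(mr - 1.0) / x)


# -- module-detection oracle ------------------------------------------------

def cohesiveness_brute(edges, genes, penalty: float) -> float:
    """edges: dict[frozenset({a, b})] -> weight."""
    genes = set(genes)
    w_in = sum(w for e, w in edges.items() if e <= genes)
    w_bound = sum(w for e, w in edges.items() if len(e & genes) == 1)
    denom = w_in + w_bound + penalty * len(genes)
    return w_in / denom if denom > 0 else 0.0


def density_brute(edges, genes) -> float:
    genes = set(genes)
    n = len(genes)
    if n < 2:
        return 0.0
    w_in = sum(w for e, w in edges.items() if e <= genes)
    return w_in / (n * (n - 1) / 2)


def is_locally_optimal(edges, nodes, genes, penalty: float, tol=1e-12) -> bool:
    """No single add (of an incident outside node) or remove improves f."""
    genes = set(genes)
    base = cohesiveness_brute(edges, genes, penalty)
    incident = {
        v for e in edges for v in e if len(e & genes) == 1 and v not in genes
    }
    for v in incident:
        if cohesiveness_brute(edges, genes | {v}, penalty) > base + tol:
            return False
    if len(genes) > 1:
        for v in genes:
            if cohesiveness_brute(edges, genes - {v}, penalty) > base + tol:
                return False
    return True


def enumerate_locally_optimal(edges, nodes, penalty, min_size, min_density):
    """All locally optimal subsets passing the size/density filters (<=~20 nodes)."""
    nodes = sorted(nodes)
    out = []
    for r in range(min_size, len(nodes) + 1):
        for comb in itertools.combinations(nodes, r):
            genes = frozenset(comb)
            if density_brute(edges, genes) < min_density:
                continue
            if is_locally_optimal(edges, nodes, genes, penalty):
                out.append(genes)
    return out


def graph_to_edges(network):
    """networkx graph -> {frozenset({a, b}): weight} dict for the oracles."""
    return {
        frozenset((a, b)): d.get("weight", 1.0)
        for a, b, d in network.edges(data=True)
    }
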