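"""Overlapping module detection by greedy cohesiveness optimisation.

Re-implements the cohesiveness-based overlapping graph clustering scheme
popularised for protein-complex detection (ClusterONE).  The quality of a
gene set V in a weighted network is its *cohesiveness*

    f(V) = w_in / (w_in + w_bound + p * |V|)

where w_in is the total weight of edges inside V, w_bound the total weight
of edges crossing V's boundary, and p a per-node penalty (default 2)
modelling unobserved connectivity.  Starting from a seed node, the single
best add-a-neighbour / remove-a-member step is applied while it strictly
increases f; the resulting locally optimal sets are filtered by size and
density, and near-duplicates (overlap score omega >= 0.8) are merged.
Modules may overlap — a gene can belong to several modules, which is how a
shared regulator shows up in the modules of each of its target pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

DEFAULT_MIN_SIZE = 3
DEFAULT_MIN_DENSITY = 0.3
DEFAULT_PENALTY = 2.0
DEFAULT_MERGE_OVERLAP = 0.8

_EPS = 1e-12


@dataclass(frozen=True)
class Module:
    """A (possibly overlapping) cohesive gene set from one network."""

    genes: frozenset[str]
    cohesiveness: float
    density: float
    source_network: str = ""
    module_id: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Metamodule:
    """Non-overlapping union of all modules containing the anchor genes."""

    genes: frozenset[str]
    contributing_modules: tuple[Module, ...]
    anchor_genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def _in_bound_weights(network: nx.Graph, genes: set[str]) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for u in genes:
        for v, data in network[u].items():
            w = data.get("weight", 1.0)
            if v in genes:
                w_in += w / 2.0  # each internal edge visited twice
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(network: nx.Graph, genes, penalty: float = DEFAULT_PENALTY) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty * |V|); 0 for a bare vertex."""
    genes = set(genes)
    if not genes:
        raise ValueError("cohesiveness of an empty gene set")
    if not genes <= set(network.nodes):
        raise ValueError("gene set contains nodes absent from the network")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    w_in, w_bound = _in_bound_weights(network, genes)
    denom = w_in + w_bound + penalty * len(genes)
    return w_in / denom if denom > 0 else 0.0


def density(network: nx.Graph, genes) -> float:
    """Internal weight density: w_in over the number of possible pairs."""
    genes = set(genes)
    n = len(genes)
    if n < 2:
        return 0.0
    w_in, _ = _in_bound_weights(network, genes)
    return w_in / (n * (n - 1) / 2.0)


def grow_module(
    network: nx.Graph,
    seed: str,
    penalty: float = DEFAULT_PENALTY,
    _degw: dict | None = None,
) -> Module:
    """Greedily grow a locally optimal cohesive set from one seed gene.

    At each step every external node incident to the set and every internal
    node is evaluated; the move with the largest strict cohesiveness gain is
    applied (ties broken by ascending gene id).  Terminates when no single
    add/remove improves f, so the result is locally optimal by construction
    and deterministic.
    """
    if seed not in network:
        raise ValueError(f"seed gene {seed!r} is not a network node")
    degw = _degw if _degw is not None else dict(network.degree(weight="weight"))

    members: set[str] = {seed}
    link = {v: d.get("weight", 1.0) for v, d in network[seed].items()}  # u -> w(u, V)
    w_in = 0.0
    w_bound = sum(link.values())

    def f(wi: float, wb: float, n: int) -> float:
        denom = wi + wb + penalty * n
        return wi / denom if denom > 0 else 0.0

    current = f(w_in, w_bound, 1)
    while True:
        best: tuple[float, str, str] | None = None  # (f_new, gene, action)
        n = len(members)
        for u, d_in in link.items():
            if u in members or d_in <= 0:
                continue
            f_new = f(w_in + d_in, w_bound - d_in + (degw[u] - d_in), n + 1)
            if best is None or f_new > best[0] or (f_new == best[0] and u < best[1]):
                best = (f_new, u, "add")
        if n > 1:
            for u in members:
                d_in = link.get(u, 0.0)
                f_new = f(w_in - d_in, w_bound + d_in - (degw[u] - d_in), n - 1)
                if best is None or f_new > best[0] or (f_new == best[0] and u < best[1]):
                    best = (f_new, u, "remove")
        if best is None or best[0] <= current + _EPS:
            break
        _, u, action = best
        if action == "add":
            members.add(u)
            d_in = link.get(u, 0.0)
            w_in += d_in
            w_bound += degw[u] - 2 * d_in
        else:
            members.remove(u)
            d_in = link.get(u, 0.0)
            w_in -= d_in
            w_bound -= degw[u] - 2 * d_in
        sign = 1.0 if action == "add" else -1.0
        for v, data in network[u].items():
            link[v] = link.get(v, 0.0) + sign * data.get("weight", 1.0)
        current = best[0]

    return Module(
        genes=frozenset(members),
        cohesiveness=cohesiveness(network, members, penalty),
        density=density(network, members),
        source_network=str(network.graph.get("name", "")),
    )


def _overlap_score(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def detect_modules(
    network: nx.Graph,
    min_size: int = DEFAULT_MIN_SIZE,
    min_density: float = DEFAULT_MIN_DENSITY,
    penalty: float = DEFAULT_PENALTY,
    merge_overlap: float = DEFAULT_MERGE_OVERLAP,
    seed_mode: str = "unused",
) -> list[Module]:
    """Detect overlapping cohesive modules in a weighted network.

    Seeds are taken in decreasing weighted-degree order (ties by gene id);
    with ``seed_mode="unused"`` (default) a node already covered by a grown
    module is not re-seeded, with ``"all"`` every node seeds a growth.
    Grown sets smaller than ``min_size`` or sparser than ``min_density`` are
    discarded; candidates whose overlap score omega(A,B) = |A&B|^2/(|A||B|)
    reaches ``merge_overlap`` are merged transitively into their union.
    Output is sorted by descending cohesiveness (ties by gene list).
    """
    if seed_mode not in ("unused", "all"):
        raise ValueError(f"unknown seed_mode: {seed_mode!r}")
    if network.number_of_nodes() == 0:
        return []
    degw = dict(network.degree(weight="weight"))
    order = sorted(network.nodes, key=lambda v: (-degw[v], v))
    covered: set[str] = set()
    grown: list[Module] = []
    seen_sets: set[frozenset] = set()
    for v in order:
        if seed_mode == "unused" and v in covered:
            continue
        m = grow_module(network, v, penalty, _degw=degw)
        covered |= m.genes
        if m.genes not in seen_sets:
            seen_sets.add(m.genes)
            grown.append(m)

    kept = [m for m in grown if len(m) >= min_size and m.density >= min_density]

    # Merge near-duplicates: connected components of the omega >= threshold
    # graph over candidates, each component collapsed to its union.
    og = nx.Graph()
    og.add_nodes_from(range(len(kept)))
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if _overlap_score(kept[i].genes, kept[j].genes) >= merge_overlap:
                og.add_edge(i, j)
    merged: list[Module] = []
    for comp in nx.connected_components(og):
        comp = sorted(comp)
        if len(comp) == 1:
            merged.append(kept[comp[0]])
        else:
            union = frozenset().union(*(kept[i].genes for i in comp))
            merged.append(
                Module(
                    genes=union,
                    cohesiveness=cohesiveness(network, union, penalty),
                    density=density(network, union),
                    source_network=str(network.graph.get("name", "")),
                )
            )

    merged.sort(key=lambda m: (-m.cohesiveness, sorted(m.genes)))
    label = str(network.graph.get("name", "NET"))
    return [
        Module(m.genes, m.cohesiveness, m.density, m.source_network,
               module_id=f"{label}:m{i:04d}")
        for i, m in enumerate(merged)
    ]


def collapse_metamodule(all_modules, anchor_genes) -> Metamodule:
    """Union of the genes of every module containing at least one anchor.

    Modules may come from any number of networks; the metamodule is a flat,
    non-overlapping gene set.  If no module contains an anchor an empty
    metamodule is returned with a warning.
    """
    anchors = frozenset(anchor_genes)
    if not anchors:
        raise ValueError("anchor_genes must be non-empty")
    contributing = tuple(m for m in all_modules if m.genes & anchors)
    if not contributing:
        warnings.warn("no module contains any anchor gene; metamodule is empty")
    genes = frozenset().union(*(m.genes for m in contributing)) if contributing else frozenset()
    return Metamodule(genes=genes, contributing_modules=contributing, anchor_genes=anchors)
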