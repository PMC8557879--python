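"""Coexpression network construction: SCC and mutual-rank (MR-PCC) graphs.

Two complementary network types are built from a scaled expression matrix:

* **SCC network** — an edge wherever the absolute Spearman rank correlation
  between two genes meets a fixed threshold (default |rho| >= 0.5).  Good at
  exposing large global coexpression neighbourhoods.
* **MR-PCC network** — Pearson correlations are converted to *mutual ranks*:
  for each gene, all other genes are ranked from most to least correlated,
  and MR(A,B) = sqrt(Rank_A(B) * Rank_B(A)).  MR is then mapped to an edge
  weight by the exponential decay exp(-(MR-1)/x); edges failing either the
  Pearson floor (default 0.3, signed) or the weight floor (default 0.1) are
  dropped.  Because a rarely expressed gene's top ranks are still owned by
  its genuinely co-regulated partners, MR is robust where sparse expression
  vectors make plain correlation spurious.

The decay parameter x controls stringency; the conventional trio x = 5, 10,
25 yields nested networks named NET05 / NET10 / NET25 (smaller x prunes
more).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_PCC_MIN = 0.3
DEFAULT_WEIGHT_MIN = 0.1
DEFAULT_RHO_MIN = 0.5
DEFAULT_XS = (5, 10, 25)


class CorrelationError(ValueError):
    """Raised for inputs a correlation matrix cannot be computed from."""


@dataclass(frozen=True)
class CorrelationMatrix:
    gene_ids: tuple[str, ...]
    values: np.ndarray  # symmetric, diag 1, in [-1, 1]
    method: str  # "pearson" | "spearman"


@dataclass(frozen=True)
class MutualRankMatrix:
    gene_ids: tuple[str, ...]
    values: np.ndarray  # symmetric, >= 1 off-diagonal; diagonal is NaN


def zero_variance_genes(matrix: pd.DataFrame) -> list[str]:
    v = matrix.to_numpy()
    flat = v.std(axis=1) == 0
    return [g for g, z in zip(matrix.index, flat) if z]


def drop_zero_variance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove constant-profile genes (undefined correlation) from the matrix."""
    dropped = zero_variance_genes(matrix)
    if dropped:
        matrix = matrix.drop(index=dropped)
    return matrix, dropped


def correlation_all_pairs(matrix: pd.DataFrame, method: str) -> CorrelationMatrix:
    """All-pairs gene-gene correlation across samples.

    Spearman uses average ranks for ties.  Genes with zero variance must be
    removed first (see :func:`drop_zero_variance`); their correlations are
    undefined.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method: {method!r}")
    if matrix.shape[1] < 3:
        raise CorrelationError("correlation requires at least 3 samples")
    zv = zero_variance_genes(matrix)
    if zv:
        raise CorrelationError(
            "zero-variance gene(s) present, drop them first: " + ", ".join(zv)
        )
    data = matrix.to_numpy(dtype=float)
    if method == "spearman":
        data = rankdata(data, axis=1)
    with np.errstate(invalid="raise"):
        corr = np.corrcoef(data)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(tuple(matrix.index), corr, method)


def rank_lists(corr: CorrelationMatrix) -> np.ndarray:
    """Integer rank table R with R[i, j] = rank of gene j in gene i's list.

    Each gene's list orders all *other* genes from most to least correlated;
    ties are broken by ascending gene id.  The diagonal (self) is 0.
    """
    n = len(corr.gene_ids)
    lex = np.empty(n, dtype=np.int64)
    lex[np.argsort(np.asarray(corr.gene_ids))] = np.arange(n)
    ranks = np.zeros((n, n), dtype=np.int64)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        order = np.lexsort((lex[others], -corr.values[i, others]))
        ranks[i, others[order]] = np.arange(1, n)
    return ranks


def mutual_rank(corr: CorrelationMatrix) -> MutualRankMatrix:
    """MR(A,B) = geometric mean of the two genes' reciprocal ranks."""
    r = rank_lists(corr).astype(float)
    mr = np.sqrt(r * r.T)
    np.fill_diagonal(mr, np.nan)
    return MutualRankMatrix(corr.gene_ids, mr)


def decay_weight(mr, x: float):
    """Map a mutual rank to an edge weight via exp(-(MR-1)/x).

    Strictly decreasing in MR; equals 1 at MR = 1 for every x, and crosses
    0.1 at MR = 1 + x*ln(10).
    """
    if x <= 0:
        raise ValueError(f"x must be positive, got {x}")
    arr = np.asarray(mr, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 1):
        raise ValueError("mutual rank must be >= 1")
    out = np.exp(-(arr - 1.0) / x)
    return float(out) if np.isscalar(mr) or arr.ndim == 0 else out


def _network_name(x: float) -> str:
    return f"NET{int(x):02d}" if float(x).is_integer() else f"NET{x:g}"


def build_mr_networks(
    matrix: pd.DataFrame,
    xs: tuple[float, ...] = DEFAULT_XS,
    pcc_min: float = DEFAULT_PCC_MIN,
    weight_min: float = DEFAULT_WEIGHT_MIN,
) -> dict[str, nx.Graph]:
    """Build one MR-PCC network per decay parameter, sharing one MR pass.

    An edge (A, B) is kept iff PCC(A,B) >= pcc_min (signed) and
    decay_weight(MR(A,B), x) >= weight_min.  Nodes carry every gene.
    """
    if matrix.shape[0] < 2:
        raise CorrelationError("network construction requires at least 2 genes")
    corr = correlation_all_pairs(matrix, "pearson")
    mr = mutual_rank(corr)
    genes = corr.gene_ids
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    pcc_ok = corr.values[iu] >= pcc_min
    nets: dict[str, nx.Graph] = {}
    for x in xs:
        w = decay_weight(np.where(np.isnan(mr.values[iu]), 1.0, mr.values[iu]), x)
        keep = pcc_ok & (w >= weight_min)
        g = nx.Graph(
            name=_network_name(x),
            method="mr-pcc",
            x=float(x),
            pcc_min=float(pcc_min),
            weight_min=float(weight_min),
        )
        g.add_nodes_from(genes)
        for a, b, wt, pcc in zip(
            iu[0][keep], iu[1][keep], w[keep], corr.values[iu][keep]
        ):
            g.add_edge(genes[a], genes[b], weight=float(wt), pcc=float(pcc))
        nets[g.graph["name"]] = g
    return nets


def build_mr_network(
    matrix: pd.DataFrame,
    x: float,
    pcc_min: float = DEFAULT_PCC_MIN,
    weight_min: float = DEFAULT_WEIGHT_MIN,
) -> nx.Graph:
    """Single-x convenience wrapper around :func:`build_mr_networks`."""
    return next(iter(build_mr_networks(matrix, (x,), pcc_min, weight_min).values()))


def build_scc_network(matrix: pd.DataFrame, rho_min: float = DEFAULT_RHO_MIN) -> nx.Graph:
    """Spearman network: edge wherever |rho| >= rho_min; edges carry signed rho."""
    if matrix.shape[0] < 2:
        raise CorrelationError("network construction requires at least 2 genes")
    corr = correlation_all_pairs(matrix, "spearman")
    genes = corr.gene_ids
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    keep = np.abs(corr.values[iu]) >= rho_min
    g = nx.Graph(name="SCC", method="scc", rho_min=float(rho_min))
    g.add_nodes_from(genes)
    for a, b, rho in zip(iu[0][keep], iu[1][keep], corr.values[iu][keep]):
        g.add_edge(genes[a], genes[b], rho=float(rho), weight=float(abs(rho)))
    return g


def subnetwork_containing(network: nx.Graph, genes) -> nx.Graph:
    """Union of the connected components containing any query gene."""
    genes = set(genes) & set(network.nodes)
    keep: set[str] = set()
    for comp in nx.connected_components(network):
        if comp & genes:
            keep |= comp
    sub = network.subgraph(keep).copy()
    sub.graph.update(network.graph)
    return sub


def largest_component(network: nx.Graph) -> nx.Graph:
    """The largest connected component (ties broken by smallest member id)."""
    if network.number_of_nodes() == 0:
        return network.copy()
    comp = sorted(nx.connected_components(network), key=lambda c: (-len(c), min(c)))[0]
    sub = network.subgraph(comp).copy()
    sub.graph.update(network.graph)
    return sub
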