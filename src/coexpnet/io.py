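"""Plain-text readers and writers for every pipeline artifact.

Conventions shared by all writers: tab-separated text, LF line endings,
floats at 6 decimals, optional ``# key=value`` provenance header lines that
readers skip.  Timestamps are never written, so fixed-seed reruns are
byte-identical.
"""

from __future__ import annotations

import json
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .modules import Metamodule, Module

FLOAT_FMT = "%.6f"


class ParseError(ValueError):
    """Raised for malformed input files; message carries the line number."""


def _provenance_lines(provenance: Mapping | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}={provenance[k]}" for k in provenance]


# -- expression matrices ----------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    ``#`` lines are skipped; ragged rows, duplicate ids and non-numeric
    cells raise :class:`ParseError` with the offending line number.
    """
    with open(path, newline=None) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln and not ln.startswith("#")]
    if not rows:
        raise ParseError(f"{path}: no data rows")
    header = rows[0][1].split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: line {rows[0][0]}: duplicate sample ids")
    if not samples:
        raise ParseError(f"{path}: line {rows[0][0]}: header has no sample columns")
    genes: list[str] = []
    seen: set[str] = set()
    data: list[list[float]] = []
    for lineno, ln in rows[1:]:
        cells = ln.split("\t")
        if len(cells) != len(samples) + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {len(samples) + 1} columns, "
                f"got {len(cells)}"
            )
        gene = cells[0]
        if gene in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        try:
            vals = [float(c) for c in cells[1:]]
        except ValueError:
            bad = next(c for c in cells[1:] if not _is_float(c))
            raise ParseError(
                f"{path}: line {lineno}: non-numeric cell {bad!r}"
            ) from None
        if not all(np.isfinite(vals)):
            raise ParseError(f"{path}: line {lineno}: non-finite value")
        genes.append(gene)
        data.append(vals)
    if not genes:
        raise ParseError(f"{path}: no gene rows")
    return pd.DataFrame(data, index=genes, columns=samples)


def _is_float(c: str) -> bool:
    try:
        float(c)
        return True
    except ValueError:
        return False


def write_expression_tsv(matrix: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        for ln in _provenance_lines(provenance):
            fh.write(ln + "\n")
        fh.write("gene_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gene, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


# -- networks ---------------------------------------------------------------

def write_network_tsv(network: nx.Graph, path) -> None:
    """Edge list TSV; graph-level construction parameters go in the header.

    MR networks write gene_a/gene_b/weight/pcc, the SCC network
    gene_a/gene_b/weight/rho (signed).
    """
    attr = "rho" if network.graph.get("method") == "scc" else "pcc"
    prov = {k: v for k, v in sorted(network.graph.items())}
    with open(path, "w", newline="\n") as fh:
        for ln in _provenance_lines(prov):
            fh.write(ln + "\n")
        fh.write(f"gene_a\tgene_b\tweight\t{attr}\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            d = network.edges[a, b]
            fh.write(
                f"{a}\t{b}\t{FLOAT_FMT % d['weight']}\t{FLOAT_FMT % d.get(attr, 0.0)}\n"
            )


def read_network_tsv(path) -> nx.Graph:
    with open(path, newline=None) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    g = nx.Graph()
    header_meta: dict[str, str] = {}
    body: list[tuple[int, str]] = []
    for i, ln in enumerate(lines):
        if not ln:
            continue
        if ln.startswith("# ") and "=" in ln:
            k, v = ln[2:].split("=", 1)
            header_meta[k] = v
        elif not ln.startswith("#"):
            body.append((i + 1, ln))
    if not body:
        raise ParseError(f"{path}: no header row")
    cols = body[0][1].split("\t")
    if cols[:3] != ["gene_a", "gene_b", "weight"] or len(cols) != 4:
        raise ParseError(f"{path}: line {body[0][0]}: unexpected header {cols}")
    attr = cols[3]
    for k in ("name", "method"):
        if k in header_meta:
            g.graph[k] = header_meta[k]
    for k in ("x", "pcc_min", "weight_min", "rho_min"):
        if k in header_meta:
            g.graph[k] = float(header_meta[k])
    for lineno, ln in body[1:]:
        cells = ln.split("\t")
        if len(cells) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        try:
            w, extra = float(cells[2]), float(cells[3])
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric weight") from None
        g.add_edge(cells[0], cells[1], weight=w, **{attr: extra})
    return g


def write_network_graphml(network: nx.Graph, path) -> None:
    """GraphML export with deterministic node/edge order (Cytoscape-ready)."""
    g = nx.Graph(**network.graph)
    g.add_nodes_from(sorted(network.nodes))
    for a, b in sorted(tuple(sorted(e)) for e in network.edges):
        g.add_edge(a, b, **network.edges[a, b])
    nx.write_graphml(g, path)


def write_node_attributes_tsv(network: nx.Graph, catalog, path) -> None:
    """Per-node annotation table (BGC membership and role) for visualisation."""
    by_gene = catalog.by_gene
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tbgc_id\trole\tcore_type\n")
        for gene in sorted(network.nodes):
            e = by_gene.get(gene)
            if e is None:
                fh.write(f"{gene}\tnone\tother\tnone\n")
            else:
                fh.write(f"{gene}\t{e.bgc_id or 'none'}\t{e.role}\t{e.core_type}\n")


# -- modules ----------------------------------------------------------------

def write_modules_json(modules, path, provenance: Mapping | None = None) -> None:
    payload = {
        "provenance": dict(provenance) if provenance else {},
        "modules": [
            {
                "module_id": m.module_id,
                "genes": sorted(m.genes),
                "cohesiveness": round(m.cohesiveness, 6),
                "density": round(m.density, 6),
                "source_network": m.source_network,
            }
            for m in modules
        ],
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_modules_json(path) -> list[Module]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Module(
            genes=frozenset(m["genes"]),
            cohesiveness=float(m["cohesiveness"]),
            density=float(m["density"]),
            source_network=m.get("source_network", ""),
            module_id=m.get("module_id", ""),
        )
        for m in payload["modules"]
    ]


def write_modules_tsv(modules, path) -> None:
    """Flat membership table (gene, module id); overlapping genes repeat."""
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tmodule_id\n")
        for m in modules:
            for g in sorted(m.genes):
                fh.write(f"{g}\t{m.module_id}\n")


def write_metamodule_json(meta: Metamodule, path) -> None:
    payload = {
        "anchor_genes": sorted(meta.anchor_genes),
        "genes": sorted(meta.genes),
        "n_genes": len(meta.genes),
        "contributing_modules": sorted(
            m.module_id for m in meta.contributing_modules
        ),
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
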