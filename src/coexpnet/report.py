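"""BGC coexpression accounting and transcription-factor shortlisting.

Given a catalog of biosynthetic gene clusters (BGCs) — which genes belong
to which genomic cluster, and their roles (core synthase, tailoring enzyme,
transporter, TF, other) — this stage reports:

* per BGC, how many member genes were recovered in any coexpression module
  and whether the BGC counts as *coexpressed* (>= 2 member genes sharing at
  least one module);
* per TF of interest, how many BGC core genes it is coexpressed with under
  two complementary rules: the **SCC rule** (core genes directly connected
  to the TF by an edge of the Spearman network — the global-regulator
  signature) and the **MR rule** (core genes sharing at least one
  mutual-rank module with the TF — the pathway-specific signature);
* a shortlist of candidate secondary-metabolism regulators: TFs whose SCC
  count reaches a floor (default 10), plus TFs whose modules tie them to
  core genes of two or more distinct BGCs (the cross-cluster pattern).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx

from .modules import Module
from .simulate import PlantedTruth

ROLES = ("core", "tailoring", "transporter", "TF", "other")
CORE_TYPES = ("PKS", "NRPS", "FAS", "terpene", "hybrid", "other", "none")
_CATALOG_COLUMNS = ("gene_id", "bgc_id", "role", "core_type", "chromosome", "start", "end")
_NONE_TOKENS = ("", ".", "none", "NA")

DEFAULT_MIN_CORE = 10


class CatalogError(ValueError):
    """Raised for malformed or inconsistent BGC catalogs."""


@dataclass(frozen=True)
class CatalogEntry:
    gene_id: str
    bgc_id: str | None
    role: str
    core_type: str = "none"
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass
class BGCCatalog:
    """Validated catalog of BGC membership and gene roles."""

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.gene_id in seen:
                raise CatalogError(f"duplicate gene id in catalog: {e.gene_id}")
            seen.add(e.gene_id)
            if e.role not in ROLES:
                raise CatalogError(f"{e.gene_id}: unknown role {e.role!r}")
            if e.core_type not in CORE_TYPES:
                raise CatalogError(f"{e.gene_id}: unknown core_type {e.core_type!r}")
            if e.role == "core" and e.core_type == "none":
                raise CatalogError(f"{e.gene_id}: core gene must have a core_type")
            if (e.start is None) != (e.end is None):
                raise CatalogError(f"{e.gene_id}: start and end must come together")
            if e.start is not None and e.start > e.end:
                raise CatalogError(f"{e.gene_id}: start > end")

    @property
    def by_gene(self) -> dict[str, CatalogEntry]:
        return {e.gene_id: e for e in self.entries}

    @property
    def bgc_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.bgc_id is not None and e.bgc_id not in out:
                out.append(e.bgc_id)
        return out

    def genes_of(self, bgc_id: str) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries if e.bgc_id == bgc_id)

    @property
    def core_genes(self) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries if e.role == "core")

    @property
    def tf_genes(self) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries if e.role == "TF")


def load_catalog(path) -> BGCCatalog:
    """Read a catalog TSV (columns gene_id, bgc_id, role, core_type
    [, chromosome, start, end]); empty / '.' / 'none' / 'NA' mark absent
    optional values.  Parse errors carry the offending line number."""
    with open(path, newline=None) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    rows = [
        (i + 1, ln) for i, ln in enumerate(lines) if ln and not ln.startswith("#")
    ]
    if not rows:
        raise CatalogError(f"{path}: empty catalog")
    header = rows[0][1].split("\t")
    if tuple(header[:4]) != _CATALOG_COLUMNS[:4] or tuple(header) != _CATALOG_COLUMNS[: len(header)]:
        raise CatalogError(
            f"{path}: line {rows[0][0]}: header must be a prefix of "
            + "/".join(_CATALOG_COLUMNS)
        )
    entries = []
    for lineno, ln in rows[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise CatalogError(
                f"{path}: line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        rec = dict(zip(header, cells))
        bgc = rec["bgc_id"] if rec["bgc_id"] not in _NONE_TOKENS else None
        chrom = rec.get("chromosome") or None
        if chrom in _NONE_TOKENS:
            chrom = None
        start = end = None
        for key in ("start", "end"):
            val = rec.get(key)
            if val not in (None, *_NONE_TOKENS):
                try:
                    parsed = int(val)
                except ValueError:
                    raise CatalogError(
                        f"{path}: line {lineno}: non-integer {key}: {val!r}"
                    ) from None
                if key == "start":
                    start = parsed
                else:
                    end = parsed
        entries.append(
            CatalogEntry(rec["gene_id"], bgc, rec["role"],
                         rec.get("core_type", "none") or "none", chrom, start, end)
        )
    try:
        return BGCCatalog(tuple(entries))
    except CatalogError as err:
        raise CatalogError(f"{path}: {err}") from None


def write_catalog(catalog: BGCCatalog, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for e in catalog.entries:
            fh.write(
                "\t".join(
                    [
                        e.gene_id,
                        e.bgc_id if e.bgc_id is not None else "none",
                        e.role,
                        e.core_type,
                        e.chromosome if e.chromosome is not None else "none",
                        str(e.start) if e.start is not None else "none",
                        str(e.end) if e.end is not None else "none",
                    ]
                )
                + "\n"
            )


_ROLE_CYCLE = ("core", "tailoring", "core", "transporter", "core", "other")
_CORE_TYPE_CYCLE = ("PKS", "NRPS", "FAS", "terpene", "hybrid")


def catalog_from_truth(truth: PlantedTruth) -> BGCCatalog:
    """Derive a BGC catalog from a simulation's planted truth.

    Planted and silent groups become BGCs (``BGC<k>``); cluster-resident
    regulators are labelled TF, the remaining members cycle through
    core/tailoring/transporter roles (half of them core, cycling PKS, NRPS,
    FAS, terpene and hybrid core types).  Global regulators enter as
    unclustered TFs.  Coordinates are synthesised from the numeric gene
    index (1 kb per gene, 1-based inclusive).
    """
    entries: list[CatalogEntry] = []
    core_counter = 0

    def coords(gene_id: str) -> tuple[str, int, int]:
        idx = int("".join(ch for ch in gene_id if ch.isdigit()))
        return "chr1", idx * 1000 + 1, idx * 1000 + 1000

    bgc_num = 0
    blocks = [
        *sorted(truth.group_members.items()),
        *sorted(truth.silent_group_members.items()),
    ]
    residents = truth.resident_regulators
    for _, members in blocks:
        bgc_num += 1
        bgc_id = f"BGC{bgc_num:02d}"
        role_i = 0
        for gene in sorted(members):
            chrom, start, end = coords(gene)
            if gene in residents:
                entries.append(CatalogEntry(gene, bgc_id, "TF", "none", chrom, start, end))
                continue
            role = _ROLE_CYCLE[role_i % len(_ROLE_CYCLE)]
            role_i += 1
            ct = "none"
            if role == "core":
                ct = _CORE_TYPE_CYCLE[core_counter % len(_CORE_TYPE_CYCLE)]
                core_counter += 1
            entries.append(CatalogEntry(gene, bgc_id, role, ct, chrom, start, end))
    for gene in sorted(truth.global_regulators):
        chrom, start, end = coords(gene)
        entries.append(CatalogEntry(gene, None, "TF", "none", chrom, start, end))
    return BGCCatalog(tuple(entries))


@dataclass(frozen=True)
class BGCReportRow:
    bgc_id: str
    n_genes: int
    recovered_genes: tuple[str, ...]  # members appearing in >= 1 module
    coexpressed: bool  # >= 2 members share >= 1 module
    shared_module_ids: tuple[str, ...]
    module_ids: tuple[str, ...]  # every module touching the BGC

    @property
    def n_recovered(self) -> int:
        return len(self.recovered_genes)


@dataclass(frozen=True)
class TFReportRow:
    tf_id: str
    scc_count: int
    scc_core_genes: tuple[str, ...]
    mr_count: int
    mr_core_genes: tuple[str, ...]
    clustered: bool
    bgc_id: str | None
    mr_bgcs: tuple[str, ...]  # BGCs whose core genes share a module with the TF


@dataclass
class CoexpressionReport:
    bgcs: tuple[BGCReportRow, ...] = ()
    tfs: tuple[TFReportRow, ...] = ()

    @property
    def n_coexpressed_bgcs(self) -> int:
        return sum(1 for b in self.bgcs if b.coexpressed)


def _membership(modules) -> dict[str, set[str]]:
    member: dict[str, set[str]] = {}
    for m in modules:
        for g in m.genes:
            member.setdefault(g, set()).add(m.module_id)
    return member


def bgc_module_overlap(modules, catalog: BGCCatalog) -> CoexpressionReport:
    """Per-BGC recovery and coexpression flags against a module set."""
    member = _membership(modules)
    rows = []
    for bgc in catalog.bgc_ids:
        genes = sorted(catalog.genes_of(bgc))
        recovered = tuple(g for g in genes if g in member)
        touching: set[str] = set().union(*(member.get(g, set()) for g in genes)) if genes else set()
        shared = sorted(
            mid
            for mid in touching
            if sum(1 for g in genes if mid in member.get(g, set())) >= 2
        )
        rows.append(
            BGCReportRow(
                bgc_id=bgc,
                n_genes=len(genes),
                recovered_genes=recovered,
                coexpressed=bool(shared),
                shared_module_ids=tuple(shared),
                module_ids=tuple(sorted(touching)),
            )
        )
    return CoexpressionReport(bgcs=tuple(rows))


def tf_core_coexpression_counts(
    scc_net: nx.Graph,
    modules,
    catalog: BGCCatalog,
    tf_ids,
) -> CoexpressionReport:
    """Count BGC core genes coexpressed with each TF under both rules.

    SCC rule: core genes adjacent to the TF in the Spearman network (1-hop —
    whole-component membership would not discriminate within the large
    Spearman blob).  MR rule: core genes sharing >= 1 module with the TF.
    """
    by_gene = catalog.by_gene
    unknown = sorted(set(tf_ids) - set(by_gene))
    if unknown:
        raise CatalogError("TF id(s) not in catalog: " + ", ".join(unknown))
    core = catalog.core_genes
    member = _membership(modules)
    rows = []
    for tf in sorted(tf_ids):
        neigh = set(scc_net[tf]) if tf in scc_net else set()
        scc_core = tuple(sorted(neigh & core))
        tf_mods = member.get(tf, set())
        mr_core = tuple(
            sorted(g for g in core if g != tf and member.get(g, set()) & tf_mods)
        )
        entry = by_gene[tf]
        mr_bgcs = tuple(
            sorted({by_gene[g].bgc_id for g in mr_core if by_gene[g].bgc_id})
        )
        rows.append(
            TFReportRow(
                tf_id=tf,
                scc_count=len(scc_core),
                scc_core_genes=scc_core,
                mr_count=len(mr_core),
                mr_core_genes=mr_core,
                clustered=entry.bgc_id is not None,
                bgc_id=entry.bgc_id,
                mr_bgcs=mr_bgcs,
            )
        )
    return CoexpressionReport(tfs=tuple(rows))


@dataclass(frozen=True)
class ShortlistEntry:
    tf_id: str
    categories: tuple[str, ...]  # "global (SCC)" and/or "pathway-specific (MR-PCC)"
    clustered: bool
    bgc_id: str | None
    scc_count: int
    mr_count: int


def shortlist_tfs(report: CoexpressionReport, min_core: int = DEFAULT_MIN_CORE):
    """Shortlist regulator candidates from a TF coexpression report.

    A TF qualifies as *global (SCC)* when its SCC count reaches ``min_core``
    and as *pathway-specific (MR-PCC)* when its modules link it to core
    genes of >= 2 distinct BGCs.
    """
    out: list[ShortlistEntry] = []
    for row in report.tfs:
        categories = []
        if row.scc_count >= min_core:
            categories.append("global (SCC)")
        if len(row.mr_bgcs) >= 2:
            categories.append("pathway-specific (MR-PCC)")
        if categories:
            out.append(
                ShortlistEntry(
                    tf_id=row.tf_id,
                    categories=tuple(categories),
                    clustered=row.clustered,
                    bgc_id=row.bgc_id,
                    scc_count=row.scc_count,
                    mr_count=row.mr_count,
                )
            )
    return out


def merge_reports(bgc_part: CoexpressionReport, tf_part: CoexpressionReport) -> CoexpressionReport:
    return CoexpressionReport(bgcs=bgc_part.bgcs, tfs=tf_part.tfs)


def report_to_dict(report: CoexpressionReport, shortlist=None) -> dict:
    d = {
        "bgcs": [
            {
                "bgc_id": b.bgc_id,
                "n_genes": b.n_genes,
                "n_recovered": b.n_recovered,
                "recovered_genes": list(b.recovered_genes),
                "coexpressed": b.coexpressed,
                "shared_module_ids": list(b.shared_module_ids),
                "module_ids": list(b.module_ids),
            }
            for b in report.bgcs
        ],
        "tfs": [
            {
                "tf_id": t.tf_id,
                "scc_count": t.scc_count,
                "scc_core_genes": list(t.scc_core_genes),
                "mr_count": t.mr_count,
                "mr_core_genes": list(t.mr_core_genes),
                "clustered": t.clustered,
                "bgc_id": t.bgc_id,
                "mr_bgcs": list(t.mr_bgcs),
            }
            for t in report.tfs
        ],
    }
    if shortlist is not None:
        d["shortlist"] = [
            {
                "tf_id": s.tf_id,
                "categories": list(s.categories),
                "clustered": s.clustered,
                "bgc_id": s.bgc_id,
                "scc_count": s.scc_count,
                "mr_count": s.mr_count,
            }
            for s in shortlist
        ]
    return d


def write_report_json(report: CoexpressionReport, path, shortlist=None) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(report_to_dict(report, shortlist), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tf_table_tsv(report: CoexpressionReport, path) -> None:
    """Flat TF table: tf_id, scc_count, mr_count, clustered, bgc_id."""
    with open(path, "w", newline="\n") as fh:
        fh.write("tf_id\tscc_count\tmr_count\tclustered\tbgc_id\n")
        for t in report.tfs:
            fh.write(
                f"{t.tf_id}\t{t.scc_count}\t{t.mr_count}\t"
                f"{'yes' if t.clustered else 'no'}\t{t.bgc_id or 'none'}\n"
            )
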