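"""BGC catalog handling, coexpression accounting, TF shortlisting."""

import networkx as nx
import pytest

import coexpnet as cx
from coexpnet.modules import Module
from coexpnet.report import (
    BGCCatalog,
    CatalogEntry,
    CatalogError,
    bgc_module_overlap,
    load_catalog,
    merge_reports,
    shortlist_tfs,
    tf_core_coexpression_counts,
    write_catalog,
)


def _mk(genes, mid):
    return Module(frozenset(genes), 0.5, 0.5, "NET10", mid)


@pytest.fixture
def small_catalog():
    return BGCCatalog(
        (
            CatalogEntry("p1", "BGC_P", "core", "PKS", "chr1", 100, 1099),
            CatalogEntry("p2", "BGC_P", "tailoring", "none", "chr1", 1100, 2099),
            CatalogEntry("p3", "BGC_P", "core", "NRPS", "chr1", 2100, 3099),
            CatalogEntry("p4", "BGC_P", "transporter", "none", "chr1", 3100, 4099),
            CatalogEntry("p5", "BGC_P", "TF", "none", "chr1", 4100, 5099),
            CatalogEntry("q1", "BGC_Q", "core", "FAS", "chr2", 100, 1099),
            CatalogEntry("q2", "BGC_Q", "other", "none", "chr2", 1100, 2099),
            CatalogEntry("t1", None, "TF", "none"),
        )
    )


def test_catalog_roundtrips_through_tsv(tmp_path, small_catalog):
    p = tmp_path / "cat.tsv"
    write_catalog(small_catalog, p)
    assert load_catalog(p) == small_catalog


def test_catalog_validation_errors(tmp_path):
    with pytest.raises(CatalogError, match="start > end"):
        BGCCatalog((CatalogEntry("g", "B", "core", "PKS", "chr1", 10, 5),))
    with pytest.raises(CatalogError, match="duplicate"):
        BGCCatalog(
            (CatalogEntry("g", "B", "core", "PKS"), CatalogEntry("g", None, "other"))
        )
    with pytest.raises(CatalogError, match="core_type"):
        BGCCatalog((CatalogEntry("g", "B", "core", "none"),))
    p = tmp_path / "bad.tsv"
    p.write_text("gene_id\tbgc_id\trole\tcore_type\ng1\tB\tcore\tPKS\textra\n")
    with pytest.raises(CatalogError, match="line 2"):
        load_catalog(p)


def test_catalog_optional_coordinates(tmp_path):
    p = tmp_path / "cat.tsv"
    p.write_text(
        "gene_id\tbgc_id\trole\tcore_type\n"
        "g1\tB1\tcore\tPKS\n"
        "g2\tnone\tTF\tnone\n"
    )
    cat = load_catalog(p)
    assert cat.by_gene["g1"].start is None and cat.by_gene["g1"].chromosome is None
    assert cat.by_gene["g2"].bgc_id is None


def test_bgc_overlap_counts_and_flag(small_catalog):
    mods = [_mk({"p1", "p2", "p3"}, "m0"), _mk({"q1", "x"}, "m1")]
    rep = bgc_module_overlap(mods, small_catalog)
    by = {b.bgc_id: b for b in rep.bgcs}
    assert by["BGC_P"].n_recovered == 3
    assert by["BGC_P"].coexpressed  # three members share module m0
    assert by["BGC_P"].shared_module_ids == ("m0",)
    assert by["BGC_Q"].n_recovered == 1
    assert not by["BGC_Q"].coexpressed  # one member alone is not coexpression


def test_bgc_flag_false_when_members_never_share(small_catalog):
    mods = [_mk({"p1", "x1"}, "m0"), _mk({"p2", "x2"}, "m1")]
    rep = bgc_module_overlap(mods, small_catalog)
    by = {b.bgc_id: b for b in rep.bgcs}
    assert by["BGC_P"].n_recovered == 2 and not by["BGC_P"].coexpressed


def test_tf_counts_under_both_rules(small_catalog):
    scc = nx.Graph()
    scc.add_nodes_from(e.gene_id for e in small_catalog.entries)
    scc.add_edge("t1", "p1", rho=0.8, weight=0.8)
    scc.add_edge("t1", "p3", rho=0.6, weight=0.6)
    scc.add_edge("t1", "q1", rho=0.7, weight=0.7)
    scc.add_edge("t1", "p2", rho=0.9, weight=0.9)  # tailoring: not a core gene
    mods = [_mk({"t1", "p1", "p2"}, "m0")]
    rep = tf_core_coexpression_counts(scc, mods, small_catalog, ["t1", "p5"])
    by = {t.tf_id: t for t in rep.tfs}
    assert by["t1"].scc_count == 3
    assert by["t1"].mr_count == 1 and by["t1"].mr_core_genes == ("p1",)
    assert not by["t1"].clustered
    assert by["p5"].scc_count == 0 and by["p5"].mr_count == 0
    assert by["p5"].clustered and by["p5"].bgc_id == "BGC_P"
    with pytest.raises(CatalogError, match="nope"):
        tf_core_coexpression_counts(scc, mods, small_catalog, ["nope"])


def test_counts_match_bruteforce_intersections(compendium, compendium_networks,
                                               compendium_modules):
    _, truth = compendium
    catalog = cx.catalog_from_truth(truth)
    mods = [m for v in compendium_modules.values() for m in v]
    scc = compendium_networks["SCC"]
    tfs = sorted(catalog.tf_genes)
    rep = tf_core_coexpression_counts(scc, mods, catalog, tfs)
    core = catalog.core_genes
    for row in rep.tfs:
        neigh = {v for v in scc[row.tf_id]} if row.tf_id in scc else set()
        assert row.scc_count == len(neigh & core)
        shared = {
            g
            for m in mods
            if row.tf_id in m.genes
            for g in m.genes & core
            if g != row.tf_id
        }
        assert set(row.mr_core_genes) == shared
        assert row.mr_count == len(shared)


def test_shortlist_patterns(small_catalog):
    # global unclustered TF (high SCC count), and a clustered TF whose module
    # reaches a second BGC's core gene (pathway-specific cross-cluster pattern)
    scc = nx.Graph()
    scc.add_nodes_from(e.gene_id for e in small_catalog.entries)
    for core in ("p1", "p3", "q1"):
        scc.add_edge("t1", core, rho=0.8, weight=0.8)
    mods = [_mk({"p5", "p1", "q1"}, "m0")]
    rep = merge_reports(
        bgc_module_overlap(mods, small_catalog),
        tf_core_coexpression_counts(scc, mods, small_catalog, ["t1", "p5"]),
    )
    short = shortlist_tfs(rep, min_core=3)
    by = {s.tf_id: s for s in short}
    assert by["t1"].categories == ("global (SCC)",) and not by["t1"].clustered
    assert by["p5"].categories == ("pathway-specific (MR-PCC)",)
    assert by["p5"].clustered and by["p5"].bgc_id == "BGC_P"
    assert shortlist_tfs(cx.CoexpressionReport(), min_core=1) == []


def test_planted_bgcs_flagged_and_silent_bgcs_clean(compendium, compendium_modules):
    """Expressed planted groups are reported coexpressed; all-baseline
    (silent) groups are never flagged — no false positives."""
    _, truth = compendium
    catalog = cx.catalog_from_truth(truth)
    mods = [m for v in compendium_modules.values() for m in v]
    rep = bgc_module_overlap(mods, catalog)
    gene_to_bgc = {e.gene_id: e.bgc_id for e in catalog.entries}
    silent_bgcs = {
        gene_to_bgc[g]
        for members in truth.silent_group_members.values()
        for g in members
    }
    for row in rep.bgcs:
        if row.bgc_id in silent_bgcs:
            assert not row.coexpressed
        else:
            assert row.coexpressed


def test_global_regulator_qualifies_for_shortlist(compendium, compendium_networks,
                                                  compendium_modules):
    _, truth = compendium
    catalog = cx.catalog_from_truth(truth)
    mods = [m for v in compendium_modules.values() for m in v]
    rep = tf_core_coexpression_counts(
        compendium_networks["SCC"], mods, catalog, sorted(catalog.tf_genes)
    )
    short = {s.tf_id: s for s in shortlist_tfs(rep)}
    glob = sorted(truth.global_regulators)[0]
    assert glob in short
    assert short[glob].scc_count >= 10
    assert not short[glob].clustered


def test_report_generation_is_pure(compendium_networks, compendium,
                                   compendium_modules):
    _, truth = compendium
    catalog = cx.catalog_from_truth(truth)
    mods = [m for v in compendium_modules.values() for m in v]
    args = (compendium_networks["SCC"], mods, catalog, sorted(catalog.tf_genes))
    assert tf_core_coexpression_counts(*args) == tf_core_coexpression_counts(*args)
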