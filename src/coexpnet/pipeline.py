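"""End-to-end pipeline: simulate -> normalize -> networks -> modules -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io, normalize, report as report_mod
from .modules import collapse_metamodule, detect_modules
from .network import (
    DEFAULT_PCC_MIN,
    DEFAULT_RHO_MIN,
    DEFAULT_WEIGHT_MIN,
    DEFAULT_XS,
    build_mr_networks,
    build_scc_network,
    drop_zero_variance,
)
from .simulate import SimulationConfig, simulate_compendium

log = logging.getLogger("coexpnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    matrix_path: str | None = None
    catalog_path: str | None = None
    trim_fraction: float = normalize.DEFAULT_TRIM
    mr_xs: tuple[float, ...] = DEFAULT_XS
    pcc_min: float = DEFAULT_PCC_MIN
    weight_min: float = DEFAULT_WEIGHT_MIN
    rho_min: float = DEFAULT_RHO_MIN
    min_size: int = 3
    min_density: float = 0.3
    penalty: float = 2.0
    merge_overlap: float = 0.8
    anchors: tuple[str, ...] = ()
    tf_ids: tuple[str, ...] = ()  # default: every TF in the catalog
    min_core: int = report_mod.DEFAULT_MIN_CORE

    def validate(self) -> None:
        if self.simulate is None and self.matrix_path is None:
            raise PipelineError("config: either a simulate block or matrix_path is required")
        if self.simulate is not None:
            self.simulate.validate()
        for name in ("matrix_path", "catalog_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {name} does not exist: {p}")
        if not 0 <= self.trim_fraction < 0.5:
            raise PipelineError("config: trim_fraction must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig.from_dict(sim)
        for key in ("mr_xs", "anchors", "tf_ids"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage {name} failed: {err}") from err
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the full pipeline; returns a name -> path map of artifacts.

    Stages: simulate (optional) -> trimmed-mean scaling -> MR networks
    (one per x) + SCC network -> module detection per MR network ->
    metamodule collapse (if anchors given) -> BGC/TF report.  All artifacts
    carry provenance headers; a fixed seed reproduces them byte for byte.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> Path:
        artifacts[name] = str(path)
        return path

    truth = None
    catalog = None

    @_stage("simulate")
    def stage_simulate():
        sim = config.simulate
        if config.seed is not None:
            sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
        matrix, tr = simulate_compendium(sim)
        io.write_expression_tsv(
            matrix, emit("matrix", outdir / "matrix.tsv"), {"stage": "simulate", "seed": sim.seed}
        )
        (outdir / "truth.json").write_text(tr.to_json())
        emit("truth", outdir / "truth.json")
        return matrix, tr

    @_stage("load")
    def stage_load():
        return io.read_expression_tsv(config.matrix_path)

    if config.simulate is not None:
        matrix, truth = stage_simulate()
    else:
        matrix = stage_load()

    if config.catalog_path is not None:
        catalog = report_mod.load_catalog(config.catalog_path)
    elif truth is not None:
        catalog = report_mod.catalog_from_truth(truth)
        report_mod.write_catalog(catalog, emit("catalog", outdir / "catalog.tsv"))

    @_stage("normalize")
    def stage_normalize():
        scaled = normalize.scale_to_cross_experiment_trimmed_mean(matrix, config.trim_fraction)
        io.write_expression_tsv(
            scaled,
            emit("matrix_scaled", outdir / "matrix.scaled.tsv"),
            {"stage": "normalize", "trim_fraction": config.trim_fraction},
        )
        return scaled

    scaled = stage_normalize()

    @_stage("network")
    def stage_network():
        usable, dropped = drop_zero_variance(scaled)
        if dropped:
            log.warning("dropped %d zero-variance gene(s): %s", len(dropped), ", ".join(dropped))
        mr_nets = build_mr_networks(usable, config.mr_xs, config.pcc_min, config.weight_min)
        scc = build_scc_network(usable, config.rho_min)
        for name, net in {**mr_nets, "SCC": scc}.items():
            stem = name.lower()
            io.write_network_tsv(net, emit(f"net_{stem}", outdir / f"{stem}.tsv"))
            io.write_network_graphml(net, emit(f"net_{stem}_graphml", outdir / f"{stem}.graphml"))
            if catalog is not None:
                io.write_node_attributes_tsv(
                    net, catalog, emit(f"net_{stem}_nodes", outdir / f"{stem}.nodes.tsv")
                )
        return mr_nets, scc

    mr_nets, scc_net = stage_network()

    @_stage("modules")
    def stage_modules():
        per_net = {}
        for name, net in mr_nets.items():
            mods = detect_modules(
                net,
                min_size=config.min_size,
                min_density=config.min_density,
                penalty=config.penalty,
                merge_overlap=config.merge_overlap,
            )
            io.write_modules_json(
                mods,
                emit(f"modules_{name.lower()}", outdir / f"modules.{name.lower()}.json"),
                {"network": name, "penalty": config.penalty, "min_size": config.min_size,
                 "min_density": config.min_density, "merge_overlap": config.merge_overlap},
            )
            per_net[name] = mods
        return per_net

    modules_by_net = stage_modules()
    all_modules = [m for mods in modules_by_net.values() for m in mods]

    if config.anchors:
        @_stage("metamodule")
        def stage_metamodule():
            meta = collapse_metamodule(all_modules, config.anchors)
            io.write_metamodule_json(meta, emit("metamodule", outdir / "metamodule.json"))
            return meta

        stage_metamodule()

    if catalog is not None:
        @_stage("report")
        def stage_report():
            tf_ids = tuple(config.tf_ids) or tuple(sorted(catalog.tf_genes))
            bgc_part = report_mod.bgc_module_overlap(all_modules, catalog)
            tf_part = report_mod.tf_core_coexpression_counts(
                scc_net, all_modules, catalog, tf_ids
            )
            full = report_mod.merge_reports(bgc_part, tf_part)
            short = report_mod.shortlist_tfs(full, config.min_core)
            report_mod.write_report_json(full, emit("report", outdir / "report.json"), short)
            report_mod.write_tf_table_tsv(full, emit("tf_table", outdir / "report.tfs.tsv"))
            return full

        stage_report()

    return artifacts
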