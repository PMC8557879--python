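"""Synthetic expression compendia with planted co-regulated gene groups.

The generator emulates the kind of bulk-transcriptome compendium used for
fungal coexpression mining: a few hundred RMA-style log-scale arrays over a
range of conditions, in which contiguous blocks of genes (BGC-like groups)
are co-activated in a subset of samples.  Planted structure includes

* frequently expressed groups (active in dozens of conditions) and rarely
  expressed groups (active in <= 5 conditions),
* unclustered *global regulators* whose profile tracks several groups,
* *cluster-resident regulators* sitting inside a group's genomic block and
  tracking one or two groups,
* sparse confounder genes that spike in 1-2 samples inside some group's
  active conditions — they acquire spurious plain-correlation links to the
  group but are not co-regulated with it, the hazard the mutual-rank
  transform is meant to defuse, and
* contiguous *silent* groups that stay at baseline in every sample
  (never-expressed BGC analogues).

All randomness flows from one seeded :class:`numpy.random.Generator`; the
same config reproduces the same matrix bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GroupSpec:
    """One planted co-regulated gene group.

    size              number of co-regulated member genes (regulators extra)
    active_samples    number of samples in which the group is switched on
    signal_mean       mean log-intensity while active
    signal_sd         intensity noise while active
    coactivated_with  index of an earlier group whose activating conditions
                      this group partially shares (co-regulated pathways
                      respond to overlapping stimuli); None = independent
    coactivation      fraction of this group's active samples drawn from
                      the partner group's active set
    exclusive_window  draw the active samples disjoint from every other
                      exclusive-window group (a cluster firing only under
                      its own specific inducing condition)
    """

    size: int
    active_samples: int
    signal_mean: float = 10.0
    signal_sd: float = 0.5
    coactivated_with: int | None = None
    coactivation: float = 0.75
    exclusive_window: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic compendium."""

    n_genes: int
    n_samples: int
    planted_groups: tuple[GroupSpec, ...] = ()
    n_global_regulators: int = 0
    n_resident_regulators: int = 0
    n_sparse_confounders: int = 0
    silent_group_sizes: tuple[int, ...] = ()
    induction_pool: int | None = None
    baseline_mean: float = 4.0
    baseline_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ConfigError("n_samples must be >= 3 (correlation needs >= 3 points)")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd must be >= 0")
        pool = self.induction_pool if self.induction_pool is not None else self.n_samples
        if not 1 <= pool <= self.n_samples:
            raise ConfigError("induction_pool must be in [1, n_samples]")
        for i, g in enumerate(self.planted_groups):
            if g.size < 1:
                raise ConfigError(f"planted group {i}: size must be >= 1")
            if not 1 <= g.active_samples <= pool:
                raise ConfigError(
                    f"planted group {i}: active_samples must be in [1, induction pool]"
                )
            if g.signal_sd < 0:
                raise ConfigError(f"planted group {i}: signal_sd must be >= 0")
            if g.coactivated_with is not None and not 0 <= g.coactivated_with < i:
                raise ConfigError(
                    f"planted group {i}: coactivated_with must name an earlier group"
                )
            if not 0 <= g.coactivation <= 1:
                raise ConfigError(f"planted group {i}: coactivation must be in [0, 1]")
            if g.exclusive_window and g.coactivated_with is not None:
                raise ConfigError(
                    f"planted group {i}: exclusive_window excludes coactivation"
                )
        excl = sum(
            g.active_samples for g in self.planted_groups if g.exclusive_window
        )
        if excl > pool:
            raise ConfigError(
                "exclusive-window groups need more samples than the induction pool holds"
            )
        for i, s in enumerate(self.silent_group_sizes):
            if s < 1:
                raise ConfigError(f"silent group {i}: size must be >= 1")
        n_regs = self.n_global_regulators + self.n_resident_regulators
        if n_regs > 0 and not self.planted_groups:
            raise ConfigError("regulators require at least one planted group")
        if min(self.n_global_regulators, self.n_resident_regulators,
               self.n_sparse_confounders) < 0:
            raise ConfigError("regulator/confounder counts must be >= 0")
        if self.n_sparse_confounders > 0 and not self.planted_groups:
            raise ConfigError("sparse confounders require at least one planted group")
        budget = (sum(g.size for g in self.planted_groups)
                  + sum(self.silent_group_sizes)
                  + n_regs + self.n_sparse_confounders)
        if budget > self.n_genes:
            raise ConfigError(
                f"planted genes ({budget}) exceed n_genes ({self.n_genes})"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        groups = tuple(
            GroupSpec(**g) if isinstance(g, Mapping) else GroupSpec(*g)
            for g in d.pop("planted_groups", ())
        )
        silent = tuple(d.pop("silent_group_sizes", ()))
        return cls(planted_groups=groups, silent_group_sizes=silent, **d)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for a simulated compendium.

    group_members includes any cluster-resident regulators assigned to the
    group (they sit inside the group's contiguous gene-id block).  Silent
    groups are all-baseline blocks kept separate from the planted groups.
    """

    group_members: dict[str, frozenset[str]]
    group_active_samples: dict[str, frozenset[str]]
    regulator_targets: dict[str, frozenset[str]]
    confounders: frozenset[str]
    silent_group_members: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def global_regulators(self) -> frozenset[str]:
        clustered = set().union(*self.group_members.values()) if self.group_members else set()
        return frozenset(g for g in self.regulator_targets if g not in clustered)

    @property
    def resident_regulators(self) -> frozenset[str]:
        return frozenset(self.regulator_targets) - self.global_regulators

    def to_json(self) -> str:
        payload = {
            "group_members": {k: sorted(v) for k, v in self.group_members.items()},
            "group_active_samples": {
                k: sorted(v) for k, v in self.group_active_samples.items()
            },
            "regulator_targets": {
                k: sorted(v) for k, v in self.regulator_targets.items()
            },
            "confounders": sorted(self.confounders),
            "silent_group_members": {
                k: sorted(v) for k, v in self.silent_group_members.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            group_members={k: frozenset(v) for k, v in d["group_members"].items()},
            group_active_samples={
                k: frozenset(v) for k, v in d["group_active_samples"].items()
            },
            regulator_targets={
                k: frozenset(v) for k, v in d["regulator_targets"].items()
            },
            confounders=frozenset(d["confounders"]),
            silent_group_members={
                k: frozenset(v) for k, v in d.get("silent_group_members", {}).items()
            },
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"s{j:0{width}d}" for j in range(n)]


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate one compendium and its ground truth.

    Returns a genes x samples :class:`pandas.DataFrame` of non-negative
    log-scale intensities and the :class:`PlantedTruth` describing every
    planted feature.  Deterministic in ``config`` (including the seed).

    Layout of gene ids (contiguous blocks, in order): planted groups (each
    block = co-regulated members followed by its resident regulators),
    silent groups, global regulators, sparse confounders, baseline filler.

    Every group's active samples are drawn from a shared *induction pool*
    of ``induction_pool`` candidate conditions (default: all samples) —
    mimicking compendia in which cluster-activating conditions are a
    restricted, partially shared subset, which is what couples a
    regulator's profile to each of its target groups.

    Regulator assignment is deterministic: resident regulator ``k`` lives in
    group ``(k // 2) % G`` and targets that group plus its successor; global
    regulator ``k`` targets groups ``{2k % G, (2k+1) % G}``.  Sparse
    confounder ``i`` spikes inside the active conditions of group
    ``i % G``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    samples = _sample_ids(config.n_samples)
    n_groups = len(config.planted_groups)

    values = rng.normal(
        config.baseline_mean, config.baseline_sd, (config.n_genes, config.n_samples)
    )
    if config.induction_pool is not None:
        pool = np.sort(rng.choice(config.n_samples, config.induction_pool, replace=False))
    else:
        pool = np.arange(config.n_samples)

    # Assign resident regulators to their home groups up front so each
    # group's genomic block can be allocated contiguously.
    residents_of: dict[int, list[int]] = {g: [] for g in range(n_groups)}
    for k in range(config.n_resident_regulators):
        residents_of[(k // 2) % n_groups].append(k)

    cursor = 0
    claimed = np.array([], dtype=int)  # samples taken by exclusive windows
    group_members: dict[str, frozenset[str]] = {}
    group_active: dict[str, frozenset[str]] = {}
    group_active_idx: list[np.ndarray] = []
    group_core_rows: list[list[int]] = []  # co-regulated members, no regulators
    resident_rows: list[tuple[int, int]] = []  # (row, regulator index k)

    for g, spec in enumerate(config.planted_groups):
        gid = f"G{g:02d}"
        block = list(range(cursor, cursor + spec.size + len(residents_of[g])))
        cursor = block[-1] + 1 if block else cursor
        members = block[: spec.size]
        regs = block[spec.size:]
        if spec.exclusive_window:
            free = np.setdiff1d(pool, claimed)
            active = np.sort(rng.choice(free, size=spec.active_samples, replace=False))
            claimed = np.union1d(claimed, active)
        elif spec.coactivated_with is not None:
            partner = group_active_idx[spec.coactivated_with]
            n_shared = min(
                round(spec.coactivation * spec.active_samples), len(partner)
            )
            shared = rng.choice(partner, size=n_shared, replace=False)
            rest_pool = np.setdiff1d(pool, partner)
            own = rng.choice(
                rest_pool, size=spec.active_samples - n_shared, replace=False
            )
            active = np.sort(np.concatenate([shared, own]))
        else:
            active = np.sort(rng.choice(pool, size=spec.active_samples, replace=False))
        for row in members:
            values[row, active] = rng.normal(
                spec.signal_mean, spec.signal_sd, spec.active_samples
            )
        group_members[gid] = frozenset(genes[i] for i in block)
        group_active[gid] = frozenset(samples[j] for j in active)
        group_active_idx.append(active)
        group_core_rows.append(members)
        for row, k in zip(regs, residents_of[g]):
            resident_rows.append((row, k))

    silent_members: dict[str, frozenset[str]] = {}
    for s, size in enumerate(config.silent_group_sizes):
        block = list(range(cursor, cursor + size))
        cursor += size
        silent_members[f"S{s:02d}"] = frozenset(genes[i] for i in block)

    global_rows = list(range(cursor, cursor + config.n_global_regulators))
    cursor += config.n_global_regulators
    confounder_rows = list(range(cursor, cursor + config.n_sparse_confounders))
    cursor += config.n_sparse_confounders

    # Mean expression profile of each group's co-regulated members; regulator
    # profiles are the mean of their target groups' profiles plus noise.
    profiles = [values[rows].mean(axis=0) for rows in group_core_rows]

    regulator_targets: dict[str, frozenset[str]] = {}

    def _write_regulator(row: int, targets: list[int]) -> None:
        sd = float(np.mean([config.planted_groups[t].signal_sd for t in targets]))
        mean_profile = np.mean([profiles[t] for t in targets], axis=0)
        values[row] = mean_profile + rng.normal(0.0, sd, config.n_samples)
        regulator_targets[genes[row]] = frozenset(f"G{t:02d}" for t in targets)

    for row, k in resident_rows:
        home = (k // 2) % n_groups
        targets = sorted({home, (home + 1) % n_groups})
        _write_regulator(row, targets)
    for k, row in enumerate(global_rows):
        targets = sorted({(2 * k) % n_groups, (2 * k + 1) % n_groups})
        _write_regulator(row, targets)

    # Sparse confounders: baseline everywhere except 1-2 spike samples drawn
    # from one planted group's active conditions (guaranteeing the spurious
    # plain-correlation hazard).  Confounders of non-exclusive groups avoid
    # the dedicated exclusive-window conditions: each of those conditions
    # activates exactly one rare cluster.
    for i, row in enumerate(confounder_rows):
        g = i % n_groups
        spec = config.planted_groups[g]
        active = group_active_idx[g]
        if not spec.exclusive_window:
            open_active = np.setdiff1d(active, claimed)
            if len(open_active) >= 2:
                active = open_active
        n_spikes = min(2, len(active))
        pos = rng.choice(active, size=n_spikes, replace=False)
        values[row, pos] = rng.normal(spec.signal_mean, spec.signal_sd, n_spikes)

    np.clip(values, 0.0, None, out=values)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    truth = PlantedTruth(
        group_members=group_members,
        group_active_samples=group_active,
        regulator_targets=regulator_targets,
        confounders=frozenset(genes[i] for i in confounder_rows),
        silent_group_members=silent_members,
    )
    return matrix, truth


def rare_cluster_scenario(seed: int) -> tuple[pd.DataFrame, PlantedTruth]:
    """Canned scenario exercising the rarely-expressed-gene failure mode.

    Twenty planted groups of 10 genes, each active in only 5 of 160
    samples, their activation windows drawn from a shared 6-condition
    induction pool, plus 40 sparse confounders spiking inside group-active
    conditions.  Under plain Pearson correlation every confounder picks up
    at least one |r| >= 0.5 link to a planted gene.  Under mutual rank the
    confounders lose: each is outranked on both sides — in a planted gene's
    list by the gene's co-regulated partners and by genes of other groups
    sharing the activation window, and in its own list by the many genuine
    rarely-expressed genes covering its spike samples.  That reciprocal
    demotion, which needs a compendium rich in rarely expressed genes, is
    exactly the failure mode of plain correlation the MR transform repairs.
    """
    config = SimulationConfig(
        n_genes=300,
        n_samples=160,
        planted_groups=tuple(
            GroupSpec(size=10, active_samples=5, signal_mean=11.0, signal_sd=0.4)
            for _ in range(20)
        ),
        n_sparse_confounders=40,
        induction_pool=6,
        baseline_mean=4.0,
        baseline_sd=0.4,
        seed=seed,
    )
    return simulate_compendium(config)


def default_compendium_config(seed: int = 0) -> SimulationConfig:
    """The canonical synthetic compendium: 1,000 genes x 155 samples.

    Mirrors the make-up of a real fungal coexpression compendium, scaled to
    desk size: twenty-four BGC-like groups of 10-20 genes — half frequently
    expressed (active in 25-60 conditions), half rarely expressed (active
    in <= 5) — one unclustered global regulator tracking two groups, two
    cluster-resident regulators inside group G00 tracking G00+G01, two
    sparse confounders per group, and two silent (never expressed) groups.
    G01 is co-activated with G00 (75% shared activating conditions), the
    signature of a pair of clusters under one regulator.  Signal
    10 +/- 0.5 over baseline 4 +/- 0.5 on the log-intensity scale.
    """
    freq_sizes = (18,) + (16,) * 15
    freq_active = (60, 45, 50, 40, 35, 45, 30, 55, 40, 30, 35, 25, 50, 30, 45, 35)
    frequent = tuple(
        GroupSpec(
            size=s,
            active_samples=a,
            coactivated_with=0 if i == 1 else None,
            coactivation=0.75 if i == 1 else 0.0,
        )
        for i, (s, a) in enumerate(zip(freq_sizes, freq_active))
    )
    # Rare clusters: strongly induced (signal 12) under 5 exclusive conditions
    rare_sizes = (16,) * 12 + (18, 18, 18, 20, 20, 20)
    rare = tuple(
        GroupSpec(
            size=s, active_samples=5, signal_mean=12.0, exclusive_window=True
        )
        for s in rare_sizes
    )
    return SimulationConfig(
        n_genes=1000,
        n_samples=155,
        planted_groups=frequent + rare,
        n_global_regulators=1,
        n_resident_regulators=2,
        n_sparse_confounders=72,
        silent_group_sizes=(8, 10),
        seed=seed,
    )
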