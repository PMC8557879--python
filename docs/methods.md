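# Methods

## Pipeline

Input is a genes × samples matrix of non-negative, log-scale intensities
(RMA-style preprocessing is assumed upstream). Stages:

1. **Cross-experiment scaling.** Each sample column j is multiplied by
   T/t_j, where t_j is the column's trimmed mean (trim fraction 0.05 per
   tail, trim count ⌊f·n⌋, no interpolation) and T is the mean of the
   per-sample trimmed means. This reading of the "cross-experiment trimmed
   mean" makes the operation exactly idempotent and leaves every column
   with the same trimmed mean; a pooled-matrix target was the alternative
   reading, rejected because re-scaling would then drift by the ratio of
   pooled to per-column trimmed means. Columns with zero trimmed mean are a
   hard error naming the sample.

2. **Correlation.** All-pairs Pearson (for the MR branch) and Spearman
   (average ranks on ties; for the SCC branch) across samples. Genes with
   zero variance have no defined correlation and must be dropped first;
   `drop_zero_variance` reports them.

3. **Mutual rank.** For each gene, all other genes are ranked 1…n−1 by
   descending correlation, ties broken by ascending gene id (deterministic
   and documented; any fixed tie rule works). MR(A,B) is the geometric
   mean √(Rank_A(B)·Rank_B(A)). MR = 1 exactly for mutual best partners.
   Ranks are computed over all genes; the Pearson ≥ 0.3 condition is
   applied at edge assembly, not before ranking.

4. **Networks.** MR-PCC edge rule: Pearson r ≥ 0.3 (signed — negative
   correlations never enter MR networks) **and** decay weight
   exp(−(MR−1)/x) ≥ 0.1. With x ∈ {5, 10, 25} the weight floor corresponds
   to MR ≤ 1 + x·ln 10 ≈ 12.5 / 24.0 / 58.6, which is what makes the three
   networks nested (NET05 ⊆ NET10 ⊆ NET25). SCC edge rule: |ρ| ≥ 0.5,
   signed ρ stored. Edge weights are kept at full precision in memory and
   serialised at 6 decimals.

5. **Modules.** Cohesiveness f(V) = w_in/(w_in + w_bound + p·|V|), node
   penalty p = 2. Growth from a seed applies the single best strictly
   improving add-neighbour/remove-member step (ties by ascending gene id;
   improvement threshold 1e−12 to keep float noise from cycling), so every
   emitted module is locally optimal by construction. Seeds are taken in
   decreasing weighted-degree order, skipping nodes already covered by a
   grown set ("unused" seeding; "all" seeding available). Grown sets with
   fewer than 3 genes or weighted density w_in/(|V| choose 2) below 0.3
   are discarded; candidates with overlap ω(A,B)=|A∩B|²/(|A||B|) ≥ 0.8 are
   merged transitively (connected components of the ω-graph), which is
   order-independent. The ClusterONE significance p-value is deliberately
   not computed; module quality is reported as cohesiveness plus density.
   Note that greedy growth emits seed-reachable local optima: a graph of
   two bridged cliques also has the whole-graph union as a (marginally
   better-scoring) local optimum, which no seeded growth reaches — the two
   cliques are the intended output.

6. **Metamodule.** The union of the genes of every module, pooled across
   any supplied networks, that contains at least one anchor gene. Empty
   result is a warning, not an error.

7. **Report.** Per BGC, member genes found in any module and a
   "coexpressed" flag requiring ≥ 2 members in one shared module (the
   count of members recovered anywhere is also emitted, so the looser
   one-gene reading remains recoverable). Per TF, two counts against the
   catalog's core genes: direct SCC edges (1-hop; component membership
   would not discriminate inside the large Spearman component) and shared
   MR modules. Shortlist rules: SCC count ≥ 10 → "global (SCC)"; shared
   modules reaching core genes of ≥ 2 distinct BGCs → "pathway-specific
   (MR-PCC)"; each entry is labelled clustered/unclustered from catalog
   membership. Catalog coordinates are 1-based inclusive.

## Synthetic compendium

The generator emulates a microarray-era compendium: a few hundred
conditions, log-intensity baseline ~N(4, 0.5²) clipped at zero, planted
contiguous gene blocks switched to a signal level on their active
conditions. It is the package's test bed and defines the study conditions
for the acceptance checks.

Elements and the data features they emulate:

- **Planted groups** (GroupSpec): co-regulated blocks with a set of active
  samples; "frequent" groups are active in dozens of conditions, "rare"
  ones in ≤ 5. Signal defaults: mean 10, sd 0.5 over baseline 4 ± 0.5 —
  a signal-to-noise regime (Δ = 12 sd) in which within-group correlation
  is near-collinear, as in strongly induced pathways.
- **Co-activation**: a group may draw a fraction (default 75%) of its
  active samples from an earlier group's active set — two clusters under
  one regulator respond to overlapping stimuli. This is what makes a
  regulator's profile (see below) correlate strongly with *both* targets;
  with independently drawn condition sets the mean-profile regulator
  correlates only ~0.4 with each target and sits below every threshold,
  which is a statement about the data model, not the method.
- **Exclusive windows**: rare groups can claim disjoint active conditions
  — each special condition induces exactly one rare cluster. Confounders
  of non-exclusive groups spike outside these dedicated conditions.
- **Regulators**: profile = mean of the target groups' mean expression
  profiles + N(0, signal_sd). Resident regulators live inside their home
  group's contiguous block (and are counted among its members); global
  regulators are unclustered. Assignment is deterministic: resident k
  lives in group ⌊k/2⌋ mod G and targets it plus its successor; global k
  targets {2k, 2k+1} mod G.
- **Sparse confounders**: baseline except for up to two spike samples
  inside one group's active conditions (group i mod G), at that group's
  signal level. By construction they reach |r| ≥ 0.5 with planted genes
  under plain correlation — the spurious-correlation hazard.
- **Silent groups**: contiguous all-baseline blocks recorded in the truth;
  they become never-expressed BGCs in the derived catalog and must not be
  flagged coexpressed.

All randomness flows from a single seeded `numpy.random.Generator`;
identical configs are bit-identical.

### Canonical scales

`default_compendium_config`: 1,000 genes × 155 samples; 16 frequent groups
(sizes 16–18, active 25–60, group 1 co-activated with group 0), 18 rare
groups (sizes 16–20, active 5 exclusive conditions, signal 12), 1 global +
2 resident regulators targeting groups 0/1, 72 confounders, 2 silent
groups, ~330 unstructured noise genes. Near-uniform group sizes keep the
median module size inside a long run of equal values, so that summary
reflects planted structure rather than the count of small chance modules
(the relaxed NET25 admits more noise pairs than NET10 by construction of
its weight floor). Rare-group induction is stronger (12 vs 10) so that a
stray sparse gene sharing a single spike with a rare window falls below
the Pearson 0.3 floor rather than sitting in a coin-flip around it.

`rare_cluster_scenario`: 300 genes × 160 samples; 20 rare groups of 10
genes, each active in 5 of only 6 pooled induction conditions, plus 40
confounders. The deliberately crowded pool gives every sparse gene many
genuinely co-expressed competitors, so a confounder is outranked on both
sides of the mutual rank — in a planted gene's list by co-regulated
partners and window-sharing genes, and in its own list by the rare genes
covering its spikes. This is precisely the mechanism by which mutual rank
defuses sparse-profile spurious correlation; with only a handful of sparse
genes in a data set the mechanism has nothing to work with, and plain
correlation and MR coincide.

### What the generator does not emulate

Probe-level effects, batch structure, missing values, heavy-tailed or
correlated noise, partially overlapping cluster membership, and regulator
profiles other than the mean-of-targets model. Passing tests therefore
demonstrate the algorithmic contracts (rank algebra, nesting, local
optimality, recovery under the stated SNR and crowding mechanisms), not
performance on real compendia.

## Numerical choices

- Trim count ⌊f·n⌋ per tail; scaling idempotent to machine precision.
- Correlations clipped to [−1, 1]; diagonal fixed to 1.
- Rank ties by ascending gene id; Spearman ties by average ranks.
- Greedy improvement threshold 1e−12; cohesiveness of a bare vertex with
  zero denominator defined as 0.
- Module output sorted by descending cohesiveness, then gene list; module
  ids are `<network>:m<index>` and stable for fixed inputs.
- Serialisation: TSV/JSON with LF endings, floats at 6 decimals, no
  timestamps — fixed-seed pipeline reruns are byte-identical.

## Problem sizes

The bundled study conditions (1,000 × 155 compendium, 300 × 160 scenario)
run the full pipeline in seconds on one CPU; they are the package's own
desk-scale stand-in for a 14k-gene, 283-array compendium, chosen so the
planted structure spans the same qualitative regimes (frequent vs rare
expression, global vs pathway-specific regulators, spurious sparse
correlates) at a size where exhaustive oracles remain feasible.

## Known limitations

- Greedy growth explores single-node moves only; sets reachable only via
  compound moves (e.g. whole-graph unions of bridged cliques) are not
  emitted, matching the reference behaviour of cohesiveness clustering.
- The SCC/MR thresholds (0.5, 0.3, 0.1) are the method's published
  operating points, exposed as parameters but not recalibrated here.
- The BGC catalog is an input; no de novo cluster prediction is done.
- The metamodule is a flat union: it does not re-score cohesiveness on the
  pooled gene set.
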