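# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite does not
itself compute.

## Design and containers

The pipeline targets a paired factorial design: two culture conditions
(tumor co-culture, default label `TPC1`; plain-medium control, `RPMI`) × two
release time points (`4h`, `24h`) × n paired donors (default 4), i.e. four
condition-groups of n samples with every donor present once per group.
Expression travels as a gene × sample matrix with an explicit scale tag
(`counts` → `cpm` → `log2cpm`); scale transitions happen only through the
declared operations so no stage can silently mix scales.

## Synthetic data

Counts are negative binomial, `var = μ + φ μ²`, around a library-size-scaled
mean whose log2 is

```
baseline_g + de(g, group) + donor(d) + activity_m(group) + λ_m · f_{m,s}
```

* **baseline** ~ Normal(5, 2) on log2 relative scale; library sizes
  ~ LogNormal(log 5e6, 0.2). The source experiment does not publish depth or
  dispersion, so these are ordinary bulk-RNA-seq values, config-exposed and
  not claims about any particular dataset.
* **dispersion** φ_g = 3·φ̄ / Gamma(4, 1) — an inverse-gamma-like spread with
  mean φ̄ (default 0.1), clipped below at 1e-4.
* **DE genes**: `n_de_per_contrast` (default 50) distinct genes per time
  contrast receive a ±`de_log2fc` (default 2) offset in the co-culture
  condition at that time, alternating sign.
* **modules**: each planted module has a per-sample shared standard-normal
  factor `f_{m,s}` entering with loading λ (default 0.9) plus a per-group
  log2 `activity` offset. The latent-factor form was chosen over explicit
  covariance matrices: simulation stays O(genes) and the implied correlation
  structure is positive-definite by construction. With λ = 0.9 and φ = 0.1
  the implied within-module correlation on log-CPM is ≈ 0.9, comfortably
  above the network threshold of 0.7 — a module is *designed* to appear as a
  network cluster.
* **donor effects** are additive on the log2 scale and shared across a
  donor's four samples, which is what makes the paired/blocked analysis
  meaningful.
* The default world plants three modules: early-response (+2 in co-culture at
  4 h), late-response (+2 at 24 h) and repressed (−2 in co-culture at both
  times) — the analogues of an early up-cluster, a late up-cluster and a
  down-cluster.

One integer seed drives everything through `numpy.random.SeedSequence.spawn`
substreams with a fixed order, so a configuration is a complete description
of the dataset. The gene-set generator emits one "true" set per module (80%
members, 20% decoys by default) plus uniform random sets; the annotation
generator mirrors this with one term per module (80% module genes).

**Not emulated**: read-level artifacts (FASTQ), isoforms, GC/length bias,
outlier samples, correlated library-size/condition confounds, ontology DAG
structure. A green recovery test therefore establishes that the algorithms
recover structure of the planted kind at realistic noise, not that they are
robust to every artifact of real data.

## Presence filter and normalization

"Present throughout all conditions" is operationalized as **median CPM ≥ 1 in
every one of the four groups** (inclusive). The median tolerates one dropout
donor per group; the rule and threshold are config-exposed because only the
outcome, not the rule, is ever published for the motivating experiment.
Normalization is `log2(CPM + 1)`; the pseudocount keeps zeros finite and is
config-exposed. TMM/median-of-ratios normalization is a declared non-goal —
at these depths and with presence-filtered genes the difference is small, and
the simulator generates no composition bias.

Fold change over mean uses the grand mean of the four **group means**, not of
raw samples, so each group weighs equally even if the design is unbalanced; a
gene is "elevated" in a group when its linear ratio ≥ 1.

## Two-way ANOVA

The classical fixed-effects decomposition on a balanced design, computed
vectorized from group means (explicitly validated to 1e-8 against brute-force
group-mean arithmetic and against `statsmodels` `anova_lm`). Donor enters as
an additive block, default on; with 4 donors this removes 3 residual df and
the donor variance. Contrasts (co-culture − control within a time) use the
pooled residual mean square — at n = 4 per cell a per-cell variance estimate
is unstable; the per-subset variant exists for the algebraic equivalence test
(t² = one-way F).

Degenerate genes (zero residual variance) are flagged: flat genes get p = 1
(claiming no effect and keeping the BH denominator stable), genes whose
variance is fully explained get p = 0. Unbalanced designs with interaction
are rejected rather than silently reweighted.

Default selection thresholds q ≤ 0.05 and |log2FC| ≥ 1 are declared choices
(the motivating experiment's exact criteria are unpublished), config-exposed.

## Co-regulation network

Edges require Pearson r ≥ `r_min` (default 0.7) over **all** samples —
correlations on the 16 raw samples, not the 4 group means, so time-specific
modules separate by profile shape. Only positive correlations form edges, per
the stated rule; anti-correlated programs therefore land in different
components, which is exactly how an induced and a repressed cluster separate.
Zero-variance genes stay as isolated nodes with a warning.

Clusters are connected components labeled C1, C2, … by decreasing size (ties:
lexicographically smallest member). Sub-clusters are greedy modularity
communities within a component — a deterministic operationalization of
substructure that a human would otherwise read off a force-directed layout.
Modularity's resolution behavior can split a dense clique in two; the
sub-cluster partition always refines the component partition, and recovery is
validated only on synthetic truth (components for well-separated modules,
communities for modules merged by weak cross-links).

The heatmap uses average linkage: genes on correlation distance (1 − r) of
z-scored rows, samples on Euclidean distance of the z-scored matrix. Leaf
orders are fixed by a smallest-original-index-first rule at every merge, so
outputs are permutation-stable.

## Self-organizing map

A batch SOM over per-gene z-scored group-mean profiles (4 values per gene):
the target is condition specificity, and averaging over donors removes
pairing noise. Batch updates keep the result independent of gene order.
Neighborhood is Gaussian with radius decaying linearly from max(grid)/2 to 0
over the epochs; once the radius is 0 an epoch is exactly a k-means step, so
quantization error is non-increasing from there (a tested invariant).

Initialization is deterministic PCA ("linear") layout over the first two
principal components, ±2 SD. Seeded random-profile initialization is
available (`init="sample"`) but not default: on well-separated repeated
profiles it reproducibly leaves dead units (a k-means local optimum with an
empty cluster), while linear initialization orders the map from the start —
this is Kohonen's standard recommendation for batch SOM.

A unit is labeled by the group of its largest codebook value; genes on the
unit are "specific" when that maximum clears the runner-up by ≥ 0.5 z-units
(margin config-exposed). Grid 8×8 and 20 epochs are declared defaults; no
grid dimensions are published for the motivating analysis.

## GSEA

Ranking metric: signal-to-noise (μ_a − μ_b)/(σ'_a + σ'_b) with
σ' = max(σ, 0.2|μ|, 1e-8) — the classic proportional variance floor, needed
at n = 4. Ties break by gene id so the ranking is a strict total order.

The enrichment score is the signed maximal deviation of the weighted KS walk
(weight p = 1 default; p = 0 reduces exactly to the two-sample KS statistic,
tested against scipy's independent implementation). Internally, null scores
are computed from hit positions only, evaluating the walk at its candidate
extrema (just after/just before each hit) — algebraically identical to the
full walk and O(k) per permutation.

The null permutes **gene labels** (random same-size sets on the fixed
ranking), drawn independently per set. Phenotype permutation is implemented
but not default: with 4 paired samples per group the relabeling space is far
too small for stable p-values. NES divides ES by the mean |null ES| of
matching sign; nominal p uses the add-one rule (k+1)/(m+1) over same-sign
nulls so p is never 0; FDR is the standard pooled null-vs-observed NES tail
ratio, clipped to [0, 1]. Sets with fewer than 5 members in the ranking are
skipped with a note.

On an exact tie between the positive and negative extremum of the walk the
positive score is reported; the two ES routes can disagree on sign only in
that measure-zero case (floating-point coincidence), never on magnitude.

## GO over-representation and enrichment map

`scipy.stats.hypergeom.sf(k−1, N, K, n)` behind a validated surface (exact
against combinatorial enumeration for all N ≤ 12). Terms are tested only when
K ≥ 1 and k ≥ 1; BH runs across tested terms; enriched means q ≤ 0.05.

The **universe is all presence-filtered genes**, not just network genes: the
study list (elevated in the co-culture group at the late time, present in the
CRA network) is already conditioned on network membership, and conditioning
the universe the same way would double-count that selection. Both the
universe rule and the q threshold are config-exposed. Annotations are flat
term → gene tables; GO DAG propagation is a declared non-goal.

The enrichment map connects enriched terms with overlap coefficient
|A∩B| / min(|A|, |B|) ≥ 0.5 (inclusive), computed on universe-restricted
annotation sets.

## Pipeline determinism

Every stage reads from and writes to one output directory in plain text
(TSV/GMT/GraphML/JSON); the monolithic runner calls the stage functions in
sequence through those same files, so chained CLI invocations are
byte-identical to `run` on `summary.json`. All floats are written with a
fixed `%.10g` format; the summary JSON is key-sorted with no timestamps.

## Known limitations

* Only balanced 2×2 designs get the interaction model; no mixed models,
  moderated variances or voom-style weights (declared non-goals).
* Gene identifiers are opaque case-sensitive strings; no symbol/ID mapping.
* Phenotype-permutation GSEA is provided but untested for power at small n
  (it is the wrong tool there, which is why gene-set permutation is default).
* The enrichment map does no term-redundancy collapsing.
* Plots are static matplotlib renderings for inspection, not
  publication-grade layouts; no interactive visualization.
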