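# Methods

## Problem and model

`synerscan` finds genes whose induction by two simultaneous treatments is
*super-multiplicative* — stronger than the product of the single-treatment
responses predicts — in a factorial expression experiment with a genotype
control. The motivating design is a breast-cancer cell model (p53-proficient
"vector" cells vs. stable p53-knockdown "p53i" cells) treated with an MDM2
inhibitor (drug factor: Nutlin-3 vs. DMSO vehicle) and a TLR5 agonist
(ligand factor: flagellin vs. none), with an optional p38-kinase-inhibitor
(SB203580) arm in the p53-proficient genotype.

All analysis is done on log2 expression. For one gene within one genotype,
replicates are averaged on the log2 scale per condition and linear fold
changes are taken against the matched vehicle/untreated reference
(DMSO, no ligand):

    FC_c = 2^( mean_log2(condition c) − mean_log2(reference) )

Averaging on the log2 scale is the geometric mean on the linear scale,
which is the natural location estimate under the log-normal noise model
used throughout.

### Synergy factor

The core statistic is a Bliss-independence-style ratio of fold changes:

    SF = FC_combo / (FC_drug · FC_ligand)

"Expression" in this ratio is deliberately interpreted as fold change
relative to the matched reference rather than raw intensity: a ratio of raw
intensities would carry units of expression in the denominator's square and
change with probe brightness, whereas fold changes make SF dimensionless
and invariant to rescaling a gene's values by any constant (a tested
invariant). Under multiplicative (Bliss-like) independence of the two
treatments SF = 1; SF > 1 is super-multiplicative induction.

### Synergistic-target classification

A gene is a **synergistic target** iff all three criteria hold, with
*strict* inequalities throughout:

1. `FC_combo > 2 · FC_drug` **and** `FC_combo > 2 · FC_ligand`
   (combination beats each single treatment at least two-fold), in the
   p53-proficient genotype. The "greater than two-fold compared with each
   single treatment" wording is read as a ratio of fold changes, not a
   difference — a difference would not be scale-free.
2. `SF > 1.5`.
3. `FC_combo(vector) > 2 · FC_combo(p53i)` (the synergy requires the
   functional genotype).

The three thresholds (2, 1.5, 2) are the `SynergyCriteria` defaults and are
individually configurable. An optional `min_combo_fc` floor (default 1,
i.e. inactive beyond requiring net induction) can exclude genes whose
combination response is weak in absolute terms.

Targets are sub-classified **inhibitor-dependent** when
`FC_combo(no inhibitor) > 2 · FC_combo(inhibitor)` in the inhibitor arm.
No quantitative attenuation criterion is established for this comparison in
the literature the pipeline models; two-fold was chosen as the same
magnitude used everywhere else in the classification and is exposed as
`attenuation_fold`.

The classification is a deterministic thresholding rule, not a statistical
test: no per-gene interaction p-value is computed. A linear-model
interaction test would be a natural extension but is out of scope.

## Preprocessing

The clustering input is prepared with Cluster 3.0 semantics:

* linear matrices get `log2(x + pseudocount)` (default pseudocount 0; RMA-
  style inputs are already log2);
* genes with across-sample standard deviation `SD > sd_threshold` (default
  0.7 log2 units, strict inequality so boundary rows are excluded) are
  retained. The SD denominator is a parameter (`sd_ddof`, default 1 =
  sample SD) because the convention is genuinely ambiguous in this setting;
* each retained row is centered (mean by default, median available) and
  scaled to unit sum of squares. Constant rows pass through unscaled with a
  warning. Filtering precedes centering, matching the order in which the
  two operations are conventionally described.

Cluster *labeling* uses centered but **unscaled** log2 values, so the
labeling margin (default 0.5 log2 units) keeps interpretable units; unit
scaling would shrink contrasts by ~1/√(n_samples) and make any fixed margin
meaningless.

## Clustering

Gene similarity is the uncentered correlation
`s(x, y) = Σxy / √(Σx² · Σy²)` (cosine similarity without mean
subtraction), distance `d = 1 − s ∈ [0, 2]`. A zero-norm row has no
direction; its similarity to anything is defined as 0 with a warning.

Average linkage agglomeration is implemented directly with Lance–Williams
updates (`d(i∪j, k) = (nᵢ·d(i,k) + nⱼ·d(j,k)) / (nᵢ+nⱼ)`, exact for average
linkage) rather than delegated to a library, because the package pins down
behavior libraries leave unspecified:

* **tie-break** — among pairs at the minimal distance, the pair whose
  sorted (min leaf index, min leaf index) key is lexicographically least
  merges first. Exact-zero ties are common in near-duplicate expression
  rows, so this matters for reproducibility;
* **leaf order** — the child with the smaller minimum leaf index is the
  left child; the CDT row order is the left-to-right traversal. No
  optimal-leaf-ordering pass is applied;
* both the fast implementation and the naive O(n³) recompute-all reference
  used in tests consume the *same* precomputed distance matrix, so their
  tie patterns coincide exactly and "same merge partners" is well defined.

Merge heights are non-decreasing (average linkage cannot invert merges,
up to float rounding ≲1e-15). Flat clusters come from cutting the last
k−1 merges (or a height threshold); the default k = 6 is then reduced by
contrast labels (drug-induced / drug-repressed / ligand-induced /
unclassified), since biologically coherent groups are better described by
their condition pattern than by a fixed k. Labels come from two
single-factor contrasts in the vector genotype (drug: Nutlin−DMSO at no
ligand; ligand: flagellin−none at DMSO), choosing the largest-magnitude
contrast above the margin, drug winning exact ties.

## Enrichment

Overrepresentation of a query list in a gene-set collection uses the
one-sided hypergeometric upper tail `P(X ≥ k)` (equivalently one-sided
Fisher's exact), delegated to `scipy.stats.hypergeom.sf`, with
Benjamini–Hochberg step-up FDR across the collection
(`statsmodels.stats.multitest`). Tests validate both against exhaustive
enumeration and hand-computed step-ups. Gene sets are intersected with the
universe; query genes outside the universe are dropped with a warning.

The pipeline's default enrichment universe is **all genes of the analyzed
matrix**. Restricting the universe to the post-filter genes (available via
`enrichment_universe: filtered`) is statistically defensible when the
filter is unrelated to the query, but a variability filter is *not*
unrelated to a response-defined query: in strongly-responding datasets the
filtered set can nearly coincide with the query, collapsing every p-value
to 1 by construction. The broad default keeps the test informative; users
comparing against platform-restricted external signatures should pass the
platform's gene list explicitly.

Signature overlap re-uses the same statistic per signature and additionally
reports the overlapping gene identities.

## Synthetic data

The generator plants six gene classes on a log2-additive signal
(multiplicative on the linear scale — a planted log2 interaction of 2 is a
4-fold super-multiplicative induction):

| class | drug | ligand | interaction |
|---|---|---|---|
| null | – | – | – |
| p53_induced | +e_d (vector only) | – | – |
| p53_repressed | −e_d (vector only) | – | – |
| ligand_induced | – | +e_l (both genotypes) | – |
| synergistic | +e_d (vector) | +e_l (both) | +e_i (vector, combo only) |
| synergistic_inhibitor_dependent | as synergistic | as synergistic | attenuated by the inhibitor |

The ligand response is genotype-independent (TLR signaling does not require
p53), while drug and interaction terms are p53-dependent: they are zeroed
in the knockdown genotype (knockdown treated as complete;
`p53_knockdown_efficiency < 1` models partial knockdown). The inhibitor
subtracts `inhibitor_attenuation` from the interaction term in the combined
condition only — subtracting it in every inhibitor sample would cancel out
of the combo fold change and make the planted dependence undetectable.

Baselines are drawn once per gene (N(7, 1.5²) log2 units, typical of
normalized array intensity); noise is i.i.d. N(0, noise_sd²) per
measurement — the simplest model satisfying the pipeline's assumptions.
Class counts follow largest-remainder apportionment so they match the
configured fractions exactly.

Defaults define the reference study conditions used by the validation
suite: 2000 genes, 3 replicates per condition, class fractions
75/8/8/4/4/1% (5% synergistic in total), log2 main effects 1 (2-fold),
log2 interaction 2 (4-fold extra), inhibitor attenuation 2, noise SD 0.25
log2 units. No quantitative effect-size distribution is established for
the biological classes being emulated; these values were chosen once as
realistic mid-range microarray effect sizes and are **not** tuned to any
particular dataset.

What the generator does *not* emulate: probe-level structure and multiple
probes per gene, array spatial artifacts, intensity-dependent
(heteroskedastic) noise, correlated genes within a pathway, count-based
RNA-seq noise. Passing recovery tests therefore demonstrate correctness of
the *pipeline logic* under a log-normal additive model, not calibrated
performance on real arrays — on real data the noise model is heavier-tailed
and per-gene effect sizes vary, so recall/precision will be lower than the
planted-data figures.

## Numerical choices

* Similarities are clipped to [−1, 1] before forming distances; distances
  to zero-norm rows are 1 (similarity 0 policy).
* TSV writers emit shortest-round-trip decimal representations
  (`repr(float)`), so `read(write(x)) == x` bitwise; CDT/GTR use 6-decimal
  fixed point (TreeView convention). All writers produce byte-identical
  output for identical inputs (fixed column order, LF endings).
* `GWEIGHT`/`EWEIGHT` are fixed at 1; no sample tree (ATR) is emitted —
  only genes are clustered.
* Hypergeometric tails are computed via scipy's log-space survival
  function; `P(X ≥ 0)` returns exactly 1.
* Probe-to-gene collapsing (when a probe-level matrix and a probe→gene map
  are supplied) keeps the probe with maximal row SD per gene by default
  (ties to the first in row order), with a mean rule available.
* Simulation determinism is bitwise for a fixed `(config, seed)`; all
  randomness flows through `numpy.random.default_rng(seed)`.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` run at the generator's
default conditions: classification recovery on 2000-gene datasets over 10
seeds (plus a no-interaction null), clustering oracle equivalence on 50
random instances of up to 25 rows, hypergeometric enumeration up to
universe size 12, and enrichment ranking over 20 seeded simulations with
15 sets of 40 genes. These sizes give stable estimates of the measured
rates while keeping a full run in seconds.

## Known limitations

* The flat-cluster labeling uses only single-factor contrasts in the vector
  genotype; clusters defined by combination-only or genotype-specific
  repression patterns come out "unclassified".
* The classification has no error model: near-threshold genes flip with
  noise, and no confidence measure is attached. The planted-data precision
  and recall quantify this only under the simulator's assumptions.
* With aggressive SD filtering the clustered gene set can be dominated by
  the strongest responders; the filter threshold should be chosen relative
  to the platform's noise floor.
* The enrichment statistic conditions on list sizes and ignores inter-gene
  correlation, as is standard for overrepresentation analysis.
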