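# synerscan

Discovery of synergistically induced genes in factorial-design expression
data.

`synerscan` is for analysts working with a 2×2×2 factorial expression
experiment — two treatments crossed with a genotype/knockdown control, with
replicates — who want to find genes whose response to the *combination* of
treatments exceeds what the single treatments predict, and to characterize
those genes. The motivating setting is p53 pathway activation (MDM2
inhibitor vs. vehicle) crossed with innate-immune TLR5 stimulation
(flagellin vs. none) in p53-proficient vs. p53-knockdown cells, with an
optional kinase-inhibitor arm, but the pipeline is agnostic to what the
factors are.

## The statistic

Within a genotype, replicate log2 values are averaged per condition and
linear fold changes are taken against the untreated reference:
FC_c = 2^(mean log2 condition − mean log2 reference). The synergy factor is
the Bliss-style ratio

    SF = FC_combo / (FC_drug × FC_ligand)

with SF = 1 under multiplicative independence. A gene is classified a
**synergistic target** iff (strict inequalities, defaults shown):

1. FC_combo > 2 × FC_drug and FC_combo > 2 × FC_ligand,
2. SF > 1.5,
3. FC_combo(proficient) > 2 × FC_combo(knockdown).

Around this classification the package provides the full analysis chain:
SD-based variability filtering and Cluster 3.0-style row normalization,
average-linkage hierarchical clustering with the uncentered-correlation
metric (with Java TreeView CDT/GTR output), condition-contrast cluster
labels, inhibitor-dependence sub-classification, hypergeometric gene-set
overrepresentation with BH-FDR, response-signature overlap, and a
synthetic-data generator with planted ground truth that the test suite uses
as its oracle. See `docs/methods.md` for the model and every default.

## Worked example

Simulate the default study conditions (2000 genes, 5% planted synergistic,
3 replicates, log2 main effects 1, log2 interaction 2, noise 0.25) and run
the full pipeline:

```sh
cat > run.yaml <<EOF
out_dir: demo/out
seed: 1
simulate:
  n_genes: 2000
EOF
synerscan run --config run.yaml
```

which prints

```
genes in: 2000; after SD filter: 100; synergistic targets: 100
```

2000 simulated genes enter; 100 pass the SD > 0.7 variability filter and
are clustered; 100 genes pass all three synergy criteria — exactly the
planted 4% synergistic + 1% inhibitor-dependent classes at this noise
level. The per-gene table `demo/out/synergy.tsv` holds the evidence, e.g.
(rounded):

```
gene_id  fc_drug  fc_ligand  fc_combo  fc_combo_p53i    sf  inhibitor_dependent
G1901       1.60       2.02     11.83           2.09  3.68  False
G1902       1.85       1.52     13.24           2.09  4.71  False
G1903       3.00       2.67     17.36           2.05  2.17  False
```

G1901 rises ~1.6-fold under drug and ~2-fold under ligand alone but
~11.8-fold under the combination (SF 3.68 — almost four times the
multiplicative prediction), and only ~2.1-fold in the knockdown genotype:
all three criteria pass. Of the 100 targets, 20 are flagged
inhibitor-dependent — the planted 1% class whose extra induction the
simulated kinase inhibitor removes.

`demo/out/enrichment.tsv` ranks the simulated gene sets by
overrepresentation of the targets (k of K set members among the n = 100
targets in the N = 2000-gene universe):

```
set                     k   K    n    N             p             q
planted_synergistic_01  40  50  100  2000  1.145056e-46  7.633704e-46
planted_synergistic_02  40  50  100  2000  1.145056e-46  7.633704e-46
planted_synergistic_03  40  50  100  2000  1.145056e-46  7.633704e-46
background_005           3  50  100  2000  4.609677e-01  9.054947e-01
```

The three sets planted at 80% synergistic membership dominate; uniform
background sets sit at unremarkable p-values. The run directory also
contains the TreeView pair (`clustered.cdt`/`clustered.gtr`), labeled
cluster assignments, differential gene lists, the signature-overlap table,
and a `manifest.json` sufficient to re-execute the run; re-running with
the same config and seed reproduces every file byte for byte.

The same stages are available individually (`synerscan simulate`,
`cluster`, `synergy`, `enrich`) and as library functions
(`synerscan.classify_synergistic`, `synerscan.average_linkage`, ...).

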