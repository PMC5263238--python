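# brainaging

Analysis pipeline for studying how gene expression and cell composition in
the human brain change with age. It serves two audiences: transcriptomics
analysts working with multi-region expression cohorts (one sample per brain
region per individual, ages spanning the adult range), and imaging analysts
quantifying immunolabeled slide tiles in which cells of interest carry a
brown DAB stain and all other nuclei a blue hematoxylin counterstain.

## What it computes

**Expression arm.** Samples are assigned to three age groups (young 16–44,
middle 45–74, old ≥ 75 years). Per region, each gene is tested by one-way
ANOVA across the groups and adjusted by Benjamini–Hochberg; a gene is
aging-altered in a region when q < 10⁻³. Genes are then classified by
*regional breadth* — the number of regions (of 10) in which they are
altered: region-specific (1), region-selective (2–7), multi-regional (≥ 8),
cross-regional (all 10). Cell-type specificity of a gene g for type t is
scored against a seven-cell-type reference panel as

    score(g, t) = (mean expression in t + ε) / (max over other types + ε),

and genes with score ≥ 5 form per-type marker lists, whose enrichment
within breadth categories is tested hypergeometrically. Samples are
compared by Spearman correlation, clustered hierarchically (Euclidean
distance), embedded by t-SNE, and scored for age-group discrimination.
Finally, age in years is predicted from each cell type's markers by
forward–backward stepwise OLS with brain-bank and cause-of-death covariates
forced in, and cell types are ranked by model R².

**Imaging arm.** RGB tiles pass an entropy QC (Shannon entropy of the
grayscale histogram must exceed 5 bits), are segmented by thresholding +
channel-based stain classification + connected components, and cells are
binned by body area (small 500–3,000 px, medium 3,000–6,000, large
6,000–9,000, very large > 9,000). Tiles are classed into low/high nucleus
density (proxying white vs gray matter) with the k most extreme tiles
selected per case, and young-vs-old count differences are tested with
shuffled-label permutation t statistics (add-one p-values, configurable
tails and round × shuffle schemes).

A synthetic-data module generates expression cohorts, reference panels and
stained tiles with planted ground truth, and every analysis operator is
validated against that truth. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

```python
import brainaging as ba

# a cohort of 40 individuals x 10 regions with nine planted
# cross-regional aging effects (+2.0 log2 in the old group)
effects = tuple(
    ba.PlantedEffect(f"g{i:05d}", ba.synthetic.REGIONS, "up", 2.0)
    for i in range(9)
)
cfg = ba.ExpressionStudyConfig(
    n_individuals=40, n_genes=2000, planted_effects=effects, seed=42
)
study = ba.generate_expression_study(cfg)

table = ba.run_de(study.expression, study.metadata, fdr_threshold=1e-3)
breadth = ba.breadth_table(table)
print(int(table.significant.sum()))            # 89
print(breadth["breadth"].value_counts().to_dict())
# {'unclassified': 1991, 'cross_regional': 8, 'multi_regional': 1}

cross = breadth.index[breadth.breadth == "cross_regional"].tolist()
report = ba.discriminate_age_groups(study.expression, study.metadata, cross)
print(report.n_correct, "of", report.n_total)  # 40 of 40

img, truth = ba.generate_tile(ba.TileConfig(n_stained=12, n_counterstained=13, seed=7))
objects = ba.segment_cells(img)
print(truth.counts)                            # {'stained': 12, 'counterstained': 13}
print(sum(o.stain_class == "stained" for o in objects))  # 12
```

The cohort holds 375 samples (missing regions are dropped at random, as in
real brain banks). Of the nine planted genes, eight are recovered as
cross-regional and one lands in the neighboring multi-regional class (it
missed the q-threshold in a single region at this cohort size) — 89
significant (gene, region) pairs in all, against zero expected false
positives genome-wide. Clustering on the recovered cross-regional genes
separates every individual into its correct age group, and segmentation of
a synthetic tile reproduces the rendered ground truth exactly.

The same steps are available from the shell:

```bash
brainaging simulate expression --config cfg.yaml --seed 42 --out cohort/
brainaging de run --expr cohort/expression.tsv --meta cohort/metadata.tsv --out de/
brainaging classify score --expr cohort/expression.tsv --meta cohort/metadata.tsv --out report.json
brainaging permtest --summary tiles.tsv --measures stained,other --seed 0 --out perm.tsv
```

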