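# omicsqc

Quality evaluation of omics quantification tables.

RNA-Seq and mass-spectrometry studies end in a feature-by-sample table —
genes, proteins or metabolites quantified across every sample of a study.
How good that table is depends as much on the processing pipeline
(normalization, imputation, batch handling, quantification settings) as on
the experiment itself, and different pipelines applied to the same raw data
yield tables of very different quality. `omicsqc` scores one or more
candidate tables on six complementary axes and renders a comparative HTML
report, so the best processing method can be chosen on evidence rather than
habit:

1. **Data depth** — identified and quantifiable feature counts, cross-table
   feature overlap (exclusive UpSet-style intersections), per-sample counts
   and missing-value distributions.
2. **Normalization** — per-sample abundance distributions, plus a pairwise
   distribution-similarity score: for samples *i*, *j* the tie-aware
   Mann–Whitney AUROC = P(x<sub>j</sub> > x<sub>i</sub>) + ½P(x<sub>j</sub> =
   x<sub>i</sub>); a pair's similarity is 1 − 2·|AUROC − ½| and the table
   score is the mean over pairs (1 = all samples identically distributed).
3. **Batch effect** — average silhouette width s(i) = (b−a)/max(a,b) of the
   batch labels in PCA space, and principal-component regression: the
   variance-weighted R² of one-way ANOVAs of PC scores on the batch factor.
   Higher = more batch structure.
4. **Biological signal** — (a) Pearson correlations of intra- versus
   inter-complex protein pairs (CORUM-style sets), summarized by a
   separation AUROC; (b) co-expression-network function prediction: a
   random walk with restart, p ← (1−r)·Mp + r·p₀ on the column-normalized
   adjacency M, ranks held-out pathway members under cross-validation
   (AUROC per pathway); (c) cross-validated AUROC of a regularized logistic
   model predicting the two-level sample class; (d) hierarchical-clustering
   concordance (adjusted Rand index) with class and batch partitions.
5. **Platform reproducibility** — per-feature coefficient of variation
   (SD/mean, linear scale) over replicated QC samples; headline metric: the
   percentage of features with CV < 30%.
6. **Multi-omics concordance** — gene-wise and sample-wise Spearman
   correlation against a paired table from another omics layer (e.g. mRNA
   for a protein table).

All scores are mapped onto a common [0, 1] scale and drawn as one radar
polygon per table; every number in the report is also written as TSV.

## Worked example

The package ships a synthetic-data generator whose fixtures exercise every
metric, so a full run needs no external data:

```sh
omicsqc fixtures --out demo --degraded-noise-sd 2.0
omicsqc run --data-dir demo/tables --sample-file demo/sample_annotation.tsv \
    --complexes demo/complexes.gmt --pathways demo/pathways.gmt \
    --paired demo/paired.tsv --scale log2 --out demo_report
```

This writes `demo_report/report.html` plus the TSV bundle. The same run
from Python:

```python
from omicsqc import (EvaluationConfig, FixtureSpec, degrade_table,
                     evaluate_tables, generate_dataset, raw_metric_table)

ds = generate_dataset(FixtureSpec(seed=1, batch_shift=0.5), name="clean")
noisy = degrade_table(ds.table, 2.0, seed=2, name="degraded")
report = evaluate_tables([ds.table, noisy], ds.annotation,
                         EvaluationConfig(random_seed=1),
                         complexes=ds.complexes, pathways=ds.pathways,
                         paired=ds.paired)
print(raw_metric_table(report).T.round(3))
```

which prints (clean vs. noise-degraded table):

```
table                          clean  degraded
n_identified                 300.000   300.000
n_quantifiable               300.000   300.000
similarity_score               0.908     0.926
asw_batch                      0.221     0.186
pcr_batch_r2                   0.155     0.095
complex_separation_auroc       1.000     0.747
median_function_auroc          1.000     0.754
class_cv_auroc                 1.000     0.850
ari_vs_class                   0.015    -0.005
ari_vs_batch                  -0.005     0.015
fraction_cv_below_threshold    0.843     0.013
median_genewise_r              0.721     0.328
```

Reading it: both tables have full depth (every feature quantifiable), and
the injected 0.5-log2 batch shift shows up in both (silhouette ≈ 0.2, PCR
R² 0.10–0.15). The signal metrics separate them sharply — the clean
table's protein-complex pairs, network-based pathway prediction and class
prediction are all at AUROC 1.0 while the degraded table drops to
0.75–0.85 — and the degraded table's QC replicates are no longer
reproducible (1% of features below 30% CV versus 84%), with mRNA–protein
concordance halved. The radar overview aggregates this into a mean quality
score of 0.88 (clean) versus 0.62 (degraded).

## Input formats

- **Data tables**: TSV, first column header `ID` (feature identifiers), one
  column per sample; empty cells / `NA` / `NaN` are missing, `0` is a value.
- **Sample annotation**: TSV with columns `sample`, `class`, and optional
  `batch`, `order` (integer run order), `is_qc` (0/1).
- **Gene sets**: standard GMT (complexes and pathways).
- **Config**: YAML mirroring `EvaluationConfig` (thresholds, CV folds, RWR
  restart probability, seed, ...).

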