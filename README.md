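# methcoord

Differential co-expression analysis of the DNA methylation enzyme panel.

DNA methylation homeostasis is maintained by a small set of enzymes acting in
a cycle: the methyltransferases DNMT1, DNMT3A and DNMT3B write 5-methyl-
cytosine; the dioxygenases TET1, TET2 and TET3 oxidize it stepwise to 5hmC,
5fC and 5caC; and the glycosylase TDG excises the oxidized forms for
replacement with unmodified cytosine. In healthy tissue the transcript levels
of these seven genes tend to rise and fall together — their pairwise
correlations are strongly positive — while in tumors this coordination is
attenuated. `methcoord` packages that analysis for anyone with a gene ×
sample expression table (RNA-seq or qPCR) and, optionally, clinical
annotations:

* **Correlation panels** — for each sample group (tissue × condition), all
  C(G, 2) pairwise Pearson coefficients of a G-gene panel, with two-sided
  p-values from t = r·√((n−2)/(1−r²)) on n−2 df, Benjamini–Hochberg
  adjustment within the group's pairs, and a "significantly positive" call
  (r > 0.3 and adjusted p < 0.05 by default).
* **Normal vs tumor coordination** — with matched panels across N tissues,
  each gene pair's per-tissue correlations form paired vectors (r_normal,
  r_tumor); a two-sided paired t-test summarizes coordination loss, an
  edge-count connectivity map counts the tissues where r_normal > r_tumor
  (strictly), coordination profiles are clustered hierarchically, and pairs
  are ranked by mean per-tissue difference.
* **Clinical stratification** — patients split by early recurrence/death
  (≤ 3 years), TNM stage (I/II vs III/IV) or lymph-node status (positive vs
  negative); a gene pair is flagged in a cancer type when the two strata's
  correlations differ by more than 0.15 in absolute value (strictly), and
  flags are tallied across cancer types.
* **qPCR normalization** — relative expression from threshold cycles via
  2^(Ct_ref − Ct_gene), i.e. 2^(−ΔCt) with ΔCt = Ct_gene − Ct_ref.
* **A synthetic-study generator** — multivariate log-normal expression with
  a specified per-group correlation matrix (Gaussian copula on the log
  scale), independent control genes, matched normal/tumor groups and
  clinical cohorts with a planted latent-group effect, so every stage is
  testable end to end with known ground truth.

The main estimators follow scikit-learn conventions
(`CorrelationPanelEstimator`, `PairedCoordinationComparison`,
`CoordinationClusterer`, `StratifiedCorrelationAnalysis`,
`DeltaCtNormalizer`, `ReferenceNormalizer`); module-level functions wrap
them for one-line use, and a `methcoord` CLI ties the stages into a
reproducible run.

## Worked example

Simulate a matched four-tissue study in which the seven enzymes are
equicorrelated at r = 0.6 in normal tissue and uncorrelated in tumors, then
run the whole pipeline:

```sh
methcoord simulate --out demo --tissues liver,lung,kidney,colon \
    --n-per-group 150 --seed 7
methcoord run-all --expression demo/expression.tsv \
    --metadata demo/metadata.tsv --out demo/results
```

`demo/results/top_divergent.tsv` then ranks the most divergent pairs:

```
pair          mean_delta  t_statistic       p  significance_tier
DNMT3B-TET1       0.6735      40.8982  0.0000                ***
TET2-TDG          0.6640      28.4927  0.0001                ***
DNMT3A-TET2       0.6412      12.7182  0.0010                 **
```

`mean_delta` is the mean over the four tissues of r_normal − r_tumor — close
to the planted 0.6 — and the paired t-test (df = 3) rejects the
no-difference null for every pair. `demo/results/edge_counts.tsv` shows each
pair more correlated in normal tissue in all four tissues (`count = 4`), and
`clusters.tsv` separates normal from tumor coordination profiles at the
two-cluster cut. `panels.tsv`, `summary.json` (full effective
configuration, seed, per-stage counts) and, when clinical data are supplied,
`clinical_differences.tsv` and `flag_tally.tsv` complete the bundle.

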