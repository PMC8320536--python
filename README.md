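# dpcnet

Differential partial-correlation network analysis for multi-omics
disease-module discovery.

`dpcnet` is for computational biologists who have matched tumor/normal
gene-expression, DNA-methylation and somatic-variant data (plus a weighted
protein–protein-interaction scaffold such as STRING) and want to nominate a
small, interacting *module* of disease genes rather than a flat list of
differentially expressed genes. The premise is that complex disease arises
from rewired regulation: edges that appear or disappear between conditions
carry more signal than per-gene expression changes.

## The method

Starting from a background PPI network restricted to expressed genes and to
interactions with a combined confidence score > 500:

1. **PCCN** — per group (tumor, normal), each background edge *(i, j)* is
   tested with the Pearson correlation *r<sub>ij</sub>* of the two genes'
   expression; p-values come from the Student-t transform
   *t = r√(n−2)/√(1−r²)*, are Benjamini–Hochberg adjusted over all
   background edges jointly, and edges with adjusted *p* < 0.01 are kept.
2. **PCORN** — Pearson correlation cannot separate direct from indirect
   coupling, so each PCCN edge is re-tested with the first-order partial
   correlation

   *r<sub>ij(k)</sub> = (r<sub>ij</sub> − r<sub>ik</sub> r<sub>jk</sub>) /
   √((1 − r<sub>ik</sub>²)(1 − r<sub>jk</sub>²))*

   conditioning on single genes *k* drawn from the PCCN common neighborhood
   of *i* and *j*; the candidate minimising |r<sub>ij(k)</sub>| is tested
   with *t = r<sub>ij(k)</sub>√(N−q−2)/√(1−r<sub>ij(k)</sub>²)* (order
   *q* = 1), Bonferroni adjusted over all PCCN edges; adjusted *p* < 0.05
   survives. An edge therefore remains only if no single network neighbor
   explains it away.
3. **Diff-PCORN** — the symmetric difference of the two PCORNs: edges
   present in exactly one condition, tagged `tumor_only` / `normal_only`.
4. **Diff-MN** — every Diff-PCORN edge is re-scored in methylation space:
   over all cross-gene pairs of CpG sites, the maximum
   |r<sub>tumor</sub> − r<sub>normal</sub>| of Beta-value correlations;
   edges scoring > 0.7 form the differential methylation network.
5. **Ranking** — hub genes of Diff-PCORN (degree > 30) are intersected with
   hub genes of Diff-MN (degree > 15) and ordered by descending somatic
   variation frequency (fraction of variant-called samples in which the
   gene carries ≥ 1 mutation; ties broken by Diff-PCORN degree); the top 15
   genes are the module biomarkers. (Degree thresholds and top-k are
   configuration; a bundled kidney-carcinoma profile uses Diff-MN
   degree > 10.)
6. **Validation** — hypergeometric enrichment of the module in a reference
   cancer-gene list, *P(X ≥ x) = 1 − Σ<sub>k<x</sub>
   C(M,k)C(N−M,n−k)/C(N,n)*; linear-SVM tumor/normal classification with
   stratified five-fold cross-validation, within-fold random oversampling
   and pooled out-of-fold ROC/AUC; and single-linkage cityblock
   hierarchical clustering cut at two clusters.

A seeded synthetic-data generator (`dpcnet.simulate`) produces paired
expression/methylation/mutation datasets from a Gaussian graphical model
with planted direct edges, indirect i–k–j chains, differential
co-methylation and elevated disease-gene mutation rates, so the whole
pipeline is testable without any downloads.

## Worked example

Simulate a default dataset (200 genes, 120 tumor / 40 normal samples, 10
planted disease genes) and run the full pipeline, with degree thresholds
scaled to the synthetic network:

```yaml
# example.yaml
ranking:
  diff_pcorn_min_degree: 6
  diff_mn_min_degree: 4
  top_k: 10
out_dir: example_out
```

```bash
dpcnet run --config example.yaml --simulate --seed 1
```

prints (stderr log, abridged):

```
PCCN(tumor): 180 / 400 edges significant (BH < 0.01)
PCCN(normal): 56 / 400 edges significant (BH < 0.01)
PCORN(tumor): 136 / 180 edges retained (Bonferroni < 0.05)
PCORN(normal): 30 / 56 edges retained (Bonferroni < 0.05)
Diff network: 112 edges (109 tumor-only), 27 common edges removed
Diff-MN: 88 / 112 scoreable edges kept (> 0.7)
candidate sets: 9 (Diff-PCORN > 6), 10 (Diff-MN > 4)
ranking: 9 overlap genes, 9 selected
classification: AUC 0.9758 over 5 folds
clustering: normal-cluster recall 1.000
selected genes: G0141, G0137, G0109, G0126, G0142, G0121, G0006, G0081, G0179
```

Reading: of 400 scaffold edges, 180 correlate in tumor; the partial-
correlation step prunes 44 of them (including the planted indirect
chains); 109 of the 112 differential edges are tumor-specific, and 88 also
rewire in methylation space. Nine hub genes pass both degree filters — all
nine are planted disease genes (`example_out/inputs/ground_truth.json`) —
and the module separates tumor from normal with AUC 0.98 supervised and
perfect normal-cluster recall unsupervised. Every stage writes its edge
list / table under `example_out/`, and `manifest.json` records all counts.

The same subcommands run stage-by-stage on real data
(`dpcnet preprocess|pccn|pcorn|diffnet|diffmn|rank|validate`); input paths
(expression TSV + label file, methylation matrix + site annotation, MAF
table, STRING-style link file) and every threshold live in the YAML config.

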