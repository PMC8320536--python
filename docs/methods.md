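# Methods

## Model and assumptions

The pipeline treats gene regulation within a condition as a sparse network
of pairwise linear dependencies over a curated PPI scaffold. Pearson
correlation detects *any* linear coupling; first-order partial correlation
r_ij(k) = (r_ij − r_ik·r_jk)/√((1−r_ik²)(1−r_jk²)) removes the coupling
explained by one intermediate gene k. Restricting to first order keeps the
cost near O(|E|·d) on a sparse network (d = typical common-neighborhood
size) and is sufficient to remove chain-type confounds i–k–j, the dominant
source of indirect edges in sparse scaffolds; higher-order confounds
(multiple parallel paths) are out of scope.

Assumptions worth keeping in mind: dependencies are approximately linear
on the measurement scale (FPKM, Beta values are used as-is, no M-value or
log transform), samples within a group are i.i.d., and the PPI scaffold is
a superset of the true regulatory edges — the method can only remove
scaffold edges, never add ones the scaffold lacks.

## Statistical procedures and their universes

* Pearson stage: two-sided p from t = r√(n−2)/√(1−r²) on n−2 df,
  Benjamini–Hochberg over **all background edges of the group jointly**,
  keep adjusted p < `pearson_alpha` (default 0.01, strict). The looser BH
  stage limits the size skew between the (large-n) tumor and (small-n)
  normal networks.
* Partial stage: t = r√(N−q−2)/√(1−r²) at order q = 1 (q = 0 when the edge
  has no conditioning candidate), Bonferroni over **all PCCN edges of the
  group jointly**, keep adjusted p < `partial_alpha` (default 0.05,
  strict). Bonferroni is deliberately conservative here because candidate
  selection below is a minimum over k, which biases |r_partial| downward
  under the null of any single explaining neighbor.
* Conditioning-set rule: k ranges over the PCCN common neighbors of the
  edge; the candidate minimising |r_ij(k)| is tested, ties broken by
  lexicographic k, so results are independent of iteration order. This is
  the package's operationalisation of "exclude indirect interference": an
  edge survives only if *no* single neighbor explains it away. An
  exhaustive mode (k over all other genes) is available via
  `SignificanceConfig.exhaustive_conditioning`; it is slower and more
  conservative.
* Degenerate inputs: a constant expression vector makes r undefined — the
  edge is treated as null (r = 0, p = 1) with a warning; |conditioning
  r| = 1 invalidates a candidate k (skipped; if all candidates are
  degenerate the edge falls back to the zero-order test). Partial
  correlations are clamped to [−1, 1] against floating-point overshoot and
  |r| = 1 maps to p = 0.
* Differential methylation score: max over cross-gene CpG-site pairs of
  |r_tumor − r_normal| (Beta-value Pearson within each group), strict
  threshold 0.7. Edges whose genes lack CpG coverage are dropped, not
  imputed. Ties on the maximum resolve to the lexicographically first
  sorted site pair.
* Ranking: descending variation frequency, ties by descending Diff-PCORN
  degree, residual ties lexicographic. (The frequency direction is the
  only reading consistent with selecting the *most* mutated genes;
  ascending would select housekeeping-like genes.) Overlap genes absent
  from the variant data rank with frequency 0 rather than being dropped.
* Enrichment: exact hypergeometric upper tail. The complement sum
  1 − Σ_{k<x} is accumulated in log space; when the tail itself is below
  0.5 it is summed directly instead so that very small p-values retain
  full relative precision. The universe N defaults to the processed
  expression gene set and is configurable.
* Classification: linear-kernel SVM with default regularisation,
  stratified k-fold (default 5), random oversampling of the minority class
  **inside each training fold only** (sampling with replacement to class
  balance) to avoid leakage, AUC from pooled out-of-fold decision scores —
  deterministic given the seed and using each sample exactly once.
* Clustering: SciPy single-linkage with cityblock distance, cut at two
  clusters; the cluster holding more true normal samples is called the
  normal cluster and recall is the fraction of normals placed there.

## Key tunable parameters

| parameter | default | meaning |
|---|---|---|
| `ppi_min_confidence` | 500 | STRING combined score, strict > (scores 1–999) |
| `min_expressed_fraction` | 0.5 | gene must be expressed (> 0) in strictly more than this fraction of pooled samples |
| `pearson_alpha` | 0.01 | BH-adjusted threshold for PCCN |
| `partial_alpha` | 0.05 | Bonferroni-adjusted threshold for PCORN |
| `meth_score_threshold` | 0.7 | strict lower bound on max \|Δr\| for Diff-MN |
| `diff_pcorn_min_degree` | 30 | hub cut in Diff-PCORN (strict >) |
| `diff_mn_min_degree` | 15 | hub cut in Diff-MN (strict >); the bundled KIRC profile uses 10 |
| `top_k` | 15 | module size |

The degree defaults are calibrated to networks with O(10⁴–10⁵) edges; on
small (synthetic) networks they must be scaled down or the candidate sets
are empty. `simulate.SYNTHETIC_RANKING` (degree > 6 / > 4, top 10) matches
the planted hub degrees of the default generator.

## The synthetic-data generator

`simulate.generate` draws per-group expression from a Gaussian graphical
model whose precision matrix Ω has unit diagonal and Ω_ij = −s on each
planted edge, so the planted full-order partial correlation equals s
exactly. Positive definiteness is verified by Cholesky and a non-PD
configuration raises, naming the strongest offending edge.

Default conditions: 200 genes, 120 tumor / 40 normal samples, 10 disease
genes. Planted structure:

* each disease gene gains 12 tumor-only edges at partial correlation 0.25
  to disjoint partner genes. 0.25·√12 ≈ 0.87 puts the hub star near its
  positive-definiteness limit (s√d < 1), which *inflates the marginal*
  correlations of the spokes to ≈ 0.45 — this is what makes the edges
  detectable under Bonferroni at n = 120 while the precision-matrix entry
  stays exactly 0.25;
* 20 chains i–k–j at strength 0.6 in both groups, with the i–j pair wired
  into the PPI scaffold but absent from the precision matrix: a pure
  indirect confound (marginal endpoint correlation ≈ 0.56, conditional
  independence given k);
* 40 weak shared edges (strength 0.2, per-gene shared degree capped at 1
  so the hubs stay jointly positive definite) common to both groups;
* decoy PPI edges fill the scaffold to an average degree of 4.

Latents are standardised per gene (hub genes otherwise dominate the
non-linear transform through their inflated marginal variance) and mapped
to an FPKM-like scale as exp(μ_g + 0.7·z) with per-gene log baselines
μ_g ~ N(1, 1). The monotone exponentiation attenuates Pearson correlations
by roughly 10–20 % — a deliberate stressor, disabled with
`fpkm_transform=False` (which yields a shifted-affine, correlation-exact
scale). Disease genes additionally receive a +1.2 SD latent shift in tumor
samples, mirroring the empirical fact that module genes in this kind of
analysis are also differentially expressed; without a mean component the
supervised/unsupervised validation stages would have nothing to measure.

Methylation: each gene gets 1–3 CpG sites; Beta values are logistic
squashes of Gaussians. In tumor samples, the sites of a disease gene and
of its partners load on a shared per-disease-gene factor whose loading
targets a site–site correlation of `diff_meth_effect`+0.1 (the margin
absorbs squash attenuation and normal-group sampling noise), absent in
normal samples — so planted disease edges carry |Δr| well above the 0.7
threshold while unplanted edges score ≈ |N(0, n⁻½)| differences.
Mutations are per-gene per-tumor-sample Bernoulli draws at 0.4 for disease
genes and 0.05 otherwise.

What the generator does **not** emulate: TCGA marginal distributions,
batch or purity effects, realistic CpG density or spatial methylation
correlation, copy-number signal, and normal-tissue mutation calls.
Passing tests therefore demonstrate that the algorithmic chain recovers
the structure it is designed for — not that it would perform identically
on real tumor cohorts, where signal strengths, confounding and scale
differ by orders of magnitude.

## Problem sizes used in the automated checks

The test suite and the acceptance script run the default 200-gene
generator (seconds per replicate): chain-removal/retention statistics
aggregate 20 replicates at n = 200 per group; planted-recovery runs use
the default 120/40 split; the large-n consistency check uses a single
n = 2000 draw. The pipeline-level tests use an 80-gene configuration with
proportionally scaled thresholds.

## Known limitations

* Only first-order conditioning; parallel multi-path confounds survive.
* The minimum-|partial| rule tests one candidate per edge; it does not
  correct for selecting the minimum, relying on Bonferroni's conservatism
  instead.
* Group sample-size imbalance translates into PCORN size imbalance (the
  smaller group has less power), which the symmetric difference then
  inherits; the BH/Bonferroni split mitigates but does not remove this.
* Beta values are analysed untransformed; near-saturated CpG sites
  (Beta ≈ 0 or 1) compress correlations.
* The sample-barcode matching across assays assumes exact string equality
  after optional prefix truncation (`barcode_prefix_len`).
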