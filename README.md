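# pgrn — integrative definition of pluripotency regulatory modules

`pgrn` implements, as a tested and fully synthetic-data-verifiable pipeline,
the integrative procedure used to re-define the pluripotency gene regulatory
network (PGRN) of embryonic stem cells:

1. **Screen integration** — gene-level results of several CRISPR knockout
   screens (MAGeCK-style normalized log2 fold change + p-values) are
   partitioned into a *common* hit set (negative selection p < 0.05 in every
   screen) and a *context-specific* set, with Pearson correlation of
   normalized LFCs, Wilcoxon gene-set comparisons and an expressed-gene
   filter (> 0.5 RPKM) as supporting analyses.
2. **Co-occupancy sub-classes** — factor binding peak sets are binarized
   over genome bins; for factors *a, b* occupying *m_a*, *m_b* of *N* bins
   with *O* shared, the co-occupancy Z-score standardizes *O* against the
   hypergeometric null: `Z = (O − m_a·m_b/N) / σ`. Average-linkage
   hierarchical clustering of `1 − corr(Z rows)` cuts the factors into
   sub-classes (CORE-, MYC-, PRC-like, ...).
3. **HDBS** — each sub-class's peak sets are union-merged; each merged site
   keeps its co-occupancy degree (distinct members overlapping ≥ 1 bp) and
   sites with degree ≥ k of n are the high-degree co-occupancy binding
   sites.
4. **Target assignment + PU refinement** — proximal targets have an HDBS
   within TSS ± 5 kb; distal targets are wired through promoter-capture
   interaction pairs (one anchor on an HDBS, the other on the promoter).
   An AdaSampling-style positive-unlabeled ensemble (kNN + logistic
   learners over resampled training sets) re-weights the putative targets
   and, at prediction threshold 1, retains only unanimously positive genes
   — the high-precision regime.
5. **Module activity** — the expression matrix G(i,j) is standardized
   `S(i,j) = log2(G(i,j)/Ḡ(i))`, centralized `C(i,j) = S(i,j) − S̄(i)`, and
   module × group activity is the plain mean
   `E(x,y) = Σ C(i_x, j_y)/(g_x·s_y)`. A rank-AUC per-sample score
   (AUCell-style recovery of module genes in the top 5% of the expression
   ranking) and Kaplan–Meier / log-rank analysis of median-split activity
   complete the chain.
6. **Enrichment patterns** — per sample, genes ≥ 2-fold over/under their
   cross-sample mean are tested against each module with the upper-tail
   hypergeometric; the smaller significant direction is reported as a
   signed −log2(p), and group-level patterns aggregate sample calls.

The headline quantities of the original analysis depend on large external
compendia (hundreds of ChIP-seq datasets, five screens' raw counts, tumour
expression cohorts), so verification here is property- and simulation-based:
the `pgrn.synth` module generates every input with planted ground truth
(essential genes, factor classes, true targets, activity shifts,
activity-dependent hazards) and every stage is scored against that truth or
against independent oracles (closed forms, exhaustive enumeration,
brute-force interval counting, permutation nulls).

## Worked example

The numbered drivers under `analysis/` run each stage on one simulated study
and print what they find:

```sh
$ python analysis/02_integrate_screens.py --seed 1
39 common genes (32.23% of 121 hits), 82 context-specific
planted common-essential recall: 0.975
mean pairwise screen correlation: 0.646

$ python analysis/03_cooccupancy_classes.py --seed 1
15 factors over 10000 bins; cut into 4 sub-classes (ARI vs planted classes: 1.000)
  CORE: 50 HDBS at k=3 of 4 (mean degree 4.00)
  ...

$ python analysis/05_module_activity.py --seed 1
module activity E(module, group):
         G1     G2
CORE  0.904 -0.904
MYC  -0.554  0.554
PRC   0.874 -0.874
```

Reading the output: 39 of the 40 planted all-screen essential genes are
recovered in the common set (recall 0.975); the Z-score clustering recovers
the three planted factor classes exactly (adjusted Rand index 1.0); and the
activity chain reports the CORE-like module up in group G1 (E = +0.90) and
down in G2, matching the planted +2 log2-fold activation, with the MYC-like
module showing the planted repression. `analysis/06_enrichment_survival.py`
then shows the corresponding signed enrichment heatmap values (±37 =
−log2 p under the hypergeometric) and log-rank p ≈ 8×10⁻⁴ for the
median-split survival difference planted at hazard ratio 3.

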