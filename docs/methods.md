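# Methods

This note documents the models, parameter choices and limitations of the
`pgrn` pipeline. Everything described here is computed by the package; no
empirical claim is made that the tests or `scripts/acceptance.py` do not
themselves measure.

## Scope and shape

The pipeline re-implements an integrative network-definition procedure:
CRISPR-screen hit integration, binding co-occupancy clustering of
transcriptional regulators, k-of-n co-bound site extraction (HDBS),
proximal/distal target assignment with positive-unlabeled refinement, and
module activity/enrichment/survival scoring. Because the original analysis
consumes large external compendia, the package ships a first-class
synthetic-data module that generates every input with planted ground truth;
all verification is against that truth or against independent oracles. The
repository is organized as an analysis project: computation lives in
`src/pgrn/`, the numbered scripts in `analysis/` are thin narrative drivers,
and `pgrn.pipeline.run_pipeline` chains all stages deterministically.

## Synthetic-data model

All randomness flows through `numpy.random.Generator` streams derived from
`SimConfig.seed` with fixed per-stage tags, so identical configs give
byte-identical output files and the stages can be re-run independently.

**Screens.** Five screens over 400 genes, 4 sgRNAs per gene, two replicates
at each of two timepoints. Counts are negative binomial (gamma–Poisson)
with dispersion 0.1 around log-normal sgRNA abundances (median ≈ 200 reads)
and log-normal(0, 0.1) library-size factors — the standard overdispersion
model for screen counts. Planted essential genes carry a −2 log2 shift
(per-sgRNA noise SD 0.3); 40 genes are essential in all screens and 60 in
random proper subsets, giving the common/context-specific structure the
integration stage must recover. Gene-level p-values are a one-sample t-test
over the 4 per-sgRNA log2 ratios; this is only approximately calibrated for
log-ratios of NB counts, so the null-rate test allows up to 8% at nominal
5%.

**Peaks.** Each planted class shares 50 binding sites; every member factor's
peak is the site center plus uniform jitter within ±bin_size/4, with width
600 bp (> 2× the jitter, so co-bound peaks always physically overlap and the
co-binding also survives 1 kb binning). Factors carry 60 private background
peaks; noise factors carry background only.

**Annotation/interactions.** Genes sit on a 12 kb grid in the proximal 55%
of each 5 Mb chromosome (no promoter windows overlap); class sites target
distinct genes, 40% proximal (center inside TSS ± 5 kb minus a peak-width
margin) and 60% distal on a 5 kb grid in the gene-free distal 30% of the
chromosome, each distal site wired to its target promoter by a BEDPE pair;
100 distractor pairs connect unused distal slots to random promoters.

**Expression.** Log-normal baseline (meanlog = log 10, sdlog = 1, RPKM-like),
multiplicative 2^effect shifts of module genes in "active" groups (default
±2 per module, alternating sign across modules so both activation and
repression are exercised), log-normal noise with SD 0.5 in log2 units, two
groups of 20 samples.

**Features.** Ten histone-mark plus four expression-time-course features;
true targets of any module are shifted +3 SD on H3K4me3/H3K27ac/H3K4me1 and
on the time-course features (cleanly separable by construction). Each
module's putative-positive set adds enough background-only genes to make
the contamination fraction exactly the configured 20% — the planted false
positives the PU refinement must reject.

**Survival.** Exponential event times with hazard h₀·HR^{1[z>0]}
(h₀ = 0.1, HR = 3 by default) on the activity z-score, with uniform
censoring whose upper bound is calibrated by bisection to the requested
censoring fraction (≈ 20%); rate 0 disables censoring.

What the generator does **not** emulate: read-level data, peak-calling
noise, correlated sgRNA efficiencies, batch effects, mixed cell
populations, overlapping factor classes, dosage-dependent (rather than
threshold) hazards. Passing tests therefore demonstrate correctness of the
algorithms under the planted model, not robustness to every artefact of
real data.

## Analysis choices

- **Coordinates** are 0-based half-open (BED) everywhere; interval overlap
  means ≥ 1 bp; merge gap is 0 (touching intervals merge), matching
  BEDTools-merge defaults.
- **Significance for screen integration** is raw p_neg < 0.05, no
  multiple-testing correction — the partition is defined on the stated
  threshold. Genes absent from a screen count as non-significant there
  (conservative for the common set). LFC pseudocount is 0.5.
- **Co-occupancy null**: the Z statistic uses the hypergeometric null of
  random bin assignment, E = m_a·m_b/N and
  σ² = E(1 − m_a/N)(N − m_b)/(N − 1), over 1 kb bins by default. This null
  is exactly testable against a permutation oracle (agreement within 0.1 on
  a 20-bin toy with 20 000 draws). The diagonal, computed with the same
  formula, equals √(N−1) and is the row maximum. A factor occupying all
  bins has σ = 0 and its entries are set to 0 with a warning.
- **Clustering**: average linkage on 1 − Pearson(Z rows), tree cut to an
  externally supplied number of clusters (the cluster count emerges from
  real data, not from an automatic criterion); deterministic, and
  permutation-equivariant in the factor order. Constant Z rows are an error
  naming the factors.
- **HDBS thresholds** k are per-class configuration; the pipeline default is
  ⌈0.75·n⌉, mirroring the ≈ 25-of-32 regime used for CORE-class sites.
- **Proximal window** is TSS ± 5 kb, half-open `[tss−w, tss+w)`,
  strand-independent. The histone-feature window ("5 kb around the TSS") is
  read as TSS ± 2.5 kb — a 5 kb total span, distinct from the ±5 kb target
  window; both are configurable.
- **PU refinement**: positives are drawn from candidates ∝ positive weight,
  negatives from non-candidates ∝ (1 − weight), balanced classes; the
  classifier's predicted probability becomes the new weight (5 rounds). The
  ensemble (10 members) alternates a 5-NN probability estimator and an
  L2-logistic model over independent sub-seeds. Each member casts a hard
  positive vote (final probability ≥ 0.5); the retained set thresholds the
  *vote fraction*, with threshold 1 − 1e−9 meaning unanimity. Thresholding
  votes rather than mean probabilities keeps threshold 1 meaningful for
  continuous classifiers (a logistic probability never reaches exactly 1);
  the ensemble-mean probability is still recorded per gene. Candidates can
  only be removed, never added, and the convergence flag reports whether
  candidate weights still moved > 1e−3 between the final two rounds.
- **Activity equations**: Ḡ(i) and S̄(i) are arithmetic means over *all*
  samples, not per group. The standardization pseudocount defaults to 1
  (prevents log 0) and is set to 0 in closed-form tests; with one sample
  per group, no noise and effect +1 the chain yields exactly ±0.5, which
  both the tests and the acceptance script recompute.
- **Rank-AUC activity**: descending expression ranks with ties broken by
  gene label; recovery curve summed over the top ⌈0.05·n⌉ ranks and
  normalized by the all-genes-at-the-top curve, so the score is in [0, 1]
  and invariant to monotone transforms of the expression column. The 5%
  top fraction follows the cited tool's convention.
- **Survival stratification**: split at the activity quantile (default
  median); ties at the cut value go to the low stratum. Log-rank and
  Kaplan–Meier estimates come from lifelines.
- **Enrichment**: upper-tail P[X ≥ k] for both directions; boundaries of
  the 2-fold rule are inclusive ("at least"), under-expression is
  value ≤ mean/fold; direction is the smaller significant p, exact ties
  resolve to "over"; no multiple-testing correction alters the direction
  calls. The universe is the genes present in the expression matrix.

## Problem sizes

The default study (400 genes, 5 screens, 3 classes × 4 factors + 3 noise
factors, 10 Mb genome at 1 kb bins, 2 × 20 samples) keeps every stage's
planted signal comfortably detectable while the full pipeline runs in
about one second; replicated checks use 20 seeds (PU refinement,
enrichment detection) and 200 replicates (log-rank calibration and power),
sizes at which binomial error bands are tight enough for the stated
thresholds.

## Known limitations

- The co-occupancy Z null is a documented stand-in for the original
  (unpublished-formula) statistic; it is exact under random bin assignment
  but ignores genomic covariates (mappability, chromatin accessibility).
- Gene-level screen p-values use a t-test rather than MAGeCK's alpha-RRA;
  MAGeCK output is consumed, not re-implemented.
- The PU ensemble's unanimity rule is aggressive by design (precision over
  recall); with non-separable features it will under-retain.
- Interaction pairs are taken as given; no contact-significance modelling.
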