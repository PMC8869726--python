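# Methods

This note records the models, estimators and design choices behind
`triadyn`, in the spirit of a statistical package's model
documentation.  It states what each stage assumes and computes; all
empirical figures it refers to are produced by the test suite or
`scripts/acceptance.py`, never asserted from memory.

## Quantification and filtering

Counts are normalized to FPKM, `FPKM[g,s] = counts[g,s] · 1e9 /
(length_bp[g] · total[s])`, with `total[s]` the summed counts of
sample s.  A gene is *expressed* at a time point when its
replicate-mean FPKM exceeds 1 strictly; the mean-over-replicates
reading was chosen (rather than any-replicate) because it is robust to
a single noisy replicate and gives one well-defined value per time
point, matching how triads are classified.  Sample QC reports Spearman
correlations (average ranks on ties), average-linkage hierarchical
clustering on 1 − SCC, and PCA of log2(FPKM + 1) — the +1 pseudocount
keeps zeros at zero and the full SVD solver is pinned so runs are
bit-reproducible.

## Differential expression

The DE stage is a self-contained negative-binomial test designed to be
*calibration-testable* rather than to reproduce any particular
packaged tool:

- **Normalization** — classic median-of-ratios size factors (genes
  with a zero anywhere excluded from the geometric means).
- **Dispersion** — gene-wise method-of-moments estimates
  `α̂_g = (v_g − m_g) / (m_g² − v_g/n)` (the denominator corrects the
  upward bias of `m²` as an estimate of μ²), pooled across genes by a
  robust trimmed least-squares fit of the trend `α(μ) = a0 + a1/μ`.
  With thousands of genes the trend is effectively known, which is
  what makes a 3-versus-3 design testable at all; purely gene-wise
  dispersions on 4 residual degrees of freedom give either an inflated
  normal test or a severely underpowered t test.  The trend is floored
  at `α_min = 1e-4`.
- **Statistic** — a score-type contrast on the raw scale,
  `z = (m₂ − m₁) / √((1/n₁ + 1/n₂)(μ̂₀ + α(μ̂₀) μ̂₀²))` with μ̂₀ the
  pooled mean of normalized counts, referred to a standard normal.
  The raw-scale difference is symmetric under the null, avoiding the
  small-count skew of log-scale Wald statistics.  Swapping the group
  labels negates the fold change and leaves p unchanged.
- **Fold change** — `log2((m₂ + c)/(m₁ + c))` with pseudocount
  c = 0.5, so fold changes stay finite at zero counts.
- **Calling** — BH adjustment per contrast over the tested genes;
  DEG ⇔ p_adj < 0.05 (strict) and |log2FC| ≥ 1, the earlier time
  point always the control.  Genes expressed at neither time point of
  a contrast are excluded from testing (and hence from the BH m),
  mirroring independent-filtering practice.
- All-zero genes report (log2FC = 0, p = 1) rather than erroring.

Measured on the generator's study conditions (2,000 genes, 3 vs 3):
null raw-p rejection at the 0.05 level sits inside the three-binomial-
SE band, and planted |log2FC| = 2 effects are recovered with
sensitivity ≥ 0.9 at false-discovery proportion ≤ 0.1
(`tests/test_acceptance.py`, `scripts/acceptance.py`).

## Co-expression clustering

DEG profiles are replicate-mean FPKM per time point, z-scored per
gene; "scaled" is implemented as z-scoring because that is the
standardization under which Pearson-correlation distance and Euclidean
distance have identical minimizers (for z-scored rows of length T,
‖x − y‖² = 2T(1 − r)), letting standard k-means optimize the
correlation objective exactly.  k-means++ with 25 restarts stabilizes
the silhouette-versus-k curve; constant profiles (undefined
correlation) are dropped and reported.  The silhouette uses the
1 − r distance; genes in singleton clusters score 0, as does the
degenerate a = b = 0 case.  `select_k` scans a k range (default 2–10
in the pipeline), keeps the highest overall (mean) silhouette and
breaks ties toward the smaller k.

## Triad bias classification

Relative contributions (fA, fB, fD) are computed from replicate-mean
FPKM — one classification per triad per time point.  Assignment is
pure nearest-centroid in Euclidean distance to the seven ideal points
listed in the README, with no dead zone between Balance and the biased
categories; ties (a measure-zero set) break conservatively in the
order Balance, suppressed (A, B, D), dominant (A, B, D), so exact
boundary points are not over-called as biased.  A triad with summed
FPKM ≤ 1.0 at a time point is Low there: the boundary value 1.0 is
assigned to Low as the complement of the strict "> 1" expressed rule.
Category proportions are emitted both including and excluding Low,
since either denominator can be wanted for a composition plot.
Transition tables count triads moving between the 8 states (7 + Low)
for every adjacent time-point pair; the stability summary reports
per-category adjacent retention (pooled over pairs) and full-series
stability (fraction of triads ever in a category that hold it at all
time points).

## Enrichment

Over-representation uses the one-sided (greater) Fisher exact test,
i.e. the upper hypergeometric tail — two-sided tests answer a
different question than "over-represented".  Odds ratios apply the
Haldane 0.5 correction only when a cell is zero.  Raw p-values are
thresholded (0.01 for TF families in clusters, 0.05 for pathway terms
in bias categories); a BH option exists but defaults off, matching the
raw-p convention for these screens.  Default backgrounds in the
pipeline: all expressed genes for cluster enrichment, all homoeologs
of expressed triads for category enrichment; category member sets are
the genes of triads assigned that category at one or more time
points.

## Synthetic data generator

The generator emulates a 6-time-point (0–10 DAP, step 2),
3-replicate grain-development design at desk scale.  Per triad it
plants a bias category drawn from a mix that mirrors the composition
reported for deep grain time courses (~79.8% of triads expressed, of
which 72.13% balanced, 20.97% suppressed, 6.90% dominant; the rest
Low); fractions come from a Dirichlet with mean at the category
centroid and concentration κ (default 200 — the imbalance noise level
has no field-standard value, so a moderately tight default was chosen
that leaves categories clearly separated yet non-trivial; κ = ∞ gives
noise-free fractions).  Zero centroid components are clamped to
ε = 1e-3 before scaling by κ, since Dirichlet parameters must be
strictly positive; classification tolerates the ε shift.

Triad totals follow a log-normal baseline (natural-log mean 2.5,
sd 1.0 — a right-skewed expressed-gene FPKM distribution) modulated by
one of up to eight fixed temporal templates (monotone trends and
early/mid/late peaks or dips, amplitude 1.5 on the log2 scale;
`n_clusters_planted = 1` means flat profiles).  A fraction of
expressed triads (`switch_fraction`, default 0.1) changes category at
one random adjacent boundary; a fraction per contrast
(`de_fraction`, default 0.1) receives a persistent ±`de_log2fc`
(default 2) step in its total from that boundary on, recorded per gene
and contrast as planted DE.  Counts are drawn gamma-Poisson with
variance μ + αμ² (default α = 0.1) from
μ = FPKM · length · library/1e9, with gene lengths uniform in
0.5–5 kb and per-sample library sizes log-uniform in 2–4 × 10⁷.

Two internal adjustments keep the planted truth well defined:

- **Scale consistency.**  FPKM recomputed from counts equals planted
  FPKM only when Σ FPKM·length ≈ 1e9 across the transcriptome; with a
  desk-scale gene count the expressed triads are rescaled by one
  global factor onto that self-consistent scale (fold changes and
  fractions are unaffected).  A consequence worth knowing: per-gene
  FPKM values are higher than in a full ~100k-gene transcriptome,
  because fewer genes carry the whole library.
- **Guard band.**  Planted totals landing in (0.5, 2.0) — adjacent to
  the expressed-triad threshold of 1 — are scaled out of the band
  (per-triad constant factor), so a planted state cannot flip between
  Low and expressed through count noise alone.  The planted category
  truth is then defined directly from the planted totals: Low wherever
  the total is ≤ 1.

All randomness derives from one master seed through per-purpose
substreams (structure, fractions, DE, counts, annotations), so a rerun
with the same config is byte-identical while stages stay statistically
independent.

**What the generator does not emulate:** positional/GC biases,
isoform-level effects, replicate-level batch structure, dependence
between the three homoeologs' counts beyond the shared total, and
genuinely continuous (non-categorical) bias.  Recovery results on this
generator therefore validate the estimators' correctness and
calibration under the stated model, not their behaviour under every
real-data pathology.

**Truth-confounding and the DE validation conditions.**  With κ < ∞
the per-time-point redraw of fractions is itself genuine differential
expression that the truth table does not flag, and category switches
move individual homoeologs by large factors.  The DE calibration and
recovery checks therefore run with fractions frozen (κ = ∞), flat
templates and no switches, so the planted DE flags are the complete
truth; the bias-recovery checks, conversely, use the full noisy
generator.  This is a property of validating on planted truth, not of
the estimators.

## Problem sizes and numerical conventions

Validation runs use 300–2,000 triads (900–6,000 genes, 18 samples),
300-gene clustering sets and 1,000-table Fisher checks — sizes at
which every check completes in seconds while leaving thousands of
cells/tests per estimate.  TSV outputs use `%.6g` floats, UTF-8 and
'.' decimals; manifests store SHA-256 checksums; k-means and PCA are
seeded/pinned so the whole pipeline is deterministic given its config.

## Known limitations

- The DE test shares dispersion only through the 1/μ trend; no
  empirical-Bayes shrinkage of gene-specific deviations, no
  fold-change shrinkage, no likelihood-ratio test.
- Nearest-centroid classification has no "unclassified" buffer;
  fractions close to a boundary are assigned a side even when the
  distance difference is tiny (the `distance` column lets callers
  apply their own cutoff).
- Enrichment treats terms as opaque ids: no ontology structure or
  term-term dependence.
- FPKM is within-sample normalization; cross-sample composition
  effects are handled only inside the DE stage (size factors), not in
  the FPKM tables themselves.
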