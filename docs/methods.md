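# Methods

This note records the statistical models behind each `sigrev` stage, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that make results
reproducible.

## Differential expression and signature extraction

Input matrices are assumed already normalized (RMA-style for arrays); the
package starts at the log2 (or raw-count) gene × sample matrix.

*Noise filter.* A gene is dropped when its log2 value falls below the noise
cutoff (default 6) in at least 85% of arrays. The 85% rule, rather than
100%, keeps genes expressed in only one biological group — precisely the
ones a two-group comparison cares about.

*Moderated t.* Per gene, the pooled two-sample variance `s2_g` with
`d_g = n1 + n2 − 2` df is shrunk toward a prior `(s0², d0)` under the
hierarchical model `s2_g ~ s0²·F(d_g, d0)`. The prior is fit by method of
moments on the log variances: with
`e_g = log s2_g − ψ(d_g/2) + log(d_g/2)`, the excess of `var(e)` over the
chi-square sampling term `ψ′(d_g/2)` identifies `d0` through a trigamma
inverse (Newton iteration), and `mean(e)` then identifies `s0²`. When the
observed spread is no wider than sampling noise alone, `d0 = ∞` and every
gene gets the common variance. The statistic
`t = logFC / (s̃·sqrt(1/n1 + 1/n2))` is referred to `t(d0 + d_g)`. This is
the standard empirical-Bayes estimator; the "fully moderated" refinement
(covariate-dependent priors) is intentionally not implemented — the
standard estimator is the reproducible core, and `prior_df=0` recovers the
ordinary pooled t exactly (tested as an oracle equivalence). Agreement
with limma's `lmFit`/`eBayes` on a seeded fixture is ~1e-13 in `t`.

*Multiplicity.* Two thresholds are exposed and neither is hard-coded:
mean-false-positive control (cutoff `k/G`; with G = 10000 tests and k = 1
this is the familiar 1e-4) for cell-line comparisons, and BH FDR for
tumor-vs-normal cohorts. Genes passing significance are then split by
fold-change cutoffs (defaults FC > 3 up, FC < 0.25 down), computed as the
anti-logged group-mean difference `2^Δlog2` per array convention.
Significance is applied before fold change; the order matters only for
which threshold is reported as binding, not for the final set.

*Signature assembly.* Up and down lists are ordered by |t| descending with
lexicographic gene-id tie-breaks, and the thresholds used are recorded in
the signature's provenance string.

*Counts.* RNA-seq counts are filtered (drop genes with count < 5 in ≥ 2
samples of any group), TMM-normalized, converted to log2 CPM with a 0.5
prior count, and passed to the same moderated t. The TMM implementation
follows the reference algorithm exactly — reference sample by closest
upper quartile, 30% two-sided trim on M-values, 5% on A-values,
inverse-delta-method-variance weighting, factors rescaled to geometric
mean 1 — and matches edgeR's `calcNormFactors` to 1e-10 on a frozen
fixture. Note that a sample that is an exact scalar multiple of another
gets factor 1: library size, not the TMM factor, absorbs global scaling.

## Connectivity scoring

Profiles are complete rankings (rank 1 = most up-regulated). The
enrichment score is the classic rank-based two-sided KS statistic
(`a`/`b` extrema over the tag positions; tie `a = b` resolves to `−b`
under the strict `a > b` reading — oracle-tested). Its range is
`[−1, 1)`; `−1` is attained when all tags occupy the very bottom ranks.
The combined score `s = ES_up − ES_down` is set to 0 when the two
enrichment scores share a sign: such a profile moves both halves of the
signature the same way and supports neither reversal nor mimicry.

Scaling divides positive raw scores by the library's positive maximum and
negative ones by the magnitude of its negative minimum, giving per-query
scores in `[−1, 1]`. Replicate profiles of one drug (different doses/time
points) are averaged *after* scaling — scores are computed per profile,
then averaged per drug. Query genes absent from the library universe raise
a hard error rather than being silently dropped, because silent drops
change scores irreproducibly.

`weight_exponent=1` enables a GSEA-style weighted running sum. Because
profiles carry ranks only (no per-gene statistic), the hit weight is the
rank's distance from the list centre, `|r − (n+1)/2|`. The default (0,
classic unweighted) is what all pipeline paths use; the combined up/down
sign rule and `[−1, 1]` scaling belong to the classic formulation.

Hierarchical clustering of score matrices uses Euclidean distance with
complete linkage; under exact ties scipy merges in input order, making
label order deterministic for a fixed input.

## Nearest-template prediction

Genes are z-scored across the cohort being classified (within-dataset
standardization; cosine distance on raw intensities would be dominated by
expression magnitude). The template is the ±1 vector over signature genes
(optional per-gene weights are supported but off by default — unit weights
are the minimal reproducible reading). A sample's distance to the template
and to its inverse satisfy `d_pos + d_neg = 2` exactly.

Significance: the observed nearest distance is compared with nearest
distances to `R` random templates of the same size and up/down split,
drawn without replacement from the matrix's gene universe;
`p = (1 + #{null ≤ observed}) / (R + 1)`, floor `1/(R+1)`. Nulls use the
nearest (two-sided) distance so pure-noise samples get uniform p-values.
BH-FDR runs across samples; calls with FDR ≥ α (default 0.05) are left
unclassified. Signature-negative means *nearest the inverse template with
significance*, not merely not-positive — the stricter of the two readings,
flagged in the API by the three-way label. Missing signature genes are
dropped from the template with a warning below 50% coverage and an error
below 10%.

A consequence worth knowing: classification needs contrast *within* the
cohort. A cohort in which every sample carries the identical pattern
z-scores to pure noise, so recovery tests always include either normals or
signature-negative tumors.

## Survival

The log-rank test accumulates, at each distinct event time, observed
events in group 1 against the hypergeometric expectation;
`chi2 = (O1 − E1)²/V` with the standard variance term (agrees with
lifelines to 1e-9). The hazard ratio is the O/E estimator
`(O1/E1)/(O2/E2)` with CI `exp(log HR ± 1.96·sqrt(1/E1 + 1/E2))` — chosen
over a Cox fit because it is self-contained and sufficient for two-group
stratification; it mildly attenuates large ratios, which the recovery test
tolerances reflect. Median bifurcation assigns values equal to the median
to "low" (deterministic contract). Chi-square tests are Pearson without
continuity correction; on 2×2 tables the statistic equals the squared
two-proportion z (identity-tested).

## Network analysis

Edges are kept at combined score ≥ 700 (inclusive) from the allowed
evidence channels (experiments, database, neighborhood, fusion by
default). Eigenvector centrality is computed per connected component by
power iteration on `A + I` — same Perron vector, but immune to the ±λ
oscillation of bipartite spectra — normalized to maximum 1 per component,
and matches dense eigendecomposition on exhaustive small graphs to 1e-6.
Communities come from deterministic greedy modularity maximization
(reproducible, unlike stochastic Louvain), with community ids ordered by
smallest member. Edge-count enrichment uses a binomial null with a
user-supplied background density: the degree-preserving null of the
upstream STRING service needs the full interactome, which this package
deliberately does not ship; the binomial null is a documented divergence.

## Prioritization and concordance

The ledger is conjunctive and keyword-exact on a normalized (lower-cased)
action vocabulary: negative averaged score AND status in
{approved, investigational} AND "antineoplastic" in actions. Free-text
matching was rejected for reproducibility. The disease-gene list is a user
input file. Concordance counts a resistance up-gene as reversed when its
treatment fold change is negative (significant at adjusted p < α) and the
drug reference moves it in the same direction — sign-only agreement, since
the reference signature's exact scale is generally unknowable; a signed
fold-change vector is accepted as an alternative reference form.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of parameters + seed (bit-reproducible;
the pipeline splits one global seed into per-stage substreams).

- **Two-group matrices**: per-gene baselines `N(baseline_mean, 1)` around
  log2 = 8, independent Gaussian noise (default sd 0.5, a typical
  between-replicate sd for arrays), planted DE genes at exactly
  ±log2_effect (default 2, matching strong resistance signatures), default
  3 samples/group as in small cell-line designs. Counts use a negative
  binomial with log-normal gene-wise dispersion (median 0.1), the standard
  bulk RNA-seq model.
- **Drug libraries**: each planted reverser places each signature
  down-gene at the top (up-gene at the bottom) independently with
  probability `strength`, giving a continuous dial from exchangeable
  (strength 0) to perfect reversal (strength 1); mimics are symmetric;
  other drugs are uniform permutations. Default universe ~1000–2000 genes,
  echoing measured-landmark-scale libraries.
- **Cohorts**: signature-positive tumors shift template genes by
  ±log2_effect (default 1.0 — patient tumors show weaker signature
  expression than the cell lines that defined it); negatives and normals
  carry the inverse pattern; background genes are pure noise.
- **Survival**: exponential event times (baseline rate 0.02/month ≈ 3-year
  median survival, advanced-HCC scale), uniform censoring calibrated so
  the expected censored fraction equals `censor_rate`.
- **Graphs**: balanced stochastic block models; edge confidences uniform
  on [700, 1000] so graphs round-trip the thresholded reader.

Not emulated: probe-level array artifacts, batch effects, inter-gene
correlation, realistic perturbation-inference noise, or covariate-linked
censoring. Passing recovery tests therefore demonstrates correctness of
the algorithms under their own assumptions, not performance on real
cohorts, where correlated genes and batch structure will widen every
interval.

## Test problem sizes and sensitivities

Recovery and calibration tests run at: 200-drug libraries × 50 seeds
(reverser recovery), 100-tumor cohorts × 20 seeds × 3 planted fractions
and 100 null cohorts of 40 samples (NTP), 500 null and 100 alternative
replicates (log-rank), 500 replicates of 1000-gene null matrices (mean-FP
control), all 4-node graphs plus random graphs to 8 nodes and 10
seeded 100-node block models (network oracles). These sizes give
Monte-Carlo error comfortably inside each asserted tolerance.

One deliberate choice: the planted-signature recovery test uses
fold-change cutoffs (2, 0.5) strictly inside the planted |log2FC| = 2.
With the study-default down cutoff 0.25 = 2^-2 sitting exactly at the
planted effect, a down-gene's observed fold change clears it with
probability ½ by construction, and even the symmetric cutoff 1/3 lies
within one standard error (0.41 at n = 3/group) of the planted effect, so
neither setting can distinguish a correct implementation from a broken
one. The cutoffs inside the effect test what the filter is for —
direction and magnitude screening — while detection sensitivity at the
mean-FP threshold is asserted separately at the study's own settings.

## Known limitations

- The moderated t assumes exchangeable gene variances around one prior;
  variance trends with intensity are not modeled.
- The O/E hazard-ratio estimator attenuates for large true ratios and has
  no covariate adjustment.
- The binomial network-enrichment null ignores the degree sequence.
- GCT support covers the common 1.2/1.3 single-description layouts, not
  multi-row-metadata extensions.
- Gene identifiers are opaque, case-sensitive strings; namespace mapping
  (probe/protein/symbol) is the caller's responsibility.
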