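# Methods

This note documents the models and procedures implemented in `apamirna`,
the choices made where the design was genuinely open, and what the
synthetic calibration does and does not demonstrate.

## Data model and conventions

Two cell states are compared throughout: line **A** (normal-like) and line
**B** (cancer-like); every "change" is B relative to A. Each APA gene is
reduced to two isoforms: the short isoform ends at the 5'-most poly(A)
site, the long isoform at the 3'-most site; reads at intermediate sites
are discarded, not merged, because merging would silently change what the
long/short ratio (LSR) measures. The UTR segment up to the proximal site
is the cUTR (on both isoforms), the segment between the two sites the aUTR
(long isoform only). On the minus strand the 5'-most site is the largest
genomic coordinate.

UTR offsets are 0-based and half-open. A target site is located by its 5'
start; a site whose start offset equals the cUTR length is assigned to the
aUTR, because any site needing sequence at or beyond the proximal cleavage
position exists only on the long isoform. Sites with offsets at or beyond
the distal site are dropped with a warning. Mature miRNAs are aggregated
into seed families by summing their read counts, since family members
share target sites; families with no aUTR site on any retained gene are
excluded.

## Filtering and per-gene metrics

A gene is retained only if, **in each cell line separately**, both isoform
counts are ≥ 1 and their total is ≥ 15 reads (`min_total`). Applying the
total-count rule per line rather than pooled is the stricter, symmetric
reading and is the package's choice. No pseudocounts are used anywhere;
zeros are handled entirely by the filter.

Per retained gene: LSR = long/short reads; log2 LSR change =
log2(LSR_B/LSR_A); the expression-weighted UTR length is
`(short·L_c + long·(L_c+L_a)) / (short+long)`; the shortened fraction is
the relative weighted-length loss from A to B (the "average shifted
length divided by the length in A" reading — the only one consistent with
a dimensionless fraction). The optional per-gene shortening call is a
two-sided Fisher exact test on the 2×2 isoform-count table gated on
LSR_B < LSR_A; it is a documented stand-in used for synthetic data and the
enrichment stage, and an externally supplied shortened-gene table always
takes precedence.

## Signed two-sample KS statistic

With Δ(t) = F_y(t) − F_x(t) over the two empirical CDFs, D is Δ at the
point of maximum |Δ|, so D < 0 when the first sample (the targets) sits
stochastically lower. When several points attain the maximum |Δ| with
different signs, the earliest pooled point decides — an explicit
convention, needed for exact antisymmetry D(x,y) = −D(y,x) and for
reproducibility under heavy ties. |D| equals the classical two-sample KS
statistic; the p-value is the classical asymptotic Kolmogorov tail at
`sqrt(nm/(n+m))·|D|`. Exact small-sample p-values are deliberately not
computed; p is approximate under heavy ties, which is documented rather
than corrected. All family-level scans report raw p-values with an α of
0.05 and no multiple-testing correction, matching how such scans are
conventionally reported in this literature; a BH-adjusted column can be
derived from the persisted tables if wanted.

## Matched non-target sampling

For family *m*, targets are retained genes with ≥ k aUTR sites of *m*
(k = 1, and 2 for the dosage criterion); the pool is retained genes with
no aUTR site of *m*. "Closely matching" is concretised as stratified
sampling: the two covariates are quantile-binned into 4×4 strata over
pool ∪ targets, and for each target one pool gene is drawn uniformly
without replacement from its stratum, falling back to the nearest stratum
(Manhattan distance on bin indices; ties resolve toward lower expression,
then lower length bins). The draw is seeded and auditable; fallback counts
are reported. The pool must be at least as large as the target set.

Two covariate choices matter and were made deliberately:

1. **Length covariate = full UTR length (cUTR+aUTR), not the
   expression-weighted length.** The weighted length is a deterministic
   function of the LSR being compared (`w = L_c + LSR/(1+LSR)·L_a`), so
   matching on it selects non-targets with systematically biased LSR — a
   collider. In null simulations this inflated the per-family
   false-positive rate from ~5% to >90%. The full UTR length is
   gene-intrinsic and carries the intended "similar 3'UTR length"
   information without touching the outcome.
2. **For the between-state z-score, the expression covariate is the mean
   of the two lines' log2 totals.** Conditioning on one line's noisy read
   total selects on that line's LSR noise and biases the B-vs-A null
   (regression to the mean); a line-symmetric covariate removes the
   asymmetry. For the within-line scans the analysed line's own total is
   used — there both sets are measured in the same line, so the selection
   affects them identically.

The dosage contrast is a paired, one-sided Wilcoxon signed-rank test
(`zsplit` zero handling) of D at the ≥2-site criterion being lower than at
≥1 site, refusing to run below 5 pairs. It is computed over all paired
families and, separately, over the families already significant at the
≥1-site criterion.

## Rank-fold-change grouping

Families are ranked ascending by read count within each line (average
ranks on ties) and RFC = rank_B/rank_A, so RFC > 1 means relatively up in
the cancer-like line; ranking is used because it is invariant to the
overall small-RNA library-depth difference between lines (severalfold in
the motivating data), so no depth normalisation is applied. The rank
direction is chosen so that the "top 25%" by RFC are the up-regulated
families. Groups are up = top ⌈n/4⌉, down = bottom ⌈n/4⌉, mid = rest,
with boundary ties broken by higher reads_B then family id — a
deterministic rule chosen purely for reproducibility.

## Resampling z-score

Per family, `d_target` is the signed KS D between the targets' LSR in B
and in A. The null is built from `n_resamples` (default 100, minimum 30)
equal-size non-target draws — matched by default, uniform via a switch —
each scored the same way; z = (d_target − mean)/sd over the null draws.
The null is treated as normal, and an empirical percentile is reported
alongside as a robustness column. A degenerate null (sd = 0) is an error,
not a silent z of ±∞. The procedure is well calibrated only when target
sets are a small fraction of the retained genes: when targets approach the
pool in size, the null draws overlap heavily and under-disperse, and
per-family z's become dominated by one shared realisation-level contrast.
The synthetic defaults keep per-family targeting at a few percent
precisely so this regime holds; on real data with dense targeting the
uniform/matched switch does not rescue the method and the z's should be
interpreted qualitatively.

## aUTR preference score

For each aUTR target gene of a family group, the score is
`(N_a/L_a) / (N_a/L_a + N_c/L_c)` — the aUTR's share of the gene's
length-normalised site density for that group. It is 1 exactly when the
gene has no group site in the cUTR, 0.5 at equal densities, strictly
increasing in N_a. Because the score is bounded and saturates at 1, group
medians can tie at the ceiling while the distributions differ; the group
comparison therefore reports the KS p-value with both medians and means,
the mean being the non-degenerate location summary in the saturated
regime.

## Synthetic-data generator

The generator encodes the differential-degradation hypothesis as a
seeded, fully parametric model (all defaults in `SyntheticConfig`):

- Gene level: cUTR length ~ LogNormal(ln 800, 0.6) truncated to
  [100, 5000] nt; aUTR length ~ LogNormal(ln 1200, 0.8) truncated to
  [100, 10000] nt; baseline abundance λ ~ LogNormal(ln 200, 1.0) reads;
  baseline long fraction p ~ Beta(2, 2).
- Family level: baseline reads ~ LogNormal(ln 1000, 1.0); between-state
  fold f ~ LogNormal(0, `fold_sigma`=1); 1–3 mature members share each
  family count (so the family-aggregation step is exercised).
- Target sites: family *m* targets a gene's aUTR with probability
  `1 − exp(−rho·L_a[kb]·(1+kappa·[f_m>1]))` and a targeted compartment
  carries `1 + Poisson(site_cluster)` sites; cUTR targeting is identical
  with no kappa term. `rho` defaults to 0.019 targeting events per kb per
  family, solved so that with kappa = 1 the up-quartile of 130 families
  leaves ≈27% of genes with no up-group aUTR site — the sparsity regime of
  conserved-site annotations this generator emulates. `site_cluster`
  defaults to 0.45, putting roughly a third of targeted UTRs at ≥2 sites,
  which is what makes the ≥2-site dosage analysis non-trivial at realistic
  sparsity. A plain per-site Poisson cannot do both: it ties the two-site
  probability to the square of the targeting rate, so any rate sparse
  enough for calibrated resampling leaves the dosage analysis empty.
- Repression: with ẽ the family's expression rank in a line rescaled to
  [0, 1], long-isoform retention is `exp(−beta·Σ_m ẽ_m·n_a(g,m))` and both
  isoforms are scaled by `exp(−beta_c·Σ_m ẽ_m·n_c(g,m))`. Rank-rescaled
  expression (rather than raw reads) bounds the effect and keeps beta
  interpretable across depth scales. `beta_c` defaults to 0 so the
  short-isoform change is uncorrelated with aUTR site count by
  construction — the negative control the correlation stage expects.
- Counts: negative binomial with mean λ(1−p)·shared (short) and
  λ·p·retention·shared (long) per line, dispersion 0.2 (variance
  μ + 0.2μ²); Poisson when dispersion is 0.

`beta = kappa = 0` is an exact null (identical expected LSR in both
lines). The generator emulates count overdispersion, depth-robust family
expression, length-dependent site placement and site clustering; it does
**not** emulate sequence-level effects (no seed-match thermodynamics, no
site-context scores), correlated expression between genes, isoform-
specific library biases, or miRNA transfection/spike-in artefacts — so
passing calibration here shows the statistics behave as designed under
the stated model, not that the biological effect sizes in real data will
match.

## Problem sizes, seeding, determinism

The reference runs use 3000 genes with 100 families (null calibration)
and 130 families (effect mode, beta = 0.5, kappa = 1) — sizes at which
every stage, including 100-resample z-scores for every family, completes
in well under a minute on a single core while leaving per-family target
sets in the calibrated sparse regime. One global seed fans out
deterministically: per-family seeds derive from a stable FNV-1a hash of
the family id combined with the stage, so single stages are independently
reproducible and results are invariant to family iteration order.
Identical config + seed reproduces byte-identical outputs; the run log
records the package version, seed and stage tallies but never wall-clock
time or absolute paths.

## Known limitations

- Asymptotic KS p-values are approximate for small target sets and under
  heavy LSR ties.
- Isoform changes use raw read counts with no cross-library
  normalisation; rank-based statistics absorb depth differences on the
  miRNA side, but the log2 isoform changes inherit any depth imbalance of
  the two APA libraries.
- The resampling z-score assumes target sets are small relative to the
  retained-gene universe (see above).
- The per-gene Fisher shortening call is a stand-in with different power
  than dedicated isoform-switch tests; supplied flag tables take
  precedence.
- Propensity-score or caliper matching, exact KS p-values and
  multiple-testing control are intentionally out of scope.
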