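# apamirna

Tools for asking whether differential microRNA expression drives the
3'UTR-shortening seen in cancer-like cells, using alternative
polyadenylation (APA) isoform counts.

## The problem

Many genes carry several poly(A) sites in their last exon, producing mRNA
isoforms that differ only in 3'UTR length. Cancerous and highly
proliferative cells systematically express more of the **short** isoform:
the long/short ratio (LSR = long-isoform reads / short-isoform reads)
drops. One proposed mechanism is differential degradation: miRNAs that are
up-regulated in the cancer-like state bind target sites in the **aUTR** —
the UTR segment between the proximal and distal poly(A) sites, present
only on the long isoform — and preferentially degrade long isoforms.

This package implements the statistical pipeline to test that hypothesis
from four tables: per-gene short/long isoform read counts in two cell
states (A = normal-like, B = cancer-like), mature-miRNA read counts,
miRNA seed-family membership, and predicted target-site coordinates. It
also ships a seeded generator that simulates all four inputs under the
degradation hypothesis, so every stage can be exercised and calibrated
without any external data.

## The statistics

- **Filtering** — a gene is analysed only if, in each cell state, both
  isoform counts are nonzero and their sum is at least 15 reads.
- **Signed two-sample KS statistic** — for family *m*, targets are
  retained genes with ≥ k aUTR sites of *m* (k = 1 and 2, the dosage
  criterion); an equal-size non-target set is sampled, stratum-matched on
  log2 expression and 3'UTR length. With Δ(t) = F_nontarget(t) −
  F_target(t) over the LSR ECDFs, D is Δ at the point of max |Δ|: D < 0
  means targets express relatively fewer long isoforms. A paired Wilcoxon
  test across families compares D at the ≥2-site versus ≥1-site criterion.
- **Rank-fold-change (RFC)** — families are ranked by expression within
  each state (robust to the large library-depth difference between
  states); RFC = rank_B/rank_A, and families split 25/50/25 into
  up/mid/down groups.
- **Resampling z-score** — per family, D between the targets' LSR in B and
  in A, standardised against 100 matched non-target draws scored the same
  way; z < 0 means the family's targets lost long isoforms beyond the
  global background drift, z < −2 is flagged strong.
- **aUTR preference score** — per aUTR target gene of a group,
  `(N_a/L_a) / (N_a/L_a + N_c/L_c)` with N/L the site counts and lengths
  of the aUTR and the common UTR (cUTR); up vs down groups are compared by
  a two-sample KS test.
- **Dosage correlations and enrichment** — Pearson correlation of the
  per-gene count of up-group aUTR sites with the log2 changes of the LSR
  and of each isoform, and Fisher enrichment of shortened genes among
  up-group aUTR targets.

## Worked example

```python
from apamirna import ApaMirnaShiftModel, SyntheticConfig
from apamirna.simulate import generate_dataset

# simulate the degradation hypothesis: beta = 0.5, aUTR enrichment kappa = 1
ds = generate_dataset(SyntheticConfig(n_genes=3000, n_families=130,
                                      beta=0.5, kappa=1.0, seed=11))
results = ApaMirnaShiftModel.from_synthetic(dataset=ds).fit(
    seed=3, n_resamples=100)
print(results.summary())
```

prints

```
APA / miRNA isoform-ratio shift analysis
========================================================
retained genes:            2399
miRNA families analysed:   130
seed:                      3

Expression change vs LSR change (OLS)
  slope=-0.1346  intercept=-0.0696  r=-0.2654

Target vs matched non-target LSR (>= 1 aUTR site(s))
  families scanned: 130; significantly lower: 47 (36%)
  median signed D: -0.1858

Target vs matched non-target LSR (>= 2 aUTR site(s))
  families scanned: 130; significantly lower: 30 (23%)
  median signed D: -0.2647

Site-dosage effect (paired Wilcoxon, D at >=2 vs >=1 sites)
  n=130  median D: -0.1858 -> -0.2647  one-sided p=4.98e-07

Between-state LSR-shift z-scores
  families: 130  mean=0.240  sd=1.597  fraction z<-2: 4.6%
  group medians: up=-0.944  mid=-0.133  down=2.292
  up vs down KS p=1.57e-07

aUTR target-site preference (up vs down group)
  medians: up=1.000 down=1.000  KS p=0.000231

Up-group aUTR site abundance vs change (Pearson)
  LSR:   r=-0.191 (p=3.64e-21)
  long:  r=-0.246 (p=1.65e-34)
  short: r=+0.002 (p=0.915)
  untargeted genes: 30%

Shortened-gene enrichment among up-group targets
  observed 484 vs expected 455.7  OR=1.34  Fisher p=0.00513
```

Reading it: target genes of each family show lower LSR than matched
non-targets (negative median D), more so when two or more aUTR sites are
required (the dosage effect, Wilcoxon p ≈ 5e-7). Targets of up-regulated
families lose long isoforms between states (median z up < mid < down), and
the up-group's sites sit preferentially in the aUTR. The per-gene count of
up-group aUTR sites correlates negatively with LSR change and long-isoform
change but not with short-isoform change — the signature of long-isoform
degradation — and shortened genes are enriched among up-group targets
(OR = 1.34). With `beta=0, kappa=0` the same pipeline yields null-calibrated
outputs (≈5% significant families, z ≈ standard normal).

The same run is available from the shell:

```bash
apa-mirna-shift run-all --simulate --beta 0.5 --kappa 1 \
    --n-genes 3000 --n-families 130 --seed 11 --out-dir out/ --plots
```

writing every intermediate TSV, `summary.json`, `summary.txt`, a run log
and optional CDF/box plots under `out/`. Subcommands `simulate`, `lsr`,
`compare`, `diffexp`, `zscore`, `preference`, `dosage` and `enrich` run
individual stages on TSV inputs (schemas in `apamirna/io.py`).

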