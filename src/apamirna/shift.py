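"""Between-state LSR-shift statistics.

Four analyses quantify how miRNA families relate to the isoform-ratio shift
from the normal-like (A) to the cancer-like (B) state:

* **Resampling z-score** — per family, the signed KS D between its aUTR
  target genes' LSR in B and in A, standardised against the D values of
  repeatedly resampled matched non-target sets (default 100 draws).  A
  strongly negative z means the family's targets lost long isoforms beyond
  the global background drift.
* **Group contrast** — two-sample KS on the z distributions of the
  rank-fold-change up vs down family groups.
* **aUTR preference score** — per aUTR target gene, the length-normalised
  share of a group's sites falling in the aUTR:
  ``(N_a/L_a) / (N_a/L_a + N_c/L_c)``.
* **Dosage correlations and enrichment** — Pearson correlation of the
  per-gene count of up-group aUTR sites with the log2 changes of LSR and of
  each isoform, and Fisher enrichment of reported shortened genes among
  up-group aUTR targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matching import MatchingConfig, StratifiedMatcher, signed_ks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZScoreResult:
    """Resampling z-score of one family's target-set LSR change."""

    family_id: str
    d_target: float
    null_mean: float
    null_sd: float
    z: float
    n_resamples: int
    n_targets: int
    empirical_percentile: float
    flag_strong: bool  # z < -2: shift well beyond background


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def lsr_change_zscore(family_id: str, targets: pd.Index,
                      summaries: pd.DataFrame, n_resamples: int = 100,
                      config: MatchingConfig | None = None,
                      null_matching: str = "matched",
                      rng: np.random.Generator | None = None) -> ZScoreResult:
    """z-score of the target set's between-state LSR shift.

    ``d_target`` is the signed KS D between the targets' LSR values in cell
    line B and in cell line A (negative when LSR dropped in B).  The null
    distribution is built from ``n_resamples`` equal-size non-target draws
    — covariate-matched by default, uniform when ``null_matching`` is
    ``"uniform"`` — each scored the same way.  The null is treated as
    normal; an empirical percentile is reported alongside as a robustness
    check.
    """
    if n_resamples < 30:
        raise ValueError("n_resamples must be >= 30 for a stable z-score")
    if null_matching not in {"matched", "uniform"}:
        raise ValueError(f"unknown null_matching {null_matching!r}")
    config = config or MatchingConfig()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    targets = pd.Index(sorted(targets))
    pool = pd.Index(sorted(summaries.index.difference(targets)))
    lsr_a = summaries["lsr_a"]
    lsr_b = summaries["lsr_b"]
    d_target, _ = signed_ks(lsr_b.loc[targets].to_numpy(),
                            lsr_a.loc[targets].to_numpy())
    if null_matching == "matched":
        # covariates must be symmetric in the two cell lines: conditioning
        # on one line's (noisy) read total selects on that line's LSR noise
        # and biases the between-line null
        sym_expr = 0.5 * (np.log2(summaries["total_a"].astype(float))
                          + np.log2(summaries["total_b"].astype(float)))
        matcher = StratifiedMatcher(targets, pool, sym_expr,
                                    summaries["utr_length"], config)
    null_d = np.empty(n_resamples)
    for i in range(n_resamples):
        if null_matching == "matched":
            sample, _ = matcher.draw(rng)
        else:
            sample = rng.choice(pool.to_numpy(), size=len(targets),
                                replace=False)
        sample = list(sample)
        null_d[i], _ = signed_ks(lsr_b.loc[sample].to_numpy(),
                                 lsr_a.loc[sample].to_numpy())
    null_mean = float(null_d.mean())
    null_sd = float(null_d.std(ddof=1))
    if null_sd == 0.0:
        raise ValueError(
            f"{family_id}: degenerate null (sd=0 over {n_resamples} draws); "
            "targets may exhaust the pool or LSR values may be constant")
    z = (d_target - null_mean) / null_sd
    return ZScoreResult(
        family_id=family_id, d_target=float(d_target),
        null_mean=null_mean, null_sd=null_sd, z=float(z),
        n_resamples=n_resamples, n_targets=int(len(targets)),
        empirical_percentile=float(np.mean(null_d <= d_target)),
        flag_strong=bool(z < -2.0))


def zscore_scan(families: pd.DataFrame, sites: pd.DataFrame,
                summaries: pd.DataFrame, n_resamples: int = 100,
                config: MatchingConfig | None = None,
                null_matching: str = "matched",
                min_targets: int = 5) -> pd.DataFrame:
    """Per-family z-scores; families with fewer than ``min_targets`` aUTR
    targets among retained genes are skipped and logged."""
    config = config or MatchingConfig()
    autr = sites[(sites["compartment"] == "aUTR")
                 & sites["gene_id"].isin(summaries.index)]
    targets_by_family = {f: pd.Index(sorted(set(g["gene_id"])))
                         for f, g in autr.groupby("family_id")}
    parent = np.random.SeedSequence(config.seed)
    rows = []
    for family_id in sorted(families["family_id"]):
        targets = targets_by_family.get(family_id, pd.Index([]))
        if len(targets) < min_targets:
            logger.info("zscore_scan: %s has %d aUTR target(s) (< %d); "
                        "skipped", family_id, len(targets), min_targets)
            continue
        child = np.random.SeedSequence(
            entropy=parent.entropy,
            spawn_key=(_stable_key(family_id), 7))
        res = lsr_change_zscore(
            family_id, targets, summaries, n_resamples=n_resamples,
            config=config, null_matching=null_matching,
            rng=np.random.default_rng(child))
        rows.append(res.__dict__)
    return pd.DataFrame(rows, columns=[
        "family_id", "d_target", "null_mean", "null_sd", "z", "n_resamples",
        "n_targets", "empirical_percentile", "flag_strong"])


def _stable_key(family_id: str) -> int:
    h = 2166136261
    for byte in family_id.encode():
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h


def compare_group_zscores(up_z, down_z, mid_z=None) -> dict:
    """Two-sample KS contrast of up- vs down-group z distributions.

    Returns the KS p-value and per-group medians (mid included when given);
    under the degradation hypothesis the up group's median z is the lowest.
    """
    up_z = np.asarray(up_z, float)
    down_z = np.asarray(down_z, float)
    if up_z.size < 3 or down_z.size < 3:
        raise ValueError("need >= 3 families per group for the contrast")
    ks = stats.ks_2samp(up_z, down_z, method="asymp")
    out = {"p_value": float(np.clip(ks.pvalue, 1e-300, 1.0)),
           "statistic": float(ks.statistic),
           "median_up": float(np.median(up_z)),
           "median_down": float(np.median(down_z))}
    if mid_z is not None and len(mid_z):
        out["median_mid"] = float(np.median(np.asarray(mid_z, float)))
    return out


# ---------------------------------------------------------------------------
# aUTR preference
# ---------------------------------------------------------------------------

def preference_score(n_a: int, n_c: int, l_a: int, l_c: int) -> float:
    """Length-normalised aUTR share of a gene's target sites, in [0, 1].

    With site densities d_a = n_a/l_a and d_c = n_c/l_c the score is
    d_a / (d_a + d_c): 1 when every site is in the aUTR, 0.5 when the two
    compartments carry equal densities.
    """
    if n_a < 1:
        raise ValueError("preference score is defined only for aUTR target "
                         "genes (n_a >= 1)")
    if n_c < 0:
        raise ValueError("negative site count")
    if l_a < 1 or l_c < 1:
        raise ValueError("UTR segment lengths must be >= 1 nt")
    d_a = n_a / l_a
    d_c = n_c / l_c
    return d_a / (d_a + d_c)


def gene_preference_scores(group_families, sites: pd.DataFrame,
                           pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene preference scores for one family group.

    Site counts are summed over the group's families; only retained genes
    with at least one aUTR site of the group qualify.  ``pairs`` supplies
    cutr/autr lengths.  Returns gene_id-indexed n_a, n_c, l_a, l_c, score.
    """
    fam = set(group_families)
    sub = sites[sites["family_id"].isin(fam)
                & sites["gene_id"].isin(pairs.index)]
    counts = (sub.groupby(["gene_id", "compartment"]).size()
              .unstack(fill_value=0).reindex(columns=["aUTR", "cUTR"],
                                             fill_value=0))
    counts = counts[counts["aUTR"] >= 1]
    if counts.empty:
        return pd.DataFrame(columns=["n_a", "n_c", "l_a", "l_c", "score"])
    l_a = pairs.loc[counts.index, "autr_length"].astype(int)
    l_c = pairs.loc[counts.index, "cutr_length"].astype(int)
    d_a = counts["aUTR"] / l_a
    d_c = counts["cUTR"] / l_c
    return pd.DataFrame({
        "n_a": counts["aUTR"].astype(int), "n_c": counts["cUTR"].astype(int),
        "l_a": l_a, "l_c": l_c, "score": d_a / (d_a + d_c),
    }).rename_axis("gene_id").sort_index()


def group_preference_test(up_scores, down_scores) -> dict:
    """Two-sample KS on per-gene preference-score distributions of the up
    vs down family groups, with medians for direction."""
    up = np.asarray(up_scores, float)
    down = np.asarray(down_scores, float)
    if up.size == 0 or down.size == 0:
        raise ValueError("empty preference-score group")
    ks = stats.ks_2samp(up, down, method="asymp")
    # the score is bounded at 1 and often saturates there, so the mean is
    # reported alongside the median as the non-degenerate location summary
    return {"p_value": float(np.clip(ks.pvalue, 1e-300, 1.0)),
            "statistic": float(ks.statistic),
            "median_up": float(np.median(up)),
            "median_down": float(np.median(down)),
            "mean_up": float(np.mean(up)),
            "mean_down": float(np.mean(down)),
            "n_up": int(up.size), "n_down": int(down.size)}


# ---------------------------------------------------------------------------
# site abundance vs isoform change; shortened-gene enrichment
# ---------------------------------------------------------------------------

def up_site_counts(up_families, sites: pd.DataFrame,
                   genes: pd.Index) -> pd.Series:
    """Per-gene total aUTR sites of the up-group families, 0 for untargeted
    genes (which stay in the analysis)."""
    fam = set(up_families)
    sub = sites[(sites["family_id"].isin(fam))
                & (sites["compartment"] == "aUTR")
                & sites["gene_id"].isin(genes)]
    counts = sub.groupby("gene_id").size()
    return counts.reindex(genes, fill_value=0).astype(int).rename("n_up_sites")


def site_abundance_vs_change(up_families, sites: pd.DataFrame,
                             summaries: pd.DataFrame) -> dict:
    """Pearson correlations of up-group aUTR site abundance with isoform
    changes, plus site-count-binned medians.

    Responses are the per-gene log2 changes (B over A) of the LSR, the
    long-isoform reads and the short-isoform reads.  Genes with zero
    up-group sites are included with covariate 0 and also summarised as
    their own bin.
    """
    x = up_site_counts(up_families, sites, summaries.index)
    if x.nunique() < 2:
        raise ValueError("constant site-abundance covariate")
    xv = x.to_numpy(float)
    out: dict = {"n_genes": int(len(x)),
                 "fraction_untargeted": float((x == 0).mean())}
    responses = {"lsr": "log2_lsr_change", "long": "log2_long_change",
                 "short": "log2_short_change"}
    for name, col in responses.items():
        yv = summaries[col].to_numpy(float)
        if np.ptp(yv) == 0.0:  # constant response: correlation undefined
            out[f"r_{name}"] = float("nan")
            out[f"p_{name}"] = float("nan")
            continue
        r, p = stats.pearsonr(xv, yv)
        out[f"r_{name}"] = float(r)
        out[f"p_{name}"] = float(p)
    bins = np.minimum(x, 5).astype(int)
    labels = {0: "0", 1: "1", 2: "2", 3: "3", 4: "4", 5: "5+"}
    med = (summaries.assign(site_bin=bins.map(labels).to_numpy())
           .groupby("site_bin")[list(responses.values())].median()
           .reindex([labels[k] for k in sorted(labels)]).dropna(how="all"))
    out["binned_medians"] = med
    return out


def shortened_enrichment(targeted: pd.Series, shortened: pd.Series) -> dict:
    """Fisher enrichment of shortened genes among up-group aUTR targets.

    Both inputs are boolean Series over the same retained-gene universe.
    Returns the two-sided Fisher p, the sample odds ratio, and the observed
    vs margin-expected count of targeted-and-shortened genes.
    """
    if not targeted.index.equals(shortened.index):
        common = targeted.index.intersection(shortened.index)
        if len(common) == 0:
            raise ValueError("disjoint gene universes")
        logger.info("shortened_enrichment: restricting to %d common genes",
                    len(common))
        targeted, shortened = targeted.loc[common], shortened.loc[common]
    t = targeted.to_numpy(bool)
    s = shortened.to_numpy(bool)
    n = t.size
    a = int((t & s).sum())
    b = int((t & ~s).sum())
    c = int((~t & s).sum())
    d = int((~t & ~s).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("empty margin in the 2x2 enrichment table")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    expected = (a + b) * (a + c) / n
    return {"observed_overlap": a, "expected_overlap": float(expected),
            "odds_ratio": float(odds), "p_value": float(p),
            "table": ((a, b), (c, d)), "n_genes": int(n)}
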