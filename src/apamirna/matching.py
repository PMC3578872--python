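"""Target versus matched non-target contrasts: stratified covariate-matched
sampling, the signed two-sample Kolmogorov-Smirnov statistic, the per-family
scan and the site-dosage test.

For every miRNA seed family the genes carrying at least ``min_autr_sites``
predicted sites of that family in their aUTR form the target set; a
non-target set of the same size is sampled from genes with no aUTR site of
the family, matched on mRNA expression and weighted 3'UTR length so that
the two sets differ (ideally) only in aUTR targeting.  The signed KS D
between the two LSR samples is negative when the target genes' LSR
distribution sits below the non-targets'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchingConfig:
    """Stratified-matching parameters.

    Covariates (log2 total expression, weighted UTR length) are quantile-
    binned into ``n_expr_bins`` x ``n_len_bins`` strata computed over the
    union of targets and pool; draws are without replacement within the
    target's stratum, falling back to the nearest stratum (Manhattan
    distance on bin indices, ties resolved toward lower expression then
    lower length bins) when a stratum is exhausted.
    """

    n_expr_bins: int = 4
    n_len_bins: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_expr_bins < 2 or self.n_len_bins < 2:
            raise ValueError("need at least 2 bins per covariate")


@dataclass(frozen=True)
class ComparisonResult:
    """Signed KS contrast of one family's targets against matched
    non-targets."""

    family_id: str
    d_signed: float
    p_value: float
    n_targets: int
    n_nontargets: int
    min_autr_sites: int
    n_fallback: int = 0


# ---------------------------------------------------------------------------
# signed two-sample KS
# ---------------------------------------------------------------------------

def signed_ks(x, y) -> tuple[float, float]:
    """Signed two-sample Kolmogorov-Smirnov statistic.

    Over the empirical CDFs let ``delta(t) = F_y(t) - F_x(t)``; the returned
    D is delta at the point of maximum |delta|, so D is negative when the
    first sample ``x`` stochastically sits below ``y`` (its CDF dominates).
    |D| equals the classical two-sample KS statistic; when several points
    attain the maximum |delta|, the earliest (smallest t) maximiser decides
    the sign.  The p-value is the standard asymptotic two-sample KS tail
    probability of |D|; it is approximate under heavy ties.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("signed_ks: empty sample")
    pooled = np.concatenate([x, y])
    pooled.sort(kind="mergesort")
    fx = np.searchsorted(x, pooled, side="right") / n
    fy = np.searchsorted(y, pooled, side="right") / m
    delta = fy - fx
    i = int(np.argmax(np.abs(delta)))
    d = float(delta[i])
    en = np.sqrt(n * m / (n + m))
    p = float(stats.kstwobign.sf(en * abs(d)))
    return d, float(np.clip(p, 5e-324, 1.0))


# ---------------------------------------------------------------------------
# target selection and stratified matching
# ---------------------------------------------------------------------------

def autr_site_counts(sites: pd.DataFrame) -> pd.DataFrame:
    """Per (family, gene) count of aUTR sites from a compartment-assigned
    site table."""
    autr = sites[sites["compartment"] == "aUTR"]
    return (autr.groupby(["family_id", "gene_id"], sort=True)
            .size().rename("n_autr_sites").reset_index())


def select_targets(family_id: str, sites: pd.DataFrame,
                   genes: pd.Index | set, min_autr_sites: int = 1) -> pd.Index:
    """Genes among ``genes`` with >= ``min_autr_sites`` aUTR sites of the
    family.  ``sites`` must carry a ``compartment`` column."""
    if min_autr_sites < 1:
        raise ValueError("min_autr_sites must be >= 1")
    if family_id not in set(sites["family_id"]):
        raise KeyError(f"unknown family {family_id!r}")
    fam = sites[(sites["family_id"] == family_id)
                & (sites["compartment"] == "aUTR")]
    counts = fam.groupby("gene_id").size()
    hits = counts[counts >= min_autr_sites].index
    genes = pd.Index(sorted(genes)) if not isinstance(genes, pd.Index) else genes
    return pd.Index(sorted(set(hits) & set(genes)), name="gene_id")


def _quantile_codes(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin codes in [0, n_bins); degenerate edges collapse bins."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


class StratifiedMatcher:
    """Reusable stratified sampler over a fixed target set and pool.

    Built once per (family, criterion); :meth:`draw` then yields independent
    matched non-target samples, one per call, for the single-draw family
    scan and for the repeated null draws of the z-score stage.
    """

    def __init__(self, targets: pd.Index, pool: pd.Index,
                 log2_expr: pd.Series, utr_length: pd.Series,
                 config: MatchingConfig):
        targets = pd.Index(targets)
        pool = pd.Index(pool)
        if len(pool) == 0 or len(targets) == 0:
            raise ValueError("empty pool or target set")
        if len(pool.intersection(targets)) > 0:
            raise ValueError("pool and targets overlap")
        if len(pool) < len(targets):
            raise ValueError(
                f"pool ({len(pool)}) smaller than target set ({len(targets)})")
        self.targets = targets
        self.pool = pool
        self.config = config
        universe = targets.append(pool)
        e = _quantile_codes(log2_expr.loc[universe].to_numpy(float),
                            config.n_expr_bins)
        l = _quantile_codes(utr_length.loc[universe].to_numpy(float),
                            config.n_len_bins)
        self._codes = list(zip(e.tolist(), l.tolist()))
        nt = len(targets)
        self._target_need: dict[tuple[int, int], int] = {}
        for c in self._codes[:nt]:
            self._target_need[c] = self._target_need.get(c, 0) + 1
        self._pool_by_stratum: dict[tuple[int, int], np.ndarray] = {}
        pool_codes = self._codes[nt:]
        order = np.argsort(np.array([c[0] * config.n_len_bins + c[1]
                                     for c in pool_codes]), kind="stable")
        pool_arr = pool.to_numpy()
        for i in order:
            self._pool_by_stratum.setdefault(pool_codes[i], [])
            self._pool_by_stratum[pool_codes[i]].append(pool_arr[i])
        for c, lst in self._pool_by_stratum.items():
            self._pool_by_stratum[c] = np.array(lst, dtype=object)
        self._strata_sorted = sorted(
            set(self._target_need) | set(self._pool_by_stratum))

    def draw(self, rng: np.random.Generator) -> tuple[np.ndarray, int]:
        """One matched non-target sample of the same size as the targets.

        Returns (gene ids, number of nearest-stratum fallback draws).
        """
        chosen: list = []
        remaining: dict[tuple[int, int], list] = {}
        for c in self._strata_sorted:
            pool_c = self._pool_by_stratum.get(c)
            perm = (rng.permutation(pool_c) if pool_c is not None
                    else np.array([], dtype=object))
            need = self._target_need.get(c, 0)
            take = min(need, len(perm))
            chosen.extend(perm[:take])
            remaining[c] = list(perm[take:])
        n_fallback = 0
        for c in self._strata_sorted:
            deficit = self._target_need.get(c, 0) - min(
                self._target_need.get(c, 0),
                len(self._pool_by_stratum.get(c, ())))
            if deficit == 0:
                continue
            # nearest strata by Manhattan distance on bin indices;
            # ties break toward the lower expression bin, then lower length
            candidates = sorted(
                (abs(s[0] - c[0]) + abs(s[1] - c[1]), s[0], s[1])
                for s in remaining if remaining[s])
            for _, e, l in candidates:
                while deficit and remaining[(e, l)]:
                    chosen.append(remaining[(e, l)].pop(0))
                    deficit -= 1
                    n_fallback += 1
                if deficit == 0:
                    break
            if deficit:  # pool >= targets guarantees this never triggers
                raise RuntimeError("stratified draw failed to fill sample")
        if n_fallback:
            logger.debug("matched draw used %d fallback assignment(s)",
                         n_fallback)
        return np.array(chosen, dtype=object), n_fallback


def sample_matched_nontargets(targets: pd.Index, pool: pd.Index,
                              log2_expr: pd.Series, utr_length: pd.Series,
                              config: MatchingConfig) -> pd.Index:
    """Single covariate-matched non-target sample (convenience wrapper)."""
    matcher = StratifiedMatcher(targets, pool, log2_expr, utr_length, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes, _ = matcher.draw(rng)
    return pd.Index(genes, name="gene_id")


# ---------------------------------------------------------------------------
# per-family scan and dosage test
# ---------------------------------------------------------------------------

def family_scan(families: pd.DataFrame, sites: pd.DataFrame,
                summaries: pd.DataFrame, cell_line: str = "b",
                min_autr_sites: int = 1,
                config: MatchingConfig | None = None,
                alpha: float = 0.05) -> pd.DataFrame:
    """Signed-KS target/non-target contrast for every family.

    ``families`` needs a ``family_id`` column; ``sites`` is compartment-
    assigned; ``summaries`` is the per-gene LSR summary restricted to
    retained genes.  The LSR compared, and the matching covariates, are
    taken from ``cell_line`` ('a' or 'b').  Families without aUTR targets
    among retained genes are skipped and logged.  Returns one row per
    scanned family plus a ``significant`` column (p < alpha and D < 0).
    """
    config = config or MatchingConfig()
    genes = summaries.index
    lsr = summaries[f"lsr_{cell_line}"]
    log2_expr = np.log2(summaries[f"total_{cell_line}"].astype(float))
    # match on the full (distal-isoform) UTR length: it is gene-intrinsic,
    # whereas the expression-weighted length is a function of the LSR being
    # compared and would bias the matched sample toward extreme LSR
    utr_len = summaries["utr_length"]
    counts = autr_site_counts(sites)
    counts = counts[counts["gene_id"].isin(genes)]
    by_family = {f: g.set_index("gene_id")["n_autr_sites"]
                 for f, g in counts.groupby("family_id")}
    seed_parent = np.random.SeedSequence(config.seed)
    rows = []
    for family_id in sorted(families["family_id"]):
        child = np.random.SeedSequence(
            entropy=seed_parent.entropy,
            spawn_key=(_stable_key(family_id), min_autr_sites))
        fam_counts = by_family.get(family_id)
        if fam_counts is None or (fam_counts >= min_autr_sites).sum() == 0:
            logger.info("family_scan: %s has no aUTR target among retained "
                        "genes at min %d site(s); skipped", family_id,
                        min_autr_sites)
            continue
        targets = pd.Index(
            sorted(fam_counts.index[fam_counts >= min_autr_sites]))
        pool = pd.Index(sorted(genes.difference(fam_counts.index)))
        if len(pool) < len(targets):
            logger.warning("family_scan: %s pool smaller than target set; "
                           "skipped", family_id)
            continue
        matcher = StratifiedMatcher(targets, pool, log2_expr, utr_len, config)
        nontargets, n_fallback = matcher.draw(np.random.default_rng(child))
        d, p = signed_ks(lsr.loc[targets].to_numpy(),
                         lsr.loc[list(nontargets)].to_numpy())
        rows.append((family_id, d, p, len(targets), len(nontargets),
                     min_autr_sites, n_fallback))
    out = pd.DataFrame(rows, columns=["family_id", "d_signed", "p_value",
                                      "n_targets", "n_nontargets",
                                      "min_autr_sites", "n_fallback"])
    out["significant"] = (out["p_value"] < alpha) & (out["d_signed"] < 0)
    return out


def _stable_key(family_id: str) -> int:
    """Deterministic 32-bit key for seed derivation (hash() is salted)."""
    h = 2166136261
    for byte in family_id.encode():
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h


def scan_summary(scan: pd.DataFrame) -> dict:
    """Headline numbers of a family scan: how many families show
    significantly lower target LSR."""
    n = len(scan)
    n_sig = int(scan["significant"].sum())
    return {"n_families": n, "n_significant_lower": n_sig,
            "fraction_significant_lower": (n_sig / n) if n else float("nan"),
            "median_d_signed": float(scan["d_signed"].median()) if n
            else float("nan")}


def dosage_effect_test(scan1: pd.DataFrame, scan2: pd.DataFrame,
                       restrict_significant: bool = False) -> dict:
    """Paired one-sided Wilcoxon signed-rank test for a site-dosage effect.

    Pairs each family's signed D at the >=1-site criterion with its D at the
    >=2-site criterion; the alternative is that the stricter criterion gives
    lower (more negative) D.  Families lacking a >=2-site target set are
    dropped and logged.  Fewer than 5 pairs is an error (underpowered).
    """
    s1 = scan1.set_index("family_id")["d_signed"]
    if restrict_significant:
        s1 = s1[scan1.set_index("family_id")["significant"]]
    s2 = scan2.set_index("family_id")["d_signed"]
    common = s1.index.intersection(s2.index)
    dropped = len(s1) - len(common)
    if dropped:
        logger.info("dosage_effect_test: %d family(ies) without a stricter-"
                    "criterion set dropped", dropped)
    if len(common) < 5:
        raise ValueError(f"only {len(common)} paired families; need >= 5")
    d1 = s1.loc[common].to_numpy(float)
    d2 = s2.loc[common].to_numpy(float)
    if np.allclose(d1, d2):
        p = 1.0
    else:
        p = float(stats.wilcoxon(d2, d1, alternative="less",
                                 zero_method="zsplit").pvalue)
    return {"p_value": p, "n_pairs": int(len(common)),
            "median_d_min1": float(np.median(d1)),
            "median_d_min2": float(np.median(d2))}
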