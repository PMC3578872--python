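"""Gene filtering, long/short isoform ratios and UTR-shortening metrics.

The long/short ratio (LSR) of a gene in one cell state is the read count of
its long (distal poly(A) site) isoform divided by that of its short
(proximal site) isoform.  Genes are analysed only when reliably quantified
in both cell lines: any zero isoform count, or a per-line total below
``min_total`` (default 15) reads, removes the gene.

The expression-weighted 3'UTR length of a gene averages the cUTR length
(short isoform) and the full UTR length (long isoform), weighted by isoform
reads; the shortened fraction divides the weighted-length loss from cell
line A to B by the weighted length in A.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import ApaGeneRecord

logger = logging.getLogger(__name__)

#: wide per-gene column layout produced by :func:`pair_table`
PAIR_COLUMNS = ["short_a", "long_a", "short_b", "long_b",
                "cutr_length", "autr_length"]


def pair_table(apa: pd.DataFrame, line_a: str = "A",
               line_b: str = "B") -> pd.DataFrame:
    """Pivot the long-format APA table to one row per gene.

    Genes present in only one of the two cell lines are excluded and logged.
    UTR lengths must agree between the lines.
    """
    a = apa[apa["cell_line"] == line_a].set_index("gene_id")
    b = apa[apa["cell_line"] == line_b].set_index("gene_id")
    common = a.index.intersection(b.index)
    lost = len(a.index.union(b.index)) - len(common)
    if lost:
        logger.info("pair_table: %d gene(s) present in only one cell line "
                    "excluded", lost)
    a, b = a.loc[common], b.loc[common]
    if not (a["cutr_length"].equals(b["cutr_length"])
            and a["autr_length"].equals(b["autr_length"])):
        raise ValueError("UTR lengths differ between cell lines")
    return pd.DataFrame({
        "short_a": a["short_reads"], "long_a": a["long_reads"],
        "short_b": b["short_reads"], "long_b": b["long_reads"],
        "cutr_length": a["cutr_length"], "autr_length": a["autr_length"],
    }).sort_index()


def filter_mask(pairs: pd.DataFrame, min_total: int = 15) -> pd.Series:
    """Boolean retention mask: both isoforms expressed and per-line totals
    at least ``min_total`` in each cell line."""
    ok = pd.Series(True, index=pairs.index)
    for s, l in (("short_a", "long_a"), ("short_b", "long_b")):
        ok &= (pairs[s] >= 1) & (pairs[l] >= 1)
        ok &= (pairs[s] + pairs[l]) >= min_total
    return ok


def filter_genes(pairs: pd.DataFrame, min_total: int = 15) -> pd.DataFrame:
    """Apply the zero-isoform / minimum-total filter; returns retained rows."""
    mask = filter_mask(pairs, min_total)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("filter_genes: removed %d of %d genes (zero isoform or "
                    "total < %d)", dropped, len(pairs), min_total)
    return pairs[mask]


# -- per-record scalar operations -------------------------------------------

def compute_lsr(record: ApaGeneRecord) -> float:
    """Long/short isoform ratio; the record must have passed filtering."""
    if record.short_reads == 0:
        raise ValueError(f"{record.gene_id}: zero short reads (unfiltered input)")
    return record.long_reads / record.short_reads


def weighted_utr_length(record: ApaGeneRecord) -> float:
    """Read-weighted mean 3'UTR length of the two isoforms, in nucleotides."""
    total = record.short_reads + record.long_reads
    if total == 0:
        raise ValueError(f"{record.gene_id}: no reads")
    return (record.short_reads * record.cutr_length
            + record.long_reads * (record.cutr_length + record.autr_length)
            ) / total


def shortened_fraction(record_a: ApaGeneRecord,
                       record_b: ApaGeneRecord) -> float:
    """Relative weighted-UTR-length loss from cell line A to B.

    Positive when the gene's UTR is shorter in the cancer-like line B;
    negative for lengthened genes.
    """
    wa = weighted_utr_length(record_a)
    return (wa - weighted_utr_length(record_b)) / wa


def flag_shortened(record_a: ApaGeneRecord, record_b: ApaGeneRecord,
                   alpha: float = 0.05) -> bool:
    """Per-gene shortening call: two-sided Fisher exact test on the 2x2
    isoform-count table, significant at ``alpha`` AND LSR lower in B.

    This is a documented stand-in for externally reported shortened-gene
    lists; a user-supplied flag table always takes precedence over it.
    """
    table = [[record_a.short_reads, record_a.long_reads],
             [record_b.short_reads, record_b.long_reads]]
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return bool(p < alpha and compute_lsr(record_b) < compute_lsr(record_a))


def shortened_gene_fraction(flags) -> int:
    """Percentage of genes flagged shortened, to the nearest integer."""
    flags = np.asarray(list(flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("empty flag set")
    return int(round(100.0 * flags.sum() / flags.size))


# -- vectorised summaries ----------------------------------------------------

def gene_summaries(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene LSR summary for genes that passed filtering.

    Columns: lsr_a, lsr_b, log2_lsr_change, log2_expr_change (total reads
    B over A), weighted_len_a, weighted_len_b, shortened_fraction.
    """
    s_a, l_a = pairs["short_a"].astype(float), pairs["long_a"].astype(float)
    s_b, l_b = pairs["short_b"].astype(float), pairs["long_b"].astype(float)
    if ((s_a == 0) | (s_b == 0) | (l_a == 0) | (l_b == 0)).any():
        raise ValueError("gene_summaries requires filtered input (no zeros)")
    full = pairs["cutr_length"] + pairs["autr_length"]
    w_a = (s_a * pairs["cutr_length"] + l_a * full) / (s_a + l_a)
    w_b = (s_b * pairs["cutr_length"] + l_b * full) / (s_b + l_b)
    lsr_a, lsr_b = l_a / s_a, l_b / s_b
    return pd.DataFrame({
        "lsr_a": lsr_a,
        "lsr_b": lsr_b,
        "total_a": s_a + l_a,
        "total_b": s_b + l_b,
        "log2_lsr_change": np.log2(lsr_b / lsr_a),
        "log2_expr_change": np.log2((s_b + l_b) / (s_a + l_a)),
        "log2_long_change": np.log2(l_b / l_a),
        "log2_short_change": np.log2(s_b / s_a),
        "weighted_len_a": w_a,
        "weighted_len_b": w_b,
        "utr_length": full.astype(float),
        "shortened_fraction": (w_a - w_b) / w_a,
    })


def flag_shortened_table(pairs: pd.DataFrame,
                         alpha: float = 0.05) -> pd.Series:
    """Vectorised :func:`flag_shortened` over a filtered pair table."""
    flags = {}
    for gene_id, row in pairs.iterrows():
        p = stats.fisher_exact([[row["short_a"], row["long_a"]],
                                [row["short_b"], row["long_b"]]])[1]
        lsr_drop = (row["long_b"] / row["short_b"]
                    < row["long_a"] / row["short_a"])
        flags[gene_id] = bool(p < alpha and lsr_drop)
    return pd.Series(flags, name="shortened").rename_axis("gene_id")


def expression_vs_lsr_regression(summaries: pd.DataFrame):
    """OLS of log2 expression change on log2 LSR change.

    Returns (slope, intercept, pearson_r).  A positive slope/correlation
    indicates genes whose isoform ratio drops also tend to drop in total
    expression.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 genes for the regression")
    x = summaries["log2_lsr_change"].to_numpy(float)
    y = summaries["log2_expr_change"].to_numpy(float)
    if math.isclose(float(np.var(x)), 0.0):
        raise ValueError("zero variance in log2 LSR change")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
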