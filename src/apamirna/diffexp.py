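"""Rank-fold-change differential expression of miRNA seed families.

Read-depth differed several-fold between the two cell states in the kind of
small-RNA libraries this pipeline consumes, so families are compared by
expression *rank* rather than by normalised counts: within each cell line
families are ranked ascending by read count (rank 1 = lowest, average ranks
on ties), and the rank-fold-change RFC = rank_B / rank_A.  RFC > 1 means
the family moved up the expression ranking in the cancer-like line.
Families are then split 25/50/25 by RFC into up / mid / down groups.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("up", "mid", "down")


def rank_fold_change(families: pd.DataFrame) -> pd.DataFrame:
    """Per-family expression ranks and rank-fold-change.

    ``families`` must carry family_id, reads_a, reads_b (aggregate family
    counts).  Returns family_id, rank_a, rank_b, rfc sorted by family_id.
    """
    if len(families) < 4:
        raise ValueError("need >= 4 families for rank-fold-change grouping")
    if families["family_id"].duplicated().any():
        raise ValueError("duplicate family_id")
    for col in ("reads_a", "reads_b"):
        if families[col].sum() == 0:
            raise ValueError(f"all-zero miRNA profiles in column {col}")
    out = families[["family_id", "reads_a", "reads_b"]].copy()
    out["rank_a"] = stats.rankdata(out["reads_a"], method="average")
    out["rank_b"] = stats.rankdata(out["reads_b"], method="average")
    out["rfc"] = out["rank_b"] / out["rank_a"]
    return out.sort_values("family_id", ignore_index=True)


def bin_families(changes: pd.DataFrame) -> pd.DataFrame:
    """25/50/25 grouping by rank-fold-change.

    Families are sorted by RFC descending; the top ceil(n/4) are the
    ``up`` group (up-regulated in the cancer-like line), the bottom
    ceil(n/4) the ``down`` group, the remainder ``mid``.  Boundary ties are
    broken deterministically by higher reads_b, then family_id.
    """
    n = len(changes)
    if n < 4:
        raise ValueError("need >= 4 families to form 25/50/25 groups")
    ordered = changes.sort_values(
        by=["rfc", "reads_b", "family_id"],
        ascending=[False, False, True], ignore_index=True)
    quarter = math.ceil(n / 4)
    group = np.full(n, "mid", dtype=object)
    group[:quarter] = "up"
    group[n - quarter:] = "down"
    ordered = ordered.assign(group=group)
    return ordered.sort_values("family_id", ignore_index=True)


def group_members(binned: pd.DataFrame) -> dict[str, list[str]]:
    """Group label -> sorted family ids."""
    return {g: sorted(binned.loc[binned["group"] == g, "family_id"])
            for g in GROUPS}
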