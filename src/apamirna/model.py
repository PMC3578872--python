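"""Model/Results interface tying the analysis stages together.

:class:`ApaMirnaShiftModel` holds the four input tables (per-gene isoform
counts in two cell states, mature-miRNA profiles, the seed-family map and
predicted target sites) and analysis settings; :meth:`ApaMirnaShiftModel.fit`
runs the full analysis sequence and returns an
:class:`ApaMirnaShiftResults` carrying every intermediate table, the
headline statistics and a text ``summary()``.

Analysis sequence (each stage is an independently tested library function):

1. pair genes across cell lines, apply the zero-isoform / minimum-total
   filter, compute per-gene LSR summaries;
2. aggregate mature miRNAs into seed families and drop families with no
   aUTR site on a retained gene;
3. per family, contrast target vs matched non-target LSR (signed KS) at
   the >=1- and >=2-aUTR-site criteria, then test the site-dosage effect
   (paired Wilcoxon);
4. rank-fold-change the families and bin 25/50/25 into up/mid/down groups;
5. per family, z-score the between-state LSR shift of its targets against
   resampled non-target backgrounds; contrast the up vs down groups;
6. score each aUTR target gene's site preference for the aUTR and contrast
   the up vs down groups;
7. correlate up-group aUTR site abundance with LSR / long-isoform /
   short-isoform changes, and test shortened-gene enrichment among
   up-group targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diffexp, io, lsr, matching, shift
from .simulate import SyntheticConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)


class ApaMirnaShiftModel:
    """APA isoform-ratio shift analysis for one pair of cell states.

    Parameters
    ----------
    apa : long-format per-gene isoform table (``io.APA_COLUMNS``).
    mirna : mature-miRNA profiles (``mirna_id reads_a reads_b``).
    family_map : mature miRNA -> seed family.
    sites : predicted target sites (``family_id gene_id utr_offset``).
    shortened : optional reported shortened-gene flags; when given they take
        precedence over the internal per-gene Fisher stand-in.
    min_total : per-cell-line minimum total isoform reads (default 15).
    alpha : significance level used throughout (raw p-values, no
        multiple-testing correction, reported as in the source analyses).
    """

    def __init__(self, apa: pd.DataFrame, mirna: pd.DataFrame,
                 family_map: pd.DataFrame, sites: pd.DataFrame,
                 shortened: pd.Series | None = None,
                 min_total: int = 15, alpha: float = 0.05,
                 line_a: str = "A", line_b: str = "B"):
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.apa = apa
        self.mirna = mirna
        self.family_map = family_map
        self.sites = sites
        self.shortened = shortened
        self.min_total = min_total
        self.alpha = alpha
        self.line_a = line_a
        self.line_b = line_b

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tables(cls, apa_path, mirna_path, family_map_path, sites_path,
                    shortened_path=None, **kwargs) -> "ApaMirnaShiftModel":
        """Build the model from the canonical TSV files."""
        shortened = (io.read_shortened_flags(shortened_path)
                     if shortened_path else None)
        return cls(apa=io.apa_frame(io.read_apa_table(apa_path)),
                   mirna=io.read_mirna_profiles(mirna_path),
                   family_map=io.read_family_map(family_map_path),
                   sites=io.read_sites(sites_path),
                   shortened=shortened, **kwargs)

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig | None = None,
                       dataset: SyntheticDataset | None = None,
                       **kwargs) -> "ApaMirnaShiftModel":
        """Build the model from a generated (or supplied) synthetic dataset."""
        if dataset is None:
            dataset = generate_dataset(config or SyntheticConfig())
        return cls(apa=dataset.apa, mirna=dataset.mirna,
                   family_map=dataset.family_map, sites=dataset.sites,
                   shortened=dataset.shortened, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0, n_resamples: int = 100,
            matching_config: matching.MatchingConfig | None = None,
            min_autr_sites: tuple[int, ...] = (1, 2),
            null_matching: str = "matched",
            scan_cell_line: str = "b",
            min_zscore_targets: int = 5) -> "ApaMirnaShiftResults":
        """Run the full analysis sequence; deterministic given ``seed``."""
        cfg = (replace(matching_config, seed=seed) if matching_config
               else matching.MatchingConfig(seed=seed))

        pairs = lsr.filter_genes(lsr.pair_table(self.apa, self.line_a,
                                                self.line_b), self.min_total)
        summaries = lsr.gene_summaries(pairs)
        regression = lsr.expression_vs_lsr_regression(summaries) \
            if len(summaries) >= 3 else None

        assigned = io.assign_compartments(self.sites, self.apa)
        families_all = io.group_families(self.mirna, self.family_map)
        autr_families = set(
            assigned.loc[(assigned["compartment"] == io.AUTR)
                         & assigned["gene_id"].isin(summaries.index),
                         "family_id"])
        families = families_all[
            families_all["family_id"].isin(autr_families)].reset_index(drop=True)
        n_dropped = len(families_all) - len(families)
        if n_dropped:
            logger.info("fit: %d family(ies) without any aUTR site on a "
                        "retained gene dropped", n_dropped)

        scans = {k: matching.family_scan(
            families, assigned, summaries, cell_line=scan_cell_line,
            min_autr_sites=k, config=cfg, alpha=self.alpha)
            for k in min_autr_sites}
        dosage = dosage_sig = None
        if len(min_autr_sites) >= 2:
            k1, k2 = min_autr_sites[0], min_autr_sites[1]
            try:
                dosage = matching.dosage_effect_test(scans[k1], scans[k2])
            except ValueError as exc:
                logger.warning("dosage test skipped: %s", exc)
            try:
                dosage_sig = matching.dosage_effect_test(
                    scans[k1], scans[k2], restrict_significant=True)
            except ValueError as exc:
                logger.info("significant-only dosage test skipped: %s", exc)

        rfc = diffexp.bin_families(diffexp.rank_fold_change(families)) \
            if len(families) >= 4 else None
        groups = diffexp.group_members(rfc) if rfc is not None else None

        zscores = shift.zscore_scan(
            families, assigned, summaries, n_resamples=n_resamples,
            config=cfg, null_matching=null_matching,
            min_targets=min_zscore_targets)
        group_z = None
        if groups is not None and not zscores.empty:
            z_by_group = {g: zscores.loc[
                zscores["family_id"].isin(groups[g]), "z"].to_numpy()
                for g in diffexp.GROUPS}
            if len(z_by_group["up"]) >= 3 and len(z_by_group["down"]) >= 3:
                group_z = shift.compare_group_zscores(
                    z_by_group["up"], z_by_group["down"], z_by_group["mid"])
            else:
                logger.info("group z contrast skipped: fewer than 3 "
                            "families in a group")

        preference: dict[str, Any] = {"up": None, "down": None, "test": None}
        if groups is not None:
            preference["up"] = shift.gene_preference_scores(
                groups["up"], assigned, pairs)
            preference["down"] = shift.gene_preference_scores(
                groups["down"], assigned, pairs)
            if len(preference["up"]) and len(preference["down"]):
                preference["test"] = shift.group_preference_test(
                    preference["up"]["score"], preference["down"]["score"])

        correlations = None
        enrichment = None
        if groups is not None:
            try:
                correlations = shift.site_abundance_vs_change(
                    groups["up"], assigned, summaries)
            except ValueError as exc:
                logger.warning("site-abundance correlations skipped: %s", exc)
            targeted = shift.up_site_counts(
                groups["up"], assigned, summaries.index) > 0
            if self.shortened is not None:
                flags = self.shortened.reindex(summaries.index,
                                               fill_value=False).astype(bool)
            else:
                flags = lsr.flag_shortened_table(pairs, self.alpha)
            try:
                enrichment = shift.shortened_enrichment(targeted, flags)
            except ValueError as exc:
                logger.warning("enrichment test skipped: %s", exc)

        return ApaMirnaShiftResults(
            model=self, seed=seed, matching_config=cfg,
            pairs=pairs, summaries=summaries, regression=regression,
            sites_assigned=assigned, families=families, scans=scans,
            dosage=dosage, dosage_significant=dosage_sig, rfc=rfc,
            zscores=zscores, group_z=group_z, preference=preference,
            correlations=correlations, enrichment=enrichment)


@dataclass
class ApaMirnaShiftResults:
    """Fitted analysis results; every table the stages produced."""

    model: ApaMirnaShiftModel
    seed: int
    matching_config: matching.MatchingConfig
    pairs: pd.DataFrame
    summaries: pd.DataFrame
    regression: tuple[float, float, float] | None
    sites_assigned: pd.DataFrame
    families: pd.DataFrame
    scans: dict[int, pd.DataFrame]
    dosage: dict | None
    dosage_significant: dict | None
    rfc: pd.DataFrame | None
    zscores: pd.DataFrame
    group_z: dict | None
    preference: dict = field(default_factory=dict)
    correlations: dict | None = None
    enrichment: dict | None = None

    @property
    def groups(self) -> dict[str, list[str]] | None:
        return diffexp.group_members(self.rfc) if self.rfc is not None else None

    def headline(self) -> dict:
        """JSON-serialisable headline statistics of the whole analysis."""
        out: dict[str, Any] = {
            "n_genes_retained": int(len(self.summaries)),
            "n_families": int(len(self.families)),
            "seed": self.seed,
        }
        if self.regression is not None:
            slope, intercept, r = self.regression
            out["expr_vs_lsr"] = {"slope": slope, "intercept": intercept,
                                  "pearson_r": r}
        for k, scan in self.scans.items():
            out[f"scan_min{k}"] = matching.scan_summary(scan)
        if self.dosage is not None:
            out["dosage"] = self.dosage
        if self.dosage_significant is not None:
            out["dosage_significant_only"] = self.dosage_significant
        if not self.zscores.empty:
            z = self.zscores["z"].to_numpy()
            out["zscores"] = {
                "n": int(z.size), "mean": float(z.mean()),
                "sd": float(z.std(ddof=1)) if z.size > 1 else float("nan"),
                "fraction_strong": float((z < -2).mean()),
            }
            if self.groups is not None:
                for g in diffexp.GROUPS:
                    zg = self.zscores.loc[
                        self.zscores["family_id"].isin(self.groups[g]), "z"]
                    if len(zg):
                        out["zscores"][f"median_{g}"] = float(zg.median())
        if self.group_z is not None:
            out["group_z"] = self.group_z
        if self.preference.get("test") is not None:
            out["preference"] = self.preference["test"]
        if self.correlations is not None:
            out["correlations"] = {
                k: v for k, v in self.correlations.items()
                if not isinstance(v, pd.DataFrame)}
        if self.enrichment is not None:
            out["enrichment"] = {k: v for k, v in self.enrichment.items()
                                 if k != "table"}
        return out

    def summary(self) -> str:
        """Human-readable multi-section results table."""
        h = self.headline()
        lines = [
            "APA / miRNA isoform-ratio shift analysis",
            "=" * 56,
            f"retained genes:            {h['n_genes_retained']}",
            f"miRNA families analysed:   {h['n_families']}",
            f"seed:                      {self.seed}",
        ]
        if "expr_vs_lsr" in h:
            e = h["expr_vs_lsr"]
            lines += ["", "Expression change vs LSR change (OLS)",
                      f"  slope={e['slope']:.4f}  intercept="
                      f"{e['intercept']:.4f}  r={e['pearson_r']:.4f}"]
        for k in sorted(self.scans):
            s = h[f"scan_min{k}"]
            lines += ["", f"Target vs matched non-target LSR "
                          f"(>= {k} aUTR site(s))",
                      f"  families scanned: {s['n_families']}; significantly "
                      f"lower: {s['n_significant_lower']} "
                      f"({100 * s['fraction_significant_lower']:.0f}%)",
                      f"  median signed D: {s['median_d_signed']:.4f}"]
        if self.dosage is not None:
            d = self.dosage
            lines += ["", "Site-dosage effect (paired Wilcoxon, D at >=2 "
                          "vs >=1 sites)",
                      f"  n={d['n_pairs']}  median D: "
                      f"{d['median_d_min1']:.4f} -> {d['median_d_min2']:.4f}"
                      f"  one-sided p={d['p_value']:.3g}"]
        if "zscores" in h:
            z = h["zscores"]
            lines += ["", "Between-state LSR-shift z-scores",
                      f"  families: {z['n']}  mean={z['mean']:.3f}  "
                      f"sd={z['sd']:.3f}  fraction z<-2: "
                      f"{100 * z['fraction_strong']:.1f}%"]
            meds = [f"{g}={z[f'median_{g}']:.3f}" for g in diffexp.GROUPS
                    if f"median_{g}" in z]
            if meds:
                lines.append("  group medians: " + "  ".join(meds))
        if self.group_z is not None:
            lines.append(f"  up vs down KS p={self.group_z['p_value']:.3g}")
        if self.preference.get("test") is not None:
            p = self.preference["test"]
            lines += ["", "aUTR target-site preference (up vs down group)",
                      f"  medians: up={p['median_up']:.3f} "
                      f"down={p['median_down']:.3f}  KS p={p['p_value']:.3g}"]
        if self.correlations is not None:
            c = self.correlations
            lines += ["", "Up-group aUTR site abundance vs change (Pearson)",
                      f"  LSR:   r={c['r_lsr']:+.3f} (p={c['p_lsr']:.3g})",
                      f"  long:  r={c['r_long']:+.3f} (p={c['p_long']:.3g})",
                      f"  short: r={c['r_short']:+.3f} (p={c['p_short']:.3g})",
                      f"  untargeted genes: "
                      f"{100 * c['fraction_untargeted']:.0f}%"]
        if self.enrichment is not None:
            e = self.enrichment
            lines += ["", "Shortened-gene enrichment among up-group targets",
                      f"  observed {e['observed_overlap']} vs expected "
                      f"{e['expected_overlap']:.1f}  OR={e['odds_ratio']:.2f}"
                      f"  Fisher p={e['p_value']:.3g}"]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every intermediate table (TSV) and the headline JSON."""
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def save(name: str, df: pd.DataFrame, index: bool) -> None:
            paths[name] = out_dir / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=index)

        save("gene_summaries", self.summaries.round(6), True)
        save("sites_assigned", self.sites_assigned, False)
        save("families", self.families, False)
        for k, scan in self.scans.items():
            save(f"family_scan_min{k}", scan.round(6), False)
        if self.rfc is not None:
            save("family_groups", self.rfc.round(6), False)
        if not self.zscores.empty:
            save("zscores", self.zscores.round(6), False)
        for g in ("up", "down"):
            df = self.preference.get(g)
            if df is not None and len(df):
                save(f"preference_{g}", df.round(6), True)
        paths["summary_json"] = out_dir / "summary.json"
        with open(paths["summary_json"], "w") as fh:
            json.dump(_jsonable(self.headline()), fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        paths["summary_txt"] = out_dir / "summary.txt"
        paths["summary_txt"].write_text(self.summary() + "\n")
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
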