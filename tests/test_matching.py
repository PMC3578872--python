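"""Signed KS statistic, stratified matching, family scan and dosage test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apamirna import lsr
from apamirna.io import assign_compartments, group_families
from apamirna.matching import (ComparisonResult, MatchingConfig,
                               StratifiedMatcher, dosage_effect_test,
                               family_scan, sample_matched_nontargets,
                               select_targets, signed_ks)


def brute_force_signed_ks(x, y):
    """Independent oracle: scan every pooled point (in ascending order) for
    the maximum CDF gap; the first maximiser wins, matching the documented
    tie convention."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for t in np.sort(np.concatenate([x, y])):
        delta = np.mean(y <= t) - np.mean(x <= t)
        if abs(delta) > abs(best) + 1e-15:
            best = delta
    return best


def kolmogorov_series_p(d, n, m):
    lam = np.sqrt(n * m / (n + m)) * abs(d)
    if lam == 0:
        return 1.0
    k = np.arange(1, 200)
    return float(np.clip(2 * np.sum((-1.0) ** (k - 1)
                                    * np.exp(-2 * k ** 2 * lam ** 2)), 0, 1))


class TestSignedKS:
    def test_identical_samples(self):
        d, p = signed_ks([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert d == 0.0
        assert p == 1.0

    def test_complete_separation_negative(self):
        d, _ = signed_ks([1, 2, 3], [10, 11, 12])
        assert d == -1.0

    def test_complete_separation_positive(self):
        d, _ = signed_ks([10, 11, 12], [1, 2, 3])
        assert d == 1.0

    def test_cdf_gap_example(self):
        # 80% of x but only 30% of y lie below a common threshold
        x = [0.5] * 8 + [2.0] * 2
        y = [0.5] * 3 + [2.0] * 7
        d, _ = signed_ks(x, y)
        assert d == pytest.approx(-0.5)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            signed_ks([], [1.0])

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n, m = rng.integers(1, 21, size=2)
            x = np.round(rng.normal(0, 1, n), 2)  # rounding induces ties
            y = np.round(rng.normal(0.4, 1.3, m), 2)
            d, p = signed_ks(x, y)
            oracle_d = brute_force_signed_ks(x, y)
            assert d == pytest.approx(oracle_d)
            assert p == pytest.approx(kolmogorov_series_p(d, n, m), abs=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=1, max_size=30),
           st.lists(st.integers(-50, 50), min_size=1, max_size=30))
    def test_antisymmetry(self, x, y):
        assert signed_ks(x, y)[0] == pytest.approx(-signed_ks(y, x)[0])

    def test_statistic_magnitude_matches_scipy(self):
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 25)
        d, _ = signed_ks(x, y)
        assert abs(d) == pytest.approx(ks_2samp(x, y).statistic)


@pytest.fixture()
def assigned_small(small_ds):
    return assign_compartments(small_ds.sites, small_ds.apa)


class TestSelectTargets:
    def test_dosage_criterion(self, assigned_small, small_ds):
        genes = lsr.filter_genes(lsr.pair_table(small_ds.apa)).index
        at_least_1 = select_targets("FAM1", assigned_small, genes, 1)
        at_least_2 = select_targets("FAM1", assigned_small, genes, 2)
        assert "G04" in at_least_1 and "G04" in at_least_2
        assert "G06" in at_least_1 and "G06" not in at_least_2
        # G05 has only a cUTR site of FAM1
        assert "G05" not in at_least_1

    def test_unknown_family_is_error(self, assigned_small):
        with pytest.raises(KeyError):
            select_targets("FAM9", assigned_small, {"G04"})

    def test_empty_site_table(self, assigned_small):
        empty = assigned_small.iloc[0:0]
        empty = empty.assign(family_id=pd.Series(dtype=str))
        with pytest.raises(KeyError):
            select_targets("FAM1", empty, {"G04"})


def covariate_series(n, rng, index=None):
    idx = index if index is not None else [f"g{i}" for i in range(n)]
    return (pd.Series(rng.normal(8, 2, n), index=idx),
            pd.Series(rng.uniform(500, 5000, n), index=idx))


class TestStratifiedMatching:
    def test_mirror_pool_draws_from_correct_strata(self):
        rng = np.random.default_rng(0)
        targets = pd.Index([f"t{i}" for i in range(40)])
        pool = pd.Index([f"p{i}" for i in range(40)])
        expr_t, len_t = covariate_series(40, np.random.default_rng(3),
                                         targets)
        # pool covariates are an exact copy of the targets'
        expr = pd.concat([expr_t, expr_t.set_axis(pool)])
        length = pd.concat([len_t, len_t.set_axis(pool)])
        matcher = StratifiedMatcher(targets, pool, expr, length,
                                    MatchingConfig(seed=0))
        sample, n_fallback = matcher.draw(rng)
        assert n_fallback == 0
        assert len(sample) == 40 and set(sample) <= set(pool)

    def test_same_seed_same_sample(self):
        rng_cov = np.random.default_rng(9)
        targets = pd.Index([f"t{i}" for i in range(25)])
        pool = pd.Index([f"p{i}" for i in range(80)])
        expr, length = covariate_series(105, rng_cov,
                                        targets.append(pool))
        cfg = MatchingConfig(seed=11)
        s1 = sample_matched_nontargets(targets, pool, expr, length, cfg)
        s2 = sample_matched_nontargets(targets, pool, expr, length, cfg)
        assert list(s1) == list(s2)

    def test_pool_smaller_than_targets_is_error(self):
        targets = pd.Index(["t0", "t1", "t2"])
        pool = pd.Index(["p0", "p1"])
        expr, length = covariate_series(5, np.random.default_rng(0),
                                        targets.append(pool))
        with pytest.raises(ValueError, match="smaller"):
            StratifiedMatcher(targets, pool, expr, length, MatchingConfig())

    def test_overlapping_pool_is_error(self):
        targets = pd.Index(["t0", "t1"])
        pool = pd.Index(["t1", "p0", "p1"])
        expr, length = covariate_series(
            5, np.random.default_rng(0), pd.Index(
                ["t0", "t1", "p0", "p1", "x"]))
        with pytest.raises(ValueError, match="overlap"):
            StratifiedMatcher(targets, pool, expr, length, MatchingConfig())

    def test_sample_stratum_frequencies_track_targets(self):
        """Repeated draws reproduce the targets' stratum profile exactly
        whenever the pool can supply it (the sampler is constrained, not
        merely unbiased)."""
        rng = np.random.default_rng(5)
        targets = pd.Index([f"t{i}" for i in range(30)])
        pool = pd.Index([f"p{i}" for i in range(300)])
        expr, length = covariate_series(330, rng, targets.append(pool))
        cfg = MatchingConfig(seed=2)
        matcher = StratifiedMatcher(targets, pool, expr, length, cfg)
        draw_rng = np.random.default_rng(2)
        strata = dict(zip(targets.append(pool), matcher._codes))
        want = pd.Series([strata[t] for t in targets]).value_counts()
        for _ in range(50):
            sample, n_fallback = matcher.draw(draw_rng)
            got = pd.Series([strata[g] for g in sample]).value_counts()
            if n_fallback == 0:
                pd.testing.assert_series_equal(
                    got.sort_index(), want.sort_index(), check_names=False)

    def test_matching_reduces_expression_confounding(self, medium_null_ds):
        """Matched non-targets sit closer to the targets in expression than
        a uniform random sample, on synthetic data."""
        ds = medium_null_ds
        pairs = lsr.filter_genes(lsr.pair_table(ds.apa))
        summ = lsr.gene_summaries(pairs)
        assigned = assign_compartments(ds.sites, ds.apa)
        autr = assigned[(assigned.compartment == "aUTR")
                        & assigned.gene_id.isin(summ.index)]
        counts = autr.groupby("gene_id").size()
        # synthetic targets biased toward high expression: top expression
        # tertile of genes with a site
        expr = np.log2(summ["total_b"].astype(float))
        targets = pd.Index(sorted(
            counts.index[expr[counts.index]
                         > expr[counts.index].quantile(0.66)]))
        pool = summ.index.difference(counts.index)
        cfg = MatchingConfig(seed=3)
        matched = sample_matched_nontargets(
            targets, pool, expr, summ["utr_length"], cfg)
        uniform = np.random.default_rng(3).choice(
            pool.to_numpy(), size=len(targets), replace=False)
        gap_matched = abs(expr[matched].mean() - expr[targets].mean())
        gap_uniform = abs(expr[uniform].mean() - expr[targets].mean())
        assert gap_matched < gap_uniform


class TestFamilyScan:
    def test_single_family_equals_direct_signed_ks(self):
        """With one stratum and a pool of exactly the target-set size, the
        matched draw is the whole pool and the scan reduces to one
        signed_ks call."""
        genes = [f"g{i}" for i in range(12)]
        lsr_b = np.array([0.2, 0.3, 0.4, 0.5, 0.6, 0.7,
                          1.2, 1.3, 1.4, 1.5, 1.6, 1.7])
        summ = pd.DataFrame({
            "lsr_a": np.ones(12), "lsr_b": lsr_b,
            "total_a": np.full(12, 100.0), "total_b": np.full(12, 100.0),
            "weighted_len_a": np.full(12, 1000.0),
            "weighted_len_b": np.full(12, 1000.0),
            "utr_length": np.full(12, 2000.0),
        }, index=pd.Index(genes, name="gene_id"))
        sites = pd.DataFrame({
            "family_id": ["F1"] * 6,
            "gene_id": genes[:6],
            "compartment": ["aUTR"] * 6,
            "utr_offset": [1500] * 6})
        families = pd.DataFrame({"family_id": ["F1"]})
        scan = family_scan(families, sites, summ, min_autr_sites=1,
                           config=MatchingConfig(seed=0))
        d, p = signed_ks(lsr_b[:6], lsr_b[6:])
        assert scan.loc[0, "d_signed"] == pytest.approx(d)
        assert scan.loc[0, "p_value"] == pytest.approx(p)
        assert scan.loc[0, "d_signed"] == -1.0  # targets all below

    def test_scan_on_fixture_is_deterministic(self, small_ds,
                                              assigned_small):
        pairs = lsr.filter_genes(lsr.pair_table(small_ds.apa))
        summ = lsr.gene_summaries(pairs)
        fams = group_families(small_ds.mirna, small_ds.family_map)
        runs = [family_scan(fams, assigned_small, summ,
                            config=MatchingConfig(seed=4))
                for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_result_type_contract(self):
        r = ComparisonResult("F1", -0.4, 0.01, 30, 30, 1)
        assert -1 <= r.d_signed <= 1 and r.n_targets == r.n_nontargets


class TestDosage:
    def scan_frame(self, fam_ids, d, min_sites):
        return pd.DataFrame({
            "family_id": fam_ids, "d_signed": d,
            "p_value": 0.01, "n_targets": 30, "n_nontargets": 30,
            "min_autr_sites": min_sites, "n_fallback": 0,
            "significant": [x < 0 for x in d]})

    def test_uniform_shift_detected(self):
        fams = [f"F{i}" for i in range(8)]
        d1 = [-0.1, -0.2, -0.15, -0.3, -0.25, -0.1, -0.2, -0.35]
        d2 = [x - 0.1 for x in d1]
        out = dosage_effect_test(self.scan_frame(fams, d1, 1),
                                 self.scan_frame(fams, d2, 2))
        assert out["p_value"] < 0.05
        assert out["median_d_min2"] < out["median_d_min1"]

    def test_no_change_gives_p_one(self):
        fams = [f"F{i}" for i in range(6)]
        d = [-0.1, -0.2, -0.3, -0.15, -0.25, -0.05]
        out = dosage_effect_test(self.scan_frame(fams, d, 1),
                                 self.scan_frame(fams, d, 2))
        assert out["p_value"] == 1.0

    def test_alternating_differences_not_significant(self):
        fams = [f"F{i}" for i in range(8)]
        d1 = [-0.2] * 8
        d2 = [-0.2 + s for s in (0.1, -0.1) * 4]
        out = dosage_effect_test(self.scan_frame(fams, d1, 1),
                                 self.scan_frame(fams, d2, 2))
        # balanced +/- differences carry no dosage evidence
        assert out["p_value"] > 0.1
        assert out["median_d_min2"] == out["median_d_min1"]

    def test_too_few_pairs_is_error(self):
        fams = ["F0", "F1", "F2", "F3"]
        with pytest.raises(ValueError, match=">= 5"):
            dosage_effect_test(self.scan_frame(fams, [-0.1] * 4, 1),
                               self.scan_frame(fams, [-0.2] * 4, 2))

    def test_unpaired_families_dropped(self):
        f1 = self.scan_frame([f"F{i}" for i in range(8)], [-0.2] * 8, 1)
        f2 = self.scan_frame([f"F{i}" for i in range(6)], [-0.3] * 6, 2)
        assert dosage_effect_test(f1, f2)["n_pairs"] == 6
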