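"""Tests for the Hudson F_ST scan and arm-block permutation calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import adaptscan as a
from adaptscan.fst import _weir_cockerham_site


def hand_hudson(ac1, an1, ac2, an2):
    p1, p2 = ac1 / an1, ac2 / an2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (an1 - 1) - p2 * (1 - p2) / (an2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


class TestSiteFst:
    def test_identical_counts_near_zero(self):
        # equal sample frequencies: only the finite-sample correction
        # remains, so the estimate is within sampling-noise of zero
        fst = a.site_fst([10], [20], [10], [20])
        assert abs(fst[0]) <= 2 / 19

    def test_fixation_is_one(self):
        assert a.site_fst([20], [20], [0], [20])[0] == pytest.approx(1.0)

    def test_matches_hand_computed_hudson(self):
        fst = a.site_fst([14], [20], [4], [20])
        assert fst[0] == pytest.approx(hand_hudson(14, 20, 4, 20), abs=1e-12)

    def test_min_allele_filter(self):
        fst = a.site_fst([5], [9], [2], [20], min_alleles=10)
        assert np.isnan(fst[0])

    def test_monomorphic_site_undefined(self):
        assert np.isnan(a.site_fst([0], [20], [0], [20])[0])
        assert np.isnan(a.site_fst([20], [20], [20], [20])[0])

    def test_weir_cockerham_agrees_at_strong_differentiation(self):
        # the alternative estimator is close to Hudson for balanced deep samples
        h = a.site_fst([90], [100], [10], [100])
        w = a.site_fst([90], [100], [10], [100], estimator="weir_cockerham")
        assert w[0] == pytest.approx(h[0], abs=0.02)


class TestWindows:
    def _gm(self, n_sites, seed=0, fst=0.0, n_hap=40):
        params = a.PopGenSimParams(n_sites=n_sites, baseline_fst=fst,
                                   n_haplotypes_per_pop=n_hap)
        gm, _, _ = a.simulate_genotypes(params, seed)
        return gm

    def test_window_count_arithmetic(self):
        gm = self._gm(3000, seed=1, fst=0.02)
        mask = a.fst.nonsingleton_variable_mask(gm, "cold")
        wins = a.partition_windows(gm, "cold", "cold", "warm",
                                   sites_per_window=250)
        assert len(wins) == int(mask.sum()) // 250

    def test_too_few_sites_zero_windows(self):
        gm = self._gm(249, seed=2, fst=0.02)
        wins = a.partition_windows(gm, "cold", "cold", "warm",
                                   sites_per_window=250)
        assert len(wins) == 0

    def test_single_site_window_equals_site_fst(self):
        gm = self._gm(400, seed=3, fst=0.1)
        wins = a.partition_windows(gm, "cold", "cold", "warm", sites_per_window=1)
        site = a.site_fst(gm.alt_counts["cold"], gm.totals["cold"],
                          gm.alt_counts["warm"], gm.totals["warm"],
                          min_alleles=5)
        pos = gm.sites["pos"].to_numpy()
        for _, w in wins.head(50).iterrows():
            i = int(np.flatnonzero(pos == w["start"])[0])
            if np.isnan(site[i]):
                assert np.isnan(w["fst"])
            else:
                assert w["fst"] == pytest.approx(site[i], abs=1e-12)

    def test_window_fst_recovers_generative_parameter(self):
        gm = self._gm(10_000, seed=4, fst=0.05, n_hap=60)
        wins = a.partition_windows(gm, "cold", "cold", "warm")
        assert wins["fst"].mean() == pytest.approx(0.05, abs=0.01)

    def test_missing_reference_errors(self):
        gm = self._gm(300, seed=5)
        with pytest.raises(ValueError):
            a.partition_windows(gm, "ZI", "cold", "warm")


class TestBaldingNichols:
    def test_zero_fst_baseline(self):
        params = a.PopGenSimParams(n_sites=5000, baseline_fst=0.0,
                                   n_haplotypes_per_pop=100)
        gm, _, _ = a.simulate_genotypes(params, 6)
        num, den = a.hudson_components(gm.alt_counts["cold"], gm.totals["cold"],
                                       gm.alt_counts["warm"], gm.totals["warm"])
        genome = np.nansum(num) / np.nansum(den)
        assert genome == pytest.approx(0.0, abs=0.01)

    def test_estimator_consistency_grows_with_sample_size(self):
        errs = []
        for n_hap in (20, 200):
            params = a.PopGenSimParams(n_sites=8000, baseline_fst=0.08,
                                       n_haplotypes_per_pop=n_hap)
            gm, _, _ = a.simulate_genotypes(params, 7)
            num, den = a.hudson_components(
                gm.alt_counts["cold"], gm.totals["cold"],
                gm.alt_counts["warm"], gm.totals["warm"])
            errs.append(abs(np.nansum(num) / np.nansum(den) - 0.08))
        assert errs[1] <= errs[0] + 0.005
        assert errs[1] < 0.01

    def test_planted_outliers_rank_top_percent(self):
        params = a.PopGenSimParams(n_sites=5000, baseline_fst=0.02,
                                   n_outlier_loci=10, outlier_delta_p=0.8,
                                   n_haplotypes_per_pop=60)
        gm, _, truth = a.simulate_genotypes(params, 8)
        fst = a.site_fst(gm.alt_counts["cold"], gm.totals["cold"],
                         gm.alt_counts["warm"], gm.totals["warm"])
        cutoff = np.nanquantile(fst, 0.99)
        assert (fst[truth["is_outlier"].to_numpy()] >= cutoff).all()

    def test_truth_aligns_with_sites(self):
        params = a.PopGenSimParams(n_sites=100)
        gm, haps, truth = a.simulate_genotypes(params, 9)
        assert (truth["pos"].to_numpy() == gm.sites["pos"].to_numpy()).all()
        assert haps.shape == (100, 2 * params.n_haplotypes_per_pop)


class TestGeneMaxima:
    def _setup(self, seed=10, n_sites=4000, **kw):
        params = a.PopGenSimParams(n_sites=n_sites, baseline_fst=0.03,
                                   n_haplotypes_per_pop=40, **kw)
        gm, _, truth = a.simulate_genotypes(params, seed)
        wins = a.partition_windows(gm, "cold", "cold", "warm",
                                   sites_per_window=100)
        site = a.site_fst(gm.alt_counts["cold"], gm.totals["cold"],
                          gm.alt_counts["warm"], gm.totals["warm"])
        return gm, wins, site, truth

    def test_global_max_window_in_focal_region(self):
        gm, wins, site, _ = self._setup()
        best = wins.loc[wins["fst"].idxmax()]
        gene = pd.Series({"gene_id": "g1", "chrom_arm": best["chrom_arm"],
                          "start": best["start"] + 10, "end": best["start"] + 500,
                          "strand": "+"})
        res = a.gene_fst_maxima(gene, wins, gm.sites["pos"].to_numpy(), site)
        assert res["fst_winmax"] == pytest.approx(max(best["fst"], 0.0))

    def test_flank_boundary_is_closed(self):
        # a SNP exactly 2000 bp beyond the last gene base is included
        pos = np.array([1000, 5000])
        fst = np.array([0.1, 0.9])
        gene = pd.Series({"gene_id": "g1", "chrom_arm": "2L",
                          "start": 900, "end": 3001, "strand": "+"})
        wins = pd.DataFrame(columns=["chrom_arm", "start", "end", "n_sites", "fst"])
        res = a.gene_fst_maxima(gene, wins, pos, fst, flank=2000)
        assert res["fst_snpmax"] == pytest.approx(0.9)  # snp at 3000+2000
        res2 = a.gene_fst_maxima(gene, wins, np.array([1000, 5001]), fst,
                                 flank=2000)
        assert res2["fst_snpmax"] == pytest.approx(0.1)  # 5001 just outside


class TestArmBlockPermutation:
    def test_most_extreme_focal_gets_minimal_quantile(self):
        gm, wins, site, _ = TestGeneMaxima()._setup(seed=11, n_sites=6000)
        best = wins.loc[wins["fst"].idxmax()]
        gene = pd.Series({"gene_id": "g1", "chrom_arm": best["chrom_arm"],
                          "start": best["start"] + 10, "end": best["start"] + 400,
                          "strand": "+"})
        summ = a.gene_fst_maxima(gene, wins, gm.sites["pos"].to_numpy(), site)
        res = a.arm_block_permutation(summ, wins, gm.sites["pos"].to_numpy(),
                                      site, a.AnalysisConfig().arm_intervals["2L"],
                                      min_blocks=10)
        assert res["win_quantile"] <= 0.1
        assert res["win_outlier"]

    def test_null_outlier_rate_calibrated(self):
        gm, wins, site, _ = TestGeneMaxima()._setup(seed=12, n_sites=8000)
        rng = np.random.default_rng(0)
        pos = gm.sites["pos"].to_numpy()
        lo, hi = a.AnalysisConfig().arm_intervals["2L"]
        flags = []
        for _ in range(60):
            start = int(rng.integers(lo + 5000, hi - 10_000))
            gene = pd.Series({"gene_id": "g", "chrom_arm": "2L",
                              "start": start, "end": start + 2000, "strand": "+"})
            summ = a.gene_fst_maxima(gene, wins, pos, site)
            res = a.arm_block_permutation(summ, wins, pos, site, (lo, hi),
                                          min_blocks=10)
            if np.isfinite(res["win_quantile"]):
                flags.append(res["win_outlier"])
        # ~5% of random genes should be called (inclusive ranking makes
        # the test slightly conservative)
        assert np.mean(flags) <= 0.15

    def test_planted_high_fst_gene_called(self):
        """A gene whose focal region holds 10 planted high-differentiation
        loci is called a SNP outlier in >= 9/10 seeds."""
        hits = 0
        lo, hi = a.AnalysisConfig().arm_intervals["2L"]
        for seed in range(10):
            params = a.PopGenSimParams(n_sites=4000, baseline_fst=0.02,
                                       n_haplotypes_per_pop=40)
            gm, _, _ = a.simulate_genotypes(params, 200 + seed)
            # plant 10 consecutive extreme loci and span the gene over them
            pos = gm.sites["pos"].to_numpy()
            centre = (lo + hi) // 2
            first = int(np.searchsorted(pos, centre))
            inside = np.arange(first, first + 10)
            gm.alt_counts.loc[inside, "cold"] = 38
            gm.alt_counts.loc[inside, "warm"] = 2
            gene = pd.Series({"gene_id": "g", "chrom_arm": "2L",
                              "start": int(pos[inside[0]]),
                              "end": int(pos[inside[-1]]) + 1,
                              "strand": "+"})
            wins = a.partition_windows(gm, "cold", "cold", "warm",
                                       sites_per_window=100)
            site = a.site_fst(gm.alt_counts["cold"], gm.totals["cold"],
                              gm.alt_counts["warm"], gm.totals["warm"])
            summ = a.gene_fst_maxima(gene, wins, pos, site)
            res = a.arm_block_permutation(summ, wins, pos, site, (lo, hi),
                                          min_blocks=10)
            hits += bool(res["snp_outlier"])
        assert hits >= 9

    def test_focal_outside_mask_flagged(self):
        gm, wins, site, _ = TestGeneMaxima()._setup(seed=13)
        gene = pd.Series({"gene_id": "g1", "chrom_arm": "2L",
                          "start": 100, "end": 600, "strand": "+"})  # below mask
        summ = a.gene_fst_maxima(gene, wins, gm.sites["pos"].to_numpy(), site)
        res = a.arm_block_permutation(summ, wins, gm.sites["pos"].to_numpy(),
                                      site, a.AnalysisConfig().arm_intervals["2L"])
        assert res["flag"] == "focal_outside_mask"
        assert not res["win_outlier"] and not res["snp_outlier"]

    def test_quantiles_invariant_to_position_shift(self):
        gm, wins, site, _ = TestGeneMaxima()._setup(seed=14, n_sites=5000)
        pos = gm.sites["pos"].to_numpy()
        lo, hi = a.AnalysisConfig().arm_intervals["2L"]
        start = int(pos[len(pos) // 2])
        gene = pd.Series({"gene_id": "g", "chrom_arm": "2L",
                          "start": start, "end": start + 1000, "strand": "+"})
        summ = a.gene_fst_maxima(gene, wins, pos, site)
        base = a.arm_block_permutation(summ, wins, pos, site, (lo, hi),
                                       min_blocks=10)
        shift = 1000
        wins2 = wins.assign(start=wins["start"] + shift, end=wins["end"] + shift)
        gene2 = gene.copy()
        gene2["start"] += shift
        gene2["end"] += shift
        summ2 = a.gene_fst_maxima(gene2, wins2, pos + shift, site)
        res2 = a.arm_block_permutation(summ2, wins2, pos + shift, site,
                                       (lo, hi + shift), min_blocks=10)
        assert res2["win_quantile"] == pytest.approx(base["win_quantile"])
        assert res2["snp_quantile"] == pytest.approx(base["snp_quantile"])


class TestCisFstEnrichment:
    def test_identical_rates_null(self):
        genes = [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(1)
        fstf = pd.Series(rng.random(200) < 0.3, index=genes)
        cis = pd.Series([True] * 100 + [False] * 100, index=genes)
        res = a.cis_fst_enrichment({"MED": cis}, {"MED": fstf})
        assert res["per_pair"]["MED"]["p_value"] > 0.2

    def test_matches_hypergeometric_enumeration(self):
        # 2x2: cis genes 8/28 fst-outlying vs non-cis 100/1100
        genes = [f"g{i}" for i in range(1128)]
        cis = pd.Series([True] * 28 + [False] * 1100, index=genes)
        fstf = pd.Series([True] * 8 + [False] * 20 + [True] * 100 + [False] * 1000,
                         index=genes)
        res = a.cis_fst_enrichment({"MED": cis}, {"MED": fstf})
        M, n, N = 1128, 108, 28
        obs_p = hypergeom.pmf(8, M, n, N)
        p_exact = sum(hypergeom.pmf(k, M, n, N)
                      for k in range(0, min(n, N) + 1)
                      if hypergeom.pmf(k, M, n, N) <= obs_p + 1e-12)
        assert res["per_pair"]["MED"]["p_value"] == pytest.approx(p_exact, rel=1e-9)

    def test_pooled_lrt_detects_planted_association(self):
        """When F_ST outliers coincide with cis genes in every pair, the
        pooled type+pair LRT flags the association in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            cis_flags, fst_flags = {}, {}
            for pair in ("MED", "ETH", "SAF"):
                genes = [f"g{i}" for i in range(300)]
                cis = pd.Series(rng.random(300) < 0.2, index=genes)
                base = rng.random(300) < 0.05
                fstf = pd.Series(np.where(cis, rng.random(300) < 0.4, base),
                                 index=genes)
                cis_flags[pair] = cis
                fst_flags[pair] = fstf
            res = a.cis_fst_enrichment(cis_flags, fst_flags)
            hits += res["pooled_lrt"]["p_value"] < 0.01
        assert hits >= 9
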