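"""Window and SNP F_ST scans around candidate genes.

The estimator is Hudson's, computed from sample allele frequencies with
the standard finite-sample correction (robust to unequal sample sizes):

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

Site F_ST is num/den; window F_ST is the ratio of sums of num and den
over the window's sites.  Windows hold a fixed number of non-singleton
variable sites of a designated reference population.  A gene's focal
region is its span plus a flank on each side; the highest overlapping
window F_ST (F_ST_winmax) and the highest SNP F_ST inside the region
(F_ST_SNPmax) are ranked against all same-size blocks along the
high-recombination portion of the same arm to call outliers.

A Weir-Cockerham site estimator is available behind a flag for
cross-checking; Hudson is the default throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datatypes import GenotypeMatrix

logger = logging.getLogger("adaptscan")


# ---------------------------------------------------------------------------
# estimators

def hudson_components(ac1, an1, ac2, an2):
    """Per-site Hudson numerator and denominator (NaN where undefined).

    Sites with fewer than two sampled alleles in either population, or
    monomorphic across both populations, are undefined.
    """
    ac1, an1, ac2, an2 = (np.asarray(a, dtype=float) for a in (ac1, an1, ac2, an2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = ac1 / an1, ac2 / an2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (an1 - 1)
               - p2 * (1 - p2) / (an2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (an1 < 2) | (an2 < 2) | (den == 0)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def site_fst(ac1, an1, ac2, an2, min_alleles: int = 10,
             estimator: str = "hudson"):
    """Per-site F_ST between two populations from allele counts.

    Sites with fewer than ``min_alleles`` sampled alleles in either
    population, or monomorphic across both, are NaN (skipped downstream).
    """
    ac1, an1, ac2, an2 = (np.asarray(a, dtype=float) for a in (ac1, an1, ac2, an2))
    if estimator == "hudson":
        num, den = hudson_components(ac1, an1, ac2, an2)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = num / den
    elif estimator == "weir_cockerham":
        fst = _weir_cockerham_site(ac1, an1, ac2, an2)
    else:
        raise ValueError(f"unknown estimator {estimator}")
    thin = (an1 < min_alleles) | (an2 < min_alleles)
    return np.where(thin, np.nan, fst)


def _weir_cockerham_site(ac1, an1, ac2, an2):
    """Weir & Cockerham (1984) theta for two populations of haploids."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = ac1 / an1, ac2 / an2
        r = 2.0
        n_bar = (an1 + an2) / r
        nc = (an1 + an2 - (an1 ** 2 + an2 ** 2) / (an1 + an2)) / (r - 1)
        p_bar = (an1 * p1 + an2 * p2) / (an1 + an2)
        s2 = (an1 * (p1 - p_bar) ** 2 + an2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
        denom = a + b
        return np.where(denom == 0, np.nan, a / denom)


# ---------------------------------------------------------------------------
# windows

def nonsingleton_variable_mask(gm: GenotypeMatrix, reference_pop: str) -> np.ndarray:
    """Sites variable in the reference population with minor allele count >= 2."""
    ac = gm.alt_counts[reference_pop].to_numpy(float)
    an = gm.totals[reference_pop].to_numpy(float)
    mac = np.minimum(ac, an - ac)
    return mac >= 2


def partition_windows(gm: GenotypeMatrix, reference_pop: str,
                      pop1: str, pop2: str,
                      sites_per_window: int = 250,
                      min_genotypes: int = 5) -> pd.DataFrame:
    """Fixed-site-count windows with ratio-of-sums Hudson F_ST.

    Consecutive windows each contain exactly ``sites_per_window``
    non-singleton variable sites of the reference population (per arm; the
    trailing partial window is dropped).  The window F_ST between
    ``pop1`` and ``pop2`` sums Hudson numerators and denominators over the
    window's sites that have at least ``min_genotypes`` called haplotypes
    in each population.  Returns one row per window with arm, start/end
    positions (inclusive), site count used and fst (raw; negative values
    are clipped to 0 for maxima ranking downstream).
    """
    if reference_pop not in gm.populations:
        raise ValueError(f"reference population {reference_pop} absent")
    rows = []
    for arm in gm.sites["chrom_arm"].unique():
        sub = gm.arm(arm)
        mask = nonsingleton_variable_mask(sub, reference_pop)
        idx = np.flatnonzero(mask)
        n_win = len(idx) // sites_per_window
        num, den = hudson_components(sub.alt_counts[pop1], sub.totals[pop1],
                                     sub.alt_counts[pop2], sub.totals[pop2])
        deep = ((sub.totals[pop1].to_numpy() >= min_genotypes)
                & (sub.totals[pop2].to_numpy() >= min_genotypes))
        pos = sub.sites["pos"].to_numpy()
        for w in range(n_win):
            widx = idx[w * sites_per_window:(w + 1) * sites_per_window]
            use = widx[deep[widx] & ~np.isnan(den[widx])]
            fst = np.nan
            if len(use) and np.nansum(den[use]) > 0:
                fst = float(np.nansum(num[use]) / np.nansum(den[use]))
            rows.append((arm, int(pos[widx[0]]), int(pos[widx[-1]]), len(use), fst))
    return pd.DataFrame(rows, columns=["chrom_arm", "start", "end", "n_sites", "fst"])


# ---------------------------------------------------------------------------
# per-gene maxima and outlier calling

def gene_fst_maxima(gene: pd.Series, windows: pd.DataFrame,
                    snp_pos: np.ndarray, snp_fst: np.ndarray,
                    flank: int = 2000) -> dict:
    """Max window and SNP F_ST in a gene's focal region (span +/- flank).

    Gene coordinates are 0-based half-open; the focal region is the closed
    position interval [start - flank, end - 1 + flank].  Negative
    estimates are clipped to 0 before taking maxima (raw values kept).
    """
    lo = int(gene["start"]) - flank
    hi = int(gene["end"]) - 1 + flank
    arm = gene["chrom_arm"]
    w = windows[(windows["chrom_arm"] == arm)
                & (windows["end"] >= lo) & (windows["start"] <= hi)]
    out = {"gene_id": gene["gene_id"], "chrom_arm": arm,
           "focal_start": lo, "focal_end": hi,
           "n_windows": len(w), "fst_winmax": np.nan, "fst_winmax_raw": np.nan}
    wf = w["fst"].dropna()
    if len(wf):
        out["fst_winmax_raw"] = float(wf.max())
        out["fst_winmax"] = float(np.clip(wf, 0, None).max())
    else:
        logger.info("gene %s: no window overlaps the focal region", gene["gene_id"])
    in_focal = (snp_pos >= lo) & (snp_pos <= hi)
    sf = snp_fst[in_focal]
    sf = sf[~np.isnan(sf)]
    out["n_snps"] = int(len(sf))
    if len(sf):
        out["fst_snpmax_raw"] = float(sf.max())
        out["fst_snpmax"] = float(np.clip(sf, 0, None).max())
    else:
        out["fst_snpmax"] = np.nan
        out["fst_snpmax_raw"] = np.nan
        logger.info("gene %s: no qualifying SNP in the focal region", gene["gene_id"])
    return out


def _block_maxima(values: np.ndarray, block_size: int,
                  exclude: np.ndarray | None = None) -> np.ndarray:
    """Maxima of every contiguous block of ``block_size`` entries, skipping
    blocks that touch an excluded index."""
    n = len(values)
    if n < block_size:
        return np.array([])
    from numpy.lib.stride_tricks import sliding_window_view
    wins = sliding_window_view(values, block_size)
    maxima = np.nanmax(wins, axis=1)
    if exclude is not None and exclude.any():
        hit = sliding_window_view(exclude.astype(float), block_size).max(axis=1) > 0
        maxima = maxima[~hit]
    return maxima


def arm_block_permutation(summary: dict, windows: pd.DataFrame,
                          snp_pos: np.ndarray, snp_fst: np.ndarray,
                          arm_interval: tuple[int, int],
                          exclusion_radius: int = 10,
                          outlier_quantile: float = 0.05,
                          min_blocks: int = 50) -> dict:
    """Rank a gene's F_ST maxima against same-size blocks on its arm.

    Candidate blocks slide one window (or one SNP) at a time along the
    arm's high-recombination interval; blocks within ``exclusion_radius``
    windows of the focal region are excluded.  The quantile is the
    fraction of block maxima >= the focal value (inclusive); outlier iff
    quantile <= ``outlier_quantile``.  Genes whose focal region leaves the
    masked interval are flagged and receive no call, as are arms with too
    few candidate blocks.
    """
    out = dict(summary)
    out.update({"win_quantile": np.nan, "snp_quantile": np.nan,
                "win_outlier": False, "snp_outlier": False, "flag": ""})
    lo, hi = arm_interval
    if summary["focal_start"] < lo or summary["focal_end"] > hi:
        out["flag"] = "focal_outside_mask"
        return out
    arm = summary["chrom_arm"]

    w = windows[(windows["chrom_arm"] == arm)
                & (windows["start"] >= lo) & (windows["end"] <= hi)].reset_index(drop=True)
    k = int(summary.get("n_windows", 0))
    if k > 0 and np.isfinite(summary["fst_winmax"]):
        near = ((w["end"] >= summary["focal_start"]) & (w["start"] <= summary["focal_end"]))
        near_idx = np.flatnonzero(near.to_numpy())
        excl = np.zeros(len(w), dtype=bool)
        if len(near_idx):
            a = max(0, near_idx.min() - exclusion_radius)
            b = min(len(w), near_idx.max() + exclusion_radius + 1)
            excl[a:b] = True
        vals = np.clip(w["fst"].to_numpy(float), 0, None)
        maxima = _block_maxima(vals, k, excl)
        maxima = maxima[~np.isnan(maxima)]
        if len(maxima) >= min_blocks:
            q = float(np.mean(maxima >= summary["fst_winmax"]))
            out["win_quantile"] = q
            out["win_outlier"] = q <= outlier_quantile
        else:
            out["flag"] = "too_few_window_blocks"

    in_mask = (snp_pos >= lo) & (snp_pos <= hi) & ~np.isnan(snp_fst)
    mpos, mfst = snp_pos[in_mask], np.clip(snp_fst[in_mask], 0, None)
    n_snp = int(summary.get("n_snps", 0))
    if n_snp > 0 and np.isfinite(summary["fst_snpmax"]):
        # exclusion zone for SNP blocks: focal region widened by the span of
        # exclusion_radius median-size windows
        med_span = float(np.median((windows.loc[windows["chrom_arm"] == arm, "end"]
                                    - windows.loc[windows["chrom_arm"] == arm, "start"]))) \
            if (windows["chrom_arm"] == arm).any() else 0.0
        pad = exclusion_radius * med_span
        excl = ((mpos >= summary["focal_start"] - pad)
                & (mpos <= summary["focal_end"] + pad))
        maxima = _block_maxima(mfst, n_snp, excl)
        maxima = maxima[~np.isnan(maxima)]
        if len(maxima) >= min_blocks:
            q = float(np.mean(maxima >= summary["fst_snpmax"]))
            out["snp_quantile"] = q
            out["snp_outlier"] = q <= outlier_quantile
        elif not out["flag"]:
            out["flag"] = "too_few_snp_blocks"
    return out


def fst_gene_scan(gm: GenotypeMatrix, annotation: pd.DataFrame,
                  pop1: str, pop2: str, reference_pop: str | None = None,
                  config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Full per-gene F_ST maxima scan with arm-block outlier calling."""
    config = config or AnalysisConfig()
    reference_pop = reference_pop or pop1
    windows = partition_windows(gm, reference_pop, pop1, pop2,
                                sites_per_window=config.window_site_count)
    rows = []
    for arm in annotation["chrom_arm"].unique():
        if arm not in config.arm_intervals:
            continue
        sub = gm.arm(arm)
        sfst = site_fst(sub.alt_counts[pop1], sub.totals[pop1],
                        sub.alt_counts[pop2], sub.totals[pop2])
        pos = sub.sites["pos"].to_numpy()
        for _, gene in annotation[annotation["chrom_arm"] == arm].iterrows():
            summ = gene_fst_maxima(gene, windows, pos, sfst,
                                   flank=config.focal_flank_bp)
            rows.append(arm_block_permutation(
                summ, windows, pos, sfst, config.arm_intervals[arm],
                outlier_quantile=config.pst_outlier_quantile))
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# enrichment of cis-effect genes among F_ST outliers

def cis_fst_enrichment(cis_flags: dict[str, pd.Series],
                       fst_flags: dict[str, pd.Series]) -> dict:
    """Are cis-effect genes enriched among F_ST outliers?

    ``cis_flags``/``fst_flags`` map pair label -> boolean Series over the
    same genes (cis call = cis_only or both categories; F_ST call =
    win or SNP outlier).  Per pair a Fisher exact test; pooled across
    pairs an OLS likelihood-ratio test on the F_ST-outlier fraction with
    model f ~ type + pair against f ~ pair.
    """
    from .parallelism import type_effect_lrt

    per_pair, table_rows = {}, []
    for pair, cis in cis_flags.items():
        fst = fst_flags[pair].loc[cis.index]
        tab = np.array([
            [int((cis & fst).sum()), int((cis & ~fst).sum())],
            [int((~cis & fst).sum()), int((~cis & ~fst).sum())],
        ])
        if cis.sum() == 0:
            logger.warning("pair %s: no cis-effect genes; excluded from pooled fit",
                           pair)
            per_pair[pair] = {"p_value": np.nan, "table": tab.tolist(),
                              "flag": "no_cis_genes"}
            continue
        res = stats.fisher_exact(tab)
        per_pair[pair] = {"p_value": float(res.pvalue), "table": tab.tolist()}
        for type_, row in zip(("cis_outlier", "nonoutlier"), tab):
            frac = row[0] / row.sum() if row.sum() else np.nan
            table_rows.append({"f": frac, "type": type_, "pair": pair})
    pooled = None
    frame = pd.DataFrame(table_rows).dropna()
    if frame["pair"].nunique() >= 2:
        pooled = type_effect_lrt(frame)
    return {"per_pair": per_pair, "pooled_lrt": pooled}
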