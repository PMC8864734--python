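"""Resampling classifier for cis- vs trans-regulatory divergence.

For a feature measured in an F1 hybrid of one cold and one warm parental
strain:

* cis effect — the cold-allele expression proportion in the F1, p_F1,
  deviates from 0.5.  Uncertainty is assessed by bootstrap: the feature's
  informative reads are resampled with replacement (a multinomial draw
  over the SNP-by-allele count vector with the total fixed), per-SNP
  cold-allele fractions recomputed and summarised across sites; the 95%
  percentile interval of p_F1' excluding 0.5 flags a cis effect.
* trans effect — the cold-parent expression proportion r_F0 =
  E_c/(E_c+E_w) deviates from p_F1.  Parental measurement uncertainty is
  propagated by binomial resampling of each parent's gene count at its
  observed per-read rate; each replicate's r_F0' is paired with the
  corresponding bootstrap p_F1' to form D' = r_F0' - p_F1', and the 95%
  interval of D' excluding 0 flags a trans effect.

Features are then classified as neither / cis_only / trans_only /
both_codir / both_antidir, where "codir" means both effects favour the
same parental allele (sign(p_F1 - 0.5) == sign(D)).

Everything is oriented as the cold-side proportion so signs are
comparable across features and population pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("adaptscan")

CATEGORIES = ("neither", "cis_only", "trans_only", "both_codir", "both_antidir")


@dataclass
class CisTransEstimate:
    feature_id: str
    p_f1: float
    r_f0: float
    cis_ci: tuple[float, float]
    d: float
    d_ci: tuple[float, float]
    cis_significant: bool
    trans_significant: bool
    category: str
    n_snps: int
    cross_id: str = ""

    @property
    def cis_effect(self) -> float:
        return self.p_f1 - 0.5

    @property
    def trans_effect(self) -> float:
        return self.d

    def as_row(self) -> dict:
        return {
            "feature_id": self.feature_id, "p_f1": self.p_f1, "r_f0": self.r_f0,
            "cis_lo": self.cis_ci[0], "cis_hi": self.cis_ci[1],
            "d": self.d, "d_lo": self.d_ci[0], "d_hi": self.d_ci[1],
            "cis_effect": self.cis_effect, "trans_effect": self.trans_effect,
            "cis_significant": self.cis_significant,
            "trans_significant": self.trans_significant,
            "category": self.category, "n_snps": self.n_snps,
            "cross_id": self.cross_id,
        }


# ---------------------------------------------------------------------------
# representative cross and SNP filtering

def select_representative_cross(parental_values: pd.DataFrame,
                                outbred_mean_diff: float) -> str | None:
    """Pick the between-population cross used to test one feature.

    ``parental_values`` is indexed by cross id with columns ``value_cold``
    and ``value_warm`` (trait-scale parental measurements).  The cross
    with the greatest absolute parental difference is chosen, but only if
    that difference strictly exceeds the mean cold-warm difference seen in
    the outbred within-population crosses; otherwise the feature is
    excluded (returns None).
    """
    if parental_values.empty:
        return None
    diffs = (parental_values["value_cold"] - parental_values["value_warm"]).abs()
    best = diffs.idxmax()
    if diffs.loc[best] > abs(outbred_mean_diff):
        return best
    return None


def filter_allelic_counts(table: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Keep SNPs whose F1 depth (cold + warm reads) is >= min_depth."""
    depth = table["cold_reads"] + table["warm_reads"]
    return table[depth >= min_depth]


# ---------------------------------------------------------------------------
# point estimates and resampling tests

def _summarise(fractions: np.ndarray, how: str) -> float:
    if how == "median":
        return float(np.nanmedian(fractions))
    if how == "mean":
        return float(np.nanmean(fractions))
    raise ValueError(f"unknown site summary: {how}")


def estimate_p_f1(table: pd.DataFrame, summary: str = "median") -> float:
    """Cold-allele expression proportion in the F1 for one feature.

    Per qualifying SNP the cold-read fraction is computed; the feature
    value is the median (default) or mean across sites.
    """
    if table.empty:
        raise ValueError("no qualifying SNPs for this feature")
    cold = table["cold_reads"].to_numpy(float)
    warm = table["warm_reads"].to_numpy(float)
    depth = cold + warm
    if (depth == 0).all():
        raise ValueError("zero depth at every SNP")
    with np.errstate(invalid="ignore"):
        frac = np.where(depth > 0, cold / depth, np.nan)
    return _summarise(frac, summary)


def bootstrap_cis_test(table: pd.DataFrame, B: int = 1000,
                       rng: np.random.Generator | None = None,
                       summary: str = "median",
                       ) -> tuple[tuple[float, float], bool, np.ndarray]:
    """Bootstrap CI for p_F1; returns (ci, significant, p_F1' draws).

    The feature's reads are resampled with replacement up to the observed
    total — a multinomial draw over the flattened (SNP x allele) count
    vector — then per-SNP fractions are recomputed and summarised across
    sites.  A SNP drawing zero reads in a replicate drops out of that
    replicate's summary.  Significant cis iff the 95% percentile interval
    excludes 0.5; an interval degenerate at 0 or 1 (all reads one allele)
    is flagged significant with a warning.
    """
    rng = rng or np.random.default_rng()
    cold = table["cold_reads"].to_numpy(np.int64)
    warm = table["warm_reads"].to_numpy(np.int64)
    counts = np.concatenate([cold, warm])
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no informative reads")
    n_snp = len(cold)
    draws = rng.multinomial(total, counts / total, size=B)
    c = draws[:, :n_snp].astype(float)
    w = draws[:, n_snp:].astype(float)
    depth = c + w
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, c / depth, np.nan)
    if summary == "median":
        p_draws = np.nanmedian(frac, axis=1)
    else:
        p_draws = np.nanmean(frac, axis=1)
    ci = (float(np.percentile(p_draws, 2.5)), float(np.percentile(p_draws, 97.5)))
    significant = ci[0] > 0.5 or ci[1] < 0.5
    if ci[0] == ci[1] and ci[0] in (0.0, 1.0):
        logger.warning("degenerate allelic CI at %g (all reads one allele)", ci[0])
        significant = True
    return ci, significant, p_draws


def resample_trans_test(e_cold: int, e_warm: int, lib_cold: int, lib_warm: int,
                        p_f1_draws: np.ndarray,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[float, tuple[float, float], bool, np.ndarray]:
    """Resampling CI for D = r_F0 - p_F1; returns (r_f0, d_ci, significant, D').

    Each replicate redraws both parents' gene counts as
    Binomial(n = parental library total, p = gene reads / library total),
    recomputes the library-size-normalised cold proportion r_F0', and
    pairs it with the b-th bootstrap p_F1' draw.  Replicates where both
    redrawn counts are zero are redrawn (count logged).  Significant trans
    iff the 95% percentile interval of D' excludes 0.
    """
    rng = rng or np.random.default_rng()
    if lib_cold <= 0 or lib_warm <= 0:
        raise ValueError("parental library totals must be positive")
    if e_cold + e_warm == 0:
        raise ValueError("feature unexpressed in both parents")
    B = len(p_f1_draws)
    ec = rng.binomial(lib_cold, e_cold / lib_cold, size=B).astype(float)
    ew = rng.binomial(lib_warm, e_warm / lib_warm, size=B).astype(float)
    n_redraw = 0
    zero = (ec + ew) == 0
    while zero.any():
        n_redraw += int(zero.sum())
        ec[zero] = rng.binomial(lib_cold, e_cold / lib_cold, size=int(zero.sum()))
        ew[zero] = rng.binomial(lib_warm, e_warm / lib_warm, size=int(zero.sum()))
        zero = (ec + ew) == 0
    if n_redraw:
        logger.info("trans resampling: redrew %d zero-sum replicate(s)", n_redraw)
    rc, rw = ec / lib_cold, ew / lib_warm
    r_draws = rc / (rc + rw)
    d_draws = r_draws - np.asarray(p_f1_draws, float)
    ci = (float(np.percentile(d_draws, 2.5)), float(np.percentile(d_draws, 97.5)))
    significant = ci[0] > 0.0 or ci[1] < 0.0
    r_f0 = (e_cold / lib_cold) / (e_cold / lib_cold + e_warm / lib_warm)
    return float(r_f0), ci, significant, d_draws


def classify_regulation(cis_significant: bool, cis_effect: float,
                        trans_significant: bool, trans_effect: float) -> str:
    """Five-way regulatory category from the two significance calls."""
    if cis_significant and trans_significant:
        return "both_codir" if np.sign(cis_effect) == np.sign(trans_effect) \
            else "both_antidir"
    if cis_significant:
        return "cis_only"
    if trans_significant:
        return "trans_only"
    return "neither"


def analyze_feature(feature_id: str, allelic: pd.DataFrame,
                    e_cold: int, e_warm: int, lib_cold: int, lib_warm: int,
                    B: int = 1000, min_depth: int = 10,
                    rng: np.random.Generator | None = None,
                    summary: str = "median", cross_id: str = "",
                    ) -> CisTransEstimate | None:
    """Full cis/trans analysis of one feature; None if no qualifying SNP."""
    rng = rng or np.random.default_rng()
    table = filter_allelic_counts(allelic, min_depth)
    if table.empty:
        logger.info("feature %s excluded: no SNP at depth >= %d", feature_id, min_depth)
        return None
    p_f1 = estimate_p_f1(table, summary)
    cis_ci, cis_sig, p_draws = bootstrap_cis_test(table, B=B, rng=rng, summary=summary)
    r_f0, d_ci, trans_sig, _ = resample_trans_test(
        e_cold, e_warm, lib_cold, lib_warm, p_draws, rng=rng)
    d = r_f0 - p_f1
    category = classify_regulation(cis_sig, p_f1 - 0.5, trans_sig, d)
    return CisTransEstimate(feature_id, p_f1, r_f0, cis_ci, d, d_ci,
                            cis_sig, trans_sig, category, len(table), cross_id)


def analyze_experiment(allelic: pd.DataFrame, parental: pd.DataFrame,
                       B: int = 1000, min_depth: int = 10,
                       rng: np.random.Generator | None = None,
                       summary: str = "median") -> pd.DataFrame:
    """Run the classifier over every gene of an allelic-count experiment."""
    rng = rng or np.random.default_rng()
    parental = parental.set_index("gene_id") if "gene_id" in parental.columns else parental
    rows = []
    for gid, snps in allelic.groupby("gene_id", sort=True):
        if gid not in parental.index:
            logger.info("gene %s skipped: no parental expression", gid)
            continue
        p = parental.loc[gid]
        est = analyze_feature(gid, snps, int(p["e_cold"]), int(p["e_warm"]),
                              int(p["lib_cold"]), int(p["lib_warm"]),
                              B=B, min_depth=min_depth, rng=rng, summary=summary,
                              cross_id=str(p.get("cross_id", "")))
        if est is not None:
            rows.append(est.as_row())
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# downstream statistics

def magnitude_comparison(estimates: pd.DataFrame) -> dict:
    """Paired signed-rank comparison of |cis| vs |trans| effect sizes."""
    cis = estimates["cis_effect"].abs().to_numpy()
    trans = estimates["trans_effect"].abs().to_numpy()
    if len(cis) < 10:
        logger.warning("magnitude comparison on %d features (< 10): low power",
                       len(cis))
    if np.allclose(cis, trans):
        p = 1.0
    else:
        p = float(stats.wilcoxon(cis, trans).pvalue)
    return {"mean_abs_cis": float(cis.mean()), "mean_abs_trans": float(trans.mean()),
            "p_value": p, "n": len(cis)}


def load_category_counts() -> pd.DataFrame:
    """Published per-pair regulatory category counts (the worked example).

    Rows are (pair, gene_class) with the five category columns; gene_class
    distinguishes expression-differentiation outliers from nonoutliers.
    """
    with resources.files("adaptscan.data").joinpath(
            "regulatory_category_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t").set_index(["pair", "gene_class"])


def category_enrichment_chisq(outlier_counts: pd.Series,
                              nonoutlier_counts: pd.Series,
                              effect: str = "cis",
                              exclude_antidir: bool = True) -> dict:
    """Is a regulatory effect enriched among differentiation outliers?

    Builds the 2x2 table of effect-affected (cis: cis_only + both_codir;
    trans: trans_only + both_codir) vs the rest, for outliers vs
    nonoutliers, dropping both_antidir features (their opposing effects
    are suspected measurement artifacts), and applies the Pearson
    chi-square with continuity correction.
    """
    if effect not in ("cis", "trans"):
        raise ValueError("effect must be 'cis' or 'trans'")
    affected_cats = ["cis_only" if effect == "cis" else "trans_only", "both_codir"]
    rows = []
    for counts in (outlier_counts, nonoutlier_counts):
        total = int(sum(counts[c] for c in CATEGORIES))
        if exclude_antidir:
            total -= int(counts["both_antidir"])
        affected = int(sum(counts[c] for c in affected_cats))
        rows.append([affected, total - affected])
    tab = np.array(rows)
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=True)
    out = {"chi2": float(chi2), "df": int(dof), "p_value": float(p),
           "table": tab.tolist()}
    if (expected < 1).any():
        logger.warning("expected cell < 1; Fisher's exact test also reported")
        out["fisher_p"] = float(stats.fisher_exact(tab).pvalue)
    return out


def category_summary_fractions(counts: pd.DataFrame) -> dict:
    """Headline fractions from a per-pair category-count table.

    Per pair: the fraction of outliers / nonoutliers with any significant
    effect (1 - neither/total) and, pooling outliers with nonoutliers, the
    fraction of genes with a cis effect (cis_only + both, either
    direction) and with a trans effect; each averaged across pairs.
    """
    pairs = counts.index.get_level_values("pair").unique()
    any_out, any_non, cis_all, trans_all = [], [], [], []
    for pair in pairs:
        out = counts.loc[(pair, "outlier")]
        non = counts.loc[(pair, "nonoutlier")]
        tot_out = sum(out[c] for c in CATEGORIES)
        tot_non = sum(non[c] for c in CATEGORIES)
        any_out.append(1 - out["neither"] / tot_out)
        any_non.append(1 - non["neither"] / tot_non)
        pooled = out + non
        n_all = tot_out + tot_non
        cis_all.append((pooled["cis_only"] + pooled["both_codir"]
                        + pooled["both_antidir"]) / n_all)
        trans_all.append((pooled["trans_only"] + pooled["both_codir"]
                          + pooled["both_antidir"]) / n_all)
    return {"pct_outliers_any_effect": 100 * float(np.mean(any_out)),
            "pct_nonoutliers_any_effect": 100 * float(np.mean(any_non)),
            "pct_genes_cis": 100 * float(np.mean(cis_all)),
            "pct_genes_trans": 100 * float(np.mean(trans_all))}


def parallel_category_fisher(parallel_flags: pd.Series,
                             effect_flags: pd.Series) -> dict:
    """Fisher's exact test: effect presence x parallel status for shared
    outliers (both series indexed by gene, booleans)."""
    idx = parallel_flags.index
    effect_flags = effect_flags.loc[idx]
    tab = np.array([
        [int((parallel_flags & effect_flags).sum()),
         int((parallel_flags & ~effect_flags).sum())],
        [int((~parallel_flags & effect_flags).sum()),
         int((~parallel_flags & ~effect_flags).sum())],
    ])
    if tab[0].sum() == 0:
        logger.warning("no parallel genes; Fisher test skipped")
        return {"p_value": np.nan, "table": tab.tolist(), "flag": "empty_parallel_class"}
    res = stats.fisher_exact(tab)
    return {"p_value": float(res.pvalue), "odds_ratio": float(res.statistic),
            "table": tab.tolist()}


# ---------------------------------------------------------------------------
# simulation-based validation of the classifier

def validate_method(grid, B: int = 1000, seed: int = 0,
                    n_genes: int = 200) -> pd.DataFrame:
    """Classification-rate table over a grid of simulated (kappa, tau, depth).

    Each grid cell simulates ``n_genes`` features and reports the fraction
    receiving a significant cis call and a significant trans call plus the
    full category distribution.  With kappa = 1 (tau = 1) the cis (trans)
    rate is a false-positive rate; away from 1 it is power.
    """
    from .simulate import AseSimParams, simulate_ase_experiment

    rows = []
    for i, (kappa, tau, depth) in enumerate(grid):
        params = AseSimParams(n_genes=n_genes, kappa=kappa, tau=tau,
                              reads_per_gene=depth)
        allelic, parental, _ = simulate_ase_experiment(params, seed=seed + i)
        rng = np.random.default_rng([seed + i, 1])
        est = analyze_experiment(allelic, parental, B=B, rng=rng)
        row = {"kappa": kappa, "tau": tau, "depth": depth,
               "n_tested": len(est),
               "cis_rate": float(est["cis_significant"].mean()),
               "trans_rate": float(est["trans_significant"].mean())}
        for cat in CATEGORIES:
            row[f"frac_{cat}"] = float((est["category"] == cat).mean())
        rows.append(row)
    return pd.DataFrame(rows)
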