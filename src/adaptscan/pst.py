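"""Quantitative trait differentiation (P_ST) for expression and splicing.

P_ST is the phenotypic analog of F_ST:

    P_ST = V_between / (V_between + 2 * V_within)

computed per feature between the cold- and warm-derived populations of one
pair, where V_between is the variance of the two population means (with two
groups this is (m_cold - m_warm)^2 / 2) and V_within is the mean of the two
within-population sample variances.  Traits are per-sample proportions of
the transcriptome (expression) or junction usage frequencies (splicing);
no log transform is applied.

Before computing P_ST, each population drops its single highest and single
lowest sample for the feature, so that a single anomalous sample cannot
drive a high P_ST value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, JunctionClusterTable

logger = logging.getLogger("adaptscan")


@dataclass
class NormalizationFactor:
    """Median cold/warm expression ratio applied to warm samples of a pair."""

    pair: str
    stage: str
    median_ratio: float


# ---------------------------------------------------------------------------
# scaling and normalization

def standardize_by_sample_total(expr: ExpressionMatrix,
                                totals: pd.Series | None = None) -> ExpressionMatrix:
    """Convert counts to per-sample transcriptome proportions.

    ``totals`` lets the caller supply totals computed before feature
    filtering (the sample's full mapped-read count); by default column sums
    are used.
    """
    if totals is None:
        totals = expr.sample_totals()
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    return ExpressionMatrix(expr.counts / totals, expr.meta, expr.feature_kind)


def normalize_warm_by_median_ratio(
    expr: ExpressionMatrix, pair: str, stage: str | None = None
) -> tuple[ExpressionMatrix, NormalizationFactor]:
    """Rescale a pair's warm-population samples by the median cold/warm ratio.

    Guards against transcriptome skew: if one population up-regulates a few
    very highly expressed genes, the relative abundance of every other gene
    shifts in the opposite direction.  Multiplying the warm samples by the
    median over genes of mean_cold/mean_warm re-centres the per-gene ratio
    distribution at 1 while being robust to the skewed genes themselves.
    """
    pops = expr.populations_of_pair(pair)
    meta = expr.meta
    in_pair = meta["pair"] == pair
    if stage is not None:
        in_pair &= meta["stage"] == stage
    cold_cols = meta.index[in_pair & (meta["population"] == pops["cold"])]
    warm_cols = meta.index[in_pair & (meta["population"] == pops["warm"])]
    if len(cold_cols) == 0 or len(warm_cols) == 0:
        raise ValueError(f"pair {pair}: a population has no samples")
    cold_mean = expr.counts[cold_cols].mean(axis=1)
    warm_mean = expr.counts[warm_cols].mean(axis=1)
    if cold_mean.sum() == 0 or warm_mean.sum() == 0:
        raise ValueError(f"pair {pair}: a population has all-zero expression")
    both = (cold_mean > 0) & (warm_mean > 0)
    if not both.any():
        raise ValueError(f"pair {pair}: no gene expressed in both populations")
    median_ratio = float((cold_mean[both] / warm_mean[both]).median())
    counts = expr.counts.copy()
    counts[warm_cols] = counts[warm_cols] * median_ratio
    factor = NormalizationFactor(pair, stage or "all", median_ratio)
    return ExpressionMatrix(counts, meta, expr.feature_kind), factor


def filter_features(expr: ExpressionMatrix, min_total: int = 200) -> ExpressionMatrix:
    """Keep features whose summed counts strictly exceed ``min_total``.

    The sum runs over every within-population sample present in the matrix
    (all pairs of a stage together).
    """
    totals = expr.counts.sum(axis=1)
    keep = totals > min_total
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no features pass the minimum-count filter")
    if n_drop:
        logger.info("filter_features: dropped %d of %d features", n_drop, len(keep))
    return expr.subset_features(expr.feature_ids[keep])


# ---------------------------------------------------------------------------
# junction usage frequencies

def compute_junction_frequencies(
    jct: JunctionClusterTable,
    meta: pd.DataFrame,
    min_cluster_reads: int = 50,
    min_mean_events: float = 5.0,
    min_nonzero_per_pop: int = 6,
) -> ExpressionMatrix:
    """Per-junction usage frequencies with the splicing input filters.

    Usage frequency of junction i in a sample is n_i / cluster total for
    that sample.  Junctions are retained only if (a) the cluster has at
    least two junctions and >= ``min_cluster_reads`` supporting reads
    summed over samples, (b) the mean excision count n_i and the mean
    alternative count (cluster total - n_i) across samples are both >=
    ``min_mean_events``, and (c) at least ``min_nonzero_per_pop`` samples
    in every population have a nonzero usage count.  Samples whose cluster
    total is zero get an undefined (NaN) frequency.
    """
    counts = jct.counts
    cluster_tot = counts.groupby(jct.cluster_of).transform("sum")
    sizes = jct.cluster_of.value_counts()
    multi = jct.cluster_of.map(sizes) >= 2
    supported = cluster_tot.sum(axis=1) >= min_cluster_reads

    n_i_mean = counts.mean(axis=1)
    n_j_mean = (cluster_tot - counts).mean(axis=1)
    events_ok = (n_i_mean >= min_mean_events) & (n_j_mean >= min_mean_events)

    nonzero_ok = pd.Series(True, index=counts.index)
    for _, pop_samples in meta.groupby("population").groups.items():
        cols = [s for s in pop_samples if s in counts.columns]
        if cols:
            nonzero_ok &= (counts[cols] > 0).sum(axis=1) >= min_nonzero_per_pop

    keep = multi & supported & events_ok & nonzero_ok
    if keep.sum() == 0:
        raise ValueError("no junctions pass the usage filters")
    logger.info("junction filters: retained %d of %d junctions",
                int(keep.sum()), len(keep))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts[keep] / cluster_tot[keep].replace(0, np.nan)
    return ExpressionMatrix(freq, meta.loc[counts.columns], "junction_frequency")


# ---------------------------------------------------------------------------
# P_ST proper

def _trim_extremes(values: pd.Series) -> pd.Series:
    """Drop the single max and single min sample (ties: first by sample id)."""
    order = values.index.sort_values()
    v = values.loc[order]
    i_max = v.index[np.flatnonzero(v.to_numpy() == v.max())[0]]
    v = v.drop(i_max)
    i_min = v.index[np.flatnonzero(v.to_numpy() == v.min())[0]]
    return v.drop(i_min)


def compute_pst(cold: pd.Series, warm: pd.Series, trim: bool = True) -> dict:
    """P_ST for one feature from per-sample trait values of the two populations.

    Returns a dict with v_between, v_within, pst, cold_proportion,
    direction, degenerate and the retained sample counts.  NaN samples
    (undefined trait values) are dropped first.
    """
    cold = cold.dropna()
    warm = warm.dropna()
    if trim:
        if len(cold) < 4 or len(warm) < 4:
            raise ValueError("trimming requires >= 4 samples per population")
        cold = _trim_extremes(cold)
        warm = _trim_extremes(warm)
    elif len(cold) < 2 or len(warm) < 2:
        raise ValueError("need >= 2 samples per population")
    m_c, m_w = float(cold.mean()), float(warm.mean())
    v_between = (m_c - m_w) ** 2 / 2.0
    v_within = (float(cold.var(ddof=1)) + float(warm.var(ddof=1))) / 2.0
    denom = v_between + 2.0 * v_within
    degenerate = denom == 0.0
    pst = 0.0 if degenerate else v_between / denom
    total = m_c + m_w
    cold_prop = 0.5 if total == 0 else m_c / total
    # exact 0.5 ties resolve to cold_up deterministically
    direction = "cold_up" if cold_prop >= 0.5 else "cold_down"
    return {
        "v_between": v_between,
        "v_within": v_within,
        "pst": float(pst),
        "cold_proportion": cold_prop,
        "direction": direction,
        "degenerate": degenerate,
        "n_cold": len(cold),
        "n_warm": len(warm),
    }


def pst_table(expr: ExpressionMatrix, pair: str, trim: bool = True) -> pd.DataFrame:
    """Per-feature P_ST for one population pair (trait-scale input)."""
    pops = expr.populations_of_pair(pair)
    meta = expr.meta
    cold_cols = meta.index[(meta["pair"] == pair) & (meta["population"] == pops["cold"])]
    warm_cols = meta.index[(meta["pair"] == pair) & (meta["population"] == pops["warm"])]
    rows = []
    for fid in expr.feature_ids:
        res = compute_pst(expr.counts.loc[fid, cold_cols],
                          expr.counts.loc[fid, warm_cols], trim=trim)
        res["feature_id"] = fid
        rows.append(res)
    out = pd.DataFrame(rows).set_index("feature_id")
    return out


def assign_quantiles_and_outliers(
    table: pd.DataFrame,
    cutoff: float = 0.05,
    gene_of: pd.Series | None = None,
) -> pd.DataFrame:
    """Upper-tail P_ST quantiles and outlier flags.

    The quantile is the rank fraction from the top (ties share the mean
    rank), so small quantiles are extreme; outlier iff quantile <= cutoff.
    For junction traits, pass ``gene_of`` mapping feature -> gene: when
    several junctions of one gene pass the cutoff, only the one with the
    highest P_ST keeps its outlier flag.
    """
    if len(table) < 20:
        raise ValueError("need >= 20 features to assign quantiles")
    table = table.copy()
    pst = table["pst"].to_numpy(float)
    ranks = rankdata(-pst, method="average")
    table["quantile"] = ranks / len(pst)
    table["outlier"] = table["quantile"] <= cutoff
    if not table["outlier"].any():
        logger.warning("no outliers at cutoff %.3g (degenerate P_ST spread?)", cutoff)
    if gene_of is not None and table["outlier"].any():
        out = table[table["outlier"]]
        for gene, grp in out.groupby(gene_of.loc[out.index]):
            if len(grp) > 1:
                best = grp["pst"].idxmax()
                drop = [i for i in grp.index if i != best]
                table.loc[drop, "outlier"] = False
    return table


# ---------------------------------------------------------------------------
# splicing gene-level quantile adjustment

def to_extreme_high_convention(upper_tail_q: np.ndarray | float):
    """Convert an upper-tail quantile (small = extreme) to the convention in
    which values near 1 are extreme, and vice versa (the map is its own
    inverse)."""
    return 1.0 - np.asarray(upper_tail_q, dtype=float)


def adjusted_gene_quantile(
    junction_table: pd.DataFrame,
    gene_of: pd.Series,
    cluster_of: pd.Series,
) -> pd.DataFrame:
    """Gene-level splicing differentiation quantile, multiplicity-adjusted.

    With q_gene the most extreme junction quantile of the gene (in the
    near-1-is-extreme convention) and n_sum = sum over the gene's clusters
    of (junctions tested - 1), the adjusted quantile is

        q'_gene = 1 - (1 - q_gene) * n_sum,   floored at 0.

    n_sum counts the effective number of independent junction tests (within
    a cluster, frequencies sum to 1, so one junction is redundant).
    """
    q_high = to_extreme_high_convention(junction_table["quantile"].to_numpy())
    per_junction = pd.DataFrame({
        "gene": gene_of.loc[junction_table.index].to_numpy(),
        "cluster": cluster_of.loc[junction_table.index].to_numpy(),
        "q_high": q_high,
    }, index=junction_table.index)
    rows = []
    for gene, grp in per_junction.groupby("gene"):
        q_gene = float(grp["q_high"].max())
        n_sum = int(sum(max(n - 1, 0) for n in grp.groupby("cluster").size()))
        n_sum = max(n_sum, 1)
        q_prime = max(0.0, 1.0 - (1.0 - q_gene) * n_sum)
        rows.append((gene, q_gene, n_sum, q_prime))
    out = pd.DataFrame(rows, columns=["gene_id", "q_gene", "n_sum", "q_prime"])
    return out.set_index("gene_id")
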