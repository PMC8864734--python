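"""Permutation tests for parallel regulatory evolution.

All tests share the same recipe: an observed statistic over the outlier
set, a null distribution built by drawing same-size random gene sets from
the tested universe, and a p-value counting null draws at least as extreme
as the observation (inclusive).  Two-tailed p-values are twice the smaller
tail proportion, capped at 1.  Subset draws are realised through
hypergeometric sampling, which is distributionally identical to permuting
gene identities and much cheaper.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger("adaptscan")


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    null_draws: np.ndarray
    p_value: float
    tail: str  # "one" or "two"
    ci95: tuple[float, float]
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": float(self.observed),
            "null_mean": float(np.mean(self.null_draws)),
            "p_value": float(self.p_value),
            "tail": self.tail,
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            **self.extra,
        }


def _finish(name: str, observed: float, null: np.ndarray, tail: str,
            extra: dict | None = None) -> PermutationResult:
    null = np.asarray(null, dtype=float)
    ge = float(np.mean(null >= observed))
    le = float(np.mean(null <= observed))
    p = ge if tail == "one" else min(1.0, 2.0 * min(ge, le))
    ci = (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5)))
    return PermutationResult(name, float(observed), null, p, tail, ci, extra or {})


# ---------------------------------------------------------------------------
# X-chromosome enrichment

def x_enrichment_test(outlier_ids, tested_arms: pd.Series, B: int = 10_000,
                      rng: np.random.Generator | None = None) -> PermutationResult:
    """Is the X-linked fraction of outliers unusual for their universe?

    ``tested_arms`` maps every tested gene to its chromosome arm.  The null
    draws B random same-size gene sets from the universe and records the
    X fraction of each; the test is two-tailed.
    """
    rng = rng or np.random.default_rng()
    outlier_ids = pd.Index(outlier_ids)
    missing = outlier_ids.difference(tested_arms.index)
    if len(missing):
        raise ValueError(f"outliers outside the tested universe: {list(missing)[:5]}")
    on_x = (tested_arms == "X")
    n_x, n = int(on_x.sum()), len(tested_arms)
    if n_x == 0:
        raise ValueError("no X-linked genes in the tested universe")
    n_out = len(outlier_ids)
    f_x = float(on_x.loc[outlier_ids].mean())
    null = rng.hypergeometric(n_x, n - n_x, n_out, size=B) / n_out
    return _finish("f_x", f_x, null, "two",
                   {"n_outliers": n_out, "genome_fraction": n_x / n})


# ---------------------------------------------------------------------------
# shared co-directional outliers between two pairs

def analytic_shared_codir_expectation(n1: int, n2: int, n_tested: int,
                                      p_codir: float = 0.5) -> dict:
    """Expected shared co-directional count under independent outlier sets.

    Two independent subsets of sizes n1 and n2 overlap in n1*n2/n genes on
    average; with directions agreeing at rate ``p_codir`` (1/2 for random
    directions) the expected co-directional shared count is
    n1*n2*p_codir/n.  For two 5% outlier sets and random directions the
    expected fraction of tested genes is 0.05 * 0.05 * 0.5 = 0.125%.
    """
    exp_count = n1 * n2 * p_codir / n_tested
    return {"expected_count": exp_count,
            "expected_fraction_of_tested": exp_count / n_tested}


def shared_codirectional_test(
    outliers1, outliers2,
    directions1: pd.Series, directions2: pd.Series,
    tested_genes, B: int = 10_000,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Count of genes outlying in both pairs with the same direction of change.

    ``directions1``/``directions2`` give the cold-vs-warm direction for
    every tested gene in each pair (the permutation reassigns outlier
    status over genes, keeping each gene's observed directions).  The null
    draws independent same-size outlier sets and counts co-directional
    intersections; sampling is a two-stage hypergeometric draw over the
    co-directional gene set.
    """
    rng = rng or np.random.default_rng()
    tested = pd.Index(tested_genes)
    o1, o2 = pd.Index(outliers1), pd.Index(outliers2)
    for o in (o1, o2):
        if len(o.difference(tested)):
            raise ValueError("outliers must be drawn from the tested universe")
    if len(o1) == 0 or len(o2) == 0:
        logger.warning("empty outlier set; shared-codirectional p undefined")
        return PermutationResult("N_shared_codir", 0.0, np.array([np.nan]), np.nan,
                                 "two", (np.nan, np.nan), {"flag": "empty_outlier_set"})
    codir = directions1.loc[tested].to_numpy() == directions2.loc[tested].to_numpy()
    m, n = int(codir.sum()), len(tested)
    shared = o1.intersection(o2)
    observed = int((directions1.loc[shared] == directions2.loc[shared]).sum())
    k1 = rng.hypergeometric(m, n - m, len(o1), size=B)   # codir genes in set 1
    null = rng.hypergeometric(k1, n - k1, len(o2))        # of those, also in set 2
    expect = analytic_shared_codir_expectation(len(o1), len(o2), n, m / n)
    return _finish("N_shared_codir", observed, null, "two",
                   {"analytic_expectation": expect["expected_count"],
                    "n_shared": len(shared)})


def codirectional_fraction_test(
    outliers1, directions1: pd.Series, directions2: pd.Series,
    tested_genes, B: int = 10_000,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Fraction of one pair's outliers changing the same way in another pair.

    The null redraws same-size gene sets from the tested universe and
    recomputes the co-directional fraction from the fixed per-gene
    directions; its 2.5/97.5 percentiles give the null band.
    """
    rng = rng or np.random.default_rng()
    tested = pd.Index(tested_genes)
    o1 = pd.Index(outliers1)
    if len(o1.difference(tested)):
        raise ValueError("outliers must be drawn from the tested universe")
    codir = directions1.loc[tested].to_numpy() == directions2.loc[tested].to_numpy()
    m, n = int(codir.sum()), len(tested)
    observed = float((directions1.loc[o1] == directions2.loc[o1]).mean())
    null = rng.hypergeometric(m, n - m, len(o1), size=B) / len(o1)
    return _finish("F_codir_fraction", observed, null, "two", {"n_outliers": len(o1)})


# ---------------------------------------------------------------------------
# overlap with an external candidate list

def external_overlap_test(
    outliers, external_directions: pd.Series,
    directions: pd.Series, tested_genes, B: int = 10_000,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Overlap of outliers with a published candidate list, plus
    co-directionality.

    One-tailed permutation p for the shared count (random same-size gene
    sets), and a continuity-corrected chi-square asking whether shared
    outliers agree in direction with the external list more often than
    shared non-outliers do.
    """
    rng = rng or np.random.default_rng()
    tested = pd.Index(tested_genes)
    o1 = pd.Index(outliers)
    ext = pd.Index(external_directions.index).intersection(tested)
    if len(ext) == 0:
        logger.warning("external list does not intersect the tested universe")
        return PermutationResult("overlap_count", 0.0, np.array([np.nan]), np.nan,
                                 "one", (np.nan, np.nan), {"flag": "empty_intersection"})
    observed = len(o1.intersection(ext))
    null = rng.hypergeometric(len(ext), len(tested) - len(ext), len(o1), size=B)
    extra: dict = {"n_external_tested": len(ext)}
    shared_out = o1.intersection(ext)
    shared_non = ext.difference(o1)
    tab = np.zeros((2, 2), dtype=int)
    for i, ids in enumerate((shared_out, shared_non)):
        agree = directions.loc[ids] == external_directions.loc[ids]
        tab[i] = [int(agree.sum()), int((~agree).sum())]
    if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
        chi2, p_chi, _, _ = stats.chi2_contingency(tab, correction=True)
        extra.update({"codir_chi2": float(chi2), "codir_chi2_p": float(p_chi),
                      "codir_table": tab.tolist()})
    return _finish("overlap_count", observed, null, "one", extra)


def codirectionality_chisq(n_codir_out: int, n_anti_out: int,
                           n_codir_non: int, n_anti_non: int) -> tuple[float, float]:
    """Continuity-corrected chi-square on a 2x2 of direction agreement."""
    tab = np.array([[n_codir_out, n_anti_out], [n_codir_non, n_anti_non]])
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# OLS likelihood-ratio tests on X-fraction (and F_ST-fraction) tables

def _ols_lrt(table: pd.DataFrame, full: str, reduced: str) -> dict:
    for formula in (full, reduced):
        model = smf.ols(formula, data=table)
        rank = np.linalg.matrix_rank(model.exog)
        if rank < model.exog.shape[1]:
            names = model.exog_names
            raise ValueError(
                f"rank-deficient design for '{formula}': {rank} < {len(names)}; "
                f"check for empty factor cells among {names}")
    fit_full = smf.ols(full, data=table).fit()
    fit_red = smf.ols(reduced, data=table).fit()
    n = len(table)
    df = fit_full.df_model - fit_red.df_model
    if fit_red.ssr < 1e-14:
        # reduced model already fits perfectly: the extra terms add nothing
        lrt = 0.0
    else:
        lrt = n * np.log(fit_red.ssr / fit_full.ssr)
    p = float(stats.chi2.sf(lrt, df))
    return {"lrt": float(lrt), "df": int(df), "p_value": p,
            "rss_full": float(fit_full.ssr), "rss_reduced": float(fit_red.ssr)}


def stage_type_interaction_lrt(table: pd.DataFrame) -> dict:
    """Does outlier X-enrichment depend on developmental stage?

    ``table`` holds one row per stage x type (outlier / nonoutlier) x pair
    with column ``f`` (X-linked fraction).  Compares
    f ~ stage + type + stage:type + pair against the no-interaction model
    with an OLS likelihood-ratio test.
    """
    return _ols_lrt(table,
                    "f ~ C(stage) * C(type) + C(pair)",
                    "f ~ C(stage) + C(type) + C(pair)")


def type_effect_lrt(table: pd.DataFrame) -> dict:
    """Pooled test of an outlier-class effect: f ~ type + pair vs f ~ pair."""
    return _ols_lrt(table, "f ~ C(type) + C(pair)", "f ~ C(pair)")


# ---------------------------------------------------------------------------
# co-regulation among outliers

@dataclass
class CoregulationSummary:
    population: str
    n_outliers: int
    n_pairs_tested: int
    prop_significant_pairs: float
    partners_per_gene: pd.Series


def _permutations_hamming(rng: np.random.Generator, n_items: int, B: int,
                          min_moved: int = 5) -> np.ndarray:
    """B uniform permutations of ``n_items`` with >= min_moved displaced
    elements, by rejection from uniform permutations (acceptance ~0.98 for
    n=8, min_moved=5)."""
    out = np.empty((0, n_items), dtype=np.intp)
    identity = np.arange(n_items)
    while len(out) < B:
        batch = rng.permuted(np.tile(identity, (max(B, 64), 1)), axis=1)
        moved = (batch != identity).sum(axis=1)
        out = np.vstack([out, batch[moved >= min_moved]])
    return out[:B]


def coregulation_test(expr: pd.DataFrame, population: str = "",
                      B: int = 10_000, alpha: float = 0.05,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[pd.DataFrame, CoregulationSummary]:
    """Pairwise expression correlation among outliers within one population.

    ``expr`` is outlier-genes x samples (the outbred samples of one
    cold-derived population).  For every gene pair the observed Pearson r
    is compared with a null built by permuting one gene's sample values,
    requiring at least five of the eight samples to move; the one-tailed p
    is the proportion of null correlations >= observed.  Each pair gets an
    independent null.  Constant genes cannot be correlated and their pairs
    are skipped.
    """
    rng = rng or np.random.default_rng()
    if expr.shape[0] < 2:
        raise ValueError("need at least two outlier genes")
    n_samples = expr.shape[1]
    genes = list(expr.index)
    x = expr.to_numpy(float)
    centred = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    rows = []
    n_skipped = 0
    for i, j in itertools.combinations(range(len(genes)), 2):
        if norms[i] == 0 or norms[j] == 0:
            n_skipped += 1
            continue
        r_obs = float(centred[i] @ centred[j] / (norms[i] * norms[j]))
        perms = _permutations_hamming(rng, n_samples, B)
        r_null = (centred[j][perms] @ centred[i]) / (norms[i] * norms[j])
        p = float(np.mean(r_null >= r_obs))
        rows.append((genes[i], genes[j], r_obs, p))
    if n_skipped:
        logger.warning("coregulation: skipped %d pair(s) with constant expression",
                       n_skipped)
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p_value"])
    sig = pairs[pairs["p_value"] < alpha]
    partners = pd.Series(0, index=genes, dtype=int)
    for col in ("gene_a", "gene_b"):
        partners = partners.add(sig[col].value_counts(), fill_value=0).astype(int)
    summary = CoregulationSummary(
        population=population,
        n_outliers=len(genes),
        n_pairs_tested=len(pairs),
        prop_significant_pairs=float(len(sig) / len(pairs)) if len(pairs) else np.nan,
        partners_per_gene=partners,
    )
    return pairs, summary
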