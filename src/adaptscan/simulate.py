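"""Synthetic data generators with known ground truth.

Three layers mirror the inputs of the real study design:

* ``simulate_study`` — negative-binomial RNA-seq counts for paired
  warm/cold populations (eight outbred crosses per population, up to three
  developmental stages), with a controlled fraction of genes truly
  differentiated between thermal classes and a controlled fraction of
  those shared co-directionally across pairs.
* ``simulate_ase_experiment`` — F1 allele-specific read counts and
  parental expression counts under a multiplicative cis/trans model: with
  cis fold-change kappa and trans fold-change tau, the F1 cold-allele
  proportion is kappa/(kappa+1) and the parental cold proportion is
  kappa*tau/(kappa*tau+1) — exact closed forms used as test oracles.
* ``simulate_genotypes`` — biallelic SNPs under a symmetric
  Balding-Nichols model at a stated baseline F_ST, with optional planted
  high-differentiation loci.

Counts are integers >= 0 and every truth table aligns one-to-one with the
emitted features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_ARM_INTERVALS, CHROM_ARMS
from .datatypes import ExpressionMatrix, GenotypeMatrix, JunctionClusterTable

logger = logging.getLogger("adaptscan")

PAIR_LABELS = ("MED", "ETH", "SAF")


@dataclass
class StudySimParams:
    """Study-level expression simulation parameters.

    Defaults mirror the study design: three population pairs, eight
    outbred crosses per population, three stages.  ``effect_lfc`` is the
    log2 fold-change magnitude of a true cold-vs-warm difference;
    ``frac_parallel`` is the fraction of differentiated genes whose
    direction is shared across all pairs; ``dispersion`` is the
    negative-binomial overdispersion (variance = mu + dispersion * mu^2).
    """

    n_pairs: int = 3
    n_crosses_per_pop: int = 8
    n_genes: int = 1000
    stages: tuple = ("larva", "pupa", "adult")
    frac_differentiated: float = 0.1
    effect_lfc: float = 1.0
    frac_parallel: float = 0.3
    dispersion: float = 0.05
    lib_size_mean: float = 1_000_000.0
    lib_size_log_sd: float = 0.1
    frac_x_linked: float = 0.2
    skew_pair: str | None = None   # add a transcriptome skew to this pair
    skew_n_genes: int = 5
    skew_factor: float = 20.0

    def __post_init__(self) -> None:
        for f in ("frac_differentiated", "frac_parallel", "frac_x_linked"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.n_crosses_per_pop < 4:
            raise ValueError("n_crosses_per_pop must be >= 4 (trimming keeps n-2)")
        if self.n_pairs < 1 or self.n_genes < 1:
            raise ValueError("n_pairs and n_genes must be positive")


@dataclass
class AseSimParams:
    """Cis/trans allele-specific expression simulation parameters.

    ``kappa`` multiplies the cold allele's expression rate (cis);
    ``tau`` multiplies the cold parental background (trans).  Optional
    lognormal spread (sd of the natural log) around each produces
    gene-to-gene effect-size variation.
    """

    n_genes: int = 200
    n_snps_per_gene: int = 4
    reads_per_gene: float = 1000.0
    kappa: float = 1.0
    tau: float = 1.0
    kappa_log_sd: float = 0.0
    tau_log_sd: float = 0.0
    parental_lib_size: float = 1_000_000.0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.tau <= 0:
            raise ValueError("kappa and tau must be positive")
        if self.n_genes < 1 or self.n_snps_per_gene < 1:
            raise ValueError("n_genes and n_snps_per_gene must be positive")


@dataclass
class PopGenSimParams:
    """Balding-Nichols genotype simulation parameters for one arm."""

    n_sites: int = 5000
    n_haplotypes_per_pop: int = 40
    baseline_fst: float = 0.05
    n_outlier_loci: int = 0
    outlier_delta_p: float = 0.8
    arm: str = "2L"
    arm_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_fst < 1.0:
            raise ValueError("baseline_fst must be in [0, 1)")
        if not 0.0 <= self.outlier_delta_p <= 1.0:
            raise ValueError("outlier_delta_p must be in [0, 1]")
        if self.arm not in CHROM_ARMS:
            raise ValueError(f"unknown arm {self.arm}")


# ---------------------------------------------------------------------------
# expression study

def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_study(params: StudySimParams, seed: int
                   ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the full paired-population expression study.

    Returns (raw count matrix with metadata, per-gene truth table, gene
    annotation).  Truth columns: ``differentiated``, ``parallel``,
    ``chrom_arm`` and one ``dir_<pair>`` column per pair (cold_up /
    cold_down / none).  Differentiated genes carry a 2**effect_lfc
    fold-change in the cold population of each pair; parallel genes share
    one direction across pairs, the rest draw directions independently.
    """
    rng = np.random.default_rng(seed)
    p = params
    pairs = [PAIR_LABELS[i] if i < len(PAIR_LABELS) else f"P{i + 1}"
             for i in range(p.n_pairs)]
    genes = [f"g{i:05d}" for i in range(p.n_genes)]

    n_diff = int(round(p.n_genes * p.frac_differentiated))
    if p.frac_differentiated > 0 and n_diff < 1:
        logger.warning("frac_differentiated too small for n_genes; 0 differentiated genes")
    diff_idx = rng.choice(p.n_genes, size=n_diff, replace=False)
    n_par = int(round(n_diff * p.frac_parallel))
    par_idx = set(diff_idx[:n_par])

    truth = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    truth["differentiated"] = False
    truth.iloc[diff_idx, truth.columns.get_loc("differentiated")] = True
    truth["parallel"] = [i in par_idx for i in range(p.n_genes)]

    shared_dir = rng.choice(["cold_up", "cold_down"], size=p.n_genes)
    for pair in pairs:
        d = np.full(p.n_genes, "none", dtype=object)
        indep = rng.choice(["cold_up", "cold_down"], size=p.n_genes)
        for i in diff_idx:
            d[i] = shared_dir[i] if i in par_idx else indep[i]
        truth[f"dir_{pair}"] = d

    # annotation: X-linked fraction, rest uniform over autosomal arms
    arms = np.where(rng.random(p.n_genes) < p.frac_x_linked, "X",
                    rng.choice([a for a in CHROM_ARMS if a != "X"], size=p.n_genes))
    truth["chrom_arm"] = arms
    ann_rows = []
    for g, arm in zip(genes, arms):
        lo, hi = DEFAULT_ARM_INTERVALS[arm]
        start = int(rng.integers(lo, hi - 10_000))
        ann_rows.append((g, arm, start, start + int(rng.integers(500, 10_000)), "+"))
    annotation = pd.DataFrame(ann_rows,
                              columns=["gene_id", "chrom_arm", "start", "end", "strand"])

    base = rng.lognormal(mean=0.0, sigma=1.5, size=p.n_genes)
    fold = 2.0 ** p.effect_lfc

    cols, meta_rows, blocks = [], [], []
    for pair in pairs:
        for cls in ("cold", "warm"):
            popname = f"{pair}_{cls}"
            rel = base.copy()
            if cls == "cold":
                dirs = truth[f"dir_{pair}"].to_numpy()
                rel = np.where(dirs == "cold_up", rel * fold, rel)
                rel = np.where(dirs == "cold_down", rel / fold, rel)
                if p.skew_pair == pair and p.skew_n_genes > 0:
                    top = np.argsort(base)[-p.skew_n_genes:]
                    rel[top] *= p.skew_factor
            prob = rel / rel.sum()
            for stage in p.stages:
                for k in range(p.n_crosses_per_pop):
                    lib = p.lib_size_mean * rng.lognormal(0.0, p.lib_size_log_sd)
                    counts = _nb_counts(rng, lib * prob, p.dispersion)
                    sid = f"{popname}_{stage}_c{k + 1}"
                    cols.append(sid)
                    blocks.append(counts)
                    meta_rows.append((sid, pair, popname, cls, stage,
                                      f"{popname}_x{k + 1}",
                                      "female" if stage == "adult" else "mixed"))
    counts = pd.DataFrame(np.column_stack(blocks), index=pd.Index(genes, name="feature_id"),
                          columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "pair", "population",
                                            "thermal_class", "stage", "cross_id",
                                            "sex_mix"]).set_index("sample_id")
    return ExpressionMatrix(counts, meta), truth, annotation


def simulate_junction_study(
    params: StudySimParams, seed: int,
    n_clusters: int = 200, reads_per_cluster: float = 200.0,
    usage_shift: float = 0.2,
) -> tuple[JunctionClusterTable, pd.DataFrame, pd.DataFrame]:
    """Simulate intron-cluster junction counts with known usage shifts.

    Clusters have 2-4 junctions; per sample the cluster total is Poisson
    and junction counts are multinomial given the population's true usage
    frequencies.  A ``frac_differentiated`` share of clusters shifts the
    first junction's usage by ``usage_shift`` in the cold population.
    Returns (junction table, sample metadata, per-junction truth).
    """
    rng = np.random.default_rng(seed)
    p = params
    pairs = [PAIR_LABELS[i] if i < len(PAIR_LABELS) else f"P{i + 1}"
             for i in range(p.n_pairs)]
    sizes = rng.choice([2, 3, 4], size=n_clusters)
    jids, cids, gids = [], [], []
    base_usage = []
    for c, k in enumerate(sizes):
        cid, gid = f"clu{c:04d}", f"jg{c:04d}"
        u = rng.dirichlet(np.full(k, 5.0))
        for j in range(k):
            jids.append(f"{cid}_j{j + 1}")
            cids.append(cid)
            gids.append(gid)
        base_usage.append(u)
    diff_cluster = rng.random(n_clusters) < p.frac_differentiated

    cols, meta_rows, blocks = [], [], []
    for pair in pairs:
        for cls in ("cold", "warm"):
            popname = f"{pair}_{cls}"
            for stage in p.stages:
                for k in range(p.n_crosses_per_pop):
                    sid = f"{popname}_{stage}_c{k + 1}"
                    col = np.empty(len(jids), dtype=int)
                    off = 0
                    for c, ksize in enumerate(sizes):
                        u = base_usage[c].copy()
                        if diff_cluster[c] and cls == "cold":
                            shift = min(usage_shift, 1.0 - u[0])
                            u[0] += shift
                            u[1:] *= (1.0 - u[0]) / max(u[1:].sum(), 1e-12)
                        tot = rng.poisson(reads_per_cluster)
                        col[off:off + ksize] = rng.multinomial(tot, u / u.sum())
                        off += ksize
                    cols.append(sid)
                    blocks.append(col)
                    meta_rows.append((sid, pair, popname, cls, stage,
                                      f"{popname}_x{k + 1}",
                                      "female" if stage == "adult" else "mixed"))
    counts = pd.DataFrame(np.column_stack(blocks),
                          index=pd.Index(jids, name="junction_id"), columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "pair", "population",
                                            "thermal_class", "stage", "cross_id",
                                            "sex_mix"]).set_index("sample_id")
    truth = pd.DataFrame({
        "cluster_id": cids,
        "gene_id": gids,
        "differentiated": [diff_cluster[int(c[3:7])] for c in cids],
    }, index=counts.index)
    table = JunctionClusterTable(counts,
                                 pd.Series(cids, index=counts.index),
                                 pd.Series(gids, index=counts.index))
    return table, meta, truth


# ---------------------------------------------------------------------------
# allele-specific expression

def simulate_ase_experiment(params: AseSimParams, seed: int
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate F1 allelic counts and parental expression counts.

    Per gene, informative F1 reads are split across SNPs and each read
    derives from the cold allele with probability kappa/(kappa+1).  The
    warm parent expresses the gene at a baseline rate q; the cold parent
    at q*kappa*tau, so the expected cold parental proportion is
    kappa*tau/(kappa*tau+1) (for q << 1 and equal library sizes).

    Returns (allelic count table, parental expression table, truth).
    """
    rng = np.random.default_rng(seed)
    p = params
    kappa = p.kappa * np.exp(rng.normal(0.0, p.kappa_log_sd, p.n_genes)) \
        if p.kappa_log_sd > 0 else np.full(p.n_genes, p.kappa)
    tau = p.tau * np.exp(rng.normal(0.0, p.tau_log_sd, p.n_genes)) \
        if p.tau_log_sd > 0 else np.full(p.n_genes, p.tau)

    # baseline expression small relative to library so binomial p stays < 1
    q = np.full(p.n_genes, 1e-4)
    allelic_rows, parental_rows, truth_rows = [], [], []
    for g in range(p.n_genes):
        gid = f"a{g:05d}"
        depth = rng.poisson(p.reads_per_gene)
        snp_depths = rng.multinomial(depth, np.full(p.n_snps_per_gene,
                                                    1.0 / p.n_snps_per_gene))
        p_cold = kappa[g] / (kappa[g] + 1.0)
        for s, d in enumerate(snp_depths):
            cold = int(rng.binomial(d, p_cold)) if d > 0 else 0
            allelic_rows.append((gid, s + 1, cold, int(d) - cold, "cross1"))
        e_w = int(rng.binomial(int(p.parental_lib_size), q[g]))
        rate_c = min(q[g] * kappa[g] * tau[g], 1.0)
        e_c = int(rng.binomial(int(p.parental_lib_size), rate_c))
        parental_rows.append((gid, "cross1", e_c, e_w,
                              int(p.parental_lib_size), int(p.parental_lib_size)))
        truth_rows.append((gid, float(kappa[g]), float(tau[g]),
                           kappa[g] / (kappa[g] + 1.0),
                           kappa[g] * tau[g] / (kappa[g] * tau[g] + 1.0)))
    allelic = pd.DataFrame(allelic_rows, columns=["gene_id", "snp_pos",
                                                  "cold_reads", "warm_reads",
                                                  "cross_id"])
    parental = pd.DataFrame(parental_rows, columns=["gene_id", "cross_id",
                                                    "e_cold", "e_warm",
                                                    "lib_cold", "lib_warm"])
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "kappa", "tau",
                                              "true_p_f1", "true_r_f0"]
                         ).set_index("gene_id")
    return allelic, parental, truth


# ---------------------------------------------------------------------------
# population genotypes

def simulate_genotypes(params: PopGenSimParams, seed: int
                       ) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate biallelic SNP haplotypes for a cold/warm population pair.

    Ancestral frequencies are uniform on (0.05, 0.95); each population's
    frequency is a Balding-Nichols Beta draw at the stated baseline F_ST
    (or the ancestral frequency exactly when baseline_fst = 0).  Planted
    outlier loci receive an extra +/- outlier_delta_p/2 frequency shift in
    opposite directions, clipped to [0, 1] with a log message.  Positions
    are uniform over the arm's high-recombination interval.

    Returns (GenotypeMatrix with populations 'cold' and 'warm', haplotype
    matrix for VCF export, per-site truth).
    """
    rng = np.random.default_rng(seed)
    p = params
    lo, hi = p.arm_interval or DEFAULT_ARM_INTERVALS[p.arm]
    pos = np.sort(rng.choice(np.arange(lo, hi), size=p.n_sites, replace=False))
    anc = rng.uniform(0.05, 0.95, p.n_sites)
    if p.baseline_fst > 0:
        f = p.baseline_fst
        a, b = anc * (1 - f) / f, (1 - anc) * (1 - f) / f
        freq_cold = rng.beta(a, b)
        freq_warm = rng.beta(a, b)
    else:
        freq_cold = anc.copy()
        freq_warm = anc.copy()
    is_outlier = np.zeros(p.n_sites, dtype=bool)
    if p.n_outlier_loci > 0:
        out_idx = rng.choice(p.n_sites, size=p.n_outlier_loci, replace=False)
        is_outlier[out_idx] = True
        half = p.outlier_delta_p / 2.0
        new_c = freq_cold[out_idx] + half
        new_w = freq_warm[out_idx] - half
        n_clip = int((new_c > 1).sum() + (new_w < 0).sum())
        if n_clip:
            logger.info("outlier shift clipped at %d site boundaries", n_clip)
        freq_cold[out_idx] = np.clip(new_c, 0.0, 1.0)
        freq_warm[out_idx] = np.clip(new_w, 0.0, 1.0)

    n_hap = p.n_haplotypes_per_pop
    hap_cold = rng.random((p.n_sites, n_hap)) < freq_cold[:, None]
    hap_warm = rng.random((p.n_sites, n_hap)) < freq_warm[:, None]
    haplotypes = pd.DataFrame(
        np.hstack([hap_cold, hap_warm]).astype(int),
        columns=[f"cold_h{i + 1}" for i in range(n_hap)]
        + [f"warm_h{i + 1}" for i in range(n_hap)])
    sites = pd.DataFrame({"chrom_arm": p.arm, "pos": pos})
    alt = pd.DataFrame({"cold": hap_cold.sum(axis=1), "warm": hap_warm.sum(axis=1)})
    tot = pd.DataFrame({"cold": n_hap, "warm": n_hap}, index=range(p.n_sites))
    truth = pd.DataFrame({"pos": pos, "freq_cold": freq_cold, "freq_warm": freq_warm,
                          "is_outlier": is_outlier})
    return GenotypeMatrix(sites, alt, tot), haplotypes, truth
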