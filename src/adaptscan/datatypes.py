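"""In-memory containers for the expression, annotation and genotype layers.

Conventions
-----------
* Counts are features x samples, metadata one row per sample (aligned to the
  count columns).
* Genomic coordinates are 0-based half-open internally; GFF/BED readers and
  writers convert at the boundary.
* Genotype data are reduced to per-site, per-population alternate-allele
  counts plus the number of called haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHROM_ARMS

META_COLUMNS = ("pair", "population", "thermal_class", "stage", "cross_id", "sex_mix")

THERMAL_CLASSES = ("cold", "warm")
STAGES = ("larva", "pupa", "adult")


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata invariants and return a normalized copy.

    Each sample belongs to one population, each population to one pair, and
    the two populations of a pair have opposite thermal classes.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    meta = meta.copy()
    if meta.index.duplicated().any():
        dupes = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    bad = set(meta["thermal_class"]) - set(THERMAL_CLASSES)
    if bad:
        raise ValueError(f"unknown thermal_class values: {sorted(bad)}")
    pop_pair = meta.groupby("population")["pair"].nunique()
    if (pop_pair > 1).any():
        raise ValueError("a population maps to more than one pair")
    pop_class = meta.groupby("population")["thermal_class"].nunique()
    if (pop_class > 1).any():
        raise ValueError("a population maps to more than one thermal class")
    for pair, sub in meta.groupby("pair"):
        classes = set(sub["thermal_class"])
        if len(set(sub["population"])) == 2 and classes != {"cold", "warm"}:
            raise ValueError(f"pair {pair}: populations do not span cold/warm")
    return meta


@dataclass
class ExpressionMatrix:
    """Feature-by-sample count matrix with aligned sample metadata.

    ``counts`` rows are features, columns are sample ids matching
    ``meta.index``.  ``feature_kind`` distinguishes gene expression
    abundance from junction usage-frequency traits (the latter are already
    proportions within an intron cluster).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    feature_kind: str = "gene_expression"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene_expression", "junction_frequency"):
            raise ValueError(f"bad feature_kind: {self.feature_kind}")
        self.meta = validate_sample_meta(self.meta)
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("count columns and metadata rows are not aligned")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        vals = self.counts.to_numpy()
        # junction frequencies may be undefined (NaN) where a cluster has
        # zero reads in a sample; raw counts must be complete
        if self.feature_kind == "gene_expression" and np.isnan(vals).any():
            raise ValueError("NaN counts")
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, mask: pd.Series) -> "ExpressionMatrix":
        keep = self.meta.index[mask.loc[self.meta.index]]
        return ExpressionMatrix(self.counts[keep], self.meta.loc[keep], self.feature_kind)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[feature_ids], self.meta, self.feature_kind)

    def populations_of_pair(self, pair: str) -> dict[str, str]:
        """Map thermal class -> population name for one pair."""
        sub = self.meta[self.meta["pair"] == pair]
        if sub.empty:
            raise ValueError(f"no samples for pair {pair}")
        out = {}
        for cls, grp in sub.groupby("thermal_class"):
            pops = sorted(set(grp["population"]))
            if len(pops) != 1:
                raise ValueError(f"pair {pair}: expected one {cls} population, got {pops}")
            out[cls] = pops[0]
        if set(out) != {"cold", "warm"}:
            raise ValueError(f"pair {pair}: missing a thermal class")
        return out

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def validate_gene_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (0-based half-open coordinates).

    Required columns: gene_id, chrom_arm, start, end, strand.  Strand is
    carried through but ignored by every statistic.
    """
    required = ["gene_id", "chrom_arm", "start", "end", "strand"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    ann = ann.copy()
    bad_arm = set(ann["chrom_arm"]) - set(CHROM_ARMS)
    if bad_arm:
        raise ValueError(f"unknown chromosome arms: {sorted(bad_arm)}")
    if (ann["start"] >= ann["end"]).any():
        raise ValueError("annotation has start >= end")
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    return ann


@dataclass
class GenotypeMatrix:
    """Per-site alternate-allele counts by population.

    ``sites`` has one row per biallelic SNP with columns ``chrom_arm`` and
    ``pos`` (0-based), sorted by position within each arm.  ``alt_counts``
    and ``totals`` are aligned tables, one column per population, giving
    the alternate-allele count and the number of successfully called
    haplotypes at the site (missing calls reduce the total).
    """

    sites: pd.DataFrame
    alt_counts: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.sites)
        if len(self.alt_counts) != n or len(self.totals) != n:
            raise ValueError("site, alt_counts and totals row counts differ")
        if list(self.alt_counts.columns) != list(self.totals.columns):
            raise ValueError("population columns differ between counts and totals")
        if (self.alt_counts.to_numpy() > self.totals.to_numpy()).any():
            raise ValueError("alt count exceeds called haplotypes")
        if (self.alt_counts.to_numpy() < 0).any():
            raise ValueError("negative allele count")
        for arm, sub in self.sites.groupby("chrom_arm"):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on arm {arm}")

    @property
    def populations(self) -> list[str]:
        return list(self.alt_counts.columns)

    def arm(self, arm: str) -> "GenotypeMatrix":
        mask = (self.sites["chrom_arm"] == arm).to_numpy()
        return GenotypeMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.alt_counts.loc[mask].reset_index(drop=True),
            self.totals.loc[mask].reset_index(drop=True),
        )

    def frequencies(self, pop: str) -> np.ndarray:
        """Sample alternate-allele frequency per site (NaN where no calls)."""
        tot = self.totals[pop].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.alt_counts[pop].to_numpy(float) / tot, np.nan)


@dataclass
class JunctionClusterTable:
    """Junction excision counts grouped into alternative-intron clusters.

    ``counts`` rows are junction ids, columns samples; ``cluster_of`` maps
    each junction to its cluster; ``gene_of`` maps junctions to genes (a
    cluster never spans genes here).
    """

    counts: pd.DataFrame
    cluster_of: pd.Series
    gene_of: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.cluster_of.index):
            raise ValueError("cluster assignment index mismatch")
        if self.gene_of is not None and not self.counts.index.equals(self.gene_of.index):
            raise ValueError("gene assignment index mismatch")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative junction counts")
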