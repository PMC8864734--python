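"""Readers and writers for the tabular interchange formats.

All tabular files are TSV with a header row and ``.`` for missing values.
Expression matrices are written as feature-by-sample tables; genotypes are
accepted either as VCF (haploid or diploid GT fields, parsed with pysam)
or as a site-by-population allele-count table, which round-trips counts
exactly.  BED input is 0-based half-open (as internal coordinates); GFF3 is
1-based inclusive and converted on read.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, validate_gene_annotation

logger = logging.getLogger("adaptscan")

MISSING = "."


# ---------------------------------------------------------------------------
# expression matrices

def load_expression_matrix(path, meta_path, feature_kind: str = "gene_expression") -> ExpressionMatrix:
    """Load a feature-by-sample count table and its sample metadata.

    Samples present in the counts but absent from the metadata are dropped
    with a warning; a metadata row without a count column is ignored.
    Negative counts are a hard error.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id", dtype=str)
    unmatched = [s for s in counts.columns if s not in meta.index]
    if unmatched:
        logger.warning("dropping %d sample(s) without metadata: %s",
                       len(unmatched), unmatched)
        counts = counts.drop(columns=unmatched)
    if counts.shape[1] == 0:
        raise ValueError("no samples remain after metadata matching")
    meta = meta.loc[counts.columns]
    return ExpressionMatrix(counts, meta, feature_kind)


def write_expression_matrix(expr: ExpressionMatrix, path, meta_path) -> None:
    counts = expr.counts.copy()
    counts.index.name = "feature_id"
    counts.to_csv(path, sep="\t")
    meta = expr.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# gene annotation

def load_annotation(path) -> pd.DataFrame:
    """Load gene annotation from BED (.bed) or GFF3 (.gff/.gff3).

    Returns a validated table with 0-based half-open coordinates.
    """
    path = str(path)
    if path.endswith(".bed"):
        return _load_bed(path)
    if path.endswith((".gff", ".gff3")):
        return _load_gff3(path)
    raise ValueError(f"unrecognised annotation format: {path}")


def _load_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            rows.append((f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                         f[0], int(f[1]), int(f[2]), strand))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom_arm", "start", "end", "strand"])
    return validate_gene_annotation(ann)


def _load_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id") or f"{f[0]}:{f[3]}"
            # GFF3 is 1-based inclusive -> 0-based half-open
            rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom_arm", "start", "end", "strand"])
    return validate_gene_annotation(ann)


def write_annotation_bed(ann: pd.DataFrame, path) -> None:
    ann = validate_gene_annotation(ann)
    with open(path, "w") as fh:
        for _, r in ann.iterrows():
            fh.write(f"{r.chrom_arm}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# genotypes

def load_genotypes(path, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load genotypes from VCF or a site-by-population allele-count table.

    ``populations`` maps sample id -> population and is required for VCF
    input.  Multi-allelic sites are skipped (count logged); unsorted
    positions are sorted with a warning; missing calls reduce the number of
    called haplotypes at the site.
    """
    path = str(path)
    if path.endswith(".vcf"):
        if populations is None:
            raise ValueError("VCF input requires a sample->population mapping")
        return _load_vcf(path, populations)
    return load_genotype_table(path)


def _load_vcf(path, populations: dict[str, str]) -> GenotypeMatrix:
    import pysam

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    missing_meta = [s for s in samples if s not in populations]
    if missing_meta:
        logger.warning("VCF samples without population assignment ignored: %s",
                       missing_meta)
    pops = sorted(set(populations[s] for s in samples if s in populations))
    rows, alt_rows, tot_rows = [], [], []
    n_multi = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        alt = dict.fromkeys(pops, 0)
        tot = dict.fromkeys(pops, 0)
        for s in samples:
            if s not in populations:
                continue
            gt = rec.samples[s].get("GT")
            if gt is None:
                continue
            for allele in gt:
                if allele is None:
                    continue
                tot[populations[s]] += 1
                alt[populations[s]] += int(allele != 0)
        rows.append((rec.chrom, rec.pos - 1))  # VCF is 1-based
        alt_rows.append([alt[p] for p in pops])
        tot_rows.append([tot[p] for p in pops])
    if n_multi:
        logger.warning("skipped %d multi-allelic site(s)", n_multi)
    sites = pd.DataFrame(rows, columns=["chrom_arm", "pos"])
    alt_counts = pd.DataFrame(alt_rows, columns=pops)
    totals = pd.DataFrame(tot_rows, columns=pops)
    return _sorted_genotypes(sites, alt_counts, totals)


def load_genotype_table(path) -> GenotypeMatrix:
    """Read the TSV fallback: chrom_arm, pos, then alt_<pop> / tot_<pop> pairs."""
    tab = pd.read_csv(path, sep="\t", na_values=[MISSING])
    pops = sorted(c[4:] for c in tab.columns if c.startswith("alt_"))
    sites = tab[["chrom_arm", "pos"]].copy()
    alt_counts = tab[[f"alt_{p}" for p in pops]].copy()
    alt_counts.columns = pops
    totals = tab[[f"tot_{p}" for p in pops]].copy()
    totals.columns = pops
    return _sorted_genotypes(sites, alt_counts, totals.astype(int))


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    out = gm.sites.copy()
    for p in gm.populations:
        out[f"alt_{p}"] = gm.alt_counts[p].to_numpy()
        out[f"tot_{p}"] = gm.totals[p].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def write_vcf(sites: pd.DataFrame, haplotypes: pd.DataFrame, path) -> None:
    """Write haploid genotypes as a minimal VCF.

    ``sites`` needs chrom_arm and pos (0-based); ``haplotypes`` is a
    site-by-haplotype 0/1 matrix (-1 = missing) whose columns are sample
    names.
    """
    arms = list(dict.fromkeys(sites["chrom_arm"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for arm in arms:
            length = int(sites.loc[sites["chrom_arm"] == arm, "pos"].max()) + 2
            fh.write(f"##contig=<ID={arm},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(haplotypes.columns) + "\n")
        hap = haplotypes.to_numpy()
        for i, (_, r) in enumerate(sites.iterrows()):
            gts = "\t".join("." if g < 0 else str(int(g)) for g in hap[i])
            fh.write(f"{r.chrom_arm}\t{int(r.pos) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _sorted_genotypes(sites, alt_counts, totals) -> GenotypeMatrix:
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom_arm"].to_numpy()))
    if not (order == np.arange(len(sites))).all():
        logger.warning("genotype positions unsorted; sorting")
        sites = sites.iloc[order].reset_index(drop=True)
        alt_counts = alt_counts.iloc[order].reset_index(drop=True)
        totals = totals.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(sites, alt_counts, totals)
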