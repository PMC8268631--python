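"""Gene-centric preprocessing.

Reproduces the standard preparation applied before map training: log10
transform of raw intensities, quantile normalization across samples,
aggregation of CpG beta values into one promoter-mean beta per gene,
exclusion of sex-chromosome genes, and per-gene centering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import (OmicsMatrix, ConfigurationError, cpg_sample_columns,
                     validate_cpg_table, validate_gene_annotation)

#: Promoter window around the TSS, in strand-relative coordinates:
#: 2 kb upstream (5') to 200 bp downstream (3'), both ends inclusive.
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200


def log10_transform(m: OmicsMatrix, offset: float = 1.0) -> OmicsMatrix:
    """log10(x + offset) for raw non-negative intensities.

    The offset guards zeros; synthetic cohorts are generated on log scale
    already and must not be passed through this.
    """
    values = m.values
    if (values + offset <= 0).any():
        raise ConfigurationError("log transform requires x + offset > 0")
    out = pd.DataFrame(np.log10(values + offset), index=m.gene_ids,
                       columns=m.sample_ids)
    return OmicsMatrix(out, "expression_log10")


def quantile_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Force every sample column onto the common distribution of mean
    order statistics, preserving within-column ranks.

    Ties receive the mean of the normalized values of their tied ranks
    (average-rank interpolation into the reference distribution).
    """
    values = m.values
    if values.size == 0:
        return m
    n_genes = values.shape[0]
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)  # mean k-th order statistic
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        # average ranks map ties onto the mean of their tied reference slots
        ranks = rankdata(values[:, j], method="average")  # 1..n
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    return OmicsMatrix(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids),
                       m.layer)


def promoter_window(tss: int, strand: str) -> Tuple[int, int]:
    """Closed 1-based interval [start, end] of the promoter for one gene."""
    if strand == "+":
        return tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    return tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM


@dataclass
class PromoterAggregation:
    """Result of CpG-to-gene aggregation."""

    matrix: OmicsMatrix
    dropped_genes: list  # genes with zero CpGs in their promoter window
    cpgs_per_gene: pd.Series


def promoter_beta(cpgs: pd.DataFrame, ann: pd.DataFrame) -> PromoterAggregation:
    """Average CpG betas inside each gene's promoter window.

    The window spans 2 kb upstream to 200 bp downstream of the TSS,
    strand-relative ("upstream" = 5'), both ends inclusive, 1-based.
    Genes with no CpG in the window are dropped and reported.  CpGs with a
    missing beta in a sample are excluded from that sample's mean
    (pairwise deletion).
    """
    validate_cpg_table(cpgs)
    validate_gene_annotation(ann)
    cpgs = cpgs.reset_index(drop=True)
    shared_chroms = set(ann["chromosome"]) & set(cpgs["chromosome"])
    if not shared_chroms:
        raise ConfigurationError(
            "no chromosome shared between CpG table and gene annotation")
    sample_cols = cpg_sample_columns(cpgs)
    betas = cpgs[sample_cols].to_numpy(dtype=float)
    rows = {}
    counts = {}
    dropped = []
    by_chrom = {chrom: grp for chrom, grp in cpgs.groupby("chromosome")}
    for rec in ann.itertuples(index=False):
        grp = by_chrom.get(rec.chromosome)
        if grp is None:
            dropped.append(rec.gene_id)
            continue
        lo, hi = promoter_window(int(rec.tss), rec.strand)
        pos = grp["position"].to_numpy()
        inside = grp.index[(pos >= lo) & (pos <= hi)]
        if len(inside) == 0:
            dropped.append(rec.gene_id)
            continue
        sub = betas[cpgs.index.get_indexer(inside)]
        with np.errstate(invalid="ignore"):
            rows[rec.gene_id] = np.nanmean(sub, axis=0)
        counts[rec.gene_id] = len(inside)
    if not rows:
        raise ConfigurationError("no gene has CpGs inside its promoter window")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_cols)
    df.index.name = "gene_id"
    return PromoterAggregation(OmicsMatrix(df, "methylation_beta"),
                               dropped, pd.Series(counts, name="n_cpgs"))


_SEX_CHROMS = {"x", "y", "chrx", "chry", "23", "24"}


def drop_sex_chromosomes(m: OmicsMatrix, ann: pd.DataFrame) -> OmicsMatrix:
    """Remove genes on chrX/chrY (case-insensitive, with or without the
    'chr' prefix) to avoid a sex bias in downstream maps."""
    validate_gene_annotation(ann)
    chrom = ann.set_index("gene_id")["chromosome"].reindex(m.gene_ids)
    if chrom.isna().any():
        missing = m.gene_ids[chrom.isna()][:5].tolist()
        raise ConfigurationError(f"annotation missing for genes {missing} ...")
    is_sex = chrom.str.lower().isin(_SEX_CHROMS)
    return OmicsMatrix(m.data.loc[~is_sex.to_numpy()], m.layer)


def center_genes(m: OmicsMatrix) -> OmicsMatrix:
    """Subtract each gene's mean across samples (rows become zero-mean)."""
    values = m.values
    centered = values - values.mean(axis=1, keepdims=True)
    return OmicsMatrix(pd.DataFrame(centered, index=m.gene_ids,
                                    columns=m.sample_ids), "centered")
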