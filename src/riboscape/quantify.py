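"""FPKM normalisation, translation efficiency (TE), and TE binning.

TE is the ratio of ribosome-footprint FPKM to RNA FPKM for a gene:
TE = FPKM(Ribo-seq) / FPKM(RNA-seq).  TE is computed per sample and
averaged per group for binning; genes with zero RNA FPKM have no defined
TE and are reported as missing.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .datamodel import ExpressionTable, Layer, Unit

#: the four log2(TE) bins, lowest to highest
TE_BIN_LABELS = ["<=-1", "(-1,0]", "(0,1]", ">1"]


def fpkm(table: ExpressionTable) -> ExpressionTable:
    """Fragments per kilobase of feature per million mapped reads.

    FPKM[g, s] = count[g, s] * 1e9 / (library_size[s] * length[g]).
    """
    if table.unit != Unit.COUNT:
        raise ValueError("fpkm() expects a count table")
    if table.gene_lengths is None:
        raise ValueError("gene_lengths required for FPKM")
    lens = table.gene_lengths
    libs = table.library_sizes
    if (lens <= 0).any() or lens.isna().any():
        bad = lens.index[(lens <= 0) | lens.isna()].tolist()
        raise ValueError(f"non-positive/missing gene lengths: {bad[:5]}")
    if (libs <= 0).any():
        raise ValueError("zero library size")
    vals = table.values * 1e9
    vals = vals.div(libs, axis=1).div(lens, axis=0)
    return ExpressionTable(
        layer=table.layer,
        unit=Unit.FPKM,
        values=vals,
        gene_lengths=lens,
        library_sizes=libs,
    )


def translation_efficiency(
    fpkm_ribo: ExpressionTable,
    fpkm_rna: ExpressionTable,
    rna_floor: float = 0.0,
) -> ExpressionTable:
    """Per-gene, per-sample TE = ribo FPKM / RNA FPKM.

    Missing (NaN) where RNA FPKM <= ``rna_floor`` (default 0: only an exact
    zero denominator is undefined).
    """
    if not fpkm_ribo.samples.equals(fpkm_rna.samples):
        unmatched = set(fpkm_ribo.samples) ^ set(fpkm_rna.samples)
        raise ValueError(f"sample sets differ: {sorted(unmatched)}")
    genes = fpkm_ribo.genes.intersection(fpkm_rna.genes)
    r = fpkm_ribo.values.loc[genes]
    m = fpkm_rna.values.loc[genes]
    te = r.where(m > rna_floor) / m.where(m > rna_floor)
    return ExpressionTable(layer=Layer.TE, unit=Unit.RATIO, values=te)


def group_means(table: ExpressionTable, groups: pd.Series) -> pd.DataFrame:
    """Mean of each gene's values within each sample group (NaN-aware)."""
    return table.values.T.groupby(groups).mean().T


def te_bins(te_means: pd.Series) -> pd.Series:
    """Assign each gene's (group-mean) TE to one of four log2(TE) bins.

    Bins: log2(TE) <= -1; (-1, 0]; (0, 1]; > 1.  Genes with TE <= 0 or
    missing get NaN (excluded; callers should report the exclusion count).
    """
    te = te_means.astype(float)
    valid = te > 0
    log2te = np.log2(te.where(valid))
    bins = pd.cut(
        log2te,
        bins=[-np.inf, -1.0, 0.0, 1.0, np.inf],
        labels=TE_BIN_LABELS,
        right=True,
    )
    return pd.Series(bins, index=te.index, name="te_bin")


def te_bin_counts(bins: pd.Series) -> Dict[str, int]:
    """Bin occupancy plus the number of excluded (unbinned) genes."""
    counts = bins.value_counts().reindex(TE_BIN_LABELS, fill_value=0)
    out = {str(k): int(v) for k, v in counts.items()}
    out["excluded"] = int(bins.isna().sum())
    return out
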