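"""Footprint quality control.

Length filtering (20-40 nt retained by default), assignment of footprints
to 5'UTR/CDS/3'UTR, 3-nt periodicity by read length, P-site offset
estimation from the meta-profile of 5' ends around annotated start codons,
and sample-level correlation/PCA on log10(FPKM + 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import ExpressionTable, TranscriptModel

log = logging.getLogger("riboscape")

REGIONS = ["5UTR", "CDS", "3UTR"]
DEFAULT_OFFSET = 12
OFFSET_CANDIDATES = range(10, 16)


@dataclass
class QcReport:
    """Collected per-sample QC metrics."""

    length_hist: pd.DataFrame            # lengths x samples
    region_fractions: pd.DataFrame       # samples x regions
    frame_fractions: pd.DataFrame        # per length (+ 'pooled'): f0, f1, f2
    offsets: Dict[int, int]              # read length -> P-site offset
    offset_flags: Dict[int, str] = field(default_factory=dict)
    correlation: Optional[pd.DataFrame] = None
    pca: Optional[pd.DataFrame] = None   # samples x PC1/PC2

    def to_json(self) -> str:
        def as_dict(df: pd.DataFrame) -> dict:
            return df.rename(index=str, columns=str).to_dict()

        return json.dumps(
            {
                "length_hist": as_dict(self.length_hist),
                "region_fractions": as_dict(self.region_fractions),
                "frame_fractions": as_dict(self.frame_fractions),
                "offsets": {str(k): v for k, v in self.offsets.items()},
                "offset_flags": {str(k): v for k, v in self.offset_flags.items()},
                "correlation": None if self.correlation is None else self.correlation.to_dict(),
                "pca": None if self.pca is None else self.pca.to_dict(),
            },
            indent=2,
            sort_keys=True,
        )


def filter_by_length(
    footprints: pd.DataFrame, min_len: int = 20, max_len: int = 40
) -> pd.DataFrame:
    """Retain footprints with min_len <= read_length <= max_len."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    keep = footprints["read_length"].between(min_len, max_len)
    removed = int((~keep).sum())
    if removed:
        log.info("length filter removed %d of %d footprints", removed, len(footprints))
    return footprints.loc[keep].reset_index(drop=True)


def _model_frame(models: Dict[str, TranscriptModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": list(models),
            "cds_start": [m.cds_start for m in models.values()],
            "cds_end": [m.cds_end for m in models.values()],
            "tx_len": [m.length for m in models.values()],
        }
    ).set_index("transcript_id")


def _anchor_positions(
    footprints: pd.DataFrame,
    mode: str,
    offsets: Optional[Dict[int, int]],
) -> pd.Series:
    if mode == "five_prime":
        return footprints["five_prime_pos"]
    if mode == "psite":
        if offsets is None:
            raise ValueError("psite mode requires offsets")
        off = footprints["read_length"].map(offsets).fillna(DEFAULT_OFFSET)
        return footprints["five_prime_pos"] + off.astype(int)
    raise ValueError(f"unknown anchor mode {mode!r}")


def assign_regions(
    footprints: pd.DataFrame,
    models: Dict[str, TranscriptModel],
    mode: str = "five_prime",
    offsets: Optional[Dict[int, int]] = None,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Label each footprint 5UTR/CDS/3UTR by its anchor position.

    Returns (per-record labels, per-sample region fractions).  Anchors past
    the transcript end are labelled ``out_of_bounds`` and excluded from the
    fractions.
    """
    mf = _model_frame(models)
    joined = footprints.join(mf, on="transcript_id")
    anchor = _anchor_positions(footprints, mode, offsets)
    labels = pd.Series(
        np.select(
            [
                (anchor < 0) | (anchor >= joined["tx_len"]),
                anchor < joined["cds_start"],
                anchor < joined["cds_end"],
            ],
            ["out_of_bounds", "5UTR", "CDS"],
            "3UTR",
        ),
        index=footprints.index,
        name="region",
    )
    ok = labels != "out_of_bounds"
    frac = (
        pd.crosstab(footprints.loc[ok, "sample_id"], labels[ok], normalize="index")
        .reindex(columns=REGIONS, fill_value=0.0)
    )
    return labels, frac


def frame_periodicity(
    footprints: pd.DataFrame,
    models: Dict[str, TranscriptModel],
    offsets: Dict[int, int],
) -> pd.DataFrame:
    """Fractions of CDS-internal P-sites per frame, by read length + pooled.

    Frame is (P-site - cds_start) mod 3; frame 0 is the first codon
    position, where actively translating ribosomes dwell longest.
    """
    mf = _model_frame(models)
    joined = footprints.join(mf, on="transcript_id")
    psite = _anchor_positions(footprints, "psite", offsets)
    in_cds = (psite >= joined["cds_start"]) & (psite < joined["cds_end"])
    if not in_cds.any():
        log.warning("no CDS-internal P-sites; periodicity table empty")
        return pd.DataFrame(columns=["f0", "f1", "f2"])
    frame = ((psite - joined["cds_start"]) % 3)[in_cds]
    length = footprints.loc[in_cds.values, "read_length"]
    tab = pd.crosstab(length, frame, normalize="index")
    tab = tab.reindex(columns=[0, 1, 2], fill_value=0.0)
    pooled = frame.value_counts(normalize=True).reindex([0, 1, 2], fill_value=0.0)
    tab.loc["pooled"] = pooled.values
    tab.columns = ["f0", "f1", "f2"]
    return tab


def estimate_psite_offsets(
    footprints: pd.DataFrame,
    models: Dict[str, TranscriptModel],
    min_reads: int = 200,
) -> Tuple[Dict[int, int], Dict[int, str]]:
    """Per-length P-site offset from 5' ends upstream of annotated starts.

    For each read length the offset is the argmax over candidates 10-15 of
    the meta-count of 5' ends at (cds_start - offset); ties resolve toward
    12.  Length classes with fewer than ``min_reads`` total reads fall back
    to the global default 12 and are flagged.
    """
    mf = _model_frame(models)
    joined = footprints.join(mf, on="transcript_id")
    delta = joined["cds_start"] - joined["five_prime_pos"]
    offsets: Dict[int, int] = {}
    flags: Dict[int, str] = {}
    for length, sub in delta.groupby(footprints["read_length"]):
        length = int(length)
        if len(sub) < min_reads:
            offsets[length] = DEFAULT_OFFSET
            flags[length] = f"sparse (n={len(sub)}), default used"
            continue
        counts = {c: int((sub == c).sum()) for c in OFFSET_CANDIDATES}
        best = max(counts.values())
        # tie-break toward the canonical mammalian offset of 12
        tied = sorted((abs(c - DEFAULT_OFFSET), c) for c, n in counts.items() if n == best)
        offsets[length] = tied[0][1]
    return offsets, flags


def sample_qc(fpkm_table: ExpressionTable) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations and 2-component PCA on log10(FPKM + 1).

    Zero-variance genes are dropped before PCA; an all-constant matrix is a
    clear error.
    """
    from sklearn.decomposition import PCA

    vals = fpkm_table.values
    if vals.shape[1] < 2:
        raise ValueError("sample_qc needs >= 2 samples")
    logged = np.log10(vals + 1.0)
    corr = logged.corr(method="pearson")
    keep = logged.var(axis=1) > 0
    if keep.sum() == 0:
        raise ValueError("zero variance: all genes constant, PCA undefined")
    mat = logged.loc[keep].T.to_numpy()
    n_comp = min(2, mat.shape[0])
    coords = PCA(n_components=n_comp, random_state=0).fit_transform(mat)
    pca = pd.DataFrame(
        coords, index=vals.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    return corr, pca


def qc_report(
    footprints: pd.DataFrame,
    models: Dict[str, TranscriptModel],
    fpkm_table: Optional[ExpressionTable] = None,
    min_len: int = 20,
    max_len: int = 40,
) -> QcReport:
    """Run the full QC stage on a footprint table."""
    fps = filter_by_length(footprints, min_len, max_len)
    hist = pd.crosstab(fps["read_length"], fps["sample_id"])
    offsets, flags = estimate_psite_offsets(fps, models)
    _, region_frac = assign_regions(fps, models, mode="five_prime")
    frames = frame_periodicity(fps, models, offsets)
    corr = pca = None
    if fpkm_table is not None:
        corr, pca = sample_qc(fpkm_table)
    return QcReport(
        length_hist=hist,
        region_fractions=region_frac,
        frame_fractions=frames,
        offsets=offsets,
        offset_flags=flags,
        correlation=corr,
        pca=pca,
    )


def plot_qc(report: QcReport, outdir) -> None:
    """Write basic QC figures (length histogram, frame bars, PCA scatter)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    fig, ax = plt.subplots()
    report.length_hist.sum(axis=1).plot.bar(ax=ax)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("footprints")
    fig.savefig(outdir / "length_hist.png", dpi=100)
    plt.close(fig)

    if "pooled" in report.frame_fractions.index:
        fig, ax = plt.subplots()
        report.frame_fractions.loc["pooled"].plot.bar(ax=ax)
        ax.set_ylabel("fraction of CDS P-sites")
        fig.savefig(outdir / "frame_pooled.png", dpi=100)
        plt.close(fig)

    if report.pca is not None:
        fig, ax = plt.subplots()
        ax.scatter(report.pca["PC1"], report.pca.get("PC2", report.pca["PC1"]))
        for name, row in report.pca.iterrows():
            ax.annotate(name, (row["PC1"], row.get("PC2", row["PC1"])))
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.savefig(outdir / "pca.png", dpi=100)
        plt.close(fig)
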