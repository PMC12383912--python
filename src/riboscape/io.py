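"""Readers and writers for the standard formats the pipeline touches.

Transcript sequences come from FASTA (via pyfaidx), transcript structure
from GTF/GFF (via gffutils; 1-based inclusive coordinates are converted to
0-based half-open here and only here), footprints from a 4-column BED-like
TSV, and count matrices from plain TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .datamodel import (
    FOOTPRINT_COLUMNS,
    ExpressionTable,
    Layer,
    TranscriptModel,
    TranscriptModelError,
    Unit,
)

log = logging.getLogger("riboscape")


@dataclass
class TranscriptomeReport:
    """Bookkeeping of what the transcriptome reader accepted and skipped."""

    n_accepted: int = 0
    skipped: Dict[str, str] = field(default_factory=dict)

    def skip(self, tx_id: str, reason: str) -> None:
        self.skipped[tx_id] = reason


def read_transcriptome(
    fasta_path: str | Path,
    gtf_path: str | Path,
    strict: bool = False,
) -> Tuple[Dict[str, TranscriptModel], TranscriptomeReport]:
    """Build one :class:`TranscriptModel` per transcript from FASTA + GTF.

    The GTF is expected in transcript space (seqid = transcript_id) with
    ``exon`` and ``CDS`` features.  UTR spans are derived from the CDS
    extent versus the exon extent.  Transcripts violating the model
    invariants are skipped (reported) unless ``strict``.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    report = TranscriptomeReport()
    models: Dict[str, TranscriptModel] = {}

    by_tx: Dict[str, Dict[str, List]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx = feat.attributes.get("transcript_id", [feat.seqid])[0]
        gene = feat.attributes.get("gene_id", [tx])[0]
        entry = by_tx.setdefault(tx, {"gene": gene, "exon": [], "CDS": []})
        # GTF is 1-based inclusive -> 0-based half-open
        entry[feat.featuretype].append((feat.start - 1, feat.end))

    missing = [tx for tx in by_tx if tx not in fasta]
    if missing:
        raise FileNotFoundError(
            f"missing FASTA sequence for annotated transcripts: {sorted(missing)}"
        )

    for tx, entry in by_tx.items():
        seq = str(fasta[tx][:])
        if not entry["CDS"]:
            report.skip(tx, "no CDS feature")
            continue
        cds_start = min(s for s, _ in entry["CDS"])
        cds_end = max(e for _, e in entry["CDS"])
        try:
            models[tx] = TranscriptModel(
                transcript_id=tx,
                gene_id=entry["gene"],
                sequence=seq,
                utr5=(0, cds_start),
                cds=(cds_start, cds_end),
                utr3=(cds_end, len(seq)),
            )
            report.n_accepted += 1
        except TranscriptModelError as exc:
            if strict:
                raise
            report.skip(tx, str(exc))
            log.warning("skipping %s: %s", tx, exc)
    return models, report


# ---------------------------------------------------------------------------
# footprint tables
# ---------------------------------------------------------------------------

def read_footprints(
    bed_path: str | Path,
    transcript_lengths: Dict[str, int] | None = None,
) -> Tuple[pd.DataFrame, int]:
    """Read a BED-like footprint table.

    Canonical dialect: TSV with header ``transcript_id five_prime_pos
    read_length sample_id`` and optionally a trailing ``count`` column for
    collapsed rows (expanded to one row per logical read).  Returns the
    table (canonical column order) and the number of rejected rows.
    """
    df = pd.read_csv(bed_path, sep="\t", dtype={"transcript_id": str, "sample_id": str})
    missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"footprint table missing columns: {missing}")
    if "count" in df.columns:
        df = df.loc[df.index.repeat(df["count"].astype(int))].drop(columns="count")
        df = df.reset_index(drop=True)
    df = df[FOOTPRINT_COLUMNS]
    bad = (df["five_prime_pos"] < 0) | (df["read_length"] <= 0)
    if transcript_lengths is not None:
        lens = df["transcript_id"].map(transcript_lengths)
        bad |= lens.isna() | (df["five_prime_pos"] >= lens.fillna(0))
    n_rejected = int(bad.sum())
    if n_rejected:
        for i in df.index[bad][:10]:
            log.warning("%s: rejected footprint row %d: %s", bed_path, i, tuple(df.loc[i]))
    return df.loc[~bad].reset_index(drop=True), n_rejected


def write_footprints(df: pd.DataFrame, path: str | Path) -> None:
    df[FOOTPRINT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(
    tsv_path: str | Path,
    layer: Layer = Layer.RNA,
    gene_lengths: pd.Series | None = None,
) -> ExpressionTable:
    """Read a genes x samples integer count matrix (header = sample IDs)."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{tsv_path}: duplicate gene IDs: {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.argwhere(~np.char.isnumeric(arr.astype(str)))
        raise ValueError(f"{tsv_path}: non-numeric cell at {bad[:5].tolist()}")
    if np.any(arr != np.round(arr)):
        g, s = np.argwhere(arr != np.round(arr))[0]
        raise ValueError(
            f"{tsv_path}: fractional count at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r} (round upstream)"
        )
    df = df.astype(np.int64)
    return ExpressionTable(layer=layer, unit=Unit.COUNT, values=df, gene_lengths=gene_lengths)


def write_counts(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA / GTF writers (used by the simulator CLI)
# ---------------------------------------------------------------------------

def write_transcriptome(
    models: Dict[str, TranscriptModel],
    fasta_path: str | Path,
    gtf_path: str | Path,
) -> None:
    """Write transcript FASTA + transcript-space GTF (exon + CDS features)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [
        SeqRecord(Seq(m.sequence), id=tx, description="")
        for tx, m in sorted(models.items())
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")

    with open(gtf_path, "w") as fh:
        for tx, m in sorted(models.items()):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{tx}";'
            # 0-based half-open -> 1-based inclusive GTF
            fh.write(
                f"{tx}\triboscape\texon\t1\t{m.length}\t.\t+\t.\t{attrs}\n"
            )
            fh.write(
                f"{tx}\triboscape\tCDS\t{m.cds_start + 1}\t{m.cds_end}\t.\t+\t0\t{attrs}\n"
            )
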