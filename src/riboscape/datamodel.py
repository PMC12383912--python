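"""Core domain types shared by every pipeline stage.

All transcript coordinates are 0-based, half-open, in transcript space
(position 0 is the first nucleotide of the mature transcript).  Conversions
from 1-based annotation formats happen inside the readers in
:mod:`riboscape.io` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np
import pandas as pd

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

Span = Tuple[int, int]


class Layer(str, Enum):
    """Which omics layer an expression matrix belongs to."""

    RNA = "RNA"
    RIBO = "RIBO"
    TE = "TE"


class Unit(str, Enum):
    COUNT = "count"
    FPKM = "FPKM"
    RATIO = "ratio"


class Category(str, Enum):
    """Five-way divergence classes for a gene across two regulatory layers."""

    TRANSCRIPTION = "Transcription"
    TRANSLATION = "Translation"
    HOMODIRECTION = "Homodirection"
    OPPOSITE = "Opposite"
    UNCHANGED = "Unchanged"


CATEGORY_ORDER = [
    Category.TRANSCRIPTION,
    Category.TRANSLATION,
    Category.HOMODIRECTION,
    Category.OPPOSITE,
    Category.UNCHANGED,
]


class TranscriptModelError(ValueError):
    """Raised when a transcript violates the coordinate-frame invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's coordinate frame: 5'UTR / CDS / 3'UTR spans + sequence.

    The three spans are contiguous, non-overlapping and tile
    ``[0, len(sequence))``; the 5'UTR (and 3'UTR) may be empty, the CDS must
    not be.  The CDS length is a multiple of 3, at least 6 nt, and starts
    with AUG unless ``nonstandard_start`` is set.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    utr5: Span
    cds: Span
    utr3: Span
    nonstandard_start: bool = False

    def __post_init__(self) -> None:
        n = len(self.sequence)
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if not (u5[0] == 0 and u5[1] == c[0] and c[1] == u3[0] and u3[1] == n):
            raise TranscriptModelError(
                f"{self.transcript_id}: spans {u5},{c},{u3} do not tile [0,{n})"
            )
        if set(self.sequence) - set("ACGTN"):
            raise TranscriptModelError(
                f"{self.transcript_id}: sequence has non-ACGTN characters"
            )
        clen = c[1] - c[0]
        if clen < 6:
            raise TranscriptModelError(f"{self.transcript_id}: CDS shorter than 6 nt")
        if clen % 3 != 0:
            raise TranscriptModelError(
                f"{self.transcript_id}: CDS length {clen} not a multiple of 3"
            )
        if not self.nonstandard_start and self.cds_seq[:3] != START_CODON:
            raise TranscriptModelError(
                f"{self.transcript_id}: CDS does not begin with {START_CODON}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_start(self) -> int:
        return self.cds[0]

    @property
    def cds_end(self) -> int:
        return self.cds[1]

    @property
    def utr5_len(self) -> int:
        return self.utr5[1] - self.utr5[0]

    @property
    def cds_len(self) -> int:
        return self.cds[1] - self.cds[0]

    @property
    def utr3_len(self) -> int:
        return self.utr3[1] - self.utr3[0]

    @property
    def utr5_seq(self) -> str:
        return self.sequence[self.utr5[0] : self.utr5[1]]

    @property
    def cds_seq(self) -> str:
        return self.sequence[self.cds[0] : self.cds[1]]

    @property
    def utr3_seq(self) -> str:
        return self.sequence[self.utr3[0] : self.utr3[1]]

    def region_of(self, pos: int) -> str:
        """Region label ('5UTR'/'CDS'/'3UTR') of a transcript position."""
        if not 0 <= pos < self.length:
            return "out_of_bounds"
        if pos < self.cds_start:
            return "5UTR"
        if pos < self.cds_end:
            return "CDS"
        return "3UTR"


@dataclass(frozen=True)
class FootprintRecord:
    """One mapped ribosome-protected fragment in transcript space."""

    sample_id: str
    transcript_id: str
    five_prime_pos: int
    read_length: int

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError("five_prime_pos must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")


#: canonical column order of a footprint table (one row per mapped read)
FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "read_length", "sample_id"]


@dataclass
class ExpressionTable:
    """Genes x samples matrix for one layer (RNA, RIBO or TE).

    ``values`` is a :class:`pandas.DataFrame` indexed by gene with sample
    columns.  ``gene_lengths`` holds the effective feature length in nt used
    for FPKM; ``library_sizes`` the total mapped reads per sample.
    """

    layer: Layer
    unit: Unit
    values: pd.DataFrame
    gene_lengths: Optional[pd.Series] = None
    library_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.unit == Unit.COUNT:
            arr = self.values.to_numpy()
            if np.isnan(arr).any() or (arr < 0).any():
                raise ValueError("counts must be non-negative and finite")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
        if self.library_sizes is None and self.unit == Unit.COUNT:
            self.library_sizes = self.values.sum(axis=0)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class DiffResult:
    """Per-gene differential-test outcome for one contrast."""

    gene_id: str
    contrast: str
    log2fc: float
    p_value: float
    fdr: float
    status: str = "ok"


@dataclass
class UorfRecord:
    """A candidate upstream ORF with its translatability evidence.

    ``start``/``end`` are half-open transcript coordinates including the stop
    codon; ``nmfe`` is minimum free energy divided by length (kcal/mol/nt);
    ``kozak_context`` is the 10-nt window -6..+4 around the start AUG
    (A of AUG = +1), padded with N where the transcript is too short.
    """

    uorf_id: str
    transcript_id: str
    start: int
    end: int
    length: int = field(init=False)
    gc: float = np.nan
    nmfe: float = np.nan
    orfscore: float = np.nan
    rrs: float = np.nan
    fickett: float = np.nan
    hexamer: float = np.nan
    mean_fpkm: float = np.nan
    kozak_context: str = ""
    dist_to_cds: int = -1
    norm_dist: float = np.nan
    translated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", self.end - self.start)
        if self.length % 3 != 0 or self.length < 6:
            raise ValueError(
                f"{self.uorf_id}: length {self.length} invalid for an ORF"
            )
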