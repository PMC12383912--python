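"""Synthetic Ribo-seq + RNA-seq data with known ground truth.

The generator emulates the structure of a two-group (e.g. yak vs
cattle-yak testis), three-replicate ribosome-profiling study: random
transcript models with 5'UTR/CDS/3'UTR architecture, negative-binomial
RNA and footprint counts with planted divergence categories, and
footprints with 28/30-nt length peaks, CDS enrichment, 3-nt periodicity
and a known P-site offset.  A configurable fraction of 5'UTRs carries a
planted AUG uORF; planted-translated uORFs receive dense, frame-biased,
coding-like footprint coverage, planted-untranslated ones background-level
uniform coverage.

Every stage draws from an explicit :class:`numpy.random.Generator`
substream derived from the single config seed, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    FOOTPRINT_COLUMNS,
    Category,
    ExpressionTable,
    Layer,
    TranscriptModel,
    Unit,
)

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOPS]

# Position-specific base weights giving CDS-like codon-position asymmetry;
# the product over the three positions defines the coding codon usage.
_POS_WEIGHTS = (
    {"A": 0.30, "C": 0.15, "G": 0.45, "T": 0.10},
    {"A": 0.40, "C": 0.30, "G": 0.10, "T": 0.20},
    {"A": 0.10, "C": 0.40, "G": 0.30, "T": 0.20},
)


def _codon_weights(codons: List[str]) -> np.ndarray:
    w = np.array(
        [np.prod([_POS_WEIGHTS[i][c[i]] for i in range(3)]) for c in codons]
    )
    return w / w.sum()


CODING_WEIGHTS = _codon_weights(SENSE_CODONS)
# uORF bodies additionally exclude ATG so planted uORFs have a unique start
BODY_CODONS = [c for c in SENSE_CODONS if c != "ATG"]
BODY_CODING_WEIGHTS = _codon_weights(BODY_CODONS)
BODY_UNIFORM_WEIGHTS = np.full(len(BODY_CODONS), 1.0 / len(BODY_CODONS))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the emulated study: 2 groups x 3 replicates, footprint
    lengths 20-40 nt peaked at 28 and 30, ~90% of CDS footprints in frame
    0, a global P-site offset of 12 nt, planted divergence categories with
    Opposite the rarest class, and uORFs of 50-200 nt planted in ~30% of
    5'UTRs.
    """

    n_genes: int = 2000
    n_reps_per_group: int = 3
    seed: int = 0
    dispersion: float = 0.1            # NB: Var = mu + phi * mu^2
    baseline_mean: float = 500.0       # mean RNA count per gene
    mu_sigma: float = 0.8              # lognormal spread of per-gene baselines
    effect_log2fc: float = 2.0
    category_fracs: Dict[str, float] = field(
        default_factory=lambda: {
            "Transcription": 0.15,
            "Translation": 0.10,
            "Homodirection": 0.15,
            "Opposite": 0.02,
            "Unchanged": 0.58,
        }
    )
    size_factor_sigma: float = 0.1
    # footprint geometry
    length_weights: Dict[int, float] = field(
        default_factory=lambda: {
            **{L: 0.01 for L in range(20, 41)},
            28: 0.29, 30: 0.28, 29: 0.13, 27: 0.07, 31: 0.07,
        }
    )
    pi_frame: float = 0.90             # frame-0 probability inside CDS
    rho_cds: float = 0.90              # fraction of footprints placed in CDS
    psite_offset: int = 12             # planted 5'end -> P-site offset (all lengths)
    # transcript architecture (nt)
    utr5_range: Tuple[int, int] = (100, 500)
    cds_range: Tuple[int, int] = (300, 3000)
    utr3_range: Tuple[int, int] = (100, 500)
    # uORF planting
    uorf_plant_rate: float = 0.30
    uorf_translated_frac: float = 0.30
    uorf_len_range: Tuple[int, int] = (51, 198)   # nt incl. stop, multiple of 3
    # footprint density inside a uORF relative to the UTR background; 15x
    # lets a typical translated uORF capture ~15-20% of its gene's
    # footprints, the strong periodic occupancy a translated-uORF screen
    # is designed to see
    uorf_density_translated: float = 15.0
    uorf_density_untranslated: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.category_fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {total}, not 1")
        if not (1 / 3 < self.pi_frame <= 1.0):
            raise ValueError("pi_frame must be in (1/3, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def samples(self) -> List[str]:
        r = self.n_reps_per_group
        return [f"Y{i+1}" for i in range(r)] + [f"CY{i+1}" for i in range(r)]

    @property
    def groups(self) -> pd.Series:
        r = self.n_reps_per_group
        return pd.Series(["g1"] * r + ["g2"] * r, index=self.samples, name="group")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class GroundTruth:
    """Planted truth: per-gene category/log2FCs and per-uORF translated flag."""

    genes: pd.DataFrame   # index gene_id: category, lfc_rna, lfc_ribo
    uorfs: pd.DataFrame   # index uorf_id: transcript_id, start, end, translated


@dataclass
class SimData:
    """A complete simulated dataset plus its ground truth."""

    config: SimConfig
    models: Dict[str, TranscriptModel]
    rna: ExpressionTable
    ribo: ExpressionTable
    footprints: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _scrub_atg(chars: List[str], keep: set) -> None:
    """Mutate the G of every ATG occurrence (except kept starts) to C.

    Removing a G can never create a new ATG, so one left-to-right pass with
    local re-checks suffices.  Applied only to 5'UTR backgrounds; for a
    planted uORF the mutation always lands on a non-start, non-stop codon
    position and turns one sense codon into another (stops need A or G in
    positions this mutation never produces).
    """
    i = 0
    while i + 2 < len(chars):
        if chars[i] == "A" and chars[i + 1] == "T" and chars[i + 2] == "G" and i not in keep:
            chars[i + 2] = "C"
        i += 1


def _random_codons(rng: np.random.Generator, n: int, codons: List[str], weights: np.ndarray) -> str:
    idx = rng.choice(len(codons), size=n, p=weights)
    return "".join(codons[i] for i in idx)


def simulate_transcriptome(
    cfg: SimConfig,
) -> Tuple[Dict[str, TranscriptModel], pd.DataFrame]:
    """Random transcript models; returns (models, planted-uORF table)."""
    rng = cfg.rng(0)
    models: Dict[str, TranscriptModel] = {}
    uorf_rows = []
    for i in range(cfg.n_genes):
        tx = f"t{i:05d}"
        gene = f"g{i:05d}"
        u5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        n_codons = int(rng.integers(cfg.cds_range[0] // 3, cfg.cds_range[1] // 3 + 1))
        u3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))

        utr5 = list("".join(rng.choice(list(BASES), size=u5)))
        plant = rng.random() < cfg.uorf_plant_rate and u5 >= 86
        keep: set = set()
        if plant:
            translated = bool(rng.random() < cfg.uorf_translated_frac)
            lo, hi = cfg.uorf_len_range
            if translated:
                # translated uORFs are planted shorter and nearer the CDS,
                # mirroring the contrast the downstream analyses look for
                hi = min(120, hi)
            hi = min(hi, u5 - 35)
            L = 3 * int(rng.integers(lo // 3 + (lo % 3 > 0), hi // 3 + 1))
            s_min, s_max = 15, u5 - L - 20
            if translated:
                s_min = s_min + (3 * (s_max - s_min)) // 4
            s = int(rng.integers(s_min, s_max + 1))
            body_w = BODY_CODING_WEIGHTS if translated else BODY_UNIFORM_WEIGHTS
            body = _random_codons(rng, L // 3 - 2, BODY_CODONS, body_w)
            uorf_seq = "ATG" + body + "TAA"   # TAA: no G, immune to scrubbing
            utr5[s : s + L] = list(uorf_seq)
            keep = {s}
            uorf_rows.append(
                {
                    "uorf_id": f"{tx}.u1",
                    "transcript_id": tx,
                    "start": s,
                    "end": s + L,
                    "translated": translated,
                }
            )
        _scrub_atg(utr5, keep)

        cds = "ATG" + _random_codons(rng, n_codons - 2, SENSE_CODONS, CODING_WEIGHTS)
        cds += STOPS[int(rng.integers(0, 3))]
        utr3 = "".join(rng.choice(list(BASES), size=u3))
        seq = "".join(utr5) + cds + utr3
        models[tx] = TranscriptModel(
            transcript_id=tx,
            gene_id=gene,
            sequence=seq,
            utr5=(0, u5),
            cds=(u5, u5 + 3 * n_codons),
            utr3=(u5 + 3 * n_codons, len(seq)),
        )
    uorfs = pd.DataFrame(
        uorf_rows, columns=["uorf_id", "transcript_id", "start", "end", "translated"]
    ).set_index("uorf_id")
    return models, uorfs


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with Var = mu + phi mu^2 via gamma-Poisson mixture."""
    if phi < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _assign_categories(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    names = list(cfg.category_fracs)
    fracs = np.array([cfg.category_fracs[k] for k in names])
    counts = np.floor(fracs * cfg.n_genes).astype(int)
    for j in np.argsort(-fracs)[: cfg.n_genes - counts.sum()]:
        counts[j] += 1
    cats = np.repeat(names, counts)
    return rng.permutation(cats)


def simulate_counts(
    models: Dict[str, TranscriptModel],
    cfg: SimConfig,
) -> Tuple[ExpressionTable, ExpressionTable, pd.DataFrame]:
    """NB counts for both layers plus the per-gene planted truth.

    Category semantics (log2FC applied to group 2): Transcription shifts
    the RNA layer only, Translation the RIBO layer only, Homodirection both
    with the same sign, Opposite both with opposite signs, Unchanged
    neither.  Signs are random per gene.
    """
    rng = cfg.rng(1)
    txs = sorted(models)
    genes = [models[t].gene_id for t in txs]
    n = len(txs)
    if n == 0:
        raise ValueError("models must be nonempty")

    mu = rng.lognormal(
        mean=np.log(cfg.baseline_mean) - cfg.mu_sigma**2 / 2.0,
        sigma=cfg.mu_sigma,
        size=n,
    )
    cats = _assign_categories(cfg, rng)[:n]
    sign = rng.choice([-1.0, 1.0], size=n)
    e = cfg.effect_log2fc
    lfc_rna = np.where(
        np.isin(cats, ["Transcription", "Homodirection", "Opposite"]), sign * e, 0.0
    )
    lfc_ribo = np.select(
        [cats == "Translation", cats == "Homodirection", cats == "Opposite"],
        [sign * e, sign * e, -sign * e],
        0.0,
    )

    samples = cfg.samples
    is_g2 = (cfg.groups == "g2").to_numpy()
    layers = {}
    for layer, lfc in (("rna", lfc_rna), ("ribo", lfc_ribo)):
        sf = rng.lognormal(0.0, cfg.size_factor_sigma, size=len(samples))
        mean = mu[:, None] * np.power(2.0, lfc[:, None] * is_g2[None, :]) * sf[None, :]
        layers[layer] = _nb_draw(rng, mean, cfg.dispersion)

    tx_len = pd.Series({models[t].gene_id: models[t].length for t in txs})
    cds_len = pd.Series({models[t].gene_id: models[t].cds_len for t in txs})
    rna = ExpressionTable(
        layer=Layer.RNA,
        unit=Unit.COUNT,
        values=pd.DataFrame(layers["rna"], index=genes, columns=samples),
        gene_lengths=tx_len,
    )
    ribo = ExpressionTable(
        layer=Layer.RIBO,
        unit=Unit.COUNT,
        values=pd.DataFrame(layers["ribo"], index=genes, columns=samples),
        gene_lengths=cds_len,
    )
    truth = pd.DataFrame(
        {"category": cats, "lfc_rna": lfc_rna, "lfc_ribo": lfc_ribo},
        index=pd.Index(genes, name="gene_id"),
    )
    return rna, ribo, truth


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def _frame_draw(rng: np.random.Generator, n: int, pi_frame: float) -> np.ndarray:
    p = [(pi_frame), (1 - pi_frame) / 2, (1 - pi_frame) / 2]
    return rng.choice(3, size=n, p=p)


def simulate_footprints(
    models: Dict[str, TranscriptModel],
    ribo: ExpressionTable,
    cfg: SimConfig,
    uorfs: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Place one footprint per RIBO count unit.

    A footprint goes to the CDS with probability ``rho_cds`` (P-site on a
    uniform codon, frame 0 with probability ``pi_frame``); otherwise to the
    UTRs, where a planted uORF claims a share of the UTR mass proportional
    to its length times its density multiplier.  The stored 5' end is
    P-site minus the planted offset.  Total footprints per sample equal the
    RIBO count sum per sample (conservation).
    """
    rng = cfg.rng(2)
    lengths = np.array(sorted(cfg.length_weights))
    lw = np.array([cfg.length_weights[L] for L in lengths], dtype=float)
    lw = lw / lw.sum()
    off = cfg.psite_offset

    uorf_by_tx: Dict[str, tuple] = {}
    if uorfs is not None:
        for _, row in uorfs.iterrows():
            uorf_by_tx[row["transcript_id"]] = (
                int(row["start"]), int(row["end"]), bool(row["translated"])
            )

    gene_to_tx = {models[t].gene_id: t for t in models}
    samples = list(ribo.samples)
    tx_names = sorted(models)
    tx_code = {t: i for i, t in enumerate(tx_names)}
    sample_code = {s: i for i, s in enumerate(samples)}
    out_tx: List[np.ndarray] = []
    out_pos: List[np.ndarray] = []
    out_len: List[np.ndarray] = []
    out_sample: List[np.ndarray] = []
    for gene_id, row in ribo.values.iterrows():
        tx = gene_to_tx[gene_id]
        m = models[tx]
        n_codons = m.cds_len // 3
        uorf = uorf_by_tx.get(tx)

        # UTR background positions: keep P-sites >= 15 from the 5' cap and
        # 28 nt from the 3' end so reads stay on the transcript
        utr_pos = np.concatenate(
            [np.arange(15, m.cds_start), np.arange(m.cds_end, m.length - 28)]
        )
        utr_total = len(utr_pos)
        if uorf is not None and utr_total > 0:
            s, e, translated = uorf
            utr_pos = utr_pos[(utr_pos < s) | (utr_pos >= e)]
            mult = (
                cfg.uorf_density_translated if translated else cfg.uorf_density_untranslated
            )
            # uORF occupancy is mult x the per-nt UTR background density, so
            # a strongly translated uORF draws extra mass beyond the plain
            # (1 - rho_cds) UTR share
            w_u = (1 - cfg.rho_cds) * mult * (e - s) / utr_total
            w_bg = (1 - cfg.rho_cds) * len(utr_pos) / utr_total
        else:
            w_u = 0.0
            w_bg = 1.0 - cfg.rho_cds
        w_tot = cfg.rho_cds + w_u + w_bg
        p_cds = cfg.rho_cds / w_tot
        p_uorf = w_u / w_tot
        p_bg = w_bg / w_tot

        for sample, n_reads in row.items():
            n_reads = int(n_reads)
            if n_reads == 0:
                continue
            n_cds, n_u, n_bg = rng.multinomial(n_reads, [p_cds, p_uorf, p_bg])
            psites = []
            if n_cds:
                codon = rng.integers(0, n_codons, size=n_cds)
                frame = _frame_draw(rng, n_cds, cfg.pi_frame)
                psites.append(m.cds_start + 3 * codon + frame)
            if n_u:
                s, e, translated = uorf
                codon = rng.integers(0, (e - s) // 3, size=n_u)
                if translated:
                    frame = _frame_draw(rng, n_u, cfg.pi_frame)
                else:
                    frame = rng.integers(0, 3, size=n_u)
                psites.append(s + 3 * codon + frame)
            if n_bg:
                psites.append(rng.choice(utr_pos, size=n_bg))
            psite = np.concatenate(psites)
            rlen = rng.choice(lengths, size=n_reads, p=lw)
            out_tx.append(np.full(n_reads, tx_code[tx], dtype=np.int32))
            out_pos.append((psite - off).astype(np.int32))
            out_len.append(rlen.astype(np.int16))
            out_sample.append(np.full(n_reads, sample_code[sample], dtype=np.int8))
    if not out_tx:
        return pd.DataFrame(columns=FOOTPRINT_COLUMNS)
    return pd.DataFrame(
        {
            "transcript_id": pd.Categorical.from_codes(
                np.concatenate(out_tx), categories=tx_names
            ),
            "five_prime_pos": np.concatenate(out_pos),
            "read_length": np.concatenate(out_len),
            "sample_id": pd.Categorical.from_codes(
                np.concatenate(out_sample), categories=samples
            ),
        }
    )[FOOTPRINT_COLUMNS]


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Run all three stages and bundle the result with its ground truth."""
    models, uorfs = simulate_transcriptome(cfg)
    rna, ribo, gene_truth = simulate_counts(models, cfg)
    fps = simulate_footprints(models, ribo, cfg, uorfs)
    return SimData(
        config=cfg,
        models=models,
        rna=rna,
        ribo=ribo,
        footprints=fps,
        truth=GroundTruth(genes=gene_truth, uorfs=uorfs),
    )
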