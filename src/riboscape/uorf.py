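"""Upstream ORF detection and translatability assessment.

uORFs are AUG-initiated ORFs with an in-frame stop entirely inside the
5'UTR.  Each candidate gets four coding/translation scores:

* **ORFscore** - chi-square-style statistic of P-site frame bias:
  with mean F of the three frame counts, log2(1 + sum_i (F_i - F)^2 / F),
  negated when frame 0 is not the strict maximum.
* **RRS** (ribosome release score) - P-site density inside the uORF over
  density in the downstream 5'UTR gap (pseudocount 1 on the gap count;
  undefined when the gap is shorter than 15 nt).
* **Fickett** (TESTCODE) - codon-position asymmetry and base composition
  converted to probabilities via the published lookup tables.
* **Hexamer** - mean natural-log likelihood ratio of in-frame hexamer
  frequencies under a coding model (in-frame CDS hexamers) versus a
  noncoding background (dinucleotide-shuffled CDS).

A uORF is called translated when all four scores pass their thresholds
and its mean footprint FPKM is at least 1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import STOP_CODONS, TranscriptModel

# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_uorfs(
    models: Mapping[str, TranscriptModel],
    min_len: int = 9,
    keep_nested: bool = False,
    allow_overlap: bool = False,
) -> pd.DataFrame:
    """All AUG-initiated ORFs terminating in-frame within the 5'UTR.

    Coordinates are half-open transcript coordinates including the stop
    codon.  Nested AUGs in one frame sharing a stop are collapsed to the
    most 5' AUG unless ``keep_nested``.  With ``allow_overlap``, AUGs whose
    first in-frame stop lies downstream of the UTR are kept and labelled
    ``overlaps_cds``.
    """
    rows = []
    for tx in sorted(models):
        m = models[tx]
        utr = m.utr5_seq
        seen_stops: Dict[int, int] = {}  # stop end -> first (most 5') start
        cands = []
        for i in range(len(utr) - 2):
            if utr[i : i + 3] != "ATG":
                continue
            end = None
            overlaps = False
            j = i + 3
            seq = utr if not allow_overlap else m.sequence[: m.cds_end]
            while j + 3 <= len(seq):
                if seq[j : j + 3] in STOP_CODONS:
                    end = j + 3
                    overlaps = end > len(utr)
                    break
                j += 3
            if end is None or (overlaps and not allow_overlap):
                continue
            if end - i < min_len:
                continue
            if not keep_nested:
                if end in seen_stops:
                    continue
                seen_stops[end] = i
            cands.append((i, end, overlaps))
        for k, (s, e, ov) in enumerate(sorted(cands)):
            rows.append(
                {
                    "uorf_id": f"{tx}.u{k+1}",
                    "transcript_id": tx,
                    "start": s,
                    "end": e,
                    "length": e - s,
                    "overlaps_cds": ov,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["uorf_id", "transcript_id", "start", "end", "length", "overlaps_cds"],
    ).set_index("uorf_id")


# ---------------------------------------------------------------------------
# ORFscore and RRS
# ---------------------------------------------------------------------------

def orfscore(frame_counts: Sequence[float]) -> float:
    """Frame-bias score from P-site counts in the three frames of an ORF.

    Returns NaN when no P-sites fall in the ORF.  The sign is positive only
    when frame 0 (the reading frame) holds the strict maximum.
    """
    f = np.asarray(frame_counts, dtype=float)
    total = f.sum()
    if total <= 0:
        return float("nan")
    mean = total / 3.0
    score = np.log2(1.0 + ((f - mean) ** 2 / mean).sum())
    if not (f[0] > f[1] and f[0] > f[2]):
        score = -score
    return float(score) + 0.0   # normalises -0.0 from the sign rule


def rrs(
    uorf_count: float, uorf_len: int, gap_count: float, gap_len: int, min_gap: int = 15
) -> float:
    """In-ORF P-site density over downstream-gap density (pseudocount 1).

    NaN when the gap to the CDS start is shorter than ``min_gap`` nt.
    """
    if gap_len < min_gap:
        return float("nan")
    return (uorf_count / uorf_len) / ((gap_count + 1.0) / gap_len)


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------

_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, para: List[float], probs: List[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Classic TESTCODE coding-potential statistic (roughly 0.16-1.30).

    Per base: position asymmetry max/(min + 1) over the three codon
    positions, and composition fraction, each mapped through the published
    probability tables and combined with the published weights.
    """
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError("fickett_score requires >= 6 nt")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt < 0.9 * len(seq):
        raise ValueError("more than 10% non-ACGT content")
    score = 0.0
    for base in "ACGT":
        counts = [seq[frame::3].count(base) for frame in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        content = seq.count(base) / acgt
        score += _lookup(position, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# hexamer score
# ---------------------------------------------------------------------------

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _hexamer_index(hexamer: str) -> int:
    idx = 0
    for ch in hexamer:
        idx = idx * 4 + _BASE_IDX[ch]
    return idx


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Altschul-Erickson).

    Chooses random terminal edges forming an arborescence toward the last
    character, shuffles the rest, and walks the Eulerian path.
    """
    if len(seq) < 3:
        return seq
    edges: Dict[str, List[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(1000):
        final = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            cur, hops = v, 0
            while cur != last and hops <= len(final):
                if cur not in final:
                    break
                cur = final[cur]
                hops += 1
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - arborescence sampling virtually always succeeds
        return seq
    walk_edges: Dict[str, List[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in final:
            rest.remove(final[v])
        rng.shuffle(rest)
        if v in final:
            rest.append(final[v])
        walk_edges[v] = rest
    out = [seq[0]]
    cur = seq[0]
    while walk_edges.get(cur):
        nxt = walk_edges[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class HexamerTable:
    """In-frame hexamer frequencies under coding and noncoding models."""

    coding: np.ndarray     # length 4096, sums to 1, strictly positive
    noncoding: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.coding, self.noncoding):
            if arr.shape != (4096,) or (arr <= 0).any():
                raise ValueError("frequencies must be 4096 strictly positive values")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError("frequencies must sum to 1")


def _count_inframe_hexamers(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(4096)
    for seq in seqs:
        for i in range(0, len(seq) - 5, 3):
            hx = seq[i : i + 6]
            if set(hx) <= set("ACGT"):
                counts[_hexamer_index(hx)] += 1
    return counts


def train_hexamer_table(
    models: Mapping[str, TranscriptModel],
    seed: int = 0,
    smoothing: float = 1e-6,
    min_cds: int = 50,
) -> HexamerTable:
    """Coding model from in-frame CDS hexamers; noncoding from
    dinucleotide-shuffled CDS (seeded, hence reproducible)."""
    cds_seqs = [m.cds_seq for m in models.values()]
    if len(cds_seqs) < min_cds:
        raise ValueError(f"need >= {min_cds} CDS sequences, got {len(cds_seqs)}")
    rng = np.random.default_rng(seed)
    coding = _count_inframe_hexamers(cds_seqs)
    shuffled = [dinucleotide_shuffle(s, rng) for s in cds_seqs]
    noncoding = _count_inframe_hexamers(shuffled)
    coding = (coding + smoothing) / (coding + smoothing).sum()
    noncoding = (noncoding + smoothing) / (noncoding + smoothing).sum()
    return HexamerTable(coding=coding, noncoding=noncoding)


def hexamer_score(sequence: str, table: HexamerTable) -> float:
    """Mean ln(F_coding / F_noncoding) over in-frame hexamers (NaN if < 6 nt)."""
    seq = sequence.upper()
    ratios = []
    for i in range(0, len(seq) - 5, 3):
        hx = seq[i : i + 6]
        if set(hx) <= set("ACGT"):
            k = _hexamer_index(hx)
            ratios.append(np.log(table.coding[k] / table.noncoding[k]))
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# per-uORF footprint evidence and scoring
# ---------------------------------------------------------------------------

@dataclass
class UorfThresholds:
    """Decision thresholds for calling a uORF translated."""

    orfscore: float = 6.0
    rrs: float = 2.0
    fickett: float = 0.74
    hexamer: float = 0.0
    min_fpkm: float = 1.0


def _psites_by_transcript(
    footprints: pd.DataFrame, offsets: Mapping[int, int], default_offset: int = 12
) -> Dict[str, pd.DataFrame]:
    off = footprints["read_length"].map(offsets).fillna(default_offset).astype(int)
    df = footprints[["transcript_id", "sample_id"]].copy()
    df["psite"] = footprints["five_prime_pos"] + off
    return {
        tx: sub
        for tx, sub in df.groupby("transcript_id", sort=False, observed=True)
    }


def score_uorfs(
    uorfs: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    footprints: pd.DataFrame,
    offsets: Mapping[int, int],
    library_sizes: pd.Series,
    groups: pd.Series,
    hexamer_table: Optional[HexamerTable] = None,
    compute_nmfe: bool = False,
    fold_backend: str = "auto",
) -> pd.DataFrame:
    """Attach the four translatability scores and context features to uORFs.

    ``library_sizes`` are total mapped footprints per sample (for uORF
    FPKM); per-group mean FPKMs and the overall mean are reported.
    """
    if hexamer_table is None:
        hexamer_table = train_hexamer_table(models)
    by_tx = _psites_by_transcript(footprints, offsets)
    samples = list(library_sizes.index)
    group_of = groups.loc[samples]

    from .seqfeat import fold_many, gc_content

    rows = []
    for uorf_id, u in uorfs.iterrows():
        tx = u["transcript_id"]
        m = models[tx]
        s, e = int(u["start"]), int(u["end"])
        useq = m.sequence[s:e]
        sub = by_tx.get(tx)
        if sub is None:
            in_u = pd.DataFrame(columns=["sample_id", "psite"])
            n_gap = 0
        else:
            mask = (sub["psite"] >= s) & (sub["psite"] < e)
            in_u = sub.loc[mask]
            n_gap = int(((sub["psite"] >= e) & (sub["psite"] < m.cds_start)).sum())
        frames = ((in_u["psite"] - s) % 3).value_counts().reindex([0, 1, 2], fill_value=0)
        per_sample = in_u["sample_id"].value_counts().reindex(samples, fill_value=0)
        fpkm = per_sample * 1e9 / (library_sizes * (e - s))
        group_fpkm = fpkm.groupby(group_of).mean()
        gap_len = m.cds_start - e
        rows.append(
            {
                "uorf_id": uorf_id,
                "transcript_id": tx,
                "start": s,
                "end": e,
                "length": e - s,
                "gc": gc_content(useq),
                "orfscore": orfscore(frames.to_numpy()),
                "rrs": rrs(int(frames.sum()), e - s, n_gap, gap_len),
                "fickett": fickett_score(useq),
                "hexamer": hexamer_score(useq, hexamer_table),
                "mean_fpkm": float(fpkm.mean()),
                **{f"fpkm_{g}": float(v) for g, v in group_fpkm.items()},
                "kozak_context": kozak_context(m, s),
                "dist_to_cds": gap_len,
                "norm_dist": gap_len / m.utr5_len if m.utr5_len else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("uorf_id")
    if compute_nmfe and len(out):
        foldable = out.index[out["length"] >= 8]
        results = fold_many(
            [models[out.loc[i, "transcript_id"]].sequence[
                int(out.loc[i, "start"]) : int(out.loc[i, "end"])
            ] for i in foldable],
            backend=fold_backend,
        )
        out["nmfe"] = np.nan
        out.loc[foldable, "nmfe"] = [r.nmfe for r in results]
    return out


def classify_translated(
    scored: pd.DataFrame, thresholds: UorfThresholds = UorfThresholds()
) -> pd.Series:
    """Translated iff all four scores pass and mean footprint FPKM >= 1.

    A missing score (e.g. RRS with a short gap) fails the rule.
    """
    t = thresholds
    flags = (
        (scored["orfscore"] >= t.orfscore)
        & (scored["rrs"] >= t.rrs)
        & (scored["fickett"] >= t.fickett)
        & (scored["hexamer"] > t.hexamer)
        & (scored["mean_fpkm"] >= t.min_fpkm)
    )
    return flags.fillna(False).astype(bool).rename("translated")


# ---------------------------------------------------------------------------
# Kozak context
# ---------------------------------------------------------------------------

KOZAK_POSITIONS = [-6, -5, -4, -3, -2, -1, 1, 2, 3, 4]


def kozak_context(model: TranscriptModel, start: int) -> str:
    """10-nt window -6..+4 around a start codon (A of AUG = +1), N-padded."""
    seq = model.sequence
    left = seq[max(0, start - 6) : start].rjust(6, "N")
    right = seq[start : start + 4].ljust(4, "N")
    return left + right


def kozak_pwm(contexts: Sequence[str]) -> pd.DataFrame:
    """Position probability matrix over the 10 Kozak positions.

    N entries are excluded position-wise; each column sums to 1 wherever
    any unambiguous base was seen.
    """
    if len(contexts) < 5:
        raise ValueError("need >= 5 contexts for a PWM")
    mat = np.zeros((len(KOZAK_POSITIONS), 4))
    for ctx in contexts:
        for i, ch in enumerate(ctx):
            if ch in _BASE_IDX:
                mat[i, _BASE_IDX[ch]] += 1
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(sums > 0, mat / sums, 0.0)
    return pd.DataFrame(probs, index=KOZAK_POSITIONS, columns=list("ACGT"))


def kozak_chi_square(
    contexts_a: Sequence[str], contexts_b: Sequence[str]
) -> pd.Series:
    """Per-position chi-square p comparing base usage between two sets.

    The AUG positions (+1..+3) are skipped (degenerate by construction).
    """
    if len(contexts_a) < 5 or len(contexts_b) < 5:
        raise ValueError("need >= 5 contexts per set")
    pvals = {}
    for i, pos in enumerate(KOZAK_POSITIONS):
        if pos in (1, 2, 3):
            continue
        counts = np.zeros((2, 4))
        for row, ctxs in enumerate((contexts_a, contexts_b)):
            for ctx in ctxs:
                if ctx[i] in _BASE_IDX:
                    counts[row, _BASE_IDX[ctx[i]]] += 1
        counts = counts[:, counts.sum(axis=0) > 0]
        if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
            pvals[pos] = 1.0
            continue
        chi2, p, _, _ = stats.chi2_contingency(counts)
        pvals[pos] = 1.0 if chi2 == 0 else float(p)
    return pd.Series(pvals, name="p_value")


# ---------------------------------------------------------------------------
# distances and uORF-mORF relationship
# ---------------------------------------------------------------------------

def uorf_distance(model: TranscriptModel, start: int, end: int) -> Tuple[int, float]:
    """(distance from uORF stop to CDS start, distance / 5'UTR length)."""
    dist = model.cds_start - end
    return dist, dist / model.utr5_len if model.utr5_len else float("nan")


def last_uorf_per_gene(scored: pd.DataFrame) -> pd.DataFrame:
    """The most 3' uORF of each transcript (the one entering distance plots)."""
    idx = scored.groupby("transcript_id")["end"].idxmax()
    return scored.loc[idx]


def uorf_morf_relation(
    uorf_lfc: pd.Series,
    morf_lfc: pd.Series,
    te: Optional[pd.Series] = None,
    uorf_features: Optional[pd.DataFrame] = None,
    te_by_class: Optional[Mapping[str, pd.Series]] = None,
    min_pairs: int = 10,
) -> Dict[str, object]:
    """Relationships between uORF evidence and mORF behaviour.

    * Pearson r between aligned uORF and mORF log2FCs.
    * Simple linear regressions of gene TE on each uORF feature column.
    * Pairwise two-sample KS tests of TE stratified by uORF class.
    """
    out: Dict[str, object] = {}
    shared = uorf_lfc.index.intersection(morf_lfc.index)
    a = uorf_lfc.loc[shared].astype(float)
    b = morf_lfc.loc[shared].astype(float)
    ok = a.notna() & b.notna()
    if ok.sum() < min_pairs:
        out["pearson"] = None
    else:
        r, p = stats.pearsonr(a[ok], b[ok])
        out["pearson"] = {"r": float(r), "p": float(p), "n": int(ok.sum())}

    regs = {}
    if te is not None and uorf_features is not None:
        for col in uorf_features.columns:
            shared = te.index.intersection(uorf_features.index)
            x = uorf_features.loc[shared, col].astype(float)
            y = te.loc[shared].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs:
                continue
            fit = stats.linregress(x[ok], y[ok])
            regs[col] = {
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r": float(fit.rvalue),
                "p": float(fit.pvalue),
                "n": int(ok.sum()),
            }
    out["regressions"] = regs

    ks = {}
    if te_by_class:
        names = list(te_by_class)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                x = pd.Series(te_by_class[names[i]]).dropna()
                y = pd.Series(te_by_class[names[j]]).dropna()
                if len(x) < min_pairs or len(y) < min_pairs:
                    continue
                res = stats.ks_2samp(x, y)
                ks[f"{names[i]}_vs_{names[j]}"] = {
                    "stat": float(res.statistic),
                    "p": float(res.pvalue),
                }
    out["ks_tests"] = ks
    return out
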