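"""CDS sequence features: length, GC content, and folding energy (NMFE).

NMFE is the minimum free energy of the predicted RNA secondary structure
divided by sequence length (kcal/mol per nt, <= 0; values closer to zero
mean a less stable structure).  Folding uses the external ViennaRNA
``RNAfold`` program when available; otherwise an internal Nussinov-style
base-pair maximisation fallback (-1 kcal/mol per canonical AU/GC/GU pair,
minimum hairpin loop of 3) that is exact for its own objective but carries
no thermodynamic parameter set.  The backend is recorded in every result.

Features are compared across the four TE bins with a Kruskal-Wallis
omnibus test followed by pairwise Mann-Whitney tests (BH-corrected) and a
compact letter display at alpha = 0.05.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TranscriptModel
from .differential import bh_adjust

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


def gc_content(sequence: str) -> float:
    """(G + C) / (A + C + G + T); N excluded from the denominator."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


@dataclass(frozen=True)
class FoldResult:
    length: int
    mfe: float           # kcal/mol, <= 0
    backend: str         # 'external-folder' | 'internal-nussinov'

    @property
    def nmfe(self) -> float:
        return self.mfe / self.length


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def nussinov_pairs(sequence: str, min_loop: int = MIN_LOOP) -> int:
    """Maximum number of non-crossing canonical pairs (hairpin loop >= min_loop)."""
    s = _to_rna(sequence)
    n = len(s)
    if n < min_loop + 2:
        return 0
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if (s[i], s[k]) in _PAIRS:
                    left = dp[i + 1, k - 1] if k - 1 > i else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return int(dp[0, n - 1])


def rnafold_available() -> bool:
    return shutil.which("RNAfold") is not None


def _rnafold_batch(seqs: Sequence[str]) -> List[float]:
    """MFEs from one RNAfold process over many sequences."""
    fasta = "".join(f">s{i}\n{_to_rna(s)}\n" for i, s in enumerate(seqs))
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=fasta, capture_output=True, text=True, check=True
    )
    mfes = []
    for line in proc.stdout.splitlines():
        if line and not line.startswith(">") and "(" in line and line.rstrip().endswith(")"):
            mfes.append(float(line.rsplit("(", 1)[1].rstrip(")").strip()))
    if len(mfes) != len(seqs):
        raise RuntimeError(
            f"RNAfold returned {len(mfes)} energies for {len(seqs)} sequences"
        )
    return mfes


def fold_nmfe(sequence: str, backend: str = "auto") -> FoldResult:
    """Fold one sequence; see :func:`fold_many` for the backend contract."""
    return fold_many([sequence], backend=backend)[0]


def fold_many(sequences: Sequence[str], backend: str = "auto") -> List[FoldResult]:
    """Fold sequences with the chosen backend.

    backend='auto' prefers external RNAfold and falls back to the internal
    Nussinov variant; 'external' requires RNAfold; 'internal' never shells
    out.
    """
    for s in sequences:
        if len(s) < 8:
            raise ValueError("fold_nmfe requires length >= 8 nt")
    if backend == "auto":
        backend = "external" if rnafold_available() else "internal"
    if backend == "external":
        if not rnafold_available():
            raise RuntimeError("RNAfold not found and internal fallback disabled")
        mfes = _rnafold_batch(sequences)
        return [
            FoldResult(length=len(s), mfe=min(m, 0.0), backend="external-folder")
            for s, m in zip(sequences, mfes)
        ]
    if backend == "internal":
        return [
            FoldResult(
                length=len(s),
                mfe=-float(nussinov_pairs(s)),
                backend="internal-nussinov",
            )
            for s in sequences
        ]
    raise ValueError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# feature-by-TE-bin comparison
# ---------------------------------------------------------------------------

def compact_letter_display(
    labels: Sequence[str], sig_pairs: Iterable[tuple]
) -> Dict[str, str]:
    """Assign letters so groups sharing a letter are not significantly different.

    Letters are the maximal cliques of the non-significance graph, ordered
    by group appearance.
    """
    g = nx.Graph()
    g.add_nodes_from(labels)
    sig = {frozenset(p) for p in sig_pairs}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if frozenset((a, b)) not in sig:
                g.add_edge(a, b)
    cliques = sorted(
        (sorted(c, key=list(labels).index) for c in nx.find_cliques(g)),
        key=lambda c: list(labels).index(c[0]),
    )
    letters = {lab: "" for lab in labels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for lab in clique:
            letters[lab] += letter
    return letters


def feature_by_te_bin(
    feature_values: pd.Series,
    te_bin: pd.Series,
    alpha: float = 0.05,
    min_bin_size: int = 3,
) -> Dict[str, object]:
    """Compare one feature's distribution across TE bins.

    Returns per-bin summaries, the Kruskal-Wallis omnibus p, the pairwise
    Mann-Whitney table (BH-corrected), and a compact letter display where
    bins sharing a letter do not differ at ``alpha``.
    """
    df = pd.DataFrame({"value": feature_values, "bin": te_bin}).dropna()
    sizes = df.groupby("bin", observed=True)["value"].size()
    usable = sizes[sizes >= min_bin_size].index.tolist()
    excluded = sizes[sizes < min_bin_size].index.tolist()
    summary = (
        df[df["bin"].isin(usable)]
        .groupby("bin", observed=True)["value"]
        .agg(["count", "median", "mean", "std"])
    )
    out: Dict[str, object] = {
        "summary": summary,
        "excluded_bins": excluded,
        "omnibus_p": np.nan,
        "pairwise": pd.DataFrame(columns=["bin_a", "bin_b", "p", "fdr"]),
        "letters": {b: "a" for b in usable},
    }
    if len(usable) < 2:
        return out
    groups = [df.loc[df["bin"] == b, "value"].to_numpy() for b in usable]
    out["omnibus_p"] = float(stats.kruskal(*groups).pvalue)
    rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            p = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided").pvalue
            rows.append({"bin_a": usable[i], "bin_b": usable[j], "p": float(p)})
    pw = pd.DataFrame(rows)
    pw["fdr"] = bh_adjust(pw["p"].to_numpy())
    out["pairwise"] = pw
    sig_pairs = [
        (r["bin_a"], r["bin_b"]) for _, r in pw.iterrows() if r["fdr"] < alpha
    ]
    out["letters"] = compact_letter_display(usable, sig_pairs)
    return out


def cds_feature_table(
    models: Dict[str, TranscriptModel],
    te_bin: pd.Series,
    backend: str = "auto",
    max_fold_len: int = 3000,
    fold_sample_per_bin: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene CDS length, GC and NMFE, joined with the gene's TE bin.

    Sequences longer than ``max_fold_len`` are truncated from the 5' end
    for folding (flagged in the ``truncated`` column).  When
    ``fold_sample_per_bin`` is set, NMFE is computed for a per-bin random
    subsample only (NaN elsewhere) to keep external folding tractable.
    """
    by_gene = {m.gene_id: m for m in models.values()}
    genes = [g for g in te_bin.index if g in by_gene]
    rows = pd.DataFrame(
        {
            "gene_id": genes,
            "te_bin": te_bin.loc[genes].to_numpy(),
            "cds_length": [by_gene[g].cds_len for g in genes],
            "gc": [gc_content(by_gene[g].cds_seq) for g in genes],
        }
    ).set_index("gene_id")
    rows["truncated"] = rows["cds_length"] > max_fold_len

    fold_genes = rows.index[rows["te_bin"].notna()]
    if fold_sample_per_bin is not None:
        rng = np.random.default_rng(seed)
        picked = []
        for b, sub in rows.loc[fold_genes].groupby("te_bin", observed=True):
            k = min(fold_sample_per_bin, len(sub))
            picked.extend(rng.choice(sub.index.to_numpy(), size=k, replace=False))
        fold_genes = pd.Index(picked)

    rows["nmfe"] = np.nan
    rows["backend"] = ""
    if len(fold_genes):
        seqs = [by_gene[g].cds_seq[:max_fold_len] for g in fold_genes]
        results = fold_many(seqs, backend=backend)
        rows.loc[fold_genes, "nmfe"] = [r.nmfe for r in results]
        rows.loc[fold_genes, "backend"] = [r.backend for r in results]
    return rows
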