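import numpy as np
import pandas as pd
import pytest

from riboscape import SimConfig, simulate_dataset
from riboscape.datamodel import TranscriptModel


def make_transcript(
    utr5: str,
    cds: str,
    utr3: str = "",
    tx_id: str = "tx1",
    gene_id: str = "g1",
) -> TranscriptModel:
    seq = utr5 + cds + utr3
    u5 = len(utr5)
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        sequence=seq,
        utr5=(0, u5),
        cds=(u5, u5 + len(cds)),
        utr3=(u5 + len(cds), len(seq)),
    )


@pytest.fixture(scope="session")
def sim_small():
    """A compact simulated dataset reused across modules (120 genes)."""
    return simulate_dataset(SimConfig(n_genes=120, seed=11))


@pytest.fixture(scope="session")
def sim_uorf():
    """A dataset sized for uORF evidence checks (400 genes, ~120 uORFs)."""
    return simulate_dataset(SimConfig(n_genes=400, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
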