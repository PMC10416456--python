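import numpy as np
import pandas as pd
import pytest

from m6adyn import quantify
from m6adyn.io_formats import STAGES, GeneAnnotation, StageCounts
from m6adyn.synthetic import SimConfig, simulate_study

SMALL = SimConfig(n_genes=300, n_peaks=520, n_targets=10, depth_mean=2000, seed=3)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across test modules."""
    return simulate_study(SMALL)


@pytest.fixture(scope="session")
def small_profile(small_study):
    kept, removed = quantify.filter_peaks(small_study.counts)
    ip_cpm, input_cpm = quantify.normalize(kept)
    prof = quantify.aggregate_levels(ip_cpm, input_cpm, small_study.peaks)
    return kept, prof


@pytest.fixture
def toy_annotation():
    """Two genes on opposite strands with explicit UTR/CDS structure."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "tx_start": [1000, 20000],
            "tx_end": [7000, 26000],
            "cds_start": [1600, 21800],
            "cds_end": [5200, 25400],
        },
        index=pd.Index(["geneA", "geneB"], name="gene_id"),
    )
    return GeneAnnotation(df)


def make_counts(ip, inp, ip_lib=None, in_lib=None, ids=None):
    """StageCounts from plain arrays (one row per peak, 4 stages)."""
    ip = np.atleast_2d(ip)
    inp = np.atleast_2d(inp)
    ids = ids or [f"p{i}" for i in range(len(ip))]
    idx = pd.Index(ids, name="peak_id")
    return StageCounts(
        ip=pd.DataFrame(ip, index=idx, columns=list(STAGES)),
        input=pd.DataFrame(inp, index=idx, columns=list(STAGES)),
        ip_libsize=pd.Series(ip_lib or [10**6] * 4, index=list(STAGES)),
        input_libsize=pd.Series(in_lib or [10**6] * 4, index=list(STAGES)),
    )
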