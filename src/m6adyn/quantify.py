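"""m6A quantification from paired IP/input counts.

The m6A level of a peak at a stage is the ratio of CPM-normalized IP
coverage to CPM-normalized input coverage.  Gene, region and sample levels
are pooled ratios (sum of IP CPM over sum of input CPM), which weights each
peak by its input depth and reduces to the peak level for single-peak genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, PeakTable, StageCounts

DRACH_RE = re.compile(r"(?=[AGT][AG]AC[ACT])")

#: default ratio above which a peak/gene is called m6A-modified
MOD_THRESHOLD = 1.5


@dataclass
class M6AProfile:
    """m6A levels at peak, gene, region and sample resolution."""

    peak_level: pd.DataFrame
    gene_level: pd.DataFrame
    region_level: pd.DataFrame
    sample_level: pd.Series


def filter_peaks(
    counts: StageCounts, min_input: int = 5
) -> tuple[StageCounts, pd.Index]:
    """Drop peaks whose input count is below ``min_input`` in any stage.

    Returns the retained counts and the index of removed peaks.
    """
    keep = (counts.input >= min_input).all(axis=1)
    removed = counts.input.index[~keep]
    if not keep.any():
        raise ValueError(
            "all peaks removed by the input-count filter; "
            "increase sequencing depth or lower min_input"
        )
    return counts.subset(counts.input.index[keep]), removed


def normalize(counts: StageCounts) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-per-million normalization against whole-library totals."""
    if (counts.ip_libsize <= 0).any() or (counts.input_libsize <= 0).any():
        raise ValueError("library sizes must be positive")
    ip_cpm = counts.ip / counts.ip_libsize.to_numpy() * 1e6
    input_cpm = counts.input / counts.input_libsize.to_numpy() * 1e6
    return ip_cpm, input_cpm


def peak_m6a_levels(ip_cpm: pd.DataFrame, input_cpm: pd.DataFrame) -> pd.DataFrame:
    """Per-peak m6A level: IP CPM / input CPM."""
    inp = input_cpm.to_numpy()
    if (inp <= 0).any():
        raise ValueError("zero input coverage after filtering; cannot form ratios")
    return ip_cpm / input_cpm


def _pooled_ratio(
    ip_cpm: pd.DataFrame, input_cpm: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    num = ip_cpm.groupby(groups).sum()
    den = input_cpm.groupby(groups).sum()
    return num / den


def aggregate_levels(
    ip_cpm: pd.DataFrame, input_cpm: pd.DataFrame, peaks: PeakTable
) -> M6AProfile:
    """Pool peak coverage into gene, region and per-sample m6A levels.

    Genes with no retained peaks are absent from the output (not zero).
    """
    d = peaks.df.loc[ip_cpm.index]
    peak_level = peak_m6a_levels(ip_cpm, input_cpm)
    with_gene = d.gene_id.notna()
    gene_level = _pooled_ratio(
        ip_cpm[with_gene], input_cpm[with_gene], d.gene_id[with_gene]
    )
    gene_level.index.name = "gene_id"
    region_level = _pooled_ratio(ip_cpm, input_cpm, d.region)
    region_level.index.name = "region"
    sample_level = ip_cpm.sum() / input_cpm.sum()
    sample_level.name = "m6a_level"
    return M6AProfile(peak_level, gene_level, region_level, sample_level)


def profile(
    counts: StageCounts, peaks: PeakTable, min_input: int = 5
) -> tuple[M6AProfile, pd.Index]:
    """Filter, normalize and aggregate in one step."""
    kept, removed = filter_peaks(counts, min_input=min_input)
    ip_cpm, input_cpm = normalize(kept)
    return aggregate_levels(ip_cpm, input_cpm, peaks), removed


def count_m6a_genes(
    gene_level: pd.DataFrame,
    expression: pd.DataFrame,
    threshold: float = MOD_THRESHOLD,
    min_expr: float = 1.0,
) -> pd.DataFrame:
    """Per-stage counts of expressed genes and m6A-modified genes.

    A gene is modified at a stage iff its pooled level is strictly above
    ``threshold``; expressed iff its expression is at least ``min_expr``.
    """
    expressed = (expression >= min_expr).sum()
    modified = (gene_level > threshold).sum().reindex(expression.columns, fill_value=0)
    out = pd.DataFrame({"n_expressed": expressed, "n_modified": modified})
    out["frac_modified"] = out.n_modified / out.n_expressed
    out.index.name = "stage"
    return out


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------


def metagene_coordinates(peaks: PeakTable, annotation: GeneAnnotation) -> pd.Series:
    """Map peak midpoints to the normalized transcript coordinate [0, 3).

    5'UTR -> [0,1), CDS -> [1,2), 3'UTR -> [2,3), by fractional position
    within the region.  Genes lacking a UTR contribute to the CDS segment
    only.  Peaks without a gene assignment are skipped.
    """
    coords = {}
    adf = annotation.df
    for pid, p in peaks.df.iterrows():
        if pd.isna(p.gene_id):
            continue
        g = adf.loc[p.gene_id]
        mid = (p.start + p.end) / 2.0
        if g.strand == "-":
            t = g.tx_end - mid
            l5 = g.tx_end - g.cds_end
            lc = g.cds_end - g.cds_start
        else:
            t = mid - g.tx_start
            l5 = g.cds_start - g.tx_start
            lc = g.cds_end - g.cds_start
        l3 = (g.tx_end - g.tx_start) - l5 - lc
        t = min(max(t, 0.0), l5 + lc + l3 - 1e-9)
        if t < l5:
            c = t / l5
        elif t < l5 + lc:
            c = 1.0 + (t - l5) / lc
        elif l3 > 0:
            c = 2.0 + (t - l5 - lc) / l3
        else:  # pragma: no cover - clamped above
            c = 2.0
        coords[pid] = c
    s = pd.Series(coords, name="metagene_coord", dtype=float)
    s.index.name = "peak_id"
    return s


def metagene_density(
    peaks: PeakTable, annotation: GeneAnnotation, bins: int = 90
) -> pd.DataFrame:
    """Area-normalized histogram of metagene coordinates (default 90 bins)."""
    coords = metagene_coordinates(peaks, annotation)
    hist, edges = np.histogram(coords, bins=bins, range=(0.0, 3.0), density=True)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "density": hist}
    ).rename_axis("bin")


# ---------------------------------------------------------------------------
# DRACH scanning
# ---------------------------------------------------------------------------


def scan_drach(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Count overlapping DRACH ([AGT][AG]AC[ACT]) occurrences per sequence."""
    rows = {}
    for name, seq in sequences.items():
        s = str(seq).upper()
        invalid = set(s) - set("ACGTN")
        if invalid:
            raise ValueError(
                f"sequence {name!r} contains non-ACGTN characters: {sorted(invalid)}"
            )
        rows[name] = len(DRACH_RE.findall(s))
    out = pd.DataFrame({"drach_count": pd.Series(rows, dtype=int)})
    out.index.name = "peak_id"
    out["has_drach"] = out.drach_count >= 1
    return out


def drach_summary(counts: pd.DataFrame) -> pd.Series:
    """Fraction of peaks with at least one DRACH plus totals."""
    return pd.Series(
        {
            "n_peaks": float(len(counts)),
            "n_with_drach": float(counts.has_drach.sum()),
            "frac_with_drach": counts.has_drach.mean() if len(counts) else np.nan,
            "total_occurrences": float(counts.drach_count.sum()),
        },
        name="value",
    )
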