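"""Readers, writers and validated domain containers.

The pipeline touches four on-disk formats: BED6 for the m6A peak catalog,
GTF (gene + CDS features) or a simplified transcript table for the gene
annotation, and TSV matrices (counts, expression, accessibility, TF
binding).  Coordinates are 0-based half-open everywhere in memory; GTF is
converted on read/write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STAGES: tuple[str, ...] = ("D0", "D2", "D5", "D15")

REGIONS = ("5UTR", "CDS", "3UTR", "stop_proximal", "other")

#: half-width (nt) of the stop-codon-proximal window used for region labels
STOP_WINDOW = 50


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Per-gene transcript model: one interval per gene with CDS bounds.

    ``df`` is indexed by ``gene_id`` with columns ``chrom``, ``strand``,
    ``tx_start``, ``tx_end``, ``cds_start``, ``cds_end`` (0-based half-open).
    Genes without annotated UTRs have ``cds_start == tx_start`` and/or
    ``cds_end == tx_end``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "strand", "tx_start", "tx_end", "cds_start", "cds_end"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        d = self.df
        bad = ~(
            (d.tx_start <= d.cds_start)
            & (d.cds_start < d.cds_end)
            & (d.cds_end <= d.tx_end)
        )
        if bad.any():
            raise FormatError(
                f"invalid CDS bounds for genes {d.index[bad].tolist()[:5]}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index


@dataclass
class PeakTable:
    """m6A peak catalog with gene assignment and transcript-region label.

    ``df`` is indexed by unique ``peak_id`` with columns ``chrom``, ``start``,
    ``end``, ``strand``, ``gene_id`` (string or NA) and ``region`` (one of
    ``REGIONS``).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate peak ids: {dups[:5]}")
        bad = ~(self.df.start < self.df.end)
        if bad.any():
            raise FormatError(
                f"peaks with start >= end: {self.df.index[bad].tolist()[:5]}"
            )
        unknown = set(self.df.region.dropna()) - set(REGIONS)
        if unknown:
            raise FormatError(f"unknown region labels: {sorted(unknown)}")

    @property
    def peak_ids(self) -> pd.Index:
        return self.df.index


@dataclass
class StageCounts:
    """Raw per-peak IP and input counts for the ordered stages.

    Library sizes are whole-library read totals (they may exceed the column
    sums, since most reads fall outside peaks).
    """

    ip: pd.DataFrame
    input: pd.DataFrame
    ip_libsize: pd.Series
    input_libsize: pd.Series
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        for name, m in (("ip", self.ip), ("input", self.input)):
            if list(m.columns) != list(self.stages):
                raise FormatError(
                    f"{name} counts columns {list(m.columns)} != stages {self.stages}"
                )
            if (m.to_numpy() < 0).any():
                raise FormatError(f"negative {name} counts")
        if not self.ip.index.equals(self.input.index):
            raise FormatError("ip and input count matrices have different peak sets")
        for name, s in (("ip", self.ip_libsize), ("input", self.input_libsize)):
            if list(s.index) != list(self.stages):
                raise FormatError(f"{name} libsize index != stages")
            if (s <= 0).any():
                raise FormatError(f"non-positive {name} library size")

    @property
    def peak_ids(self) -> pd.Index:
        return self.ip.index

    def subset(self, peak_ids: pd.Index) -> "StageCounts":
        return StageCounts(
            ip=self.ip.loc[peak_ids],
            input=self.input.loc[peak_ids],
            ip_libsize=self.ip_libsize,
            input_libsize=self.input_libsize,
            stages=self.stages,
        )


# ---------------------------------------------------------------------------
# gene annotation I/O
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | os.PathLike) -> GeneAnnotation:
    """Read a GTF with ``gene`` and (optionally) ``CDS`` features.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    Genes without CDS features are treated as CDS over the whole interval.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    rows: dict[str, dict] = {}
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("gene_id", [f.id])[0]
        rows[gid] = dict(
            chrom=f.seqid,
            strand=f.strand if f.strand in "+-" else ".",
            tx_start=f.start - 1,
            tx_end=f.end,
            cds_start=None,
            cds_end=None,
        )
    for f in db.features_of_type("CDS"):
        gid = f.attributes.get("gene_id", [None])[0]
        if gid not in rows:
            continue
        r = rows[gid]
        s, e = f.start - 1, f.end
        r["cds_start"] = s if r["cds_start"] is None else min(r["cds_start"], s)
        r["cds_end"] = e if r["cds_end"] is None else max(r["cds_end"], e)
    if not rows:
        raise FormatError(f"no gene features found in {path}")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    df["cds_start"] = df["cds_start"].fillna(df["tx_start"]).astype(int)
    df["cds_end"] = df["cds_end"].fillna(df["tx_end"]).astype(int)
    return GeneAnnotation(df)


def read_gene_table(path: str | os.PathLike) -> GeneAnnotation:
    """Read the simplified transcript table (TSV, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return GeneAnnotation(df)


def write_gene_annotation(ann: GeneAnnotation, path: str | os.PathLike) -> None:
    """Write the annotation as GTF with gene and CDS features."""
    with open(path, "w") as fh:
        for gid, r in ann.df.iterrows():
            attrs = f'gene_id "{gid}";'
            fh.write(
                f"{r.chrom}\tm6adyn\tgene\t{r.tx_start + 1}\t{r.tx_end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{r.chrom}\tm6adyn\tCDS\t{r.cds_start + 1}\t{r.cds_end}\t.\t"
                f"{r.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def _region_label(mid: float, gene: pd.Series) -> str:
    """Transcript-region label of a position, strand-aware.

    The stop-codon-proximal window (midpoint within +-STOP_WINDOW nt of the
    stop codon) takes precedence over the plain 5'UTR/CDS/3'UTR split.
    """
    stop = gene.cds_end if gene.strand != "-" else gene.cds_start
    if abs(mid - stop) <= STOP_WINDOW:
        return "stop_proximal"
    if gene.strand == "-":
        if mid >= gene.cds_end:
            return "5UTR"
        if mid < gene.cds_start:
            return "3UTR"
        return "CDS"
    if mid < gene.cds_start:
        return "5UTR"
    if mid >= gene.cds_end:
        return "3UTR"
    return "CDS"


def assign_peaks_to_genes(
    peaks: pd.DataFrame, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Assign each peak to the gene whose interval contains its midpoint.

    Ties (overlapping genes) are broken by longest peak/gene overlap, then
    lexicographic gene_id.  Unassigned peaks get gene_id NA, region "other".
    """
    trees: dict[str, IntervalTree] = {}
    for gid, r in annotation.df.iterrows():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.tx_start, r.tx_end, gid)
    gene_ids: list[object] = []
    regions: list[str] = []
    adf = annotation.df
    for pid, p in peaks.iterrows():
        mid = (p.start + p.end) / 2.0
        tree = trees.get(p.chrom)
        hits = tree[mid] if tree is not None else set()
        if not hits:
            gene_ids.append(pd.NA)
            regions.append("other")
            continue
        best = min(
            hits,
            key=lambda iv: (-(min(p.end, iv.end) - max(p.start, iv.begin)), iv.data),
        )
        gid = best.data
        gene_ids.append(gid)
        regions.append(_region_label(mid, adf.loc[gid]))
    out = peaks.copy()
    out["gene_id"] = pd.array(gene_ids, dtype="string")
    out["region"] = regions
    return out


def read_peaks(path: str | os.PathLike, annotation: GeneAnnotation) -> PeakTable:
    """Read a BED6 peak file and annotate peaks against ``annotation``."""
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty BED file: {path}") from None
    if raw.shape[1] < 3:
        raise FormatError(f"BED file {path} has fewer than 3 columns")
    df = pd.DataFrame(
        {
            "chrom": raw[0],
            "start": pd.to_numeric(raw[1], errors="coerce"),
            "end": pd.to_numeric(raw[2], errors="coerce"),
        }
    )
    bad = df.start.isna() | df.end.isna()
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise FormatError(f"non-numeric coordinate at line {line} of {path}")
    df["start"] = df.start.astype(int)
    df["end"] = df.end.astype(int)
    malformed = df.start >= df.end
    if malformed.any():
        line = int(malformed.idxmax()) + 1
        raise FormatError(f"malformed coordinate (start >= end) at line {line} of {path}")
    names = (
        raw[3]
        if raw.shape[1] >= 4
        else pd.Series([f"peak_{i + 1}" for i in range(len(raw))])
    )
    df["strand"] = raw[5] if raw.shape[1] >= 6 else "."
    df.index = pd.Index(names, name="peak_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate peak id {dup!r} in {path}")
    return PeakTable(assign_peaks_to_genes(df, annotation))


def write_peaks(peaks: PeakTable, path: str | os.PathLike) -> None:
    """Write the peak catalog as BED6 (name = peak_id, score = 0)."""
    d = peaks.df
    bed = pd.DataFrame(
        {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "name": d.index,
            "score": 0,
            "strand": d.strand,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a keyed numeric TSV matrix (header = sample ids, col 0 = keys)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty matrix file: {path}") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"empty matrix file: {path}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicated row key {dup!r} in {path}")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col].mask(df[col] == ""), errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = df.index[bad][0]
            cell = df.loc[row, col]
            what = "missing value" if cell == "" else f"non-numeric cell {cell!r}"
            raise FormatError(f"{what} at row {row!r}, column {col!r} in {path}")
        out[col] = vals
    return pd.DataFrame(out, index=df.index)


def read_stage_counts(
    ip_path: str | os.PathLike,
    input_path: str | os.PathLike,
    libsize_path: str | os.PathLike,
    stages: Iterable[str] = STAGES,
) -> StageCounts:
    """Assemble StageCounts from count matrices plus a libsize table.

    The libsize table has rows ``ip`` and ``input`` and one column per stage.
    """
    stages = tuple(stages)
    ip = read_matrix(ip_path).loc[:, list(stages)].astype(int)
    inp = read_matrix(input_path).loc[:, list(stages)].astype(int)
    libs = read_matrix(libsize_path)
    return StageCounts(
        ip=ip,
        input=inp.loc[ip.index],
        ip_libsize=libs.loc["ip", list(stages)].astype(int),
        input_libsize=libs.loc["input", list(stages)].astype(int),
        stages=stages,
    )


def write_results(
    tables: Mapping[str, pd.DataFrame | pd.Series],
    out_dir: str | os.PathLike,
    float_format: str = "%.6g",
) -> list[Path]:
    """Write one TSV per result table with stable order and 6-sig-digit floats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        t = tables[name]
        if isinstance(t, pd.Series):
            t = t.to_frame(t.name or "value")
        path = out / f"{name}.tsv"
        t.to_csv(path, sep="\t", float_format=float_format)
        written.append(path)
    return written
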