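"""Readers and writers for the plain-text formats the pipeline exchanges.

Transcripts travel as BED12 (name encodes ``gene_id|transcript_id``), peaks
as BED6 plus extra numeric columns, strand signal as bedGraph (one file per
strand), and counts / expression / survival / truth tables as TSV with a
header. All interval files are 0-based half-open (BED dialect).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .nascent import RegionCountMatrix

__all__ = [
    "write_transcripts_bed12", "read_transcripts_bed12",
    "read_transcripts_tsv",
    "write_peaks_bed", "read_peaks_bed",
    "write_bedgraph", "read_bedgraph",
    "write_models_tsv", "read_models_tsv",
    "write_counts", "read_counts",
    "write_region_counts", "read_region_counts",
]


def write_transcripts_bed12(transcripts: pd.DataFrame, path) -> None:
    df = transcripts
    size = (df["end"] - df["start"]).astype(int)
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df["gene_id"].astype(str) + "|" + df["transcript_id"].astype(str),
        "score": 0,
        "strand": df["strand"],
        "thickStart": df["start"].astype(int),
        "thickEnd": df["end"].astype(int),
        "itemRgb": "0,0,0",
        "blockCount": 1,
        "blockSizes": size.astype(str) + ",",
        "blockStarts": "0,",
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_transcripts_bed12(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    name = bed[3].astype(str).str.split("|", n=1, expand=True)
    return pd.DataFrame({
        "gene_id": name[0],
        "transcript_id": name[1].fillna(name[0]),
        "chrom": bed[0],
        "start": bed[1].astype(int),
        "end": bed[2].astype(int),
        "strand": bed[5],
    })


def read_transcripts_tsv(path) -> pd.DataFrame:
    """Six-column TSV: gene_id, transcript_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "transcript_id", "chrom", "start", "end", "strand"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"transcript TSV missing columns: {sorted(missing)}")
    return df


def write_peaks_bed(peaks: pd.DataFrame, path, score_col: str = "pnrd_hypoxia") -> None:
    extra = [c for c in peaks.columns
             if c not in {"chrom", "start", "end", "peak_id"} and c != score_col]
    bed = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"].astype(int),
        "end": peaks["end"].astype(int),
        "name": peaks["peak_id"],
        "score": peaks[score_col],
        "strand": ".",
    })
    for c in extra:
        bed[c] = peaks[c].to_numpy()
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({
        "peak_id": bed[3],
        "chrom": bed[0],
        "start": bed[1].astype(int),
        "end": bed[2].astype(int),
        "score": bed[4],
    })
    out["center"] = (out["start"] + out["end"]) // 2
    for i, c in enumerate(extra_cols or []):
        out[c] = bed[6 + i]
    return out


def write_bedgraph(signal: pd.DataFrame, path) -> None:
    signal[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="t",
                     names=["chrom", "start", "end", "value"])
    df = df.dropna()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_models_tsv(models: pd.DataFrame, path) -> None:
    models.to_csv(path, sep="\t", index=False)


def read_models_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    counts.to_csv(path, sep="\t", index_label=index_label)


def read_counts(path, index_col: str = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_region_counts(rcm: RegionCountMatrix, outdir, prefix: str) -> None:
    """Write one region-count matrix as counts + lengths + sample sheet TSVs."""
    outdir = Path(outdir)
    write_counts(rcm.counts, outdir / f"{prefix}_counts.tsv")
    rcm.region_lengths.rename("length").to_csv(
        outdir / f"{prefix}_lengths.tsv", sep="\t", index_label="gene_id")
    sheet = rcm.samples.copy()
    sheet["library_size"] = rcm.library_sizes
    sheet.to_csv(outdir / f"{prefix}_samples.tsv", sep="\t", index_label="sample")


def read_region_counts(outdir, prefix: str, region_class: str) -> RegionCountMatrix:
    outdir = Path(outdir)
    counts = read_counts(outdir / f"{prefix}_counts.tsv")
    lengths = pd.read_csv(outdir / f"{prefix}_lengths.tsv", sep="\t",
                          index_col="gene_id")["length"]
    sheet = pd.read_csv(outdir / f"{prefix}_samples.tsv", sep="\t",
                        index_col="sample")
    lib = sheet.pop("library_size")
    return RegionCountMatrix(region_class, counts, lengths, lib.astype(float), sheet)


def write_signal_tracks(signal: Mapping[tuple[str, str], pd.DataFrame], outdir) -> None:
    outdir = Path(outdir)
    for (strand, condition), df in signal.items():
        tag = "plus" if strand == "+" else "minus"
        write_bedgraph(df, outdir / f"signal_{condition}_{tag}.bedGraph")


def read_signal_tracks(outdir, conditions=("normoxia", "hypoxia")) -> dict:
    outdir = Path(outdir)
    out = {}
    for condition in conditions:
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = outdir / f"signal_{condition}_{tag}.bedGraph"
            if p.exists():
                out[(strand, condition)] = read_bedgraph(p)
    return out
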