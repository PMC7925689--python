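"""Build a one-record-per-gene annotation for nascent-transcription analysis.

The pipeline quantifies two regions per gene: a 550 bp TSS window covering
the promoter-proximal pause site (-50 to +500 around the transcription start)
and a gene body (+1001 to the 3' end of the shortest retained transcript,
avoiding alternative termination sites). Because genes have several annotated
isoforms, the annotation is reduced to a single "most-active" TSS per gene —
the candidate with the most sense reads in its TSS window — combined with the
shortest gene body.

Coordinates are 0-based half-open throughout (BED dialect on disk).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default allow-list for "standard" chromosomes
STANDARD_CHROMS: frozenset[str] = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY"}
)

TSS_UPSTREAM = 50
TSS_DOWNSTREAM = 500  # TSS window is [tss-50, tss+500), 550 bp
BODY_OFFSET = 1001  # gene body starts +1001 downstream of the TSS

__all__ = [
    "STANDARD_CHROMS",
    "filter_transcripts",
    "select_most_active_tss",
    "build_gene_models",
    "build_annotation",
    "tss_position",
]


def tss_position(transcripts: pd.DataFrame) -> np.ndarray:
    """Strand-aware TSS coordinate: start for '+', end for '-' records."""
    return np.where(
        transcripts["strand"].to_numpy() == "+",
        transcripts["start"].to_numpy(),
        transcripts["end"].to_numpy(),
    )


def filter_transcripts(
    transcripts: pd.DataFrame,
    min_length: int = 1500,
    allowed_chroms: frozenset[str] | set[str] = STANDARD_CHROMS,
) -> pd.DataFrame:
    """Drop short transcripts, non-standard chromosomes and duplicates.

    Retains records with ``end - start >= min_length`` on an allowed
    chromosome, keeping only one transcript per gene for each unique
    (start, end) pair. The 1500 bp default also removes rRNA-scale genes and
    guarantees a non-empty gene body downstream of the +1001 offset.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    length = transcripts["end"] - transcripts["start"]
    if (length <= 0).any():
        raise ValueError("transcript with end <= start")
    keep = (length >= min_length) & transcripts["chrom"].isin(allowed_chroms)
    out = transcripts.loc[keep].drop_duplicates(
        subset=["gene_id", "start", "end"], keep="first"
    )
    if out.empty:
        logger.warning("filter_transcripts: no transcripts retained")
    return out.reset_index(drop=True)


def select_most_active_tss(
    transcripts: pd.DataFrame,
    tss_counts: pd.DataFrame,
    ranking: str = "lexicographic",
) -> pd.DataFrame:
    """Pick one TSS per gene, ranked by reads in the candidate TSS windows.

    ``tss_counts`` carries ``transcript_id``, ``sense`` and ``antisense``
    read counts over each candidate's [-50, +500) window. With the default
    ``ranking="lexicographic"`` candidates are ordered by sense reads, then
    antisense reads, then 5'-most position in transcription direction, then
    transcript_id; ``ranking="combined"`` orders by sense + antisense first.

    Returns one row per gene: gene_id, transcript_id, chrom, strand, tss.
    Genes without any counted candidate are excluded with a log entry.
    """
    if ranking not in {"lexicographic", "combined"}:
        raise ValueError(f"unknown ranking {ranking!r}")
    cand = transcripts.merge(
        tss_counts[["transcript_id", "sense", "antisense"]],
        on="transcript_id", how="left",
    )
    missing = cand["sense"].isna()
    if missing.any():
        dropped = cand.loc[missing, "gene_id"].unique()
        cand = cand.loc[~missing]
        only_missing = set(dropped) - set(cand["gene_id"])
        if only_missing:
            logger.warning(
                "select_most_active_tss: %d gene(s) without counted candidates "
                "excluded: %s", len(only_missing), sorted(only_missing)[:10],
            )
    cand = cand.copy()
    cand["tss"] = tss_position(cand)
    # 5'-most in transcription direction: smallest tss on '+', largest on '-'
    cand["_five_prime"] = np.where(cand["strand"] == "+", cand["tss"], -cand["tss"])
    if ranking == "combined":
        cand["_primary"] = cand["sense"] + cand["antisense"]
        order = ["_primary", "sense", "antisense"]
    else:
        order = ["sense", "antisense"]
    cand = cand.sort_values(
        ["gene_id"] + order + ["_five_prime", "transcript_id"],
        ascending=[True] + [False] * len(order) + [True, True],
        kind="mergesort",
    )
    best = cand.groupby("gene_id", sort=True).head(1)
    return best[["gene_id", "transcript_id", "chrom", "strand", "tss"]].reset_index(drop=True)


def build_gene_models(
    transcripts: pd.DataFrame, chosen_tss: pd.DataFrame
) -> pd.DataFrame:
    """Combine each gene's chosen TSS with its shortest retained gene body.

    The body ends at the gene-strand 3' end of the shortest retained
    transcript; genes whose shortest body would be empty (3' end within
    +1001 bp of the TSS in transcription direction) are dropped with a log
    entry. Output columns: gene_id, chrom, strand, tss, tss_start, tss_end,
    body_start, body_end, tss_len, body_len.
    """
    rows = []
    dropped = []
    tx_by_gene = dict(tuple(transcripts.groupby("gene_id", sort=False)))
    for rec in chosen_tss.itertuples():
        tx = tx_by_gene.get(rec.gene_id)
        if tx is None:
            dropped.append(rec.gene_id)
            continue
        if not ((tx["chrom"] == rec.chrom) & (tx["strand"] == rec.strand)).all():
            raise ValueError(
                f"gene {rec.gene_id}: transcripts disagree with chosen TSS on "
                "chromosome/strand"
            )
        lengths = tx["end"] - tx["start"]
        shortest = tx.loc[lengths.idxmin()]
        if rec.strand == "+":
            tss_start, tss_end = rec.tss - TSS_UPSTREAM, rec.tss + TSS_DOWNSTREAM
            body_start, body_end = rec.tss + BODY_OFFSET, int(shortest["end"])
        else:
            tss_start, tss_end = rec.tss - TSS_DOWNSTREAM, rec.tss + TSS_UPSTREAM
            body_start, body_end = int(shortest["start"]), rec.tss - BODY_OFFSET
        if body_end <= body_start:
            dropped.append(rec.gene_id)
            continue
        rows.append(dict(
            gene_id=rec.gene_id, chrom=rec.chrom, strand=rec.strand, tss=rec.tss,
            tss_start=int(tss_start), tss_end=int(tss_end),
            body_start=int(body_start), body_end=int(body_end),
            tss_len=int(tss_end - tss_start), body_len=int(body_end - body_start),
        ))
    if dropped:
        logger.warning(
            "build_gene_models: %d gene(s) dropped (empty body or no retained "
            "transcript): %s", len(dropped), dropped[:10],
        )
    models = pd.DataFrame(rows)
    if not models.empty and models["gene_id"].duplicated().any():
        raise ValueError("duplicate gene models")
    return models


def build_annotation(
    transcripts: pd.DataFrame,
    tss_counts: pd.DataFrame,
    min_length: int = 1500,
    allowed_chroms: frozenset[str] | set[str] = STANDARD_CHROMS,
    ranking: str = "lexicographic",
) -> pd.DataFrame:
    """Filter transcripts, pick the most-active TSS, build one model per gene."""
    retained = filter_transcripts(transcripts, min_length, allowed_chroms)
    chosen = select_most_active_tss(retained, tss_counts, ranking=ranking)
    return build_gene_models(retained, chosen)
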