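"""Promoter-usage classification of multi-transcript tissue-specific genes.

The transcription start site (TSS) of a transcript is its strand-aware 5'
end: the ``start`` coordinate on the + strand, the ``end`` coordinate on the
- strand (1-based).  A gene whose tissue-specific transcripts all start
within ``tss_threshold`` base pairs of each other (maximum pairwise distance
strictly below the threshold) is called ``same_promoter``; otherwise
``multi_promoter``.  The three conventional thresholds 50, 500 and 5000 bp
are computed side by side.  Genes are additionally split by tissue scope:
``single_tissue`` when all their TSp transcripts are specific to the same
tissue, ``multi_tissue`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .formats_io import AnnotationTable

__all__ = [
    "PromoterCall",
    "get_tss",
    "classify_promoters",
    "classify_tissue_scope",
    "analyze_promoters",
    "DEFAULT_TSS_THRESHOLDS",
]

DEFAULT_TSS_THRESHOLDS = (50, 500, 5000)


@dataclass(frozen=True)
class PromoterCall:
    gene_id: str
    n_tsp_transcripts: int
    transcript_group: str  # single_transcript | multi_transcript
    tissue_scope: str | None  # single_tissue | multi_tissue (multi-transcript only)
    promoter_call: str | None  # same_promoter | multi_promoter (multi-transcript only)
    tss_threshold: int | None
    max_pairwise_tss_distance: int | None


def get_tss(start: int, end: int, strand: str) -> int:
    """Strand-aware transcription start site (1-based)."""
    if strand == "+":
        return int(start)
    if strand == "-":
        return int(end)
    raise ValidationError(f"unknown strand symbol {strand!r}")


def _tss_vector(sub: pd.DataFrame) -> np.ndarray:
    return np.array(
        [get_tss(s, e, st) for s, e, st in zip(sub["start"], sub["end"], sub["strand"])],
        dtype=np.int64,
    )


def max_pairwise_distance(tss: Sequence[int]) -> int:
    """Largest |TSS_a - TSS_b| over all pairs (= range of the positions)."""
    tss = np.asarray(tss, dtype=np.int64)
    if len(tss) < 2:
        return 0
    return int(tss.max() - tss.min())


def classify_promoters(gene_id: str, transcripts: pd.DataFrame, tss_threshold: int) -> PromoterCall:
    """Same/multi-promoter call for one gene's TSp transcripts (n >= 2).

    ``transcripts`` is an annotation sub-frame (chrom/start/end/strand); all
    rows must lie on one chromosome.  The maximum pairwise TSS distance
    strictly below the threshold means ``same_promoter`` (max-linkage: every
    pair is then within threshold).
    """
    if len(transcripts) < 2:
        raise ValidationError(f"gene {gene_id}: promoter call needs >= 2 transcripts")
    chroms = set(transcripts["chrom"])
    if len(chroms) != 1:
        raise ValidationError(
            f"gene {gene_id} has transcripts on multiple chromosomes: {sorted(chroms)}"
        )
    dist = max_pairwise_distance(_tss_vector(transcripts))
    call = "same_promoter" if dist < tss_threshold else "multi_promoter"
    return PromoterCall(
        gene_id=gene_id,
        n_tsp_transcripts=len(transcripts),
        transcript_group="multi_transcript",
        tissue_scope=None,
        promoter_call=call,
        tss_threshold=int(tss_threshold),
        max_pairwise_tss_distance=dist,
    )


def classify_tissue_scope(assigned_tissues: Iterable[str]) -> str:
    """single_tissue if every transcript is specific to the same tissue."""
    tissues = set(assigned_tissues)
    if not tissues:
        raise ValidationError("tissue scope needs at least one assigned tissue")
    return "single_tissue" if len(tissues) == 1 else "multi_tissue"


def analyze_promoters(
    result,
    annotation: AnnotationTable,
    tss_thresholds: Sequence[int] = DEFAULT_TSS_THRESHOLDS,
) -> pd.DataFrame:
    """Promoter/scope table for every gene with >= 1 TSp transcript.

    ``result`` is a :class:`~transpec.classifier.ClassificationResult`; its
    TSp transcripts are mapped to genes through the annotation.  Output: one
    row per gene with the transcript group, tissue scope, max pairwise TSS
    distance and a same/multi promoter call per threshold.
    """
    tsp = result.frame[result.frame["class"] == "TSp"]
    ann = annotation.df.set_index("transcript_id")
    missing = [t for t in tsp["transcript_id"] if t not in ann.index]
    if missing:
        raise ValidationError(
            f"TSp transcripts absent from annotation: {', '.join(missing[:10])}"
        )
    thresholds = [int(t) for t in tss_thresholds]
    rows = []
    sub = ann.loc[tsp["transcript_id"]].copy()
    sub["assigned_tissue"] = tsp["assigned_tissues"].to_numpy()
    for gene_id, g in sub.groupby("gene_id", sort=True):
        if len(g) == 1:
            row = {
                "gene_id": gene_id,
                "n_tsp_transcripts": 1,
                "transcript_group": "single_transcript",
                "tissue_scope": "",
                "max_pairwise_tss_distance": 0,
            }
            for t in thresholds:
                row[f"promoter_call_{t}"] = ""
        else:
            dist = max_pairwise_distance(_tss_vector(g))
            row = {
                "gene_id": gene_id,
                "n_tsp_transcripts": len(g),
                "transcript_group": "multi_transcript",
                "tissue_scope": classify_tissue_scope(g["assigned_tissue"]),
                "max_pairwise_tss_distance": dist,
            }
            chroms = set(g["chrom"])
            if len(chroms) != 1:
                raise ValidationError(
                    f"gene {gene_id} has transcripts on multiple chromosomes: {sorted(chroms)}"
                )
            for t in thresholds:
                row[f"promoter_call_{t}"] = (
                    "same_promoter" if dist < t else "multi_promoter"
                )
        rows.append(row)
    return pd.DataFrame.from_records(rows)
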