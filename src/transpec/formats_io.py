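"""Readers, writers and validated containers for the pipeline's file formats.

The pipeline touches four plain-text formats:

* expression matrices as GCT 1.2 (the GTEx transcript-TPM dialect) or plain
  TSV with transcript rows and sample columns,
* sample metadata (sample_id / tissue / rin) as TSV,
* transcript models as GTF 2.2 (parsed through :mod:`pyranges`),
* result tables as TSV.

All coordinates are 1-based inclusive (GTF convention) everywhere in the
public API.  Numeric TSV output uses pandas' shortest round-tripping float
representation, so a write/read cycle reproduces values exactly.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "AnnotationTable",
    "read_expression",
    "write_expression",
    "read_sample_table",
    "write_sample_table",
    "read_annotation",
    "write_annotation",
    "write_results",
    "read_results",
]

_VALID_STRANDS = frozenset({"+", "-"})


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


class ExpressionMatrix:
    """Dense transcripts × samples TPM matrix with identifier bookkeeping.

    Parameters
    ----------
    values
        Non-negative, finite TPM values, shape ``(n_transcripts, n_samples)``.
    transcript_ids, sample_ids
        Duplicate-free identifier sequences matching the matrix dimensions.
    description
        Optional per-transcript description column (preserved from GCT input,
        never used by any computation).
    """

    def __init__(
        self,
        values,
        transcript_ids: Sequence[str],
        sample_ids: Sequence[str],
        description: Sequence[str] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        tx = np.asarray(list(transcript_ids), dtype=object)
        sm = np.asarray(list(sample_ids), dtype=object)
        if values.shape != (len(tx), len(sm)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(tx)} transcript IDs x {len(sm)} sample IDs"
            )
        _check_unique(tx, "transcript IDs")
        _check_unique(sm, "sample IDs")
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValidationError("expression matrix contains negative TPM values")
        if description is not None:
            description = np.asarray(list(description), dtype=object)
            if len(description) != len(tx):
                raise ValidationError("description length does not match transcript count")
        self.values = values
        self.transcript_ids = tx
        self.sample_ids = sm
        self.description = description

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame indexed by transcript ID, columns = samples."""
        return cls(df.to_numpy(dtype=float), df.index, df.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column subset (and reorder) by sample ID."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples absent from matrix: {', '.join(missing[:10])}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx], self.transcript_ids, list(sample_ids), self.description
        )

    def __eq__(self, other: object) -> bool:  # identifier-exact, value-exact
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            list(self.transcript_ids) == list(other.transcript_ids)
            and list(self.sample_ids) == list(other.sample_ids)
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} transcripts x {self.shape[1]} samples)"


class SampleTable:
    """Per-sample tissue assignment and RIN quality score.

    Wraps a DataFrame with columns ``sample_id``, ``tissue``, ``rin``;
    sample IDs unique, tissues non-empty, RIN within [1, 10].
    """

    REQUIRED = ("sample_id", "tissue", "rin")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing required columns: {', '.join(missing)}")
        df = df.loc[:, list(self.REQUIRED)].reset_index(drop=True).copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["tissue"] = df["tissue"].astype(str)
        try:
            df["rin"] = pd.to_numeric(df["rin"], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"RIN values are not numeric: {exc}") from exc
        _check_unique(df["sample_id"].to_numpy(dtype=object), "sample IDs")
        bad_rin = df.loc[~df["rin"].between(1.0, 10.0), "sample_id"]
        if len(bad_rin):
            raise ValidationError(
                f"RIN outside [1, 10] for samples: {', '.join(bad_rin.head(10))}"
            )
        if (df["tissue"].str.len() == 0).any():
            raise ValidationError("empty tissue label")
        self.df = df

    @classmethod
    def from_records(
        cls, sample_ids: Iterable[str], tissues: Iterable[str], rins: Iterable[float]
    ) -> "SampleTable":
        return cls(pd.DataFrame({"sample_id": list(sample_ids),
                                 "tissue": list(tissues),
                                 "rin": list(rins)}))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy(dtype=object)

    @property
    def tissues(self) -> list[str]:
        """Sorted unique tissue labels — the canonical tissue order everywhere."""
        return sorted(self.df["tissue"].unique())

    def tissue_sizes(self) -> pd.Series:
        return self.df.groupby("tissue").size()

    def with_tissues(self, tissues: Sequence[str]) -> "SampleTable":
        df = self.df.copy()
        df["tissue"] = list(tissues)
        return SampleTable(df)

    def __repr__(self) -> str:
        return f"SampleTable({len(self)} samples, {len(self.tissues)} tissues)"


class AnnotationTable:
    """Transcript models: one row per transcript, 1-based inclusive coordinates."""

    REQUIRED = ("transcript_id", "gene_id", "chrom", "start", "end", "strand")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing required columns: {', '.join(missing)}")
        df = df.loc[:, list(self.REQUIRED)].reset_index(drop=True).copy()
        for col in ("transcript_id", "gene_id", "chrom", "strand"):
            if df[col].isna().any():
                bad = df.index[df[col].isna()][:5].tolist()
                raise ValidationError(f"annotation rows {bad} lack a {col} attribute")
            df[col] = df[col].astype(str)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        _check_unique(df["transcript_id"].to_numpy(dtype=object), "transcript IDs")
        bad_strand = sorted(set(df["strand"]) - _VALID_STRANDS)
        if bad_strand:
            raise ValidationError(f"unknown strand symbol(s): {', '.join(bad_strand)}")
        if (df["start"] < 1).any():
            raise ValidationError("annotation start positions must be >= 1 (1-based)")
        if (df["start"] > df["end"]).any():
            raise ValidationError("annotation rows with start > end")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"AnnotationTable({len(self)} transcripts)"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    return "gct" if str(path).lower().endswith(".gct") else "tsv"


def read_expression(path: str, format: str | None = None) -> ExpressionMatrix:
    """Read a transcripts × samples TPM matrix from GCT 1.2 or TSV.

    GCT 1.2 layout: a ``#1.2`` version line, a ``<rows>\\t<cols>`` line, then a
    header row (``Name``, ``Description``, sample IDs) and one row per
    transcript.  The declared row/column counts must match the body.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("gct", "tsv"):
        raise ValidationError(f"unknown expression format {fmt!r} (expected gct or tsv)")
    if fmt == "gct":
        with open(path, "rt", encoding="utf-8") as fh:
            version = fh.readline().rstrip("\n")
            if version.strip() != "#1.2":
                raise FormatError(f"not a GCT 1.2 file; first line is {version!r}")
            dims = fh.readline().rstrip("\n")
            parts = dims.split("\t")
            try:
                n_rows, n_cols = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                raise FormatError(f"malformed GCT dimension line: {dims!r}") from None
            body = pd.read_csv(fh, sep="\t", header=0, dtype={0: str, 1: str},
                                float_precision="round_trip")
        if body.shape[1] - 2 != n_cols:
            raise FormatError(
                f"GCT header declares {n_cols} samples but body has {body.shape[1] - 2}"
            )
        if len(body) != n_rows:
            raise FormatError(f"GCT header declares {n_rows} rows but body has {len(body)}")
        try:
            values = body.iloc[:, 2:].to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric TPM value in GCT body: {exc}") from exc
        return ExpressionMatrix(
            values,
            body.iloc[:, 0].tolist(),
            [str(c) for c in body.columns[2:]],
            description=body.iloc[:, 1].tolist(),
        )
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#",
                     float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric TPM value in TSV body: {exc}") from exc
    return ExpressionMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_expression(path: str, expr: ExpressionMatrix, format: str | None = None) -> None:
    """Write an :class:`ExpressionMatrix` as GCT 1.2 or TSV (full precision)."""
    fmt = format or _infer_format(path)
    if fmt == "gct":
        desc = expr.description
        if desc is None:
            desc = np.full(len(expr.transcript_ids), "na", dtype=object)
        body = pd.DataFrame(expr.values, columns=list(expr.sample_ids))
        body.insert(0, "Description", desc)
        body.insert(0, "Name", expr.transcript_ids)
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            body.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    elif fmt == "tsv":
        expr.to_frame().to_csv(path, sep="\t", lineterminator="\n")
    else:
        raise ValidationError(f"unknown expression format {fmt!r} (expected gct or tsv)")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_table(path: str) -> SampleTable:
    """Read sample metadata TSV with (case-insensitive) columns sample_id, tissue, rin."""
    df = pd.read_csv(path, sep="\t", header=0, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return SampleTable(df)


def write_sample_table(path: str, samples: SampleTable) -> None:
    samples.df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str) -> AnnotationTable:
    """Read transcript records from a GTF file.

    Only ``transcript`` feature rows are used; each must carry ``gene_id``
    and ``transcript_id`` attributes and a ``+``/``-`` strand.  pyranges is
    used for parsing (it returns 0-based starts, converted back to the GTF
    1-based convention here).
    """
    import pyranges as pr  # deferred: pyranges import is slow

    if not os.path.exists(path):
        raise ValidationError(f"annotation file not found: {path}")
    gr = pr.read_gtf(path)
    df = gr.df
    if len(df) == 0 or "Feature" not in df.columns:
        raise FormatError(f"no features parsed from GTF {path}")
    df = df[df["Feature"].astype(str) == "transcript"].copy()
    if len(df) == 0:
        raise ValidationError(f"GTF {path} contains no 'transcript' feature rows")
    for col in ("gene_id", "transcript_id"):
        if col not in df.columns:
            raise ValidationError(f"GTF transcript rows lack the {col} attribute")
    out = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"].to_numpy(dtype=object),
            "gene_id": df["gene_id"].to_numpy(dtype=object),
            "chrom": df["Chromosome"].astype(str).to_numpy(dtype=object),
            "start": df["Start"].to_numpy(dtype=int) + 1,  # back to 1-based
            "end": df["End"].to_numpy(dtype=int),
            "strand": df["Strand"].astype(str).to_numpy(dtype=object),
        }
    )
    return AnnotationTable(out)


def write_annotation(path: str, annotation: AnnotationTable, source: str = "transpec") -> None:
    """Write transcript records as GTF 2.2 (one ``transcript`` row each)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for row in annotation.df.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";'
            fh.write(
                f"{row.chrom}\t{source}\ttranscript\t{row.start}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(path: str, result, stats, run_id: str | None = None) -> None:
    """Write the per-transcript classification + statistics table.

    One row per transcript, lexicographic by transcript ID: class label,
    expressed-tissue count ``k``, assigned tissues (semicolon-joined), the
    per-tissue expression probabilities, FC-MAX, EMP-p and tau.  ``result``
    and ``stats`` must cover the same transcript set.

    A ``# run <id>`` comment line is prepended when ``run_id`` is given;
    readers skip comment lines.
    """
    frame = result.frame
    tau = stats.tau
    res_tx = set(frame["transcript_id"])
    stat_tx = set(tau.index)
    if res_tx != stat_tx:
        raise ValidationError(
            "classification and statistics cover different transcript sets "
            f"({len(res_tx ^ stat_tx)} mismatched IDs)"
        )
    probs = result.probabilities
    out = frame.copy().sort_values("transcript_id", kind="mergesort").reset_index(drop=True)
    if probs is not None:
        pf = probs.to_frame().add_prefix("P_")
        out = out.merge(pf, left_on="transcript_id", right_index=True, how="left")
    out["tau"] = tau.reindex(out["transcript_id"]).to_numpy()
    buf = io.StringIO()
    if run_id is not None:
        buf.write(f"# run {run_id}\n")
    out.to_csv(buf, sep="\t", index=False, na_rep="NA", lineterminator="\n")
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_results(path: str) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                       keep_default_na=False, float_precision="round_trip",
                       dtype={"transcript_id": str, "class": str})
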