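"""Sample- and tissue-level quality control.

Two sequential filters run before any statistic is computed: samples with an
RNA integrity number (RIN) below ``min_rin`` are discarded first, then
tissues whose *surviving* sample count falls below ``min_samples_per_tissue``
are dropped entirely.  Both comparisons are strict (a sample at exactly
RIN 7.0, or a tissue with exactly 50 samples, is kept).  An optional
tissue-grouping map collapses subregion labels (e.g. brain subregions) into
one tissue group before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .exceptions import ValidationError
from .formats_io import ExpressionMatrix, SampleTable

__all__ = ["QCConfig", "QCReport", "apply_grouping", "filter_samples", "read_grouping"]


@dataclass(frozen=True)
class QCConfig:
    """Quality-control thresholds.

    min_rin: minimum RNA integrity number a sample must have (default 7).
    min_samples_per_tissue: minimum surviving samples for a tissue to be
        analysed (default 50).
    tissue_grouping: optional raw-label -> grouped-label map applied before
        filtering.
    """

    min_rin: float = 7.0
    min_samples_per_tissue: int = 50
    tissue_grouping: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not 1.0 <= self.min_rin <= 10.0:
            raise ValidationError("min_rin must lie in [1, 10]")
        if self.min_samples_per_tissue < 1:
            raise ValidationError("min_samples_per_tissue must be >= 1")


@dataclass
class QCReport:
    """Per-tissue accounting of what the two filter steps removed."""

    per_tissue: pd.DataFrame  # tissue, n_before, n_removed_rin, n_after_rin, removed_by_size, n_after
    n_samples_in: int
    n_samples_out: int

    def to_frame(self) -> pd.DataFrame:
        return self.per_tissue.copy()

    def write(self, path: str) -> None:
        self.per_tissue.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_grouping(path: str) -> dict[str, str]:
    """Read a two-column (raw label, grouped label) TSV into a grouping map."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("grouping map TSV needs two columns: raw label, grouped label")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def apply_grouping(samples: SampleTable, grouping: Mapping[str, str] | None) -> SampleTable:
    """Replace tissue labels found in the map; unmapped labels pass through."""
    if not grouping:
        return samples
    tissues = samples.df["tissue"].map(lambda t: grouping.get(t, t))
    return samples.with_tissues(list(tissues))


def filter_samples(
    samples: SampleTable, expr: ExpressionMatrix, config: QCConfig | None = None
) -> tuple[SampleTable, ExpressionMatrix, QCReport]:
    """Apply the RIN filter, then the tissue-size filter.

    Every sample must have a column in the expression matrix.  The returned
    matrix is subset (in sample-table order) to surviving samples.  Raises
    :class:`ValidationError` if nothing survives.
    """
    config = config or QCConfig()
    if config.tissue_grouping:
        samples = apply_grouping(samples, config.tissue_grouping)
    matrix_samples = set(expr.sample_ids)
    missing = [s for s in samples.sample_ids if s not in matrix_samples]
    if missing:
        raise ValidationError(
            f"samples without a matrix column: {', '.join(missing[:10])}"
        )

    df = samples.df
    n_before = df.groupby("tissue").size()

    pass_rin = df["rin"] >= config.min_rin
    after_rin = df[pass_rin]
    n_after_rin = after_rin.groupby("tissue").size().reindex(n_before.index, fill_value=0)

    sizes_ok = n_after_rin[n_after_rin >= config.min_samples_per_tissue].index
    surviving = after_rin[after_rin["tissue"].isin(sizes_ok)]

    report = QCReport(
        per_tissue=pd.DataFrame(
            {
                "tissue": n_before.index,
                "n_before": n_before.to_numpy(),
                "n_removed_rin": (n_before - n_after_rin).to_numpy(),
                "n_after_rin": n_after_rin.to_numpy(),
                "removed_by_size": [t not in set(sizes_ok) for t in n_before.index],
                "n_after": [
                    (n_after_rin[t] if t in set(sizes_ok) else 0) for t in n_before.index
                ],
            }
        ).reset_index(drop=True),
        n_samples_in=len(df),
        n_samples_out=len(surviving),
    )

    if len(surviving) == 0:
        raise ValidationError("no samples survive QC")

    kept = SampleTable(surviving.reset_index(drop=True))
    return kept, expr.subset_samples(list(kept.sample_ids)), report
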