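"""Synthetic GTEx-like corpora with planted expression classes.

The generator emulates the statistical shape the pipeline is built for: a
transcripts × samples TPM matrix over ~26 tissues with >= 50 samples each,
whose pooled per-tissue expression probabilities follow a U-shaped
distribution (a large unexpressed left peak near 0 and an expressed right
peak near 1 - dropout).

Expression is modelled as a two-state mixture per sample: an *expressed*
state (lognormal, median ~20 TPM) entered with a class-dependent per-sample
probability, and a *background* state (lognormal, median ~0.01 TPM, far
below the 0.5 TPM baseline).  Planted classes:

* **TSp** — expressed with probability ``1 - dropout`` in one target tissue;
  one competitor tissue expresses the transcript in a fraction ``1/fc_effect``
  of its samples, so the true mean ratio to the best other tissue is about
  ``fc_effect`` while the competitor's probability stays far below the R-IP
  cutoff.
* **TEn** — the same with a target *set* of 2 .. floor(n/2) tissues.
* **Wide** — housekeeping-like: detected in nearly every sample (per-sample
  probability uniform in ``wide_core_range``, default (0.98, 1.0)) in a core
  of more than half the tissues, and *partially* detected (uniform in
  ``wide_partial_range``, default (0.70, 0.95)) everywhere else.  Partial
  tissues may fall on either side of the R-IP cutoff — harmless for a Wide
  call.  Together the two ranges reproduce the anatomy of real P_ij right
  peaks: a mode anchored at 1 by ubiquitously detected transcripts plus a
  broad left shoulder of variably detected ones, with the density inflection
  — the R-IP cutoff — in between.
* **Low** — per-sample expression probability drawn uniformly from the
  interior of the low band (default (0.30, 0.70)) in 1-3 tissues, never
  above it: consistently *inconsistent* expression.
* **Null** — background everywhere, with a tiny leak probability
  (uniform(0, 0.005)) small enough that realized probabilities stay below
  the L-IP cutoff in every tissue.

RIN scores are synthetic metadata drawn independently of expression, purely
to exercise the QC path: within each tissue exactly
``round(rin_below7_fraction * n)`` samples get RIN < 7 (stratified, so QC
removes a fixed share per tissue and no tissue ever falls below the 50-sample
floor by luck of the draw).  Generation is O(transcripts × samples) and fully
determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .formats_io import AnnotationTable, ExpressionMatrix, SampleTable

__all__ = ["CorpusSpec", "GroundTruth", "generate_corpus", "generate_annotation",
           "generate_null_corpus"]

DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "TSp": 500, "TEn": 500, "Wide": 1500, "Low": 1250, "Null": 1250,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a planted corpus.

    Defaults describe a GTEx-like design: 26 tissues, 60 samples each, a
    strong fold-change effect (8x) and 5% dropout in the expressed state.
    """

    n_tissues: int = 26
    samples_per_tissue: int | Mapping[str, int] = 60
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    high_median_tpm: float = 20.0
    high_sigma: float = 0.8
    background_median_tpm: float = 0.01
    background_sigma: float = 1.0
    dropout_expressed: float = 0.05
    fc_effect: float = 8.0
    low_prob_range: tuple[float, float] = (0.30, 0.70)
    wide_core_range: tuple[float, float] = (0.98, 1.00)
    wide_partial_range: tuple[float, float] = (0.70, 0.95)
    null_leak_max: float = 0.005
    rin_below7_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise ValidationError("need >= 2 tissues")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValidationError("class counts must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise ValidationError("class counts sum to zero: nothing to generate")
        unknown = set(self.class_counts) - {"TSp", "TEn", "Wide", "Low", "Null"}
        if unknown:
            raise ValidationError(f"unknown planted classes: {sorted(unknown)}")
        if self.fc_effect <= 1:
            raise ValidationError("fc_effect must exceed 1")
        for p in (self.dropout_expressed, self.null_leak_max, self.rin_below7_fraction,
                  *self.low_prob_range, *self.wide_partial_range,
                  *self.wide_core_range):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")


class GroundTruth:
    """Planted class, tissue set and gene of every generated transcript."""

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"transcript_id", "gene_id", "planted_class", "planted_tissues"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"ground truth missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    def write(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read(cls, path: str) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))

    def __len__(self) -> int:
        return len(self.frame)


def _tissue_names(n: int) -> list[str]:
    return [f"tissue{i + 1:02d}" for i in range(n)]


def _sample_layout(spec: CorpusSpec) -> tuple[list[str], list[str]]:
    tissues = _tissue_names(spec.n_tissues)
    if isinstance(spec.samples_per_tissue, Mapping):
        sizes = {t: int(spec.samples_per_tissue[t]) for t in tissues}
    else:
        sizes = {t: int(spec.samples_per_tissue) for t in tissues}
    sample_ids, labels = [], []
    i = 0
    for t in tissues:
        for _ in range(sizes[t]):
            i += 1
            sample_ids.append(f"S{i:05d}")
            labels.append(t)
    return sample_ids, labels


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size) -> np.ndarray:
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def generate_corpus(spec: CorpusSpec) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Generate (ExpressionMatrix, SampleTable, GroundTruth) for a planted corpus.

    The same seed reproduces the corpus bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids, labels = _sample_layout(spec)
    labels_arr = np.asarray(labels, dtype=object)
    tissues = _tissue_names(spec.n_tissues)
    tissue_cols = {t: np.flatnonzero(labels_arr == t) for t in tissues}
    n_samples = len(sample_ids)
    n_tx = sum(spec.class_counts.values())
    kmax = spec.n_tissues // 2

    # background state everywhere; class-specific columns are overwritten below
    values = _lognormal(rng, spec.background_median_tpm, spec.background_sigma,
                        (n_tx, n_samples))

    def express(row: int, tissue: str, prob: float) -> None:
        cols = tissue_cols[tissue]
        on = rng.random(len(cols)) < prob
        if on.any():
            values[row, cols[on]] = _lognormal(rng, spec.high_median_tpm,
                                               spec.high_sigma, int(on.sum()))

    order = [c for c in ("TSp", "TEn", "Wide", "Low", "Null") if spec.class_counts.get(c, 0)]
    tx_ids, planted_class, planted_tissues = [], [], []
    row = 0
    competitor_prob = 1.0 / spec.fc_effect
    for cls in order:
        for _ in range(spec.class_counts[cls]):
            tx_ids.append(f"TX{row + 1:06d}")
            planted_class.append(cls)
            if cls == "TSp":
                target = tissues[int(rng.integers(spec.n_tissues))]
                others = [t for t in tissues if t != target]
                competitor = others[int(rng.integers(len(others)))]
                express(row, target, 1.0 - spec.dropout_expressed)
                express(row, competitor, competitor_prob)
                tset = [target]
            elif cls == "TEn":
                k = int(rng.integers(2, kmax + 1))
                chosen = rng.choice(spec.n_tissues, size=k, replace=False)
                tset = sorted(tissues[i] for i in chosen)
                rest = [t for t in tissues if t not in tset]
                competitor = rest[int(rng.integers(len(rest)))]
                for t in tset:
                    express(row, t, 1.0 - spec.dropout_expressed)
                express(row, competitor, competitor_prob)
            elif cls == "Wide":
                k = int(rng.integers(kmax + 1, spec.n_tissues + 1))
                chosen = rng.choice(spec.n_tissues, size=k, replace=False)
                tset = sorted(tissues[i] for i in chosen)
                core = set(tset)
                for t in tissues:
                    if t in core:
                        express(row, t, float(rng.uniform(*spec.wide_core_range)))
                    else:
                        express(row, t, float(rng.uniform(*spec.wide_partial_range)))
            elif cls == "Low":
                k = int(rng.integers(1, 4))
                chosen = rng.choice(spec.n_tissues, size=k, replace=False)
                tset = sorted(tissues[i] for i in chosen)
                lo, hi = spec.low_prob_range
                for t in tset:
                    express(row, t, float(rng.uniform(lo, hi)))
            else:  # Null
                leak = float(rng.uniform(0.0, spec.null_leak_max))
                for t in tissues:
                    express(row, t, leak)
                tset = []
            planted_tissues.append(";".join(tset))
            row += 1

    # gene structure: TSp transcripts are grouped into genes (some multi-
    # transcript, exercising the promoter analysis); other classes get one
    # gene per transcript.
    gene_ids = _assign_genes(rng, tx_ids, planted_class)

    # stratified RIN: exactly round(fraction * n) low-quality samples per tissue
    rin = rng.uniform(7.0, 10.0, n_samples)
    for t in tissues:
        cols = tissue_cols[t]
        n_low = int(round(spec.rin_below7_fraction * len(cols)))
        low_idx = rng.choice(cols, size=n_low, replace=False)
        rin[low_idx] = rng.uniform(5.0, 6.9, n_low)
    samples = SampleTable.from_records(sample_ids, labels, rin.tolist())
    expr = ExpressionMatrix(values, tx_ids, sample_ids)
    truth = GroundTruth(
        pd.DataFrame(
            {
                "transcript_id": tx_ids,
                "gene_id": gene_ids,
                "planted_class": planted_class,
                "planted_tissues": planted_tissues,
            }
        )
    )
    return expr, samples, truth


def _assign_genes(rng: np.random.Generator, tx_ids, planted_class) -> list[str]:
    """Group ~40% of TSp transcripts into multi-transcript genes (2-4 each)."""
    gene_ids = [""] * len(tx_ids)
    tsp_rows = [i for i, c in enumerate(planted_class) if c == "TSp"]
    gene_no = 0
    i = 0
    while i < len(tsp_rows):
        gene_no += 1
        if rng.random() < 0.4 and len(tsp_rows) - i >= 2:
            size = int(rng.integers(2, min(4, len(tsp_rows) - i) + 1))
        else:
            size = 1
        for j in range(size):
            gene_ids[tsp_rows[i + j]] = f"GENE{gene_no:06d}"
        i += size
    for i, c in enumerate(planted_class):
        if c != "TSp":
            gene_no += 1
            gene_ids[i] = f"GENE{gene_no:06d}"
    return gene_ids


def generate_annotation(
    truth: GroundTruth,
    promoter_layout: str = "mixed",
    seed: int = 0,
    alternative_fraction: float = 0.5,
    shared_span: int = 30,
    alternative_gap: int = 6000,
) -> AnnotationTable:
    """Transcript models matching the ground truth's gene structure.

    ``shared`` layout puts every gene's TSSs within ``shared_span`` bp
    (< 50); ``alternative`` separates consecutive TSSs by ``alternative_gap``
    bp (> 5000); ``mixed`` assigns exactly
    ``round(alternative_fraction * n_multi_genes)`` multi-transcript genes
    (seeded shuffle) to the alternative layout.
    """
    if promoter_layout not in ("shared", "alternative", "mixed"):
        raise ValidationError(f"unknown promoter layout {promoter_layout!r}")
    rng = np.random.default_rng(seed)
    frame = truth.frame
    genes = frame.groupby("gene_id", sort=True)["transcript_id"].apply(list)

    multi = [g for g, txs in genes.items() if len(txs) > 1]
    alt_genes: set[str]
    if promoter_layout == "shared":
        alt_genes = set()
    elif promoter_layout == "alternative":
        alt_genes = set(multi)
    else:
        shuffled = list(multi)
        rng.shuffle(shuffled)
        n_alt = int(round(alternative_fraction * len(shuffled)))
        alt_genes = set(shuffled[:n_alt])

    chroms = [f"chr{c}" for c in (1, 2, 3, 4)]
    rows = []
    base_step = 10 * alternative_gap * 8  # generous per-gene spacing
    for g_idx, (gene_id, txs) in enumerate(genes.items()):
        chrom = chroms[g_idx % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        base = 100_000 + (g_idx // len(chroms)) * base_step
        for t_idx, tx in enumerate(txs):
            if gene_id in alt_genes:
                offset = t_idx * alternative_gap + int(rng.integers(0, shared_span))
            else:
                offset = int(rng.integers(0, shared_span))
            tss = base + offset
            length = int(rng.integers(800, 5000))
            if strand == "+":
                start, end = tss, tss + length
            else:
                start, end = max(1, tss - length), tss
            rows.append(
                {"transcript_id": tx, "gene_id": gene_id, "chrom": chrom,
                 "start": start, "end": end, "strand": strand}
            )
    return AnnotationTable(pd.DataFrame.from_records(rows))


def generate_null_corpus(
    n_tissues: int = 6,
    samples_per_tissue: int = 50,
    n_transcripts: int = 500,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Corpus with no true specificity anywhere.

    Each transcript's samples are i.i.d. from one transcript-specific
    lognormal shared by all tissues, so any apparent tissue enrichment is
    sampling noise.  Used to check the type-I error of the permutation
    p-value.
    """
    rng = np.random.default_rng(seed)
    tissues = _tissue_names(n_tissues)
    sample_ids, labels = [], []
    for t in tissues:
        for _ in range(samples_per_tissue):
            sample_ids.append(f"S{len(sample_ids) + 1:05d}")
            labels.append(t)
    mu = rng.uniform(math.log(0.5), math.log(50.0), n_transcripts)
    values = rng.lognormal(
        mean=mu[:, None], sigma=1.0, size=(n_transcripts, len(sample_ids))
    )
    tx_ids = [f"TX{i + 1:06d}" for i in range(n_transcripts)]
    samples = SampleTable.from_records(
        sample_ids, labels, rng.uniform(7.0, 10.0, len(sample_ids)).tolist()
    )
    return ExpressionMatrix(values, tx_ids, sample_ids), samples
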