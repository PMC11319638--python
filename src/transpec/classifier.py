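"""The five-way expression-class decision tree.

With per-tissue probabilities P_ij and cutoffs (R-IP_i, L-IP_i), let
``k = #{i : P_ij >= R-IP_i}`` be the number of tissues in which transcript
*j* is expressed.  The classes are then assigned as:

* ``k = 0``  — **Null** if ``P_ij < L-IP_i`` in *every* tissue (the transcript
  sits in the unexpressed left peak everywhere), otherwise **Low**.
* ``k = 1``  — a tissue-specific candidate: **TSp** if both FC-MAX >= 1 and
  EMP-p <= 0.05 hold in the expressed tissue, otherwise demoted (default to
  **Low**).
* ``2 <= k <= floor(0.5 n)`` — a tissue-enhanced candidate: **TEn** if the
  fold-change/p-value criterion passes for the expressed tissue set,
  otherwise demoted.
* ``k > floor(0.5 n)`` — **Wide**, with no further statistics required.

Boundary comparisons are exactly as stated: ``P_ij >= R-IP`` counts as
expressed, ``FC-MAX >= 1`` and ``EMP-p <= 0.05`` pass, ``P_ij < L-IP`` is
null.  Every transcript receives exactly one label plus a decision trace
recording which rule fired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .specificity import SpecificityStats
from .thresholds import ProbabilityTable

__all__ = [
    "CLASSES",
    "ClassificationConfig",
    "ClassificationResult",
    "count_expressed_tissues",
    "candidate_pairs",
    "classify",
    "summarize",
]

CLASSES = ("TSp", "TEn", "Wide", "Low", "Null")


@dataclass(frozen=True)
class ClassificationConfig:
    """Cutoffs of the decision tree.

    fc_cutoff: minimum FC-MAX (log2 units) for a TSp/TEn call (default 1.0,
        i.e. two-fold over the best competing tissue).
    emp_p_cutoff: maximum empirical p-value (default 0.05).
    ten_max_fraction: fraction of tissues bounding the TEn class; transcripts
        expressed in more than ``floor(ten_max_fraction * n)`` tissues are
        Wide (default 0.5).
    demotion_class: class for TSp/TEn candidates failing the fold-change or
        p-value cutoff (default "Low").
    ten_mode: how the statistic is defined for multi-tissue candidates —
        "set" (the expressed set's weakest member versus the strongest
        outside tissue, default) or "best_tissue" (plain FC-MAX at the
        set member with the highest mean).
    """

    fc_cutoff: float = 1.0
    emp_p_cutoff: float = 0.05
    ten_max_fraction: float = 0.5
    demotion_class: str = "Low"
    ten_mode: str = "set"

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 0:
            raise ValidationError("fc_cutoff must be > 0")
        if not 0.0 < self.emp_p_cutoff < 1.0:
            raise ValidationError("emp_p_cutoff must lie in (0, 1)")
        if not 0.0 < self.ten_max_fraction < 1.0:
            raise ValidationError("ten_max_fraction must lie in (0, 1)")
        if self.demotion_class not in CLASSES:
            raise ValidationError(f"demotion_class must be one of {CLASSES}")
        if self.ten_mode not in ("set", "best_tissue"):
            raise ValidationError("ten_mode must be 'set' or 'best_tissue'")


class ClassificationResult:
    """Per-transcript class labels with full decision provenance.

    ``frame`` columns: ``transcript_id``, ``k``, ``expressed_tissues``
    (semicolon-joined tissues counted in k), ``class``, ``assigned_tissues``
    (set for final TSp/TEn calls, empty otherwise), ``fc_max``, ``emp_p``
    (NA where the decision needed no statistic) and ``decision_trace``.
    """

    def __init__(self, frame: pd.DataFrame, probabilities: ProbabilityTable | None = None):
        required = {"transcript_id", "k", "class", "assigned_tissues", "decision_trace"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"classification frame missing columns: {sorted(missing)}")
        bad = set(frame["class"]) - set(CLASSES)
        if bad:
            raise ValidationError(f"unknown class labels: {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)
        self.probabilities = probabilities

    def class_counts(self) -> pd.Series:
        counts = self.frame["class"].value_counts()
        return counts.reindex(CLASSES, fill_value=0).rename("n_transcripts")

    def __len__(self) -> int:
        return len(self.frame)


def count_expressed_tissues(
    probs: ProbabilityTable, thresholds: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """k[j] = #{i : P_ij >= R-IP_i}, plus the boolean expressed matrix.

    ``thresholds`` must cover every tissue column of the probability table.
    """
    missing = [t for t in probs.tissue_ids if t not in thresholds.index]
    if missing:
        raise ValidationError(f"no threshold for tissue(s): {', '.join(missing)}")
    rip = thresholds.loc[probs.tissue_ids, "rip"].to_numpy(dtype=float)
    expressed = probs.p >= rip[None, :]
    return expressed.sum(axis=1), expressed


def candidate_pairs(
    probs: ProbabilityTable,
    thresholds: pd.DataFrame,
    config: ClassificationConfig | None = None,
    means: "np.ndarray | None" = None,
) -> list[tuple[str, tuple[str, ...]]]:
    """(transcript, expressed-tissue set) pairs needing FC-MAX / EMP-p.

    These are the transcripts with ``1 <= k <= floor(ten_max_fraction * n)``.
    Under ``ten_mode='best_tissue'`` the candidate set is collapsed to the
    expressed tissue with the highest mean TPM (``means`` required, aligned
    with the probability table).
    """
    config = config or ClassificationConfig()
    k, expressed = count_expressed_tissues(probs, thresholds)
    n = len(probs.tissue_ids)
    kmax = int(np.floor(config.ten_max_fraction * n))
    tissue_arr = np.asarray(probs.tissue_ids, dtype=object)
    pairs: list[tuple[str, tuple[str, ...]]] = []
    for j in np.flatnonzero((k >= 1) & (k <= kmax)):
        tset = tuple(tissue_arr[expressed[j]])
        if config.ten_mode == "best_tissue" and len(tset) > 1:
            if means is None:
                raise ValidationError("ten_mode='best_tissue' requires the mean matrix")
            cols = np.flatnonzero(expressed[j])
            tset = (tissue_arr[cols[np.argmax(means[j, cols])]],)
        pairs.append((str(probs.transcript_ids[j]), tset))
    return pairs


def classify(
    probs: ProbabilityTable,
    thresholds: pd.DataFrame,
    stats: SpecificityStats,
    config: ClassificationConfig | None = None,
) -> ClassificationResult:
    """Assign every transcript to exactly one of the five classes.

    ``stats`` must contain a candidate row (FC-MAX and EMP-p) for every
    transcript with ``1 <= k <= floor(ten_max_fraction * n)``; a missing
    statistic is a hard error naming the transcript.
    """
    config = config or ClassificationConfig()
    k_vec, expressed = count_expressed_tissues(probs, thresholds)
    lip = thresholds.loc[probs.tissue_ids, "lip"].to_numpy(dtype=float)
    below_lip_all = (probs.p < lip[None, :]).all(axis=1)
    n = len(probs.tissue_ids)
    kmax = int(np.floor(config.ten_max_fraction * n))
    tissue_arr = np.asarray(probs.tissue_ids, dtype=object)

    records = []
    for j, tx in enumerate(probs.transcript_ids):
        k = int(k_vec[j])
        tset = tuple(tissue_arr[expressed[j]])
        fc = np.nan
        p = np.nan
        if k == 0:
            if below_lip_all[j]:
                label = "Null"
                trace = "k=0; P<L-IP in all tissues -> Null"
            else:
                label = "Low"
                trace = "k=0; P>=L-IP somewhere -> Low"
            assigned: tuple[str, ...] = ()
        elif k > kmax:
            label = "Wide"
            trace = f"k={k}>{kmax} -> Wide"
            assigned = ()
        else:
            row = stats.lookup(str(tx))
            if row is None or not np.isfinite(row.fc_max) or not np.isfinite(row.emp_p):
                raise ValidationError(
                    f"transcript {tx} (k={k}) is a TSp/TEn candidate but has no "
                    "FC-MAX / EMP-p statistics"
                )
            fc, p = float(row.fc_max), float(row.emp_p)
            target = "TSp" if k == 1 else "TEn"
            fc_ok = fc >= config.fc_cutoff
            p_ok = p <= config.emp_p_cutoff
            if fc_ok and p_ok:
                label = target
                assigned = tset
                trace = (
                    f"k={k}; FC-MAX={fc:.3g}>={config.fc_cutoff:g} and "
                    f"EMP-p={p:.3g}<={config.emp_p_cutoff:g} -> {target}"
                )
            else:
                label = config.demotion_class
                assigned = ()
                fails = []
                if not fc_ok:
                    fails.append(f"FC-MAX={fc:.3g}<{config.fc_cutoff:g}")
                if not p_ok:
                    fails.append(f"EMP-p={p:.3g}>{config.emp_p_cutoff:g}")
                trace = f"k={k}; {target} candidate failed {', '.join(fails)} -> {label}"
        records.append(
            {
                "transcript_id": str(tx),
                "k": k,
                "expressed_tissues": ";".join(tset),
                "class": label,
                "assigned_tissues": ";".join(assigned),
                "fc_max": fc,
                "emp_p": p,
                "decision_trace": trace,
            }
        )
    columns = [
        "transcript_id", "k", "expressed_tissues", "class", "assigned_tissues",
        "fc_max", "emp_p", "decision_trace",
    ]
    frame = pd.DataFrame.from_records(records, columns=columns)
    return ClassificationResult(frame, probabilities=probs)


def summarize(
    result: ClassificationResult,
    tx2gene: "pd.Series | None" = None,
) -> dict[str, pd.DataFrame]:
    """Per-class transcript (and gene) counts plus per-tissue TSp counts."""
    if len(result) == 0:
        raise ValidationError("cannot summarize an empty classification")
    frame = result.frame
    counts = result.class_counts().rename_axis("class").reset_index()
    if tx2gene is not None:
        genes = frame["transcript_id"].map(tx2gene)
        n_genes = (
            pd.DataFrame({"class": frame["class"], "gene": genes})
            .dropna()
            .groupby("class")["gene"]
            .nunique()
            .reindex(CLASSES, fill_value=0)
        )
        counts["n_genes"] = n_genes.to_numpy()
    tsp = frame[frame["class"] == "TSp"]
    per_tissue = (
        tsp.groupby("assigned_tissues").size().rename("n_tsp").rename_axis("tissue").reset_index()
        if len(tsp)
        else pd.DataFrame({"tissue": [], "n_tsp": []})
    )
    return {"class_counts": counts, "tsp_per_tissue": per_tissue}
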