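"""Fold-change, empirical p-values and the tau specificity index.

Given per-tissue mean TPM values ``m[j, i]`` for transcript *j*:

* **FC-MAX** — ``log2((m[j,i] + c) / (max_{k != i} m[j,k] + c))``, the log2
  ratio of the tissue of interest over the *best competing* tissue; ``c`` is
  a small pseudocount (default 0.001 TPM) so zero denominators are defined.
  At most one tissue per transcript can reach FC-MAX >= 1, because a ratio of
  2 over the best of the rest is only possible at the unique row maximum.
  For a candidate *set* of tissues the statistic generalises to the set's
  weakest member over the strongest outsider:
  ``log2((min_{i in S} m + c) / (max_{k not in S} m + c))``.

* **EMP-p** — an empirical p-value for FC-MAX obtained by stratified
  resampling.  Two modes:

  - ``permutation_null`` (default): tissue labels are permuted across all
    samples, preserving each tissue's sample count, and FC-MAX recomputed;
    ``p = (1 + #{null >= observed}) / (n_iterations + 1)``.
  - ``subsample_stability``: 80% of each tissue's samples are redrawn without
    replacement and FC-MAX recomputed; ``p`` is the add-one fraction of
    iterations in which the statistic drops below the fold-change cutoff,
    i.e. an instability score for the call.

  The add-one rule keeps p-values in ``[1/(B+1), 1]`` and valid under the
  null.  Note these p-values are exact for a candidate pair chosen *a
  priori*; in the full pipeline candidates are pre-filtered by the
  probability cutoff, so downstream p-values are conditional on that
  selection.

* **tau** — the classical specificity index ``sum(1 - x_hat_i) / (n - 1)``
  with ``x_hat_i = x_i / max_i x_i``; 1 means single-tissue expression, 0
  uniform expression.  Computed on ``log2(x + 1)``-transformed means by
  default (raw scale selectable); all-zero transcripts get tau = 0 and an
  ``all_zero`` flag.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .formats_io import ExpressionMatrix, SampleTable

__all__ = [
    "MeanExpressionTable",
    "SpecificityStats",
    "compute_means",
    "compute_fc_max",
    "fc_for_sets",
    "compute_emp_p",
    "compute_tau",
]

DEFAULT_PSEUDOCOUNT = 0.001
RESAMPLING_MODES = ("permutation_null", "subsample_stability")

# a candidate is (transcript_id, tissue) or (transcript_id, tuple-of-tissues)
Candidate = tuple[str, "str | tuple[str, ...]"]


class MeanExpressionTable:
    """Arithmetic mean TPM per transcript per tissue."""

    def __init__(self, m, transcript_ids, tissue_ids) -> None:
        m = np.asarray(m, dtype=float)
        if m.shape != (len(transcript_ids), len(tissue_ids)):
            raise ValidationError("mean matrix shape does not match identifier lists")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValidationError("mean TPM values must be finite and non-negative")
        self.m = m
        self.transcript_ids = np.asarray(list(transcript_ids), dtype=object)
        self.tissue_ids = list(tissue_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.m,
            index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=self.tissue_ids,
        )


class SpecificityStats:
    """Per-candidate FC-MAX / EMP-p plus the per-transcript tau vector.

    ``frame`` has one row per candidate transcript with columns
    ``transcript_id``, ``tissues`` (semicolon-joined candidate set),
    ``mtpm`` (mean TPM of the candidate tissue, or the set minimum),
    ``fc_max`` and ``emp_p``.  Resampling provenance (mode, iteration count,
    seed, pseudocount) is carried as attributes and written with all outputs.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        tau: pd.Series,
        mode: str = "permutation_null",
        n_iterations: int = 0,
        seed: int = 0,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> None:
        required = {"transcript_id", "tissues", "fc_max", "emp_p"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"stats frame missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self.tau = tau
        self.mode = mode
        self.n_iterations = int(n_iterations)
        self.seed = int(seed)
        self.pseudocount = float(pseudocount)
        self._by_tx = {
            row.transcript_id: row for row in self.frame.itertuples(index=False)
        }

    def lookup(self, transcript_id: str):
        """Candidate row for a transcript, or None."""
        return self._by_tx.get(transcript_id)

    def write(self, path: str, run_id: str | None = None) -> None:
        out = self.frame.copy()
        out["mode"] = self.mode
        out["n_iterations"] = self.n_iterations
        out["seed"] = self.seed
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            if run_id is not None:
                fh.write(f"# run {run_id}\n")
            out.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def compute_means(expr: ExpressionMatrix, samples: SampleTable) -> MeanExpressionTable:
    """Mean TPM of each transcript in each tissue."""
    tissues = samples.tissues
    expr = expr.subset_samples(list(samples.sample_ids))
    labels = samples.df["tissue"].to_numpy()
    m = np.empty((expr.shape[0], len(tissues)))
    for col, tissue in enumerate(tissues):
        mask = labels == tissue
        if not mask.any():
            raise ValidationError(f"tissue {tissue} has zero samples")
        m[:, col] = expr.values[:, mask].mean(axis=1)
    return MeanExpressionTable(m, expr.transcript_ids, tissues)


def _fc_matrix(m: np.ndarray, pseudocount: float) -> np.ndarray:
    """FC-MAX for every (transcript, tissue) pair, vectorised via top-2 row values."""
    if m.shape[1] < 2:
        raise ValidationError("FC-MAX is undefined with a single tissue")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    order = np.sort(m, axis=1)
    top1 = order[:, -1][:, None]
    top2 = order[:, -2][:, None]
    # max over k != i: the row max, unless column i *is* the unique max holder
    other_max = np.where(m == top1, top2, top1)
    # ties at the max: every tied column still sees the max (ratio 1, FC 0)
    tie = (m == top1) & (top1 == top2)
    other_max = np.where(tie, top1, other_max)
    return np.log2((m + pseudocount) / (other_max + pseudocount))


def compute_fc_max(means: MeanExpressionTable, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """FC-MAX matrix (log2 units) for all transcript-tissue pairs."""
    return _fc_matrix(means.m, pseudocount)


def _set_stat(m: np.ndarray, in_set: np.ndarray, pseudocount: float) -> np.ndarray:
    """log2((min over the set + c) / (max outside the set + c)) per row.

    ``m`` is (n_rows, n_tissues); ``in_set`` a boolean matrix of the same
    shape marking each row's candidate tissue set.  For singleton sets this
    is exactly FC-MAX at the candidate tissue.
    """
    big = np.inf
    set_min = np.where(in_set, m, big).min(axis=1)
    out_max = np.where(in_set, -big, m).max(axis=1)
    if np.isinf(set_min).any() or np.isinf(out_max).any():
        raise ValidationError("candidate tissue sets must be non-empty proper subsets")
    return np.log2((set_min + pseudocount) / (out_max + pseudocount))


def fc_for_sets(
    means: MeanExpressionTable,
    candidates: Sequence[Candidate],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Observed set-versus-rest FC-MAX for each candidate."""
    m, in_set, _ = _candidate_arrays(means.m, means.transcript_ids, means.tissue_ids, candidates)
    return _set_stat(m, in_set, pseudocount)


def _normalize_set(tissues) -> tuple[str, ...]:
    if isinstance(tissues, str):
        return (tissues,)
    return tuple(tissues)


def _candidate_arrays(m, transcript_ids, tissue_ids, candidates):
    tx_pos = {t: i for i, t in enumerate(transcript_ids)}
    ti_pos = {t: i for i, t in enumerate(tissue_ids)}
    rows = []
    in_set = np.zeros((len(candidates), len(tissue_ids)), dtype=bool)
    for r, (tx, tissues) in enumerate(candidates):
        if tx not in tx_pos:
            raise ValidationError(f"candidate transcript {tx} not in expression matrix")
        rows.append(tx_pos[tx])
        tset = _normalize_set(tissues)
        if not tset or len(tset) >= len(tissue_ids):
            raise ValidationError(
                f"candidate tissue set for {tx} must be a non-empty proper subset"
            )
        for t in tset:
            if t not in ti_pos:
                raise ValidationError(f"candidate tissue {t} unknown")
            in_set[r, ti_pos[t]] = True
    return m[rows], in_set, np.asarray(rows)


def _group_mean_operator(labels: np.ndarray, tissue_ids: list[str]) -> np.ndarray:
    """(n_samples, n_tissues) matrix W with column i = 1/n_i on tissue i's samples,
    so that ``X @ W`` is the per-tissue mean matrix."""
    W = np.zeros((len(labels), len(tissue_ids)))
    for col, tissue in enumerate(tissue_ids):
        mask = labels == tissue
        n = int(mask.sum())
        if n == 0:
            raise ValidationError(f"tissue {tissue} has zero samples")
        W[mask, col] = 1.0 / n
    return W


def compute_emp_p(
    expr: ExpressionMatrix,
    samples: SampleTable,
    candidates: Sequence[Candidate],
    n_iterations: int = 999,
    seed: int = 0,
    mode: str = "permutation_null",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    subsample_fraction: float = 0.8,
    stability_fc_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Empirical p-values for the candidates' FC-MAX by stratified resampling.

    Returns a DataFrame with columns ``transcript_id``, ``tissues``, ``mtpm``,
    ``fc_max`` (observed) and ``emp_p``.  Identical seed and input give
    bitwise-identical output.  Needs ``n_iterations >= 99`` (add-one p-value
    resolution of 0.01 or better).
    """
    if mode not in RESAMPLING_MODES:
        raise ValidationError(f"unknown resampling mode {mode!r}; use one of {RESAMPLING_MODES}")
    if n_iterations < 99:
        raise ValidationError(
            f"n_iterations={n_iterations} gives p-value resolution worse than 0.01; use >= 99"
        )
    tissue_ids = samples.tissues
    expr = expr.subset_samples(list(samples.sample_ids))
    labels = samples.df["tissue"].to_numpy()

    X, in_set, _ = _candidate_arrays(expr.values, expr.transcript_ids, tissue_ids, candidates)
    if len(candidates) == 0:
        return pd.DataFrame(
            columns=["transcript_id", "tissues", "mtpm", "fc_max", "emp_p"]
        )
    W = _group_mean_operator(labels, tissue_ids)
    M_obs = X @ W
    stat_obs = _set_stat(M_obs, in_set, pseudocount)
    mtpm = np.where(in_set, M_obs, np.inf).min(axis=1)

    rng = np.random.default_rng(seed)
    n_samples = len(labels)
    counts = np.zeros(len(candidates), dtype=int)

    if mode == "permutation_null":
        for _ in range(n_iterations):
            perm = rng.permutation(n_samples)
            M_null = X[:, perm] @ W
            stat_null = _set_stat(M_null, in_set, pseudocount)
            counts += stat_null >= stat_obs
    else:  # subsample_stability
        tissue_masks = [np.flatnonzero(labels == t) for t in tissue_ids]
        for _ in range(n_iterations):
            Wb = np.zeros_like(W)
            for col, idx in enumerate(tissue_masks):
                k = max(1, int(np.floor(subsample_fraction * len(idx))))
                chosen = rng.choice(idx, size=k, replace=False)
                Wb[chosen, col] = 1.0 / k
            stat_b = _set_stat(X @ Wb, in_set, pseudocount)
            counts += stat_b < stability_fc_cutoff

    emp_p = (1.0 + counts) / (n_iterations + 1.0)
    return pd.DataFrame(
        {
            "transcript_id": [tx for tx, _ in candidates],
            "tissues": [";".join(_normalize_set(t)) for _, t in candidates],
            "mtpm": mtpm,
            "fc_max": stat_obs,
            "emp_p": emp_p,
        }
    )


def compute_tau(means: MeanExpressionTable, log_transform: bool = True) -> pd.DataFrame:
    """tau specificity index per transcript.

    Returns a DataFrame indexed by transcript ID with columns ``tau`` and
    ``all_zero``.  Scale-invariant on the raw scale; the default log2(x+1)
    transform matches common practice for expression data.
    """
    if means.m.shape[1] < 2:
        raise ValidationError("tau needs >= 2 tissues")
    x = np.log2(means.m + 1.0) if log_transform else means.m.copy()
    mx = x.max(axis=1)
    all_zero = mx == 0
    safe_mx = np.where(all_zero, 1.0, mx)
    xhat = x / safe_mx[:, None]
    tau = (1.0 - xhat).sum(axis=1) / (x.shape[1] - 1)
    tau = np.where(all_zero, 0.0, tau)
    return pd.DataFrame(
        {"tau": tau, "all_zero": all_zero},
        index=pd.Index(means.transcript_ids, name="transcript_id"),
    )
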