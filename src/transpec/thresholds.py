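"""Expression probabilities and density-inflection thresholds.

For transcript *j* and tissue *i*, the expression probability

    P_ij = #{samples of tissue i with TPM >= tpm_threshold} / n_i

summarises how consistently the transcript clears a baseline of 0.5 TPM
across the tissue's samples.  Pooled over a transcriptome, the per-tissue
P_ij values follow a U-shaped (beta-like) distribution: a left peak of
transcripts essentially never expressed and a right peak of transcripts
expressed in almost every sample.

The per-tissue cutoffs are read off a Gaussian kernel density estimate of
that distribution:

* **R-IP** (right inflection point) — the rightmost inflection point of the
  density inside a search window (default [0.75, 0.9]); transcripts with
  P_ij >= R-IP count as *expressed* in tissue i.  The R-IP density is
  estimated on the *right peak only* (values with P_ij > 0.5): on the full
  vector, the overwhelming unexpressed mass near zero inflates the Silverman
  bandwidth so much that the right peak's internal structure — where the
  cutoff lives — is smoothed away.
* **L-IP** (left inflection point) — the rightmost inflection point inside
  the left window (default [0.05, 0.25]), delimiting the unexpressed left
  peak; transcripts with P_ij < L-IP in every tissue are *null*.  The left
  peak dominates the full vector, so L-IP is read off the full-vector
  density.

The KDE is boundary-reflected at 0 and 1 so probability mass is conserved on
the unit interval; the bandwidth follows Silverman's normal-reference rule
``(3n/4)^(-1/5) * sd`` unless a fixed bandwidth is supplied (the IQR-robust
variant degenerates on zero-inflated probability vectors).
Inflection points are the sign changes of the discrete second derivative
(central differences on a uniform grid), located by linear interpolation.
If no inflection point falls inside a window, the window bound nearer the
centre of the distribution is used and flagged as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .exceptions import ValidationError
from .formats_io import ExpressionMatrix, SampleTable

__all__ = [
    "ProbabilityTable",
    "DensityCurve",
    "TissueThresholds",
    "compute_probabilities",
    "estimate_density",
    "find_inflection_points",
    "select_rip",
    "select_lip",
    "compute_tissue_thresholds",
]

DEFAULT_RIP_WINDOW = (0.75, 0.9)
DEFAULT_LIP_WINDOW = (0.05, 0.25)


class ProbabilityTable:
    """Per-tissue expression probabilities, rows = transcripts, columns = tissues."""

    def __init__(self, p, transcript_ids, tissue_ids, tpm_threshold: float = 0.5) -> None:
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape != (len(transcript_ids), len(tissue_ids)):
            raise ValidationError("probability matrix shape does not match identifier lists")
        if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
            raise ValidationError("probabilities must lie in [0, 1]")
        self.p = p
        self.transcript_ids = np.asarray(list(transcript_ids), dtype=object)
        self.tissue_ids = list(tissue_ids)
        self.tpm_threshold = float(tpm_threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.p,
            index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=self.tissue_ids,
        )

    def __repr__(self) -> str:
        return (
            f"ProbabilityTable({self.p.shape[0]} transcripts x {self.p.shape[1]} tissues, "
            f"TPM >= {self.tpm_threshold})"
        )


@dataclass(frozen=True)
class DensityCurve:
    """KDE of a P_ij vector on a uniform grid over [0, 1]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if len(self.grid) < 64:
            raise ValidationError("density grid needs >= 64 points")
        if (np.diff(self.grid) <= 0).any():
            raise ValidationError("density grid must be strictly increasing")
        if (self.density < 0).any():
            raise ValidationError("density must be non-negative")
        mass = float(np.trapezoid(self.density, self.grid))
        if not 0.98 <= mass <= 1.02:
            raise ValidationError(
                f"density integrates to {mass:.4f}, outside 1 +/- 0.02 "
                "(degenerate or unnormalised input)"
            )


@dataclass(frozen=True)
class TissueThresholds:
    """Per-tissue cutoffs with provenance flags."""

    tissue_id: str
    rip: float
    lip: float
    rip_fallback: bool
    lip_fallback: bool
    bandwidth: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lip < self.rip <= 1.0):
            raise ValidationError(
                f"thresholds for {self.tissue_id}: need 0 <= L-IP < R-IP <= 1, "
                f"got L-IP={self.lip}, R-IP={self.rip}"
            )


def compute_probabilities(
    expr: ExpressionMatrix, samples: SampleTable, tpm_threshold: float = 0.5
) -> ProbabilityTable:
    """P_ij = fraction of tissue i's samples with TPM >= tpm_threshold (>=, not >)."""
    tissues = samples.tissues
    if len(tissues) < 2:
        raise ValidationError("need >= 2 tissues to compute specificity probabilities")
    expr = expr.subset_samples(list(samples.sample_ids))
    above = expr.values >= tpm_threshold
    labels = samples.df["tissue"].to_numpy()
    p = np.empty((expr.shape[0], len(tissues)))
    for col, tissue in enumerate(tissues):
        mask = labels == tissue
        n = int(mask.sum())
        if n == 0:
            raise ValidationError(f"tissue {tissue} has zero samples")
        p[:, col] = above[:, mask].sum(axis=1) / n
    return ProbabilityTable(p, expr.transcript_ids, tissues, tpm_threshold)


def _silverman_bandwidth(values: np.ndarray) -> float:
    # Silverman's normal-reference rule, (3n/4)^(-1/5) * sd.  The IQR-robust
    # variant is deliberately NOT used: P_ij vectors are zero-inflated (most
    # transcripts are unexpressed in a tissue), so their IQR can be ~0 and
    # would collapse the bandwidth to a comb of spikes.
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValidationError(
            "degenerate input: all values identical; no density can be estimated"
        )
    return (0.75 * len(values)) ** (-0.2) * sd


def estimate_density(
    values: Sequence[float],
    bandwidth_rule: str = "silverman",
    grid_size: int = 512,
    bandwidth: float | None = None,
) -> DensityCurve:
    """Boundary-reflected Gaussian KDE of values in [0, 1].

    Mass falling outside the unit interval is folded back (reflection at 0
    and 1), so the estimate integrates to 1 on [0, 1].  With the default
    Silverman rule at least 100 values are required; a fixed bandwidth lifts
    that requirement (but still needs >= 2 distinct values).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValidationError("density input must be a 1-D vector")
    if not np.isfinite(v).all() or ((v < 0) | (v > 1)).any():
        raise ValidationError("density input values must be finite and inside [0, 1]")
    if bandwidth_rule not in ("silverman", "fixed"):
        raise ValidationError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValidationError("fixed bandwidth rule requires a positive bandwidth")
        h = float(bandwidth)
        if len(v) < 2:
            raise ValidationError("need >= 2 values for a density estimate")
    else:
        if len(v) < 100:
            raise ValidationError(
                f"only {len(v)} values: Silverman's rule needs >= 100; supply more "
                "transcripts or use a fixed bandwidth"
            )
        h = _silverman_bandwidth(v)
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValidationError(
            "degenerate input: all values identical; no density can be estimated"
        )
    kde = gaussian_kde(v, bw_method=h / sd)
    grid = np.linspace(0.0, 1.0, int(grid_size))
    # reflect at both boundaries: f(x) + f(-x) + f(2 - x)
    evals = kde(np.concatenate([grid, -grid, 2.0 - grid]))
    n = len(grid)
    density = evals[:n] + evals[n : 2 * n] + evals[2 * n :]
    return DensityCurve(grid=grid, density=density, bandwidth=h)


def find_inflection_points(curve: DensityCurve) -> list[float]:
    """Abscissae where the discrete second derivative changes sign, ascending.

    The second derivative is taken by central differences on the uniform
    grid; each sign change is located by linear interpolation between the
    bracketing grid points.  Runs of exact zeros between opposite signs
    contribute their midpoint.  May return an empty list.
    """
    f = curve.density
    x = curve.grid
    dx = x[1] - x[0]
    d2 = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / dx**2
    # curvature below floating-point resolution of the differencing is zero
    # (an exactly linear segment must report no inflection)
    tol = 64.0 * np.finfo(float).eps * float(np.abs(f).max()) / dx**2
    d2 = np.where(np.abs(d2) <= tol, 0.0, d2)
    xs = x[1:-1]
    roots: list[float] = []
    i = 0
    m = len(d2)
    while i < m - 1:
        a = d2[i]
        if a == 0.0:
            i += 1
            continue
        j = i + 1
        while j < m and d2[j] == 0.0:
            j += 1
        if j >= m:
            break
        b = d2[j]
        if a * b < 0:
            if j == i + 1:
                roots.append(float(xs[i] + (xs[j] - xs[i]) * a / (a - b)))
            else:  # zero plateau between opposite signs
                roots.append(float(0.5 * (xs[i + 1] + xs[j - 1])))
        i = j
    return sorted(roots)


def _select_in_window(
    ips: Sequence[float], window: tuple[float, float], fallback: float
) -> tuple[float, bool]:
    lo, hi = window
    inside = [p for p in ips if lo <= p <= hi]
    if inside:
        return max(inside), False
    return fallback, True


def select_rip(
    ips: Sequence[float], window: tuple[float, float] = DEFAULT_RIP_WINDOW
) -> tuple[float, bool]:
    """Rightmost inflection point inside the window (closed on both ends).

    Falls back to the lower window bound — the bound nearer the centre of the
    distribution — when no inflection point qualifies, and flags it.
    """
    lo, hi = window
    if not (0.5 <= lo < hi <= 1.0):
        raise ValidationError("R-IP window must lie within [0.5, 1]")
    return _select_in_window(ips, window, fallback=lo)


def select_lip(
    ips: Sequence[float], window: tuple[float, float] = DEFAULT_LIP_WINDOW
) -> tuple[float, bool]:
    """Rightmost inflection point inside the left window (the left-peak cutoff).

    Falls back to the upper window bound when no inflection point qualifies.
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= 0.5):
        raise ValidationError("L-IP window must lie within [0, 0.5]")
    return _select_in_window(ips, window, fallback=hi)


def compute_tissue_thresholds(
    probs: ProbabilityTable,
    rip_window: tuple[float, float] = DEFAULT_RIP_WINDOW,
    lip_window: tuple[float, float] = DEFAULT_LIP_WINDOW,
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
    grid_size: int = 512,
    rip_subset_min: float | None = 0.5,
    return_curves: bool = False,
):
    """Estimate each tissue's P_ij density and derive (R-IP, L-IP).

    L-IP comes from the density of the full P_ij vector; R-IP from the
    density of the right peak alone (values with ``P_ij > rip_subset_min``,
    default 0.5), falling back to the full-vector density when fewer than
    100 values lie in the right peak.  Set ``rip_subset_min=None`` to derive
    both cutoffs from the full-vector density.

    Returns a DataFrame indexed by tissue with columns ``rip``, ``lip``,
    ``rip_fallback``, ``lip_fallback``, ``bandwidth`` (the R-IP curve's
    bandwidth; and, with ``return_curves``, also a dict of per-tissue
    :class:`DensityCurve` pairs ``{"full": ..., "right": ...}``).
    """
    rows = []
    curves: dict[str, dict[str, DensityCurve]] = {}
    for col, tissue in enumerate(probs.tissue_ids):
        p = probs.p[:, col]
        curve = estimate_density(
            p, bandwidth_rule=bandwidth_rule, grid_size=grid_size, bandwidth=bandwidth,
        )
        ips_full = find_inflection_points(curve)
        right_curve = curve
        if rip_subset_min is not None:
            right = p[p > rip_subset_min]
            if len(right) >= 100 or bandwidth_rule == "fixed":
                right_curve = estimate_density(
                    right, bandwidth_rule=bandwidth_rule,
                    grid_size=grid_size, bandwidth=bandwidth,
                )
        ips_right = (
            ips_full if right_curve is curve else find_inflection_points(right_curve)
        )
        rip, rip_fb = select_rip(ips_right, rip_window)
        lip, lip_fb = select_lip(ips_full, lip_window)
        thr = TissueThresholds(
            tissue_id=tissue, rip=rip, lip=lip,
            rip_fallback=rip_fb, lip_fallback=lip_fb,
            bandwidth=right_curve.bandwidth,
        )
        rows.append(
            {
                "tissue": thr.tissue_id,
                "rip": thr.rip,
                "lip": thr.lip,
                "rip_fallback": thr.rip_fallback,
                "lip_fallback": thr.lip_fallback,
                "bandwidth": thr.bandwidth,
            }
        )
        if return_curves:
            curves[tissue] = {"full": curve, "right": right_curve}
    frame = pd.DataFrame(rows).set_index("tissue")
    if return_curves:
        return frame, curves
    return frame
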