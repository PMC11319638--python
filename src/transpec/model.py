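"""Model / results objects orchestrating the full scoring pipeline.

:class:`TissueSpecificityModel` is constructed from an expression matrix and
sample metadata (plus configuration); :meth:`~TissueSpecificityModel.fit`
runs QC -> expression probabilities -> per-tissue density thresholds ->
fold-change and permutation p-values -> five-way classification -> tau, and
returns a :class:`TissueSpecificityResults` carrying every intermediate
table, a text ``summary()`` and writers for the standard output files.

    >>> model = TissueSpecificityModel(expr, samples)
    >>> res = model.fit(n_iterations=999, seed=1)
    >>> print(res.summary())
    >>> res.write("out/")
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Sequence

import pandas as pd

from . import __version__
from .classifier import (
    ClassificationConfig,
    ClassificationResult,
    candidate_pairs,
    classify,
    summarize,
)
from .exceptions import ValidationError
from .formats_io import (
    AnnotationTable,
    ExpressionMatrix,
    SampleTable,
    read_expression,
    read_sample_table,
    write_results,
)
from .promoters import DEFAULT_TSS_THRESHOLDS, analyze_promoters
from .qc import QCConfig, filter_samples
from .specificity import (
    DEFAULT_PSEUDOCOUNT,
    SpecificityStats,
    compute_emp_p,
    compute_means,
    compute_tau,
)
from .thresholds import (
    DEFAULT_LIP_WINDOW,
    DEFAULT_RIP_WINDOW,
    compute_probabilities,
    compute_tissue_thresholds,
)

__all__ = ["TissueSpecificityModel", "TissueSpecificityResults"]


class TissueSpecificityModel:
    """Transcript-level tissue-specificity scoring model.

    Parameters mirror the method's published defaults: baseline 0.5 TPM,
    RIN >= 7 and >= 50 samples per tissue, R-IP search window [0.75, 0.9],
    FC-MAX >= 1 and EMP-p <= 0.05.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        samples: SampleTable,
        qc_config: QCConfig | None = None,
        tpm_threshold: float = 0.5,
        rip_window: tuple[float, float] = DEFAULT_RIP_WINDOW,
        lip_window: tuple[float, float] = DEFAULT_LIP_WINDOW,
        bandwidth_rule: str = "silverman",
        bandwidth: float | None = None,
        grid_size: int = 512,
        classification: ClassificationConfig | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        tau_log_transform: bool = True,
    ) -> None:
        self.expression = expression
        self.samples = samples
        self.qc_config = qc_config or QCConfig()
        self.tpm_threshold = float(tpm_threshold)
        self.rip_window = tuple(rip_window)
        self.lip_window = tuple(lip_window)
        self.bandwidth_rule = bandwidth_rule
        self.bandwidth = bandwidth
        self.grid_size = int(grid_size)
        self.classification = classification or ClassificationConfig()
        self.pseudocount = float(pseudocount)
        self.tau_log_transform = bool(tau_log_transform)

    @classmethod
    def from_files(
        cls,
        expression_path: str,
        samples_path: str,
        expression_format: str | None = None,
        **kwargs,
    ) -> "TissueSpecificityModel":
        expr = read_expression(expression_path, format=expression_format)
        samples = read_sample_table(samples_path)
        return cls(expr, samples, **kwargs)

    def params(self) -> dict:
        """All model parameters (goes into the run manifest)."""
        qc = self.qc_config
        cl = self.classification
        return {
            "version": __version__,
            "tpm_threshold": self.tpm_threshold,
            "min_rin": qc.min_rin,
            "min_samples_per_tissue": qc.min_samples_per_tissue,
            "tissue_grouping": dict(qc.tissue_grouping) if qc.tissue_grouping else None,
            "rip_window": list(self.rip_window),
            "lip_window": list(self.lip_window),
            "bandwidth_rule": self.bandwidth_rule,
            "bandwidth": self.bandwidth,
            "grid_size": self.grid_size,
            "fc_cutoff": cl.fc_cutoff,
            "emp_p_cutoff": cl.emp_p_cutoff,
            "ten_max_fraction": cl.ten_max_fraction,
            "demotion_class": cl.demotion_class,
            "ten_mode": cl.ten_mode,
            "pseudocount": self.pseudocount,
            "tau_log_transform": self.tau_log_transform,
        }

    def fit(
        self,
        n_iterations: int = 999,
        seed: int = 0,
        mode: str = "permutation_null",
    ) -> "TissueSpecificityResults":
        """Run the full pipeline; deterministic given (inputs, params, seed)."""
        samples, expr, qc_report = filter_samples(
            self.samples, self.expression, self.qc_config
        )
        probs = compute_probabilities(expr, samples, self.tpm_threshold)
        thresholds = compute_tissue_thresholds(
            probs,
            rip_window=self.rip_window,
            lip_window=self.lip_window,
            bandwidth_rule=self.bandwidth_rule,
            bandwidth=self.bandwidth,
            grid_size=self.grid_size,
        )
        means = compute_means(expr, samples)
        pairs = candidate_pairs(probs, thresholds, self.classification, means.m)
        emp = compute_emp_p(
            expr,
            samples,
            pairs,
            n_iterations=n_iterations,
            seed=seed,
            mode=mode,
            pseudocount=self.pseudocount,
        )
        tau = compute_tau(means, log_transform=self.tau_log_transform)
        stats = SpecificityStats(
            frame=emp,
            tau=tau["tau"],
            mode=mode,
            n_iterations=n_iterations,
            seed=seed,
            pseudocount=self.pseudocount,
        )
        result = classify(probs, thresholds, stats, self.classification)
        return TissueSpecificityResults(
            model=self,
            qc_report=qc_report,
            samples=samples,
            probabilities=probs,
            thresholds=thresholds,
            means=means,
            stats=stats,
            tau=tau,
            classification=result,
            n_iterations=n_iterations,
            seed=seed,
            mode=mode,
        )


class TissueSpecificityResults:
    """Fitted pipeline output.

    Attributes
    ----------
    qc_report : QCReport
    probabilities : ProbabilityTable
    thresholds : DataFrame (per tissue: rip, lip, fallback flags, bandwidth)
    means : MeanExpressionTable
    stats : SpecificityStats (per-candidate FC-MAX / EMP-p, tau)
    tau : DataFrame (tau, all_zero) per transcript
    classification : ClassificationResult
    """

    def __init__(
        self, model, qc_report, samples, probabilities, thresholds, means,
        stats, tau, classification, n_iterations, seed, mode,
    ) -> None:
        self.model = model
        self.qc_report = qc_report
        self.samples = samples
        self.probabilities = probabilities
        self.thresholds = thresholds
        self.means = means
        self.stats = stats
        self.tau = tau
        self.classification = classification
        self.n_iterations = int(n_iterations)
        self.seed = int(seed)
        self.mode = mode

    # -- reporting ---------------------------------------------------------

    def class_counts(self) -> pd.Series:
        return self.classification.class_counts()

    def manifest(self) -> dict:
        params = self.model.params()
        params.update(
            {"n_iterations": self.n_iterations, "seed": self.seed, "mode": self.mode}
        )
        digest = hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:12]
        return {"run_id": digest, "parameters": params}

    def summary(self) -> str:
        """Human-readable run summary (class counts, thresholds, top tissues)."""
        man = self.manifest()
        lines = [
            "Tissue-specificity classification results",
            "=" * 41,
            f"run {man['run_id']}  (seed={self.seed}, {self.mode}, "
            f"B={self.n_iterations})",
            f"samples: {self.qc_report.n_samples_in} in, "
            f"{self.qc_report.n_samples_out} after QC; "
            f"tissues: {len(self.probabilities.tissue_ids)}",
            "",
            "Class counts",
            "------------",
            self.class_counts().to_string(),
            "",
            "Per-tissue thresholds",
            "---------------------",
            self.thresholds[["rip", "lip", "rip_fallback", "lip_fallback"]].to_string(),
        ]
        tsp = summarize(self.classification)["tsp_per_tissue"]
        if len(tsp):
            lines += ["", "TSp transcripts per tissue", "--------------------------",
                      tsp.sort_values("n_tsp", ascending=False).to_string(index=False)]
        return "\n".join(lines)

    def promoter_analysis(
        self,
        annotation: AnnotationTable,
        tss_thresholds: Sequence[int] = DEFAULT_TSS_THRESHOLDS,
    ) -> pd.DataFrame:
        return analyze_promoters(self.classification, annotation, tss_thresholds)

    def plot_density(self, tissue: str, ax=None):
        """Diagnostic plot of a tissue's P_ij density and its cutoffs."""
        import matplotlib.pyplot as plt  # optional dependency

        from .thresholds import estimate_density

        col = self.probabilities.tissue_ids.index(tissue)
        curve = estimate_density(
            self.probabilities.p[:, col],
            bandwidth_rule=self.model.bandwidth_rule,
            grid_size=self.model.grid_size,
            bandwidth=self.model.bandwidth,
        )
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.grid, curve.density)
        thr = self.thresholds.loc[tissue]
        ax.axvline(thr["rip"], color="C1", ls="--", label=f"R-IP {thr['rip']:.3f}")
        ax.axvline(thr["lip"], color="C2", ls="--", label=f"L-IP {thr['lip']:.3f}")
        ax.set(xlabel="expression probability", ylabel="density", title=tissue)
        ax.legend()
        return ax

    # -- persistence ---------------------------------------------------------

    def write(self, out_dir: str) -> dict[str, str]:
        """Write the standard output files; byte-identical across reruns.

        qc_report.tsv, thresholds.tsv, stats.tsv, classification.tsv,
        summary.tsv and manifest.json.  Every TSV carries the manifest run id
        as a leading comment line.
        """
        os.makedirs(out_dir, exist_ok=True)
        man = self.manifest()
        run_id = man["run_id"]
        paths: dict[str, str] = {}

        def _path(name: str) -> str:
            p = os.path.join(out_dir, name)
            paths[name] = p
            return p

        def _tsv(name: str, frame: pd.DataFrame, index: bool) -> None:
            with open(_path(name), "wt", encoding="utf-8", newline="\n") as fh:
                fh.write(f"# run {run_id}\n")
                frame.to_csv(fh, sep="\t", index=index, na_rep="NA",
                             lineterminator="\n")

        _tsv("qc_report.tsv", self.qc_report.to_frame(), index=False)
        _tsv("thresholds.tsv", self.thresholds, index=True)
        self.stats.write(_path("stats.tsv"), run_id=run_id)
        write_results(_path("classification.tsv"), self.classification, self.stats,
                      run_id=run_id)
        summary = summarize(self.classification)
        _tsv("summary.tsv", summary["class_counts"], index=False)
        with open(_path("manifest.json"), "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(man, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths

    def recovery_report(self, truth) -> pd.DataFrame:
        """Confusion summary against a planted :class:`~transpec.synthetic.GroundTruth`."""
        truth_map = truth.frame.set_index("transcript_id")["planted_class"]
        frame = self.classification.frame
        planted = frame["transcript_id"].map(truth_map)
        if planted.isna().any():
            raise ValidationError("ground truth does not cover all classified transcripts")
        tab = (
            pd.crosstab(planted.rename("planted"), frame["class"].rename("recovered"))
            .reindex(index=list(truth_map.unique()))
        )
        tab["recovery"] = [
            (tab.loc[c, c] / tab.loc[c].drop("recovery", errors="ignore").sum())
            if c in tab.columns else 0.0
            for c in tab.index
        ]
        return tab
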