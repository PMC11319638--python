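import numpy as np
import pandas as pd
import pytest

import transpec as tp


@pytest.fixture(scope="session")
def small_corpus():
    """6 tissues x 60 samples, 300 transcripts, strong effects."""
    spec = tp.CorpusSpec(
        n_tissues=6,
        samples_per_tissue=60,
        class_counts={"TSp": 30, "TEn": 30, "Wide": 120, "Low": 60, "Null": 60},
        seed=11,
    )
    return tp.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_fit(small_corpus):
    expr, samples, truth = small_corpus
    model = tp.TissueSpecificityModel(expr, samples)
    return model.fit(n_iterations=99, seed=7), truth


@pytest.fixture()
def tiny_expr():
    values = np.array([[1.0, 0.0, 2.0, 0.5], [0.5, 2.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
    return tp.ExpressionMatrix(values, ["t1", "t2", "t3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture()
def tiny_samples():
    return tp.SampleTable.from_records(
        ["s1", "s2", "s3", "s4"], ["liver", "liver", "brain", "brain"], [8.0, 9.0, 7.5, 10.0]
    )


def make_probs(p, tissues=None, transcripts=None):
    p = np.asarray(p, dtype=float)
    tissues = tissues or [f"T{i}" for i in range(p.shape[1])]
    transcripts = transcripts or [f"tx{j}" for j in range(p.shape[0])]
    return tp.ProbabilityTable(p, transcripts, tissues)


def make_thresholds(tissues, rip=0.8, lip=0.1):
    rips = np.full(len(tissues), rip, dtype=float) if np.isscalar(rip) else np.asarray(rip)
    lips = np.full(len(tissues), lip, dtype=float) if np.isscalar(lip) else np.asarray(lip)
    return pd.DataFrame(
        {
            "rip": rips,
            "lip": lips,
            "rip_fallback": False,
            "lip_fallback": False,
            "bandwidth": 0.05,
        },
        index=pd.Index(tissues, name="tissue"),
    )


def make_stats(records, tau=None):
    """records: list of (transcript_id, tissues_str, fc, p)."""
    frame = pd.DataFrame(
        records, columns=["transcript_id", "tissues", "fc_max", "emp_p"]
    )
    if tau is None:
        tau = pd.Series(0.5, index=frame["transcript_id"])
    return tp.SpecificityStats(frame=frame, tau=tau, n_iterations=99, seed=0)
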