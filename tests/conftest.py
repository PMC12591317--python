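import numpy as np
import pandas as pd
import pytest

from phosdiff.model import (
    COMPARISONS,
    GROUPS,
    AnalysisParams,
    IntensityMatrix,
    SampleMetadata,
    comparison_name,
)

COMPARISON_NAMES = [comparison_name(p) for p in COMPARISONS]


@pytest.fixture
def params():
    return AnalysisParams()


@pytest.fixture
def small_meta():
    """Four groups of 3/4/4/3 samples — small but valid."""
    rows = []
    for g, n in zip(GROUPS, (3, 4, 4, 3)):
        rows += [{"sample_id": f"{g}_{i}", "group": g} for i in range(n)]
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture
def cohort_meta():
    """The modelled cohort's group sizes: 6/23/31/22."""
    rows = []
    for g, n in zip(GROUPS, (6, 23, 31, 22)):
        rows += [{"sample_id": f"{g}_{i:02d}", "group": g} for i in range(n)]
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def make_matrix(values, feature_ids=None, sample_ids=None, scale="log2"):
    values = np.asarray(values, float)
    feature_ids = feature_ids or [f"F{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids),
        scale=scale,
    )


def stats_row(feature, comparison, fdr, log2fc, raw_p=None, significant=None):
    sig = (fdr < 0.05 and abs(log2fc) > 1.0) if significant is None else significant
    return {
        "feature_id": feature,
        "omnibus_test": "ANOVA",
        "omnibus_p": 0.001,
        "comparison": comparison,
        "pairwise_test": "Student_t",
        "raw_p": fdr if raw_p is None else raw_p,
        "fdr": fdr,
        "log2fc": log2fc,
        "significant": sig,
    }
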