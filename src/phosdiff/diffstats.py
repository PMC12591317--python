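"""Adaptive omnibus / pairwise test cascade with per-feature BH FDR.

For every feature, normality is assessed per group (Shapiro-Wilk) and
variance homogeneity across the compared groups (Levene, median-centred).
The omnibus test across all four groups is then ANOVA (normal, equal
variances), Welch-ANOVA (normal, unequal variances) or Kruskal-Wallis
(any non-normal group).  Pairwise tests are run only for features whose raw
omnibus p falls below ``omnibus_alpha``, with the analogous cascade:
Student's t / Welch's t / Wilcoxon rank-sum.  The six pairwise p-values of
each feature are then Benjamini-Hochberg adjusted *within that feature*,
and a comparison is called significant when the adjusted p is below
``fdr_q`` and the absolute log2 fold-change exceeds ``log2(fc_threshold)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    COMPARISONS,
    GROUPS,
    AnalysisParams,
    IntensityMatrix,
    SampleMetadata,
    comparison_name,
)

log = logging.getLogger(__name__)

STAT_COLUMNS = [
    "feature_id",
    "omnibus_test",
    "omnibus_p",
    "comparison",
    "pairwise_test",
    "raw_p",
    "fdr",
    "log2fc",
    "significant",
]


@dataclass(frozen=True)
class GateResult:
    normal_all: bool
    equal_var: bool


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk normality verdict; tiny or constant groups are treated
    as non-normal (the test is undefined there)."""
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.shapiro(x).pvalue
    return bool(p >= alpha)


def gate_tests(groups: list[np.ndarray], params: AnalysisParams) -> GateResult:
    """Normality (per group) and equal-variance gates for a set of groups."""
    normal_all = all(_shapiro_normal(np.asarray(g, float), params.gate_alpha) for g in groups)
    if all(np.ptp(g) == 0 for g in groups):
        equal_var = True  # Levene undefined on all-constant input
    else:
        p = stats.levene(*groups, center="median").pvalue
        equal_var = bool(p >= params.gate_alpha)
    return GateResult(normal_all=normal_all, equal_var=equal_var)


def _welch_anova_p(groups: list[np.ndarray]) -> float:
    data = pd.DataFrame(
        {
            "y": np.concatenate(groups),
            "g": np.repeat(np.arange(len(groups)), [len(g) for g in groups]),
        }
    )
    res = pingouin.welch_anova(data=data, dv="y", between="g")
    return float(res["p_unc"].iloc[0])


def omnibus_test(groups: list[np.ndarray], gates: GateResult) -> tuple[str, float]:
    """Four-group omnibus test selected by the gate outcome."""
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if not gates.normal_all:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = stats.kruskal(*groups).pvalue
        except ValueError:  # all values identical
            p = 1.0
        return "Kruskal_Wallis", 1.0 if np.isnan(p) else float(p)
    if gates.equal_var:
        res = stats.f_oneway(*groups)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        return "ANOVA", p
    return "Welch_ANOVA", _welch_anova_p(groups)


def _wilcoxon_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    otherwise normal approximation with continuity correction."""
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def pairwise_test(
    a: np.ndarray, b: np.ndarray, params: AnalysisParams
) -> tuple[str, float, float]:
    """One two-group comparison: (test_name, raw_p, log2fc).

    ``log2fc = mean(a) - mean(b)``; on log2 intensities this is the signed
    log2 fold-change.  Gates are evaluated on the two groups alone.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    log2fc = float(np.mean(a) - np.mean(b))
    gates = gate_tests([a, b], params)
    if not gates.normal_all:
        if np.ptp(np.concatenate([a, b])) == 0:
            return "Wilcoxon", 1.0, log2fc
        return "Wilcoxon", _wilcoxon_ranksum_p(a, b), log2fc
    if gates.equal_var:
        res = stats.ttest_ind(a, b, equal_var=True)
        name = "Student_t"
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "Welch_t"
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return name, p, log2fc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_features(
    matrix: IntensityMatrix,
    meta: SampleMetadata,
    params: AnalysisParams,
) -> pd.DataFrame:
    """Full per-feature cascade over all six pairwise comparisons.

    Returns a long-format DataFrame (one row per feature per comparison)
    with the omnibus verdict, the pairwise test used, raw and BH-adjusted
    p-values, the signed log2 fold-change, and the significance call.
    Features whose omnibus p is not below ``omnibus_alpha`` carry no
    pairwise results and are non-significant everywhere.
    """
    if matrix.scale != "log2":
        raise ValueError("analyze_features expects a log2-scaled matrix")
    if matrix.values.isna().any().any():
        raise ValueError("analyze_features expects a fully imputed matrix")
    meta.check_against(matrix)
    group_samples = {g: meta.samples_in(g) for g in GROUPS}
    for g, s in group_samples.items():
        if len(s) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")

    values = matrix.values
    records: list[dict] = []
    n_sig_features = 0
    for feature in values.index:
        row = values.loc[feature]
        groups = [row[group_samples[g]].to_numpy() for g in GROUPS]
        gates = gate_tests(groups, params)
        omnibus_name, omnibus_p = omnibus_test(groups, gates)

        if omnibus_p < params.omnibus_alpha:
            names, raws, fcs = [], [], []
            for g1, g2 in COMPARISONS:
                i, j = GROUPS.index(g1), GROUPS.index(g2)
                name, p, fc = pairwise_test(groups[i], groups[j], params)
                names.append(name)
                raws.append(p)
                fcs.append(fc)
            fdrs = bh_adjust(raws)
            sigs = (fdrs < params.fdr_q) & (np.abs(fcs) > params.log2_fc_threshold)
            if sigs.any():
                n_sig_features += 1
            for k, pair in enumerate(COMPARISONS):
                records.append(
                    {
                        "feature_id": feature,
                        "omnibus_test": omnibus_name,
                        "omnibus_p": omnibus_p,
                        "comparison": comparison_name(pair),
                        "pairwise_test": names[k],
                        "raw_p": raws[k],
                        "fdr": float(fdrs[k]),
                        "log2fc": fcs[k],
                        "significant": bool(sigs[k]),
                    }
                )
        else:
            for pair in COMPARISONS:
                records.append(
                    {
                        "feature_id": feature,
                        "omnibus_test": omnibus_name,
                        "omnibus_p": omnibus_p,
                        "comparison": comparison_name(pair),
                        "pairwise_test": "none",
                        "raw_p": np.nan,
                        "fdr": np.nan,
                        "log2fc": np.nan,
                        "significant": False,
                    }
                )
    log.info(
        "analyze_features: %d/%d features significant in >= 1 comparison",
        n_sig_features,
        matrix.n_features,
    )
    return pd.DataFrame.from_records(records, columns=STAT_COLUMNS)
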