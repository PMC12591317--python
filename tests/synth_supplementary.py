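"""SYNTHETIC stand-in result tables at published-cohort scale.

The original per-feature statistics tables (per-comparison p-values and
fold-changes for 504 proteins / 211 phosphosites) are distributed as
journal supplementary spreadsheets and are not bundled here.  This module
builds *synthetic* long-format stats tables with the same marginal
composition: the generator assigns each feature a pattern category
(single-group specific, 2-vs-2 partition, partial/mixed, or sub-fold-change)
and emits concrete fdr/log2fc numbers realizing it.  The significance and
specificity rules must then recover the designed counts from the numbers
alone — the generator and the classifier share no code path.
"""

import numpy as np
import pandas as pd

from phosdiff.model import COMPARISONS, GROUPS, PARTITIONS, comparison_name

SIG_FDR = 0.01
NULL_FDR = 0.5
BIG_FC = 1.5  # |log2fc| above the FC>2 threshold
SMALL_FC = 0.5  # below it
NULL_FC = 0.1

COMPARISON_NAMES = [comparison_name(p) for p in COMPARISONS]


def _rows(feature, fdrs, fcs):
    return [
        {
            "feature_id": feature,
            "omnibus_test": "ANOVA",
            "omnibus_p": 0.001,
            "comparison": comp,
            "pairwise_test": "Student_t",
            "raw_p": fdr,
            "fdr": fdr,
            "log2fc": fc,
            "significant": bool(fdr < 0.05 and abs(fc) > 1.0),
        }
        for comp, fdr, fc in zip(COMPARISON_NAMES, fdrs, fcs)
    ]


def _group_specific_rows(feature, group, direction):
    fdrs, fcs = [], []
    for g1, g2 in COMPARISONS:
        if group in (g1, g2):
            oriented = BIG_FC if direction == "UP" else -BIG_FC
            fc = oriented if g1 == group else -oriented
            fdrs.append(SIG_FDR)
            fcs.append(fc)
        else:
            fdrs.append(NULL_FDR)
            fcs.append(NULL_FC)
    return _rows(feature, fdrs, fcs)


def _partition_rows(feature, partition_index, direction):
    side_a, side_b = PARTITIONS[partition_index]
    fdrs, fcs = [], []
    for g1, g2 in COMPARISONS:
        cross = (g1 in side_a) != (g2 in side_a)
        if cross:
            oriented = BIG_FC if direction == "UP" else -BIG_FC
            fc = oriented if g1 in side_a else -oriented
            fdrs.append(SIG_FDR)
            fcs.append(fc)
        else:
            fdrs.append(NULL_FDR)
            fcs.append(NULL_FC)
    return _rows(feature, fdrs, fcs)


def _double_group_rows(feature, g_up, g_down):
    """g_up sits above every group and g_down below every group (the two
    middle groups are tied): the feature carries two group labels."""
    fdrs, fcs = [], []
    for g1, g2 in COMPARISONS:
        if g_up in (g1, g2):
            fc = BIG_FC if g1 == g_up else -BIG_FC
        elif g_down in (g1, g2):
            fc = -BIG_FC if g1 == g_down else BIG_FC
        else:
            fdrs.append(NULL_FDR)
            fcs.append(NULL_FC)
            continue
        fdrs.append(SIG_FDR)
        fcs.append(fc)
    return _rows(feature, fdrs, fcs)


def _partial_rows(feature, k):
    """Significant with FC>2 in exactly one comparison -> a mixed pattern."""
    fdrs = [NULL_FDR] * 6
    fcs = [NULL_FC] * 6
    fdrs[k % 6] = SIG_FDR
    fcs[k % 6] = BIG_FC if k % 2 == 0 else -BIG_FC
    return _rows(feature, fdrs, fcs)


def _subfold_rows(feature, k):
    """Significant by FDR somewhere but fold-change below 2 everywhere."""
    fdrs = [NULL_FDR] * 6
    fcs = [NULL_FC] * 6
    fdrs[k % 6] = SIG_FDR
    fcs[k % 6] = SMALL_FC if k % 2 == 0 else -SMALL_FC
    return _rows(feature, fdrs, fcs)


def build_stats_table(
    per_group: dict[str, int],
    n_partition: int,
    n_total_fdr: int,
    n_fc_over_2: int,
    prefix: str,
    double_labels: tuple[tuple[str, str], ...] = (),
) -> pd.DataFrame:
    """Synthetic stats table with a designed pattern composition.

    ``per_group`` gives the per-group specific counts (a feature named in
    ``double_labels`` as ``(g_up, g_down)`` counts in both groups),
    ``n_partition`` the 2-vs-2 multi-group features, ``n_fc_over_2`` the
    features passing both rules in >= 1 comparison, and ``n_total_fdr`` the
    features passing the FDR rule alone in >= 1 comparison.
    """
    singles = dict(per_group)
    for g_up, g_down in double_labels:
        singles[g_up] -= 1
        singles[g_down] -= 1
    n_unique_specific = sum(singles.values()) + len(double_labels)
    n_partial = n_fc_over_2 - n_unique_specific - n_partition
    n_subfold = n_total_fdr - n_fc_over_2
    assert n_partial >= 0 and n_subfold >= 0 and all(v >= 0 for v in singles.values())

    rows = []
    i = 0
    for g in GROUPS:
        for j in range(singles.get(g, 0)):
            rows += _group_specific_rows(f"{prefix}{i:04d}", g, "UP" if j % 2 == 0 else "DOWN")
            i += 1
    for g_up, g_down in double_labels:
        rows += _double_group_rows(f"{prefix}{i:04d}", g_up, g_down)
        i += 1
    for j in range(n_partition):
        rows += _partition_rows(f"{prefix}{i:04d}", j % 3, "UP" if j % 2 == 0 else "DOWN")
        i += 1
    for j in range(n_partial):
        rows += _partial_rows(f"{prefix}{i:04d}", j)
        i += 1
    for j in range(n_subfold):
        rows += _subfold_rows(f"{prefix}{i:04d}", j)
        i += 1
    return pd.DataFrame(rows)


def protein_stand_in() -> pd.DataFrame:
    """504 proteins: 166 with FC>2, of which 36 single-group specific
    (16 EGFR / 13 EML4-ALK / 2 KRAS / 5 WT) plus 7 multi-group."""
    return build_stats_table(
        per_group={"EGFR": 16, "EML4_ALK": 13, "KRAS": 2, "WT": 5},
        n_partition=7,
        n_total_fdr=504,
        n_fc_over_2=166,
        prefix="SPROT",
    )


def phospho_stand_in() -> pd.DataFrame:
    """211 sites: 183 with FC>2, of which 52 unique group-specific sites;
    per-group counts 18 EML4-ALK / 12 EGFR / 10 KRAS / 14 WT sum to 54
    because two sites carry two labels (up in one group, down in another),
    plus 17 multi-group sites."""
    return build_stats_table(
        per_group={"EML4_ALK": 18, "EGFR": 12, "KRAS": 10, "WT": 14},
        n_partition=17,
        n_total_fdr=211,
        n_fc_over_2=183,
        prefix="SSITE",
        double_labels=(("EML4_ALK", "WT"), ("EGFR", "KRAS")),
    )
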