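"""Alteration-specificity classification of significant features.

A feature is *group-specific* for genotype g when all three pairwise
comparisons involving g are significant (FDR below threshold and absolute
fold-change above threshold) with a consistent direction once each
comparison is oriented as (g minus other).  A feature matching no single
group may instead show a *2-vs-2 partition* pattern: all four
cross-partition comparisons significant with consistent orientation and
both within-side comparisons null.  Features with significant comparisons
that fit neither pattern are labelled ``mixed``.  A feature can carry two
group labels on opposite sides (e.g. UP in one group and DOWN in another,
with the remaining two groups in between).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    COMPARISONS,
    GROUPS,
    PARTITIONS,
    AnalysisParams,
    comparison_name,
    partition_label,
)

_PAIR_INDEX = {pair: i for i, pair in enumerate(COMPARISONS)}
COMPARISON_NAMES = [comparison_name(p) for p in COMPARISONS]


@dataclass(frozen=True)
class SpecificityCall:
    """One specificity label for one feature.

    ``kind`` is ``group``, ``partition``, ``mixed`` or ``none``; ``label``
    holds the group name or canonical partition string (empty for mixed /
    none); ``direction`` is UP/DOWN relative to the labelled group or to
    the first-listed partition side.
    """

    feature_id: str
    kind: str
    label: str
    direction: str


def significance_matrix(stats: pd.DataFrame, params: AnalysisParams) -> pd.DataFrame:
    """Feature x comparison sign matrix from a long-format stats table.

    Entries are ``sign(log2fc)`` where ``fdr < fdr_q`` and
    ``|log2fc| > log2(fc_threshold)`` (both strict), else 0.
    """
    sig = stats.copy()
    passing = (sig["fdr"] < params.fdr_q) & (
        sig["log2fc"].abs() > params.log2_fc_threshold
    )
    sig["entry"] = np.where(passing.fillna(False), np.sign(sig["log2fc"]), 0.0)
    wide = sig.pivot(index="feature_id", columns="comparison", values="entry")
    wide = wide.reindex(columns=COMPARISON_NAMES).fillna(0.0).astype(int)
    # preserve input feature order
    order = stats["feature_id"].drop_duplicates()
    return wide.loc[order]


def _oriented_sign(signs: np.ndarray, group: str, pair: tuple[str, str]) -> int:
    """Sign of a comparison re-oriented as (group minus the other group)."""
    s = int(signs[_PAIR_INDEX[pair]])
    return s if pair[0] == group else -s


def classify_pattern(signs: np.ndarray) -> list[tuple[str, str, str]]:
    """Classify one 6-vector of comparison signs.

    Returns a list of ``(kind, label, direction)`` tuples: one or two group
    labels, or one partition label, or a single ``mixed`` / ``none`` entry.
    """
    signs = np.asarray(signs, int)
    calls: list[tuple[str, str, str]] = []
    for g in GROUPS:
        pairs = [p for p in COMPARISONS if g in p]
        oriented = [_oriented_sign(signs, g, p) for p in pairs]
        if all(o != 0 for o in oriented) and len(set(oriented)) == 1:
            calls.append(("group", g, "UP" if oriented[0] > 0 else "DOWN"))
    if calls:
        return calls
    for side_a, side_b in PARTITIONS:
        cross = [(a, b) for a in side_a for b in side_b]
        oriented = []
        for a, b in cross:
            pair = (a, b) if (a, b) in _PAIR_INDEX else (b, a)
            s = int(signs[_PAIR_INDEX[pair]])
            oriented.append(s if pair[0] in side_a else -s)
        within_a = signs[_PAIR_INDEX[tuple(side_a)]]
        within_b = signs[_PAIR_INDEX[tuple(side_b)]]
        if (
            all(o != 0 for o in oriented)
            and len(set(oriented)) == 1
            and within_a == 0
            and within_b == 0
        ):
            direction = "UP" if oriented[0] > 0 else "DOWN"
            return [("partition", partition_label(side_a), direction)]
    if np.any(signs != 0):
        return [("mixed", "", "")]
    return [("none", "", "")]


def classify_specific(sig_matrix: pd.DataFrame) -> list[SpecificityCall]:
    """Apply :func:`classify_pattern` to every feature of a sign matrix."""
    calls: list[SpecificityCall] = []
    values = sig_matrix[COMPARISON_NAMES].to_numpy()
    for i, feature in enumerate(sig_matrix.index):
        for kind, label, direction in classify_pattern(values[i]):
            calls.append(SpecificityCall(str(feature), kind, label, direction))
    return calls


def calls_table(calls: list[SpecificityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": c.feature_id,
                "kind": c.kind,
                "label": c.label,
                "direction": c.direction,
            }
            for c in calls
        ],
        columns=["feature_id", "kind", "label", "direction"],
    )


def summarize_specificity(calls: list[SpecificityCall]) -> pd.DataFrame:
    """Count group-specific and partition features.

    A feature carrying two group labels counts once in each group; the
    ``unique_group_specific`` row deduplicates features across groups.
    """
    rows = []
    group_features: set[str] = set()
    for g in GROUPS:
        members = {c.feature_id for c in calls if c.kind == "group" and c.label == g}
        group_features |= members
        rows.append({"category": f"group:{g}", "count": len(members)})
    for side_a, _ in PARTITIONS:
        label = partition_label(side_a)
        members = {c.feature_id for c in calls if c.kind == "partition" and c.label == label}
        rows.append({"category": f"partition:{label}", "count": len(members)})
    n_partition = len({c.feature_id for c in calls if c.kind == "partition"})
    rows.append({"category": "unique_group_specific", "count": len(group_features)})
    rows.append({"category": "partition_total", "count": n_partition})
    rows.append({"category": "mixed", "count": len({c.feature_id for c in calls if c.kind == "mixed"})})
    return pd.DataFrame(rows, columns=["category", "count"])


def phospho_vs_protein(
    site_stats: pd.DataFrame,
    protein_stats: pd.DataFrame,
    site_to_protein: dict[str, str],
    params: AnalysisParams,
    candidate_ratio: float = 0.75,
) -> pd.DataFrame:
    """Compare each significant site's fold-change to its parent protein's.

    For every significant site/comparison, the parent protein's log2
    fold-change on the same comparison is joined in (NaN when the protein
    is absent from the protein table).  Sites where the protein change
    matches or exceeds the site change (``|protein| >= |site|``) are flagged
    ``protein_driven``; sites where it reaches ``candidate_ratio`` of the
    site change with the same sign are flagged ``protein_driven_candidate``
    (e.g. a 2.0-fold site change over a 1.7-fold protein change).
    """
    sig_sites = site_stats[site_stats["significant"]]
    prot_fc = protein_stats.set_index(["feature_id", "comparison"])["log2fc"]
    rows = []
    for _, r in sig_sites.iterrows():
        protein = site_to_protein.get(r["feature_id"])
        key = (protein, r["comparison"]) if protein is not None else None
        p_fc = float(prot_fc[key]) if key is not None and key in prot_fc.index else np.nan
        s_fc = float(r["log2fc"])
        same_sign = np.isfinite(p_fc) and np.sign(p_fc) == np.sign(s_fc) and p_fc != 0
        rows.append(
            {
                "site_id": r["feature_id"],
                "protein_id": protein,
                "comparison": r["comparison"],
                "site_log2fc": s_fc,
                "protein_log2fc": p_fc,
                "protein_driven": bool(same_sign and abs(p_fc) >= abs(s_fc)),
                "protein_driven_candidate": bool(
                    same_sign and abs(p_fc) >= candidate_ratio * abs(s_fc)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "protein_id",
            "comparison",
            "site_log2fc",
            "protein_log2fc",
            "protein_driven",
            "protein_driven_candidate",
        ],
    )
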