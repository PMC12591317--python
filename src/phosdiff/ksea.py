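"""Kinase-substrate enrichment analysis (KSEA) from site fold-changes.

The activity of a kinase on one comparison is scored against the background
of all quantified sites: with ``s_bar`` the mean log2 fold-change of the
kinase's matched substrates, ``p_bar`` the mean over all sites, ``delta``
the (sample, n-1) standard deviation over all sites and ``m`` the number of
matched substrates,

    z = (s_bar - p_bar) * sqrt(m) / delta

and the p-value is the two-sided normal tail probability of z.  A kinase is
called significant when ``m >= ksea_min_substrates`` and ``p < ksea_alpha``.
All quantified sites contribute to the background, not only significant
ones.  Substrates are matched by exact ``GENE;residue+position`` key.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _st

from .model import AnalysisParams, KinaseSubstrateMap, comparison_name, COMPARISONS

KSEA_COLUMNS = ["kinase_id", "comparison", "m", "s_bar", "p_bar", "delta", "z", "p_value", "significant"]


def ksea_scores(
    site_log2fc: dict[str, float] | pd.Series,
    ksmap: KinaseSubstrateMap,
    params: AnalysisParams,
    comparison: str = "",
) -> pd.DataFrame:
    """Score every kinase of ``ksmap`` against one comparison's fold-changes.

    Kinases with zero matched substrates are reported with ``m = 0`` and no
    score.  The result is sorted by descending z (scored kinases first).
    """
    fc = pd.Series(site_log2fc, dtype=float)
    if len(fc) < 2:
        raise ValueError("need at least 2 site fold-changes")
    p_bar = float(fc.mean())
    delta = float(fc.std(ddof=1))
    if delta == 0:
        raise ValueError("degenerate fold-change distribution (all sites identical)")

    rows = []
    for kinase in ksmap.kinases:
        matched = fc.index.intersection(sorted(ksmap.substrates(kinase)))
        m = len(matched)
        if m == 0:
            rows.append(
                dict(kinase_id=kinase, comparison=comparison, m=0, s_bar=np.nan,
                     p_bar=p_bar, delta=delta, z=np.nan, p_value=np.nan, significant=False)
            )
            continue
        s_bar = float(fc[matched].mean())
        z = (s_bar - p_bar) * np.sqrt(m) / delta
        p = float(2.0 * _st.norm.sf(abs(z)))
        rows.append(
            dict(
                kinase_id=kinase,
                comparison=comparison,
                m=m,
                s_bar=s_bar,
                p_bar=p_bar,
                delta=delta,
                z=float(z),
                p_value=p,
                significant=bool(m >= params.ksea_min_substrates and p < params.ksea_alpha),
            )
        )
    out = pd.DataFrame(rows, columns=KSEA_COLUMNS)
    return out.sort_values("z", ascending=False, na_position="last", kind="stable").reset_index(drop=True)


def ksea_all_comparisons(
    stats: pd.DataFrame,
    ksmap: KinaseSubstrateMap,
    params: AnalysisParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`ksea_scores` for each of the six comparisons.

    ``stats`` is the long-format feature-statistics table; each site's
    log2 fold-change feeds the score regardless of its own significance.
    Sites without a pairwise fold-change on a comparison (omnibus-gated
    features) do not contribute there.  Returns the full score table and a
    summary of kinases significant in at least one comparison.
    """
    tables = []
    for pair in COMPARISONS:
        comp = comparison_name(pair)
        sub = stats[(stats["comparison"] == comp) & stats["log2fc"].notna()]
        fc = sub.set_index("feature_id")["log2fc"]
        if len(fc) < 2:
            continue
        tables.append(ksea_scores(fc, ksmap, params, comparison=comp))
    scores = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=KSEA_COLUMNS)
    )
    sig = scores[scores["significant"]]
    summary = (
        sig.groupby("kinase_id")
        .agg(
            n_significant_comparisons=("comparison", "nunique"),
            max_abs_z=("z", lambda s: float(np.max(np.abs(s)))),
        )
        .reset_index()
        .sort_values("kinase_id", kind="stable")
        .reset_index(drop=True)
    )
    return scores, summary
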