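"""Preranked gene set enrichment analysis with Cohen's d ranking.

Genes are ranked by a standardized effect size (Cohen's d with pooled SD)
between the two compared groups.  Enrichment of a gene set is the classic
weighted Kolmogorov-Smirnov running-sum statistic (weight exponent 1):
walking down the ranking, the sum rises by ``|d| / sum(|d| over members)``
at member genes and falls by ``1 / (N - m)`` at non-members; the enrichment
score (ES) is the signed extreme deviation.  Significance comes from a
gene-set permutation null: ``nperm`` random same-size draws from the ranked
universe; the p-value is the one-sided tail frequency with a +1 pseudocount
and NES = ES divided by the mean |null ES| of matching sign.  BH adjustment
is applied across the reported sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffstats import bh_adjust
from .model import AnalysisParams, GeneSetCollection

log = logging.getLogger(__name__)


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD.

    Pooled SD uses the usual (n_a + n_b - 2)-denominator form.  Returns NaN
    when the pooled SD is 0 (the effect size is undefined)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("Cohen's d needs at least 2 values per group")
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if np.mean(a) == np.mean(b):
            return 0.0
        return float("nan")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(pooled_var))


def rank_genes(d_values: dict[str, float] | pd.Series) -> pd.Series:
    """Sort a gene -> d map descending by d, gene id ascending on ties.

    Genes with undefined (NaN) d are excluded with a warning.
    """
    s = pd.Series(d_values, dtype=float)
    n_bad = int(s.isna().sum())
    if n_bad:
        log.warning("excluding %d genes with undefined effect size", n_bad)
        s = s.dropna()
    frame = s.rename("d").rename_axis("gene").reset_index()
    frame = frame.sort_values(["d", "gene"], ascending=[False, True], kind="stable")
    return frame.set_index("gene")["d"]


def _running_es(weights: np.ndarray, member: np.ndarray) -> tuple[float, int]:
    """ES and peak position for a membership vector over a ranked universe.

    ``weights`` are |d| per ranked gene; ``member`` is boolean.  Returns the
    signed extreme of the running sum and the index at which it occurs.
    """
    n = len(member)
    m = int(member.sum())
    w_members = weights * member
    total_w = w_members.sum()
    if total_w == 0 or m == 0 or m == n:
        raise ValueError("degenerate set for ES computation")
    step = w_members / total_w - (~member) / (n - m)
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: tuple[str, ...]


def preranked_gsea(
    ranking: dict[str, float] | pd.Series,
    sets: GeneSetCollection,
    params: AnalysisParams,
    seed: int,
) -> list[EnrichmentResult]:
    """Permutation preranked GSEA over a gene -> effect-size ranking."""
    ranked = rank_genes(ranking)
    genes = np.array(ranked.index)
    weights = np.abs(ranked.to_numpy())
    n = len(genes)
    restricted = sets.restrict(genes, params.gsea_min_set, params.gsea_max_set)
    if len(restricted) == 0:
        log.warning("no gene sets survive size restriction")
        return []

    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    # one permutation null per distinct set size
    sizes = sorted({len(v) for v in restricted.sets.values()})
    null_by_size: dict[int, np.ndarray] = {}
    for m in sizes:
        null = np.empty(params.gsea_nperm)
        for i in range(params.gsea_nperm):
            member = np.zeros(n, dtype=bool)
            member[rng.choice(n, size=m, replace=False)] = True
            null[i], _ = _running_es(weights, member)
        null_by_size[m] = null

    results = []
    for name in sorted(restricted.sets):
        members_set = restricted.sets[name]
        member = np.zeros(n, dtype=bool)
        member[[gene_pos[g] for g in members_set]] = True
        es, peak = _running_es(weights, member)
        null = null_by_size[len(members_set)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if es >= 0:
            p = (1.0 + np.sum(same_sign >= es)) / (1.0 + len(same_sign))
        else:
            p = (1.0 + np.sum(same_sign <= es)) / (1.0 + len(same_sign))
        denom = float(np.mean(np.abs(same_sign))) if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        if es >= 0:
            leading = tuple(g for g in genes[: peak + 1] if g in members_set)
        else:
            leading = tuple(g for g in genes[peak:] if g in members_set)
        results.append((name, len(members_set), es, nes, float(p), leading))

    fdrs = bh_adjust([r[4] for r in results])
    return [
        EnrichmentResult(name, size, es, nes, p, float(fdr), leading)
        for (name, size, es, nes, p, leading), fdr in zip(results, fdrs)
    ]


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ],
        columns=["set_name", "size", "es", "nes", "p_value", "fdr", "leading_edge"],
    )
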