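"""Filtering, imputation and normalization of intensity matrices.

The order of operations for a protein dataset is: log2 transform, presence
filter, group-wise hybrid imputation (sample-percentile fill for sparsely
observed feature/group cells, feature-kNN fill otherwise).  A phosphosite
dataset additionally passes the localization-probability filter before the
presence filter, uses condition-specific + tail-based imputation instead of
the protein scheme, and is median-scaled afterwards.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import (
    GROUPS,
    AnalysisParams,
    IntensityMatrix,
    PhosphoSiteAnnotation,
    SampleMetadata,
)

log = logging.getLogger(__name__)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Replace observed raw intensities by their log2; mask is untouched."""
    if matrix.scale != "raw":
        raise ValueError("matrix is already log2-scaled")
    vals = matrix.values.to_numpy()
    observed = ~np.isnan(vals)
    if np.any(vals[observed] <= 0):
        raise ValueError("nonpositive observed intensity; cannot log2 transform")
    out = matrix.values.copy()
    out[:] = np.where(observed, np.log2(vals, where=observed, out=np.full_like(vals, np.nan)), np.nan)
    return IntensityMatrix(out, scale="log2")


def presence_summary(matrix: IntensityMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Observed count / group size / fraction per feature per group."""
    meta.check_against(matrix)
    observed = ~matrix.values.isna()
    rows = {}
    for g in meta.groups_present:
        samples = meta.samples_in(g)
        count = observed[samples].sum(axis=1)
        rows[f"count_{g}"] = count
        rows[f"size_{g}"] = len(samples)
        rows[f"fraction_{g}"] = count / len(samples)
    return pd.DataFrame(rows, index=matrix.values.index)


def presence_filter(
    matrix: IntensityMatrix, meta: SampleMetadata, params: AnalysisParams
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Keep features quantified often enough in at least one group.

    A feature is kept iff its observed fraction is at least
    ``presence_fraction`` in KRAS, EGFR or WT, **or** its observed count in
    the (small) EML4_ALK group reaches ``eml4alk_min_present``.  Input
    feature order is preserved.
    """
    if matrix.scale != "log2":
        raise ValueError("presence_filter expects a log2-scaled matrix")
    for g in GROUPS:
        if g not in meta.groups_present:
            raise ValueError(f"group {g} absent from metadata")
    summary = presence_summary(matrix, meta)
    keep = pd.Series(False, index=matrix.values.index)
    for g in ("KRAS", "EGFR", "WT"):
        keep |= summary[f"fraction_{g}"] >= params.presence_fraction
    keep |= summary[f"count_EML4_ALK"] >= params.eml4alk_min_present
    kept = IntensityMatrix(matrix.values.loc[keep], scale="log2")
    log.info("presence filter kept %d of %d features", kept.n_features, matrix.n_features)
    return kept, summary


def localization_filter(
    sites: list[PhosphoSiteAnnotation],
    matrix: IntensityMatrix,
    params: AnalysisParams,
) -> IntensityMatrix:
    """Keep sites with localization probability >= the class-I threshold.

    The boundary (0.75 by default) is inclusive.  Every matrix row must have
    an annotation.
    """
    probs = {a.site_id: a.localization_probability for a in sites}
    missing = [f for f in matrix.feature_ids if f not in probs]
    if missing:
        raise ValueError(f"sites without localization annotation: {missing[:5]}")
    keep = [f for f in matrix.feature_ids if probs[f] >= params.localization_min]
    if not keep:
        log.warning("localization filter removed every site")
    return IntensityMatrix(matrix.values.loc[keep], scale=matrix.scale)


def _sample_percentiles(matrix: IntensityMatrix, q: float) -> pd.Series:
    """Per-sample percentile of observed log2 values (linear interpolation)."""
    out = {}
    for s in matrix.sample_ids:
        col = matrix.values[s].dropna()
        if col.empty:
            raise ValueError(f"sample {s!r} has no observed values; percentile undefined")
        out[s] = float(np.percentile(col.to_numpy(), q))
    return pd.Series(out)


def _pairwise_feature_distances(X: np.ndarray) -> np.ndarray:
    """Euclidean feature-feature distances on pairwise-complete columns.

    Squared distances are summed over samples observed in both features and
    rescaled by ``n_total / n_shared``, so sparsity does not deflate the
    distance.  Pairs sharing no sample get an infinite distance.
    """
    n_total = X.shape[1]
    mask = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X, nan=0.0)
    A2 = A * A
    n_shared = mask @ mask.T
    sumsq = A2 @ mask.T + mask @ A2.T - 2.0 * (A @ A.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(n_shared > 0, sumsq * (n_total / np.maximum(n_shared, 1)), np.inf)
    np.fill_diagonal(d2, np.inf)
    return np.clip(d2, 0.0, None)  # numerical noise can produce tiny negatives


def impute_proteomic(
    matrix: IntensityMatrix, meta: SampleMetadata, params: AnalysisParams
) -> IntensityMatrix:
    """Group-wise hybrid imputation for the protein dataset.

    For each missing feature/group cell: if the feature was observed in less
    than half of that group's samples, fill with the recipient sample's 5th
    percentile of observed log2 intensities (a left-censoring floor);
    otherwise fill with the mean over the k nearest features (Euclidean
    distance over that group's samples) that were observed in the recipient
    sample.  Observed values are never altered.
    """
    if matrix.scale != "log2":
        raise ValueError("impute_proteomic expects a log2-scaled matrix")
    meta.check_against(matrix)
    floor = _sample_percentiles(matrix, params.low_presence_percentile)

    out = matrix.values.copy()
    for g in meta.groups_present:
        samples = meta.samples_in(g)
        X = matrix.values[samples].to_numpy()
        observed = ~np.isnan(X)
        frac = observed.sum(axis=1) / len(samples)
        need_any = ~observed.all(axis=1)
        low = need_any & (frac < 0.5)
        high = need_any & (frac >= 0.5)

        # sparse branch: per-sample percentile floor
        for fi in np.flatnonzero(low):
            for sj in np.flatnonzero(~observed[fi]):
                out.iat[fi, out.columns.get_loc(samples[sj])] = floor[samples[sj]]

        # kNN branch: neighbours are other features, observed in the target sample
        if high.any():
            d2 = _pairwise_feature_distances(X)
            for fi in np.flatnonzero(high):
                order = np.argsort(d2[fi], kind="stable")
                for sj in np.flatnonzero(~observed[fi]):
                    candidates = order[observed[order, sj] & np.isfinite(d2[fi, order])]
                    if len(candidates) == 0:
                        out.iat[fi, out.columns.get_loc(samples[sj])] = floor[samples[sj]]
                        continue
                    if len(candidates) < params.knn_k:
                        log.warning(
                            "only %d kNN candidates for feature %s in sample %s",
                            len(candidates), matrix.feature_ids[fi], samples[sj],
                        )
                    nn = candidates[: params.knn_k]
                    out.iat[fi, out.columns.get_loc(samples[sj])] = float(np.mean(X[nn, sj]))
    return IntensityMatrix(out, scale="log2")


def impute_phospho(
    matrix: IntensityMatrix,
    meta: SampleMetadata,
    params: AnalysisParams,
    seed: int,
    deterministic: bool = False,
) -> IntensityMatrix:
    """Condition-specific then tail-based imputation for phosphosites.

    Pass 1 (condition-specific): for each feature/group cell with within-
    group quantitation rate >= ``condition_rate_min``, missing values are
    drawn from Normal(group mean, group SD) of the observed values (the SD
    of a single observation is treated as 0).  Pass 2 (tail-based): cells
    still missing are drawn from a down-shifted normal
    Normal(sample_mean - tail_shift * sample_SD, tail_scale * sample_SD)
    computed over the recipient sample's observed values.  With
    ``deterministic=True`` the distribution means are filled instead of
    random draws.
    """
    if matrix.scale != "log2":
        raise ValueError("impute_phospho expects a log2-scaled matrix")
    meta.check_against(matrix)
    rng = np.random.default_rng(seed)

    sample_mean = matrix.values.mean(axis=0, skipna=True)
    sample_sd = matrix.values.std(axis=0, ddof=1, skipna=True)

    out = matrix.values.copy()
    for g in meta.groups_present:
        samples = meta.samples_in(g)
        if not samples:
            raise ValueError(f"empty group {g}")
        sub = matrix.values[samples]
        observed = ~sub.isna()
        frac = observed.sum(axis=1) / len(samples)
        eligible = (frac >= params.condition_rate_min) & (frac < 1.0) & (frac > 0)
        for feature in sub.index[eligible]:
            row = sub.loc[feature]
            obs = row.dropna()
            mu = float(obs.mean())
            sd = float(obs.std(ddof=1)) if len(obs) > 1 else 0.0
            for s in row.index[row.isna()]:
                draw = mu if deterministic or sd == 0 else float(rng.normal(mu, sd))
                out.loc[feature, s] = draw

    # tail pass: whatever remains missing, per recipient sample
    still = out.isna()
    for s in matrix.sample_ids:
        idx = still.index[still[s]]
        if idx.empty:
            continue
        mu = float(sample_mean[s] - params.tail_shift * sample_sd[s])
        sd = float(params.tail_scale * sample_sd[s])
        if deterministic or sd == 0:
            out.loc[idx, s] = mu
        else:
            out.loc[idx, s] = rng.normal(mu, sd, size=len(idx))
    return IntensityMatrix(out, scale="log2")


def median_scale(matrix: IntensityMatrix) -> IntensityMatrix:
    """Shift each sample so all per-sample medians agree.

    Each sample is shifted additively to the grand median of the per-sample
    medians; there is no multiplicative rescaling.  Requires a fully imputed
    matrix.
    """
    if matrix.values.isna().any().any():
        raise ValueError("median_scale requires a fully imputed matrix")
    medians = matrix.values.median(axis=0)
    grand = float(np.median(medians.to_numpy()))
    out = matrix.values + (grand - medians)
    return IntensityMatrix(out, scale=matrix.scale)
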