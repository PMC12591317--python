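"""Synthetic cohort generator with ground truth for recovery testing.

The generator emulates the statistical structure of a label-free
(phospho)proteomic cohort of four genotype groups sized 6/23/31/22:

* per-feature baseline log2 intensities drawn from a normal between-feature
  distribution (log-normal raw intensities),
* additive group-specific log2 effects ("spikes") on designated features,
  targeting either a single group or one side of a 2-vs-2 partition,
* within-feature residual noise,
* intensity-dependent (MNAR) dropout: a cell goes missing with probability
  ``logistic((midpoint - log2_intensity) * slope)``, so low-abundance cells
  are censored more often — the left-censoring that motivates percentile and
  tail-based imputation,
* for phosphosites: Beta-distributed localization probabilities and
  kinase-driven coordinated shifts of a kinase's substrate sites, plus decoy
  kinases whose substrates receive no shift.

Every draw comes from a single seeded generator, so identical configs and
seeds give bit-identical cohorts.  The emitted truth tables use the same
label vocabulary as :mod:`phosdiff.specificity`, which makes them directly
comparable to the classifier's calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (
    GROUPS,
    IntensityMatrix,
    KinaseSubstrateMap,
    PhosphoSiteAnnotation,
    SampleMetadata,
    comparison_name,
    partition_label,
)


@dataclass(frozen=True)
class SpikeEffect:
    """A group-specific log2 effect on a set of features.

    ``target`` is one group name (single-group effect) or two group names
    (one side of a 2-vs-2 partition).  ``effect_log2`` is signed: positive
    means the target side sits higher than the rest.
    """

    feature_indices: tuple[int, ...]
    target: tuple[str, ...]
    effect_log2: float

    def __post_init__(self) -> None:
        if not set(self.target) <= set(GROUPS):
            raise ValueError(f"unknown groups in spike target: {self.target}")
        if len(self.target) not in (1, 2):
            raise ValueError("spike target must name 1 or 2 groups")
        if not np.isfinite(self.effect_log2):
            raise ValueError("spike effect must be finite")


@dataclass(frozen=True)
class KinaseEffect:
    """A coordinated substrate shift attributed to one kinase.

    All substrate features receive ``shift_log2`` added to the first group
    of ``comparison``, so the true substrate log2 difference on that
    comparison equals the shift.  ``shift_log2 = 0`` defines a decoy kinase.
    """

    kinase_id: str
    substrate_indices: tuple[int, ...]
    comparison: tuple[str, str]
    shift_log2: float


@dataclass
class SynthConfig:
    """Study-condition parameters of the simulated cohort.

    Defaults mirror the modelled cohort: group sizes 6/23/31/22 (82 samples),
    log2 baselines around 25 with between-feature SD 2 and within-feature
    noise SD 0.5, and logistic MNAR dropout placed to censor roughly a fifth
    of cells (midpoint 22.5 log2 units, slope 1).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"EML4_ALK": 6, "EGFR": 23, "KRAS": 31, "WT": 22}
    )
    n_features: int = 2000
    baseline_mean: float = 25.0
    feature_sd: float = 2.0
    noise_sd: float = 0.5
    spikes: tuple[SpikeEffect, ...] = ()
    dropout_midpoint: float = 22.5
    dropout_slope: float = 1.0  # 0 disables dropout
    loc_prob_alpha: float = 9.0
    loc_prob_beta: float = 1.0
    kinase_effects: tuple[KinaseEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")
        for spike in self.spikes:
            if any(i < 0 or i >= self.n_features for i in spike.feature_indices):
                raise ValueError("spike feature index out of range")
        for ke in self.kinase_effects:
            if any(i < 0 or i >= self.n_features for i in ke.substrate_indices):
                raise ValueError(f"kinase {ke.kinase_id}: substrate index out of range")


def single_group_spikes(
    n_per_group: int,
    effect_log2: float = 2.0,
    start_index: int = 0,
    alternate_sign: bool = True,
) -> tuple[SpikeEffect, ...]:
    """Convenience design: ``n_per_group`` spiked features for each group.

    Signs alternate UP/DOWN within each group so both directions are
    exercised.  Features are assigned consecutive indices from
    ``start_index``.
    """
    spikes = []
    idx = start_index
    for g in GROUPS:
        for j in range(n_per_group):
            sign = -1.0 if (alternate_sign and j % 2) else 1.0
            spikes.append(SpikeEffect((idx,), (g,), sign * effect_log2))
            idx += 1
    return tuple(spikes)


def _group_offsets(config: SynthConfig) -> np.ndarray:
    """Per feature x group additive log2 offsets from spikes and kinases."""
    delta = np.zeros((config.n_features, len(GROUPS)))
    gidx = {g: i for i, g in enumerate(GROUPS)}
    for spike in config.spikes:
        for f in spike.feature_indices:
            for g in spike.target:
                delta[f, gidx[g]] += spike.effect_log2
    for ke in config.kinase_effects:
        for f in ke.substrate_indices:
            delta[f, gidx[ke.comparison[0]]] += ke.shift_log2
    return delta


def _spike_truth_columns(config: SynthConfig) -> tuple[list[bool], list[str], list[str], list[float]]:
    spiked = [False] * config.n_features
    labels = [""] * config.n_features
    directions = [""] * config.n_features
    effects = [0.0] * config.n_features
    for spike in config.spikes:
        direction = "UP" if spike.effect_log2 > 0 else "DOWN"
        if len(spike.target) == 1:
            label = spike.target[0]
        else:
            label = partition_label(spike.target)
            if not label.startswith("+".join(t for t in GROUPS if t in spike.target)):
                # effect sits on the second-listed side: flip the direction
                direction = "DOWN" if direction == "UP" else "UP"
        for f in spike.feature_indices:
            if spiked[f]:
                raise ValueError(f"feature {f} spiked twice")
            spiked[f] = True
            labels[f] = label
            directions[f] = direction
            effects[f] = spike.effect_log2
    return spiked, labels, directions, effects


def simulate_cohort(
    config: SynthConfig,
    feature_prefix: str = "PROT",
) -> tuple[IntensityMatrix, SampleMetadata, pd.DataFrame]:
    """Simulate a raw-scale protein cohort.

    Returns ``(matrix, metadata, truth)`` where ``truth`` is a per-feature
    DataFrame with the true group means (log2), the spiked flag, and the
    intended specificity label and direction.
    """
    rng = np.random.default_rng(config.seed)
    feature_ids = [f"{feature_prefix}{i:05d}" for i in range(config.n_features)]

    sample_ids, groups = [], []
    for g in GROUPS:
        n = config.group_sizes.get(g, 0)
        for j in range(n):
            sample_ids.append(f"{g}_{j + 1:02d}")
            groups.append(g)
    meta = SampleMetadata(pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id")))

    mu = rng.normal(config.baseline_mean, config.feature_sd, size=config.n_features)
    delta = _group_offsets(config)
    gcol = np.array([GROUPS.index(g) for g in groups])
    true_log2 = mu[:, None] + delta[:, gcol]
    log2_values = true_log2 + rng.normal(0.0, config.noise_sd, size=true_log2.shape)

    if config.dropout_slope > 0:
        p_miss = expit((config.dropout_midpoint - log2_values) * config.dropout_slope)
        missing = rng.random(size=log2_values.shape) < p_miss
    else:
        missing = np.zeros(log2_values.shape, dtype=bool)

    raw = np.exp2(log2_values)
    raw[missing] = np.nan
    matrix = IntensityMatrix(
        pd.DataFrame(raw, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids),
        scale="raw",
    )

    spiked, labels, directions, effects = _spike_truth_columns(config)
    truth = pd.DataFrame(
        {
            "spiked": spiked,
            "label": labels,
            "direction": directions,
            "effect_log2": effects,
            **{f"mean_{g}": mu + delta[:, i] for i, g in enumerate(GROUPS)},
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return matrix, meta, truth


def simulate_phospho(
    config: SynthConfig,
) -> tuple[
    IntensityMatrix,
    SampleMetadata,
    list[PhosphoSiteAnnotation],
    KinaseSubstrateMap,
    pd.DataFrame,
    pd.DataFrame,
]:
    """Simulate a phosphosite cohort with kinase-driven substrate shifts.

    As :func:`simulate_cohort`, plus Beta-distributed localization
    probabilities, site identifiers of the form ``GENE00007;S123``, a
    kinase-substrate map covering the designed (and decoy) kinases, and a
    per-kinase truth table (kinase, comparison, intended shift, decoy flag).
    """
    matrix, meta, truth = simulate_cohort(config, feature_prefix="TMP")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    residues = rng.choice(["S", "T", "Y"], p=[0.82, 0.15, 0.03], size=config.n_features)
    positions = rng.integers(1, 2000, size=config.n_features)
    site_ids = [
        f"GENE{i:05d};{residues[i]}{positions[i]}" for i in range(config.n_features)
    ]
    matrix = IntensityMatrix(
        matrix.values.set_axis(pd.Index(site_ids, name="feature_id"), axis=0),
        scale="raw",
    )
    truth = truth.set_axis(pd.Index(site_ids, name="feature_id"), axis=0)

    loc_probs = rng.beta(config.loc_prob_alpha, config.loc_prob_beta, size=config.n_features)
    annotations = [
        PhosphoSiteAnnotation(site_ids[i], site_ids[i].split(";")[0], float(loc_probs[i]))
        for i in range(config.n_features)
    ]

    mapping = {
        ke.kinase_id: {site_ids[i] for i in ke.substrate_indices}
        for ke in config.kinase_effects
    }
    ksmap = KinaseSubstrateMap(mapping) if mapping else KinaseSubstrateMap({})

    kinase_truth = pd.DataFrame(
        [
            {
                "kinase_id": ke.kinase_id,
                "comparison": comparison_name(ke.comparison),
                "shift_log2": ke.shift_log2,
                "n_substrates": len(ke.substrate_indices),
                "is_decoy": ke.shift_log2 == 0.0,
            }
            for ke in config.kinase_effects
        ]
    )
    return matrix, meta, annotations, ksmap, truth, kinase_truth


def truth_gene_sets(
    truth: pd.DataFrame,
    n_decoy_sets: int = 20,
    decoy_size: int = 25,
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Build gene sets from a cohort truth table for enrichment testing.

    One set per group collects that group's spiked features; decoy sets are
    uniform random draws from the whole feature universe.
    """
    rng = np.random.default_rng(seed)
    universe = np.array(truth.index)
    sets: dict[str, frozenset[str]] = {}
    for g in GROUPS:
        members = truth.index[(truth["spiked"]) & (truth["label"] == g)]
        if len(members):
            sets[f"SPIKED_{g}"] = frozenset(members)
    for d in range(n_decoy_sets):
        sets[f"DECOY_{d:02d}"] = frozenset(rng.choice(universe, size=decoy_size, replace=False))
    return sets
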