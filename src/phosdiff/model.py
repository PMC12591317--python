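"""Core data containers shared by every pipeline stage.

The pipeline models a four-group lung adenocarcinoma cohort: tumors carrying
an EML4--ALK rearrangement, an EGFR mutation, a KRAS mutation, or none of the
three ("triple wild-type", WT).  Quantities move through the stages as a
feature x sample intensity matrix with an explicit missingness convention
(``NaN`` = not quantified), accompanied by sample metadata assigning each
sample to one genotype group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical genotype group names, in fixed display order.
GROUPS: tuple[str, ...] = ("EML4_ALK", "EGFR", "KRAS", "WT")

#: The six pairwise group comparisons in canonical order.  The sign
#: convention everywhere is ``log2fc = mean(first) - mean(second)``.
COMPARISONS: tuple[tuple[str, str], ...] = (
    ("EML4_ALK", "EGFR"),
    ("EML4_ALK", "KRAS"),
    ("EML4_ALK", "WT"),
    ("EGFR", "KRAS"),
    ("EGFR", "WT"),
    ("KRAS", "WT"),
)


def comparison_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


#: The three 2-vs-2 splits of the four groups.  Each is given as
#: (side_a, side_b) with EML4_ALK always on side_a.
PARTITIONS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("EML4_ALK", "EGFR"), ("KRAS", "WT")),
    (("EML4_ALK", "KRAS"), ("EGFR", "WT")),
    (("EML4_ALK", "WT"), ("EGFR", "KRAS")),
)


def partition_label(side: Iterable[str]) -> str:
    """Canonical label for the 2-vs-2 partition containing ``side``.

    Input is either side of the split; output is e.g.
    ``"EML4_ALK+KRAS|EGFR+WT"`` with the EML4_ALK-containing side first.
    """
    side_set = frozenset(side)
    if len(side_set) != 2 or not side_set <= set(GROUPS):
        raise ValueError(f"a partition side must be 2 distinct groups, got {sorted(side_set)}")
    other = tuple(g for g in GROUPS if g not in side_set)
    a = tuple(g for g in GROUPS if g in side_set)
    first, second = (a, other) if "EML4_ALK" in side_set else (other, a)
    return f"{'+'.join(first)}|{'+'.join(second)}"


_GROUP_ALIASES = {
    "EML4_ALK": "EML4_ALK",
    "EML4-ALK": "EML4_ALK",
    "EML4ALK": "EML4_ALK",
    "ALK": "EML4_ALK",
    "EGFR": "EGFR",
    "KRAS": "KRAS",
    "WT": "WT",
    "WILD_TYPE": "WT",
    "WILDTYPE": "WT",
}


def canonical_group(label: str) -> str:
    """Map a free-form group label to one of the four canonical names.

    Matching is case-insensitive and tolerant of the common dash/underscore
    spellings of the fusion name.  Unknown labels raise ``ValueError``.
    """
    key = str(label).strip().upper().replace("–", "-").replace(" ", "_")
    key2 = key.replace("-", "_")
    for candidate in (key, key2, key2.replace("_", "")):
        if candidate in _GROUP_ALIASES:
            return _GROUP_ALIASES[candidate]
    raise ValueError(f"unknown sample group label: {label!r}")


class IntensityMatrix:
    """A feature x sample intensity matrix with an explicit missing mask.

    Values are stored in a pandas DataFrame whose index holds feature
    identifiers and whose columns hold sample identifiers; ``NaN`` marks a
    missing (not-quantified) cell.  ``scale`` records whether values are raw
    intensities or log2 intensities; the raw -> log2 transition happens
    exactly once, in :func:`phosdiff.preprocess.log2_transform`.
    """

    __slots__ = ("values", "scale")

    def __init__(self, values: pd.DataFrame, scale: str = "raw") -> None:
        if scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {scale!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        self.values = values.astype(float)
        self.scale = scale

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is missing."""
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.scale)

    def subset_features(self, feature_ids: Iterable[str]) -> "IntensityMatrix":
        ids = list(feature_ids)
        return IntensityMatrix(self.values.loc[ids], self.scale)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"IntensityMatrix({self.n_features} features x {self.n_samples} "
            f"samples, scale={self.scale}, "
            f"{int(self.missing_mask.values.sum())} missing)"
        )


class SampleMetadata:
    """Sample -> genotype group assignment, with optional clinical covariates.

    ``table`` is indexed by sample identifier and has at least a ``group``
    column restricted to the four canonical group names.
    """

    __slots__ = ("table",)

    def __init__(self, table: pd.DataFrame) -> None:
        if "group" not in table.columns:
            raise ValueError("metadata requires a 'group' column")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        tab = table.copy()
        tab["group"] = [canonical_group(g) for g in tab["group"]]
        counts = tab["group"].value_counts()
        small = [g for g, n in counts.items() if n < 2]
        if small:
            raise ValueError(f"groups with fewer than 2 samples: {small}")
        self.table = tab

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups_present(self) -> list[str]:
        present = set(self.table["group"])
        return [g for g in GROUPS if g in present]

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups_present}

    def check_against(self, matrix: IntensityMatrix) -> None:
        """Every matrix sample must appear exactly once in the metadata."""
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing[:5]}")

    def __repr__(self) -> str:  # pragma: no cover
        sizes = self.group_sizes()
        return f"SampleMetadata({sum(sizes.values())} samples, {sizes})"


_SITE_RE = re.compile(r"^(?P<gene>[^;]+);(?P<residue>[STY])(?P<pos>[1-9]\d*)$")


def parse_site_id(site_id: str) -> tuple[str, str, int]:
    """Split ``GENE;residue+position`` (e.g. ``SRSF1;S94``) into its parts.

    The residue must be S, T, or Y and the position a positive integer;
    anything else raises ``ValueError``.
    """
    m = _SITE_RE.match(site_id)
    if not m:
        raise ValueError(f"malformed phosphosite identifier: {site_id!r}")
    return m.group("gene"), m.group("residue"), int(m.group("pos"))


def is_valid_site_id(site_id: str) -> bool:
    return _SITE_RE.match(str(site_id)) is not None


@dataclass(frozen=True)
class PhosphoSiteAnnotation:
    """Per-site annotation: parent protein and localization confidence."""

    site_id: str
    protein_id: str
    localization_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                f"localization probability outside [0,1]: "
                f"{self.localization_probability} for {self.site_id}"
            )
        parse_site_id(self.site_id)

    @property
    def gene(self) -> str:
        return parse_site_id(self.site_id)[0]


class KinaseSubstrateMap:
    """Mapping kinase -> set of substrate site identifiers."""

    __slots__ = ("mapping",)

    def __init__(self, mapping: Mapping[str, Iterable[str]]) -> None:
        clean: dict[str, frozenset[str]] = {}
        for kinase, sites in mapping.items():
            site_set = frozenset(sites)
            if not site_set:
                raise ValueError(f"kinase {kinase!r} has an empty substrate set")
            bad = [s for s in site_set if not is_valid_site_id(s)]
            if bad:
                raise ValueError(
                    f"kinase {kinase!r} has malformed substrate ids: {bad[:5]}"
                )
            clean[kinase] = site_set
        self.mapping = clean

    @property
    def kinases(self) -> list[str]:
        return sorted(self.mapping)

    def substrates(self, kinase: str) -> frozenset[str]:
        return self.mapping[kinase]

    def __len__(self) -> int:
        return len(self.mapping)

    def __repr__(self) -> str:  # pragma: no cover
        n_sites = sum(len(v) for v in self.mapping.values())
        return f"KinaseSubstrateMap({len(self.mapping)} kinases, {n_sites} pairs)"


class GeneSetCollection:
    """Named gene sets (GMT semantics), with optional per-set descriptions."""

    __slots__ = ("sets", "descriptions")

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.sets = {name: frozenset(members) for name, members in sets.items()}
        self.descriptions = dict(descriptions or {})

    def restrict(
        self, universe: Iterable[str], min_size: int, max_size: int
    ) -> "GeneSetCollection":
        """Intersect each set with ``universe`` and keep sizes in bounds."""
        uni = frozenset(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = members & uni
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
        return GeneSetCollection(kept, {k: v for k, v in self.descriptions.items() if k in kept})

    def __len__(self) -> int:
        return len(self.sets)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSetCollection({len(self.sets)} sets)"


@dataclass
class AnalysisParams:
    """All tunable constants of the analysis, with the study defaults.

    presence_fraction
        Minimum observed fraction within at least one of the KRAS / EGFR / WT
        groups for a feature to pass the presence filter.
    eml4alk_min_present
        Alternative presence route for the small EML4--ALK group: minimum
        observed *count* (4 of its 6 samples).
    knn_k
        Neighbour count for the k-nearest-neighbour imputation branch.
    low_presence_percentile
        Percentile of a sample's observed log2 intensities used to fill
        features observed in less than half of a group (left-censored fill).
    localization_min
        Minimum site localization probability kept ("class I" sites at 0.75).
    condition_rate_min
        Minimum within-group quantitation rate for condition-specific
        (group-distribution) phospho imputation.
    gate_alpha
        Alpha for the Shapiro-Wilk and Levene gating tests that select the
        parametric / nonparametric branch.
    omnibus_alpha
        Raw omnibus p-value below which pairwise tests are run.
    fdr_q
        Benjamini-Hochberg threshold applied per feature across its pairwise
        comparisons (significance requires adjusted p strictly below this).
    fc_threshold
        Linear fold-change threshold; applied as ``|log2fc| > log2(fc)``.
    ksea_min_substrates, ksea_alpha
        Kinase-score significance rule (m >= 3 and p < 0.05).
    tail_shift, tail_scale
        Down-shifted-normal parameters (in units of per-sample SD) for
        tail-based phospho imputation.
    gsea_nperm, gsea_min_set, gsea_max_set
        Permutation count and set-size bounds for preranked GSEA.
    """

    presence_fraction: float = 0.5
    eml4alk_min_present: int = 4
    knn_k: int = 10
    low_presence_percentile: float = 5.0
    localization_min: float = 0.75
    condition_rate_min: float = 0.5
    gate_alpha: float = 0.05
    omnibus_alpha: float = 0.05
    fdr_q: float = 0.05
    fc_threshold: float = 2.0
    ksea_min_substrates: int = 3
    ksea_alpha: float = 0.05
    tail_shift: float = 1.8
    tail_scale: float = 0.3
    gsea_nperm: int = 1000
    gsea_min_set: int = 10
    gsea_max_set: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presence_fraction", "condition_rate_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("gate_alpha", "omnibus_alpha", "fdr_q", "ksea_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1 (linear fold-change)")
        for name in ("knn_k", "eml4alk_min_present", "ksea_min_substrates",
                     "gsea_nperm", "gsea_min_set", "gsea_max_set"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.low_presence_percentile < 100.0:
            raise ValueError("low_presence_percentile must lie in (0, 100)")
        for name in ("tail_shift", "tail_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)
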