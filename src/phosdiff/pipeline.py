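"""End-to-end orchestration: simulate -> preprocess -> statistics ->
specificity -> KSEA -> GSEA, with a machine-readable run manifest.

A run either simulates a cohort (protein or phosphosite flavour) or loads
intensity/metadata tables from disk.  Stages execute in a fixed order; each
stochastic stage receives a child seed derived from the single run seed by
a fixed offset, so re-running with the same config and seed reproduces
byte-identical outputs and toggling one stage off does not shift the seeds
of the others.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffstats, gsea, io, ksea, preprocess, specificity
from .model import (
    COMPARISONS,
    AnalysisParams,
    GeneSetCollection,
    IntensityMatrix,
    KinaseSubstrateMap,
    SampleMetadata,
    comparison_name,
)
from .simulate import SynthConfig, simulate_cohort, simulate_phospho, single_group_spikes

log = logging.getLogger(__name__)

# fixed child-seed offsets per stochastic stage
_SEED_OFFSETS = {"simulate": 0, "impute": 1, "gsea": 2}

DEFAULT_STAGES = ("preprocess", "diffstats", "specificity", "ksea", "gsea")


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    dataset: str = "protein"  # or "phospho"
    simulate: SynthConfig | None = None
    intensity_path: str | None = None
    metadata_path: str | None = None
    kinase_substrate_path: str | None = None
    gmt_path: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    out_dir: str = "phosdiff_out"
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    gsea_comparison: tuple[str, str] = ("EGFR", "WT")

    def to_dict(self) -> dict:
        d = {
            "dataset": self.dataset,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "stages": list(self.stages),
            "gsea_comparison": list(self.gsea_comparison),
            "params": self.params.to_dict(),
            "intensity_path": self.intensity_path,
            "metadata_path": self.metadata_path,
            "kinase_substrate_path": self.kinase_substrate_path,
            "gmt_path": self.gmt_path,
        }
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["spikes"] = [
                {"feature_indices": list(s.feature_indices), "target": list(s.target),
                 "effect_log2": s.effect_log2}
                for s in self.simulate.spikes
            ]
            sim["kinase_effects"] = [
                {"kinase_id": k.kinase_id, "substrate_indices": list(k.substrate_indices),
                 "comparison": list(k.comparison), "shift_log2": k.shift_log2}
                for k in self.simulate.kinase_effects
            ]
            d["simulate"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .simulate import KinaseEffect, SpikeEffect

        sim = None
        if d.get("simulate") is not None:
            s = dict(d["simulate"])
            s["spikes"] = tuple(
                SpikeEffect(tuple(x["feature_indices"]), tuple(x["target"]), x["effect_log2"])
                for x in s.get("spikes", [])
            )
            s["kinase_effects"] = tuple(
                KinaseEffect(x["kinase_id"], tuple(x["substrate_indices"]),
                             tuple(x["comparison"]), x["shift_log2"])
                for x in s.get("kinase_effects", [])
            )
            sim = SynthConfig(**s)
        params = AnalysisParams(**d.get("params", {}))
        return cls(
            dataset=d.get("dataset", "protein"),
            simulate=sim,
            intensity_path=d.get("intensity_path"),
            metadata_path=d.get("metadata_path"),
            kinase_substrate_path=d.get("kinase_substrate_path"),
            gmt_path=d.get("gmt_path"),
            params=params,
            out_dir=d.get("out_dir", "phosdiff_out"),
            seed=d.get("seed", 0),
            stages=tuple(d.get("stages", DEFAULT_STAGES)),
            gsea_comparison=tuple(d.get("gsea_comparison", ("EGFR", "WT"))),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_synth_config(seed: int, n_features: int = 2000, n_spiked_per_group: int = 10) -> SynthConfig:
    """The default simulated study: four groups 6/23/31/22, spiked
    single-group effects of +/-2 log2 units on the leading features."""
    return SynthConfig(
        n_features=n_features,
        spikes=single_group_spikes(n_spiked_per_group, effect_log2=2.0),
        seed=seed,
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages and write all outputs plus a manifest.

    Returns the mapping of output names to file paths.
    """
    params = config.params
    seeds = {k: config.seed + off for k, off in _SEED_OFFSETS.items()}
    tables: dict[str, pd.DataFrame] = {}
    input_checksums: dict[str, str] = {}

    annotations = None
    ksmap: KinaseSubstrateMap | None = None
    gene_sets: GeneSetCollection | None = None
    truth = kinase_truth = None

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            if config.dataset == "phospho":
                matrix, meta, annotations, ksmap, truth, kinase_truth = simulate_phospho(sim_cfg)
            else:
                matrix, meta, truth = simulate_cohort(sim_cfg)
            tables["synth_truth"] = truth.reset_index()
            if kinase_truth is not None and len(kinase_truth):
                tables["synth_kinase_truth"] = kinase_truth
        else:
            if not config.intensity_path or not config.metadata_path:
                raise ValueError("need intensity_path and metadata_path when not simulating")
            dialect = "phosphosite" if config.dataset == "phospho" else "protein"
            matrix, annotations = io.read_intensity_table(config.intensity_path, dialect=dialect)
            meta = io.read_metadata(config.metadata_path)
            input_checksums["intensity"] = io.file_sha256(config.intensity_path)
            input_checksums["metadata"] = io.file_sha256(config.metadata_path)
        if config.kinase_substrate_path:
            ksmap = io.read_kinase_substrate_table(config.kinase_substrate_path)
            input_checksums["kinase_substrate"] = io.file_sha256(config.kinase_substrate_path)
        if config.gmt_path:
            gene_sets = io.read_gmt(config.gmt_path)
            input_checksums["gmt"] = io.file_sha256(config.gmt_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("input", e) from e

    # --- preprocess -------------------------------------------------------
    if "preprocess" in config.stages:
        try:
            matrix = preprocess.log2_transform(matrix)
            if config.dataset == "phospho" and annotations is not None:
                matrix = preprocess.localization_filter(annotations, matrix, params)
            matrix, summary = preprocess.presence_filter(matrix, meta, params)
            if config.dataset == "phospho":
                matrix = preprocess.impute_phospho(matrix, meta, params, seed=seeds["impute"])
                matrix = preprocess.median_scale(matrix)
            else:
                matrix = preprocess.impute_proteomic(matrix, meta, params)
            tables["presence_summary"] = summary.reset_index()
            tables["processed_matrix"] = matrix.values.reset_index()
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("preprocess", e) from e

    # --- diffstats --------------------------------------------------------
    stats = None
    if "diffstats" in config.stages:
        try:
            stats = diffstats.analyze_features(matrix, meta, params)
            tables["feature_stats"] = stats
        except Exception as e:  # noqa: BLE001
            raise StageError("diffstats", e) from e

    # --- specificity ------------------------------------------------------
    if "specificity" in config.stages and stats is not None:
        try:
            sig = specificity.significance_matrix(stats, params)
            calls = specificity.classify_specific(sig)
            tables["specificity_calls"] = specificity.calls_table(calls)
            tables["specificity_summary"] = specificity.summarize_specificity(calls)
        except Exception as e:  # noqa: BLE001
            raise StageError("specificity", e) from e

    # --- ksea -------------------------------------------------------------
    if "ksea" in config.stages and stats is not None and ksmap is not None and len(ksmap):
        try:
            scores, summary = ksea.ksea_all_comparisons(stats, ksmap, params)
            tables["kinase_scores"] = scores
            tables["kinase_summary"] = summary
        except Exception as e:  # noqa: BLE001
            raise StageError("ksea", e) from e

    # --- gsea -------------------------------------------------------------
    if "gsea" in config.stages and gene_sets is not None:
        try:
            g1, g2 = config.gsea_comparison
            a = matrix.values[meta.samples_in(g1)]
            b = matrix.values[meta.samples_in(g2)]
            d_values = {
                feat: gsea.cohens_d(a.loc[feat].to_numpy(), b.loc[feat].to_numpy())
                for feat in matrix.feature_ids
            }
            results = gsea.preranked_gsea(d_values, gene_sets, params, seed=seeds["gsea"])
            tables["gsea_results"] = gsea.results_table(results)
        except Exception as e:  # noqa: BLE001
            raise StageError("gsea", e) from e

    manifest_params = dict(params.to_dict())
    manifest_params.update(
        {
            "dataset": config.dataset,
            "stages": list(config.stages),
            "stage_seeds": seeds,
            "gsea_comparison": comparison_name(config.gsea_comparison),
        }
    )
    return io.write_results(
        tables,
        config.out_dir,
        params=manifest_params,
        seed=config.seed,
        input_checksums=input_checksums,
    )
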