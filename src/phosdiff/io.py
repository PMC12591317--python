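"""Readers and writers for the tabular formats the pipeline touches.

Input dialects follow the MaxQuant convention, simplified to one intensity
column per sample: proteins carry ``LFQ intensity <sample>`` columns, site
tables carry ``Intensity <sample>`` columns plus a ``Localization prob``
column.  Zero and blank intensity cells both mean "not quantified" and
become missing; contaminant (``CON__``) and reversed-decoy (``REV__``) rows
are dropped at read time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    GeneSetCollection,
    IntensityMatrix,
    KinaseSubstrateMap,
    PhosphoSiteAnnotation,
    SampleMetadata,
    is_valid_site_id,
)

log = logging.getLogger(__name__)

_EXCLUDED_PREFIXES = ("CON__", "REV__")

_DIALECTS = {
    "protein": {"prefix": "LFQ intensity ", "id_candidates": ["Protein IDs", "Majority protein IDs", "protein_id", "feature_id"]},
    "phosphosite": {"prefix": "Intensity ", "id_candidates": ["Site ID", "site_id", "feature_id"]},
}


def read_intensity_table(
    path: str | Path,
    dialect: str = "protein",
    intensity_prefix: str | None = None,
) -> tuple[IntensityMatrix, list[PhosphoSiteAnnotation] | None]:
    """Read a MaxQuant-style TSV into a raw-scale :class:`IntensityMatrix`.

    Returns ``(matrix, annotations)`` where ``annotations`` is a list of
    :class:`PhosphoSiteAnnotation` for the phosphosite dialect and ``None``
    for proteins.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be 'protein' or 'phosphosite', got {dialect!r}")
    spec = _DIALECTS[dialect]
    prefix = intensity_prefix if intensity_prefix is not None else spec["prefix"]

    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_cols = [c for c in df.columns if c.startswith(prefix)]
    if not sample_cols:
        raise ValueError(
            f"no sample intensity columns found: expected columns starting "
            f"with {prefix!r} in {path}"
        )
    id_col = next((c for c in spec["id_candidates"] if c in df.columns), df.columns[0])

    ids = df[id_col].astype(str)
    drop = ids.str.startswith(_EXCLUDED_PREFIXES)
    n_dropped = int(drop.sum())
    if n_dropped:
        log.info("dropped %d contaminant/reverse rows from %s", n_dropped, path)
    df = df.loc[~drop.values].reset_index(drop=True)
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate feature identifier in {path}: {dup!r}")

    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    values = values.where(values > 0)  # 0 and blank both mean missing
    values.index = pd.Index(ids, name="feature_id")
    values.columns = [c[len(prefix):] for c in sample_cols]
    matrix = IntensityMatrix(values, scale="raw")

    annotations = None
    if dialect == "phosphosite":
        if "Localization prob" not in df.columns:
            raise ValueError(f"phosphosite table lacks a 'Localization prob' column: {path}")
        prot_col = next(
            (c for c in ("Protein", "Proteins", "protein_id") if c in df.columns), None
        )
        annotations = []
        for i, site_id in enumerate(ids):
            protein = str(df[prot_col].iloc[i]) if prot_col else site_id.split(";")[0]
            annotations.append(
                PhosphoSiteAnnotation(
                    site_id=site_id,
                    protein_id=protein,
                    localization_probability=float(df["Localization prob"].iloc[i]),
                )
            )
    return matrix, annotations


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a CSV/TSV sample table with ``sample_id`` and ``group`` columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata file {path} lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in {path}: {dup!r}")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, tab-separated members)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = parts
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_kinase_substrate_table(path: str | Path) -> KinaseSubstrateMap:
    """Read kinase-substrate pairs from a PhosphoSitePlus-style TSV.

    The substrate may be given either as a single ``GENE;residue+position``
    column or as separate gene / residue / position columns (auto-detected).
    Malformed sites are skipped with a warning; zero valid rows is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}

    kin_col = next(
        (cols[c] for c in ("kinase", "kinase_id", "gene_kinase") if c in cols), None
    )
    if kin_col is None:
        raise ValueError(f"no kinase column found in {path}")

    site_col = next(
        (cols[c] for c in ("substrate_site", "site", "site_id", "substrate") if c in cols),
        None,
    )
    mapping: dict[str, set[str]] = {}
    n_bad = 0
    if site_col is not None and df[site_col].map(is_valid_site_id).any():
        pairs = zip(df[kin_col], df[site_col])
    else:
        gene_col = next((cols[c] for c in ("substrate_gene", "gene", "sub_gene") if c in cols), None)
        res_col = next((cols[c] for c in ("residue", "sub_mod_rsd", "site_residue") if c in cols), None)
        pos_col = next((cols[c] for c in ("position", "site_position") if c in cols), None)
        if gene_col is None or res_col is None:
            raise ValueError(f"could not detect substrate-site columns in {path}")
        if pos_col is None:  # residue column like "S94"
            sites = df[gene_col].astype(str) + ";" + df[res_col].astype(str)
        else:
            sites = (
                df[gene_col].astype(str) + ";" + df[res_col].astype(str) + df[pos_col].astype(str)
            )
        pairs = zip(df[kin_col], sites)

    for kinase, site in pairs:
        if not is_valid_site_id(site):
            n_bad += 1
            continue
        mapping.setdefault(str(kinase), set()).add(str(site))
    if n_bad:
        log.warning("skipped %d malformed substrate sites in %s", n_bad, path)
    if not mapping:
        raise ValueError(f"no valid kinase-substrate rows in {path}")
    return KinaseSubstrateMap(mapping)


def write_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write an IntensityMatrix as TSV; missing cells are empty fields."""
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.10g")


def read_matrix(path: str | Path, scale: str = "log2") -> IntensityMatrix:
    """Read a TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return IntensityMatrix(df, scale=scale)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    params: dict | None = None,
    seed: int | None = None,
    input_checksums: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write result tables as TSVs plus a JSON run manifest.

    Column order of each table is preserved; identical inputs produce
    byte-identical files.  The manifest records every parameter, the seed,
    input checksums, and the checksum of each written table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    checksums: dict[str, str] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")
        paths[name] = path
        checksums[name] = file_sha256(path)
    manifest = {
        "tables": sorted(tables),
        "parameters": params or {},
        "seed": seed,
        "input_checksums": input_checksums or {},
        "output_checksums": checksums,
        "percentile_method": "linear",
    }
    manifest_path = out_dir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    paths["run_manifest"] = manifest_path
    return paths
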