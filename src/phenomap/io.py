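"""Readers and writers for the pipeline's plain-text contracts.

All tabular files are UTF-8 TSV with '.' decimals; missing values are empty
fields or ``NA``.  Formats:

* growth curves — long format, columns ``strain_id, environment_id, run_id,
  replicate, time_h, od``;
* trait matrix (native) — first column ``strain_id``, remaining columns trait
  ids ``ENV|variable``; trait classes in an optional side table
  ``trait_id\tenvironment_class``;
* trait matrix (``dataset_s1_export`` dialect) — a CSV export of the study's
  deposited fitness-variable workbook: strain rows carrying ``strain_id,
  species, population, source`` followed by trait columns named
  ``class|environment|variable``; returns annotations alongside the matrix;
* annotations — ``strain_id, species, population, source, mosaic, auxotroph,
  clean_lineage``;
* genotype features — gene rows (``feature_id, gene, chrom, pos, kind``)
  followed by one column per strain (0/1 indicators or CNV float ratios);
* crosses — a marker map (``marker_id, chrom, pos``), a genotype matrix
  (offspring x markers, values ``A``/``B``/``NA``) and a trait vector;
* QTL regions — ``cross_id, chrom, start, end, peak_marker, lod`` (1-based
  inclusive coordinates);
* dendrograms — Newick.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ANNOTATION_COLUMNS,
    GenotypeFeatureSet,
    StrainAnnotation,
    TraitMatrix,
    split_trait_id,
    trait_id,
)
from .growth import GrowthCurve
from .linkage import Cross

__all__ = [
    "read_growth_curves",
    "write_growth_curves",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_annotations",
    "write_annotations",
    "read_genotype_features",
    "write_genotype_features",
    "read_cross",
    "write_cross",
    "read_qtl_regions",
    "write_qtl_regions",
    "write_newick",
]

NA_VALUES = ["", "NA"]


def read_growth_curves(path) -> list[GrowthCurve]:
    """Read long-format growth-curve TSV into per-well curves."""
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES)
    required = {"strain_id", "environment_id", "run_id", "replicate", "time_h", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    keys = ["strain_id", "environment_id", "run_id", "replicate"]
    for (s, e, r, rep), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(str(s), str(e), str(r), int(rep),
                        grp["time_h"].to_numpy(), grp["od"].to_numpy())
        )
    return curves


def write_growth_curves(curves, path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "strain_id": c.strain_id,
                    "environment_id": c.environment_id,
                    "run_id": c.run_id,
                    "replicate": c.replicate,
                    "time_h": c.times,
                    "od": c.od,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def _read_table(path, sep):
    try:
        return pd.read_csv(path, sep=sep, na_values=NA_VALUES, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc


def read_trait_matrix(
    path, dialect: str = "native", classes_path=None
):
    """Read a trait matrix; the ``dataset_s1_export`` dialect also returns annotations.

    Native dialect returns a :class:`TraitMatrix`; ``dataset_s1_export``
    (a CSV export of the deposited fitness-variable workbook) returns a
    ``(TraitMatrix, StrainAnnotation)`` pair.  Errors name the offending
    columns or strains.
    """
    if dialect == "native":
        df = _read_table(path, "\t")
        if df.columns[0] != "strain_id":
            raise ValueError(f"{path}: first column must be strain_id, got {df.columns[0]!r}")
        df = df.set_index("strain_id")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate strain ids {dupes}")
        for col in df.columns:
            split_trait_id(col)  # validates header shape
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            for col in bad:
                rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                                & df[col].notna() & (df[col] != "")].tolist()
                raise ValueError(f"{path}: non-numeric cells in {col!r}, strains {rows}")
        matrix = TraitMatrix(df.astype(float))
        if classes_path is not None:
            classes = pd.read_csv(classes_path, sep="\t").set_index("trait_id")
            matrix.traits["environment_class"] = (
                classes["environment_class"].reindex(matrix.trait_ids).fillna("unclassified")
            )
        return matrix
    if dialect == "dataset_s1_export":
        df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
        meta_cols = ["strain_id", "species", "population", "source"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: export missing columns {missing}")
        df = df.set_index("strain_id")
        value_cols = [c for c in df.columns if c not in meta_cols]
        tids, classes = [], {}
        for col in value_cols:
            parts = col.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: trait column {col!r} not of form 'class|environment|variable'"
                )
            cls, env, var = parts
            tid = trait_id(env, var)
            tids.append(tid)
            classes[tid] = cls
        values = df[value_cols].apply(pd.to_numeric, errors="coerce")
        values.columns = tids
        matrix = TraitMatrix(values)
        matrix.traits["environment_class"] = [
            classes[t] for t in matrix.trait_ids
        ]
        ann_tab = df[["species", "population", "source"]].copy()
        ann_tab["mosaic"] = ann_tab["population"].str.lower() == "mosaic"
        ann_tab["auxotroph"] = False
        ann_tab["clean_lineage"] = ~ann_tab["mosaic"]
        return matrix, StrainAnnotation(ann_tab)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_trait_matrix(matrix: TraitMatrix, path, classes_path=None) -> None:
    out = matrix.values.copy()
    out.index.name = "strain_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    if classes_path is not None:
        matrix.traits[["environment_class"]].rename_axis("trait_id").to_csv(
            classes_path, sep="\t"
        )


def read_annotations(path) -> StrainAnnotation:
    df = _read_table(path, "\t")
    if "strain_id" not in df.columns:
        raise ValueError(f"{path}: missing strain_id column")
    for col in ("mosaic", "auxotroph", "clean_lineage"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1", "yes"])
    return StrainAnnotation(df)


def write_annotations(ann: StrainAnnotation, path) -> None:
    ann.table[list(ANNOTATION_COLUMNS)].rename_axis("strain_id").to_csv(
        path, sep="\t"
    )


def read_genotype_features(path) -> GenotypeFeatureSet:
    """Read a feature table: gene rows, metadata columns, then strain columns."""
    df = _read_table(path, "\t")
    meta_cols = ["feature_id", "gene", "chrom", "pos", "kind"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    features = df[meta_cols].set_index("feature_id")
    features["pos"] = features["pos"].astype(int)
    strain_cols = [c for c in df.columns if c not in meta_cols]
    values = (
        df.set_index("feature_id")[strain_cols]
        .apply(pd.to_numeric, errors="coerce")
        .T
    )
    values.index.name = "strain_id"
    values.columns.name = None
    return GenotypeFeatureSet(features, values)


def write_genotype_features(fs: GenotypeFeatureSet, path) -> None:
    out = fs.features.copy()
    out = pd.concat([out, fs.values.T], axis=1)
    out.rename_axis("feature_id").to_csv(path, sep="\t", na_rep="NA")


def read_cross(markers_path, genotypes_path, trait_path, cross_id="cross") -> Cross:
    """Read a cross from its marker map, A/B genotype matrix and trait vector."""
    markers = _read_table(markers_path, "\t")
    geno = _read_table(genotypes_path, "\t").set_index("offspring_id")
    code = {"A": 0.0, "B": 1.0}
    vals = geno.apply(
        lambda col: col.map(lambda v: code.get(str(v).strip(), np.nan))
    )
    trait = _read_table(trait_path, "\t").set_index("offspring_id")["trait"]
    return Cross(cross_id, markers, vals[markers["marker_id"]], trait)


def write_cross(cross: Cross, markers_path, genotypes_path, trait_path) -> None:
    cross.markers.to_csv(markers_path, sep="\t", index=False)
    decode = {0.0: "A", 1.0: "B"}
    out = cross.genotypes.apply(
        lambda col: col.map(lambda v: decode.get(v, "NA"))
    )
    out.rename_axis("offspring_id").to_csv(genotypes_path, sep="\t")
    cross.trait.rename("trait").rename_axis("offspring_id").to_csv(
        trait_path, sep="\t", na_rep="NA"
    )


def read_qtl_regions(path) -> pd.DataFrame:
    df = _read_table(path, "\t")
    required = {"cross_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_qtl_regions(regions: pd.DataFrame, path) -> None:
    regions.to_csv(path, sep="\t", index=False)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))
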