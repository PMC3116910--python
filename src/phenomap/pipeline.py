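"""End-to-end pipeline: normalize -> stats -> cluster -> associate -> crosscheck.

:func:`run_pipeline` ties the stages together under a single
:class:`RunConfig` and writes every result as tidy TSV plus one machine-
readable JSON summary.  Each output records the configuration hash and seed;
rerunning with the same configuration reproduces the deterministic stages
byte-identically.  A stage failure aborts the run naming the stage and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import clustering as clus_mod
from . import io as pio
from . import linkage as link_mod
from . import simulate as sim_mod
from . import stats as stats_mod

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("phenomap")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``trait_matrix_path`` is unset a synthetic panel (with planted
    alleles and decoys) is simulated instead, making the pipeline runnable
    without any input files.
    """

    output_dir: str = "phenomap_out"
    seed: int = 0
    # inputs (optional; simulated when absent)
    trait_matrix_path: str | None = None
    annotations_path: str | None = None
    features_path: str | None = None
    cross_paths: list = field(default_factory=list)  # [{markers, genotypes, trait, cross_id}]
    # analysis levels
    bonferroni_alpha: float = 0.1
    fdr: float = 0.02
    t_alpha: float = 0.015
    ks_alpha: float = 0.15
    qtl_alpha: float = 0.05
    n_permutations: int = 1000
    flank_bp: int = 25_000
    min_overlap: int = 10
    exclude_auxotrophs: bool = True
    exclude_mosaics: bool = True
    basal_environment: str | None = None
    # synthetic fallback
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bonferroni_alpha", "fdr", "t_alpha", "ks_alpha", "qtl_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("trait_matrix_path", "annotations_path", "features_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (pd.Series, pd.Index)):
        return _jsonable(list(obj))
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it also writes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "bonferroni_alpha": config.bonferroni_alpha,
            "fdr": config.fdr,
            "t_alpha": config.t_alpha,
            "ks_alpha": config.ks_alpha,
            "qtl_alpha": config.qtl_alpha,
        },
    }

    def stage(name):
        log.info("stage: %s", name)
        return name

    # ---- load or simulate ------------------------------------------------
    name = stage("load")
    try:
        crosses = []
        truth = None
        if config.trait_matrix_path is not None:
            matrix = pio.read_trait_matrix(config.trait_matrix_path)
            if config.annotations_path is None:
                raise ValueError("annotations_path required with trait_matrix_path")
            ann = pio.read_annotations(config.annotations_path)
            features = (
                pio.read_genotype_features(config.features_path)
                if config.features_path
                else None
            )
            for spec in config.cross_paths:
                crosses.append(
                    pio.read_cross(
                        spec["markers"], spec["genotypes"], spec["trait"],
                        spec.get("cross_id", "cross"),
                    )
                )
        else:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            panel_cfg = sim_mod.PanelConfig(**sim_kwargs)
            matrix, ann, features, truth = sim_mod.simulate_panel(panel_cfg)
            for planted in truth.planted_features.itertuples():
                cross, ctruth = sim_mod.simulate_cross(
                    causal_marker=_nearest_marker(planted.chrom, planted.pos),
                    effect_fraction_of_variance=0.5,
                    seed=config.seed + 1000 + planted.Index,
                    cross_id=f"cross_{planted.feature_id}",
                )
                crosses.append(cross)
        ann.require_strains(matrix.strains)
        if matrix.n_strains == 0 or matrix.n_traits == 0:
            raise ValueError("empty panel")
        summary["panel"] = matrix.coverage_report()
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # ---- exclusions ------------------------------------------------------
    name = stage("exclusions")
    try:
        keep = pd.Index(matrix.strains)
        if config.exclude_auxotrophs:
            keep = keep.difference(ann.auxotrophs())
        log.info("after auxotroph exclusion: %d strains", len(keep))
        stats_matrix = matrix.subset_strains(keep)
        labels = ann.populations().reindex(stats_matrix.strains)
        if config.exclude_mosaics:
            labels = labels[labels != "mosaic"]
        summary["exclusions"] = {
            "n_auxotrophs_excluded": int(matrix.n_strains - stats_matrix.n_strains),
            "n_strains_for_stats": int(len(labels)),
        }
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # ---- normalize (optional basal) -------------------------------------
    if config.basal_environment:
        name = stage("normalize")
        try:
            stats_matrix, basal_report = stats_mod.basal_normalize(
                stats_matrix, config.basal_environment
            )
            summary["basal_normalization"] = _jsonable(basal_report)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # ---- stats -----------------------------------------------------------
    name = stage("stats")
    try:
        calls, call_summary = stats_mod.call_specific_traits(
            stats_matrix, labels, fdr=config.fdr
        )
        calls.to_csv(out / "specific_trait_calls.tsv", sep="\t", index=False)
        summary["specific_traits"] = _jsonable(call_summary)
        re_struct = stats_mod.rate_efficiency_structure(stats_matrix)
        re_struct["per_environment"].to_csv(
            out / "rate_efficiency_by_environment.tsv", sep="\t", index=False
        )
        summary["rate_efficiency"] = {
            k: _jsonable(v) for k, v in re_struct.items() if k != "per_environment"
        }
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # ---- cluster ---------------------------------------------------------
    name = stage("cluster")
    try:
        dist = clus_mod.centered_pearson_distance(
            stats_matrix, min_overlap=config.min_overlap
        )
        dist.table.to_csv(out / "trait_distances.tsv", sep="\t")
        dendro = clus_mod.average_linkage(dist)
        pio.write_newick(dendro.to_newick(), out / "trait_dendrogram.nwk")
        (out / "leaf_order.txt").write_text("\n".join(dendro.leaf_order()) + "\n")
        summary["clustering"] = {"n_leaves": len(dendro.leaves)}
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # ---- associate + linkage + crosscheck --------------------------------
    if features is not None and len(features.values.columns):
        name = stage("associate")
        try:
            targets = (
                list(truth.planted_features["trait_id"])
                if truth is not None and len(truth.planted_features)
                else list(stats_matrix.trait_ids[: 3])
            )
            frames = []
            for tid in targets:
                frames.append(
                    assoc_mod.associate_features(
                        features, stats_matrix, tid,
                        t_alpha=config.t_alpha, ks_alpha=config.ks_alpha,
                        cnv_alpha=config.t_alpha,
                    )
                )
            assoc = pd.concat(frames, ignore_index=True)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        name = stage("linkage")
        try:
            regions = []
            for cross in crosses:
                profile = link_mod.marker_scan(cross)
                thr = link_mod.permutation_threshold(
                    cross, n_perm=config.n_permutations, alpha=config.qtl_alpha,
                    seed=config.seed,
                )
                regs = link_mod.qtl_regions(profile, thr, flank_bp=config.flank_bp)
                profile.table.assign(cross_id=cross.cross_id).to_csv(
                    out / f"lod_{cross.cross_id}.tsv", sep="\t", index=False
                )
                regions.append(regs)
            qtls = (
                pd.concat(regions, ignore_index=True)
                if regions
                else pd.DataFrame(columns=["cross_id", "chrom", "start", "end",
                                            "peak_marker", "lod"])
            )
            pio.write_qtl_regions(qtls, out / "qtl_regions.tsv")
            summary["linkage"] = {
                "n_crosses": len(crosses),
                "n_qtl_regions": int(len(qtls)),
                "qtl_alpha": config.qtl_alpha,
            }
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        name = stage("crosscheck")
        try:
            checked = assoc_mod.qtl_crosscheck(assoc, qtls)
            checked.to_csv(out / "associations.tsv", sep="\t", index=False)
            summary["associations"] = {
                "n_tested": int(checked["tested"].sum()),
                "n_candidates": int(checked["candidate"].sum()),
                "n_retained": int(checked["retained"].sum()),
                "retained": _jsonable(
                    checked.loc[checked["retained"], "feature_id"]
                ),
            }
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    if truth is not None:
        summary["ground_truth"] = {
            "planted_features": _jsonable(
                truth.planted_features["feature_id"]
            ),
            "n_population_effect_traits": int(
                truth.population_effects["trait_id"].nunique()
            ),
        }
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    return summary


def _nearest_marker(chrom: str, pos: int) -> str:
    """Closest default-map marker to a locus (same chromosome index by name)."""
    marker_map = sim_mod.default_marker_map()
    roman = {"chrI": 1, "chrII": 2, "chrIII": 3, "chrIV": 4, "chrV": 5,
             "chrVI": 6, "chrVII": 7, "chrVIII": 8, "chrIX": 9, "chrX": 10,
             "chrXI": 11, "chrXII": 12, "chrXIII": 13, "chrXIV": 14,
             "chrXV": 15, "chrXVI": 16}
    num = roman.get(chrom)
    name = f"chr{num:02d}" if num else chrom
    sub = marker_map[marker_map["chrom"] == name]
    if sub.empty:
        sub = marker_map
    idx = (sub["pos"] - pos).abs().idxmin()
    return sub.loc[idx, "marker_id"]
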