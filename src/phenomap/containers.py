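"""Core in-memory containers shared across the pipeline.

The pipeline's central object is the :class:`TraitMatrix`: strains x traits of
log2 relative fitness, where a *trait* is one (environment, fitness-component)
pair.  Each of the ~200 environments contributes three traits — the
proliferative lag (adaptation time), rate (population doubling time) and
efficiency (total density change) — so a full panel carries ~600 traits.
Missing cells are NaN and are always distinguished from zero (a value of zero
means "indistinguishable from the reference strain").

Strain-level metadata lives in :class:`StrainAnnotation`; every grouping used
by the statistics layer (species, population, source habitat, mosaic genome,
auxotrophy) is driven from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three fitness components extracted from a growth curve.
VARIABLES = ("lag", "rate", "efficiency")

#: Separator between environment and variable in a trait identifier.
TRAIT_SEP = "|"


def trait_id(environment_id: str, variable: str) -> str:
    """Compose the canonical trait identifier ``ENV|variable``."""
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    return f"{environment_id}{TRAIT_SEP}{variable}"


def split_trait_id(tid: str) -> tuple[str, str]:
    """Split ``ENV|variable`` into its parts, validating the variable tag."""
    env, _, var = tid.rpartition(TRAIT_SEP)
    if not env or var not in VARIABLES:
        raise ValueError(f"malformed trait id {tid!r}; expected 'ENV{TRAIT_SEP}variable'")
    return env, var


@dataclass
class TraitMatrix:
    """Strains x traits of log2 relative fitness with missing-value support.

    Parameters
    ----------
    values
        DataFrame indexed by strain id, columns are trait ids ``ENV|variable``.
        NaN encodes missing data.
    traits
        Trait metadata indexed by trait id with columns ``environment_id``,
        ``environment_class`` and ``variable``.  Built from the value columns
        when not supplied (class then defaults to ``"unclassified"``).
    """

    values: pd.DataFrame
    traits: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate strain ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate trait ids: {dupes}")
        if self.traits is None:
            meta = []
            for tid in self.values.columns:
                env, var = split_trait_id(tid)
                meta.append((tid, env, "unclassified", var))
            self.traits = pd.DataFrame(
                meta, columns=["trait_id", "environment_id", "environment_class", "variable"]
            ).set_index("trait_id")
        missing_meta = self.values.columns.difference(self.traits.index)
        if len(missing_meta):
            raise ValueError(f"traits without metadata: {missing_meta.tolist()}")
        self.traits = self.traits.loc[self.values.columns]
        bad = set(self.traits["variable"]) - set(VARIABLES)
        if bad:
            raise ValueError(f"unknown variable tags: {sorted(bad)}")
        self.values = self.values.astype(float)
        self.values.index.name = "strain_id"
        self.values.columns.name = None

    # -- basic geometry -------------------------------------------------
    @property
    def strains(self) -> pd.Index:
        return self.values.index

    @property
    def trait_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def environments(self) -> pd.Index:
        return pd.Index(self.traits["environment_id"].unique())

    # -- views ----------------------------------------------------------
    def subset_strains(self, strain_ids) -> "TraitMatrix":
        keep = [s for s in self.values.index if s in set(strain_ids)]
        return TraitMatrix(self.values.loc[keep].copy(), self.traits.copy())

    def subset_traits(self, tids) -> "TraitMatrix":
        keep = [t for t in self.values.columns if t in set(tids)]
        return TraitMatrix(self.values[keep].copy(), self.traits.loc[keep].copy())

    def for_variable(self, variable: str) -> "TraitMatrix":
        keep = self.traits.index[self.traits["variable"] == variable]
        return self.subset_traits(keep)

    def complete_traits(self) -> pd.Index:
        """Trait ids with no missing value in any strain."""
        return self.values.columns[self.values.notna().all(axis=0)]

    def coverage_report(self) -> dict:
        miss = self.values.isna()
        return {
            "n_strains": self.n_strains,
            "n_traits": self.n_traits,
            "n_missing_cells": int(miss.values.sum()),
            "missing_fraction": float(miss.values.mean()) if miss.size else 0.0,
            "strains_with_missing": int(miss.any(axis=1).sum()),
        }


#: Columns of a strain annotation table, in file order.
ANNOTATION_COLUMNS = (
    "species",
    "population",
    "source",
    "mosaic",
    "auxotroph",
    "clean_lineage",
)


@dataclass
class StrainAnnotation:
    """Per-strain labels: species, population, source, mosaic and auxotrophy.

    ``population`` is the strain's phylogenetic population, or ``"mosaic"`` for
    strains whose genomes recombine several populations.  ``auxotroph`` marks
    strains with nutrient-requirement markers whose trait values confound
    comparisons; the statistics layer excludes them from group tests and mean
    profiles.  ``clean_lineage`` marks non-mosaic strains assigned to a single
    well-defined population.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "strain_id":
            if "strain_id" in self.table.columns:
                self.table = self.table.set_index("strain_id")
            else:
                self.table.index.name = "strain_id"
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate annotation rows for strains: {dupes}")
        for col in ANNOTATION_COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        for col in ("mosaic", "auxotroph", "clean_lineage"):
            self.table[col] = self.table[col].astype(bool)

    @property
    def strains(self) -> pd.Index:
        return self.table.index

    def require_strains(self, strain_ids) -> None:
        """Check every strain has exactly one annotation row."""
        missing = pd.Index(strain_ids).difference(self.table.index)
        if len(missing):
            raise ValueError(f"strains without annotation: {missing.tolist()}")

    def species_of(self, species: str) -> pd.Index:
        return self.table.index[self.table["species"] == species]

    def auxotrophs(self) -> pd.Index:
        return self.table.index[self.table["auxotroph"]]

    def non_auxotrophs(self) -> pd.Index:
        return self.table.index[~self.table["auxotroph"]]

    def clean_lineages(self) -> pd.Index:
        return self.table.index[self.table["clean_lineage"]]

    def populations(self, species: str | None = None) -> pd.Series:
        """strain -> population labels, optionally restricted to one species."""
        tab = self.table
        if species is not None:
            tab = tab[tab["species"] == species]
        return tab["population"]

    def sources(self, species: str | None = None) -> pd.Series:
        tab = self.table
        if species is not None:
            tab = tab[tab["species"] == species]
        return tab["source"]


@dataclass
class GenotypeFeatureSet:
    """Genotype features over strains: gene presence, premature stops, CNV ratios.

    ``features`` is indexed by feature id with columns ``gene``, ``chrom``,
    ``pos`` (1-based) and ``kind`` in {``presence``, ``stop``, ``cnv``}.
    ``values`` is strains x features; presence uses 1 = gene present / 0 = not
    detected, stop uses 0 = premature stop / 1 = reference sequence, cnv holds
    the log copy-number read ratio.  NaN encodes missing genotype data.
    """

    features: pd.DataFrame
    values: pd.DataFrame

    KINDS = ("presence", "stop", "cnv")

    def __post_init__(self) -> None:
        for col in ("gene", "chrom", "pos", "kind"):
            if col not in self.features.columns:
                raise ValueError(f"feature table missing column {col!r}")
        bad = set(self.features["kind"]) - set(self.KINDS)
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")
        missing = self.values.columns.difference(self.features.index)
        if len(missing):
            raise ValueError(f"feature values without metadata: {missing.tolist()}")
        self.features = self.features.loc[self.values.columns]
        binary = self.features.index[self.features["kind"].isin(["presence", "stop"])]
        vals = self.values[binary]
        ok = vals.isna() | vals.isin([0, 1, 0.0, 1.0])
        if not ok.values.all():
            raise ValueError("presence/stop indicators must be 0, 1 or missing")
        if (self.features["pos"] < 1).any():
            raise ValueError("feature positions are 1-based; got pos < 1")

    def of_kind(self, kind: str) -> pd.Index:
        return self.features.index[self.features["kind"] == kind]

    def locus(self, feature_id: str) -> tuple[str, int]:
        row = self.features.loc[feature_id]
        return str(row["chrom"]), int(row["pos"])


@dataclass
class GroundTruth:
    """Ground truth emitted next to every simulated dataset.

    Sufficient to score every calling operation downstream: which traits carry
    which population shifts, which features were planted with what effect and
    carriers, and which cross markers are causal.
    """

    population_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["population", "trait_id", "effect"]
        )
    )
    planted_features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature_id", "kind", "chrom", "pos", "trait_id", "effect", "carriers"]
        )
    )
    causal_markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cross_id", "marker_id", "chrom", "pos", "effect_fraction"]
        )
    )

    def shifted_traits(self, population: str) -> set[str]:
        pe = self.population_effects
        return set(pe.loc[pe["population"] == population, "trait_id"])
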