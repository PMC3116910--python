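"""Synthetic panels, growth curves, genotype features and crosses.

Every generator emits ground truth next to its data, so each calling operation
in the pipeline can be scored against what was planted.  The defaults emulate
the study design this package targets: a multi-population strain panel
(populations of a handful of strains each, mirroring five clean populations of
a partially domesticated species), ~200 environments x 3 fitness components =
600 traits, 2 replicates per strain, random missingness, and — optionally —
planted large-effect alleles: a premature stop codon carried by one
population, a copy-number variant with a dose-dependent effect, and a
presence/absence gene.

Trait effects act directly on the log2 relative-fitness scale when matrices
are simulated (the fast path used by the statistics layer); growth curves for
the end-to-end path come from :func:`simulate_growth_curve`, a shifted
logistic whose analytic maximal log-slope, tangent-intercept time and
asymptotic rise map one-to-one onto the three fitness components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    GenotypeFeatureSet,
    GroundTruth,
    StrainAnnotation,
    TraitMatrix,
    trait_id,
)
from .growth import GrowthCurve
from .linkage import Cross

__all__ = [
    "PanelConfig",
    "PlantedStop",
    "PlantedCNV",
    "PlantedPresence",
    "PlantedShift",
    "simulate_panel",
    "simulate_growth_curve",
    "simulate_cross",
    "default_marker_map",
]

#: Default environment classes, cycled over environments.
ENVIRONMENT_CLASSES = (
    "carbon",
    "nitrogen",
    "toxin",
    "vitamin",
    "mineral",
    "temperature",
)


@dataclass(frozen=True)
class PlantedShift:
    """A population-wide mean shift on a fraction of traits (in within-sd units)."""

    population: str
    fraction_of_traits: float = 0.35
    effect_sd: float = 2.0
    direction: int = -1  # deleterious by default, mirroring degenerated lineages

    def validate(self, populations) -> None:
        if self.population not in populations:
            raise ValueError(f"PlantedShift.population {self.population!r} not in panel")
        if not 0 <= self.fraction_of_traits <= 1:
            raise ValueError("PlantedShift.fraction_of_traits must be in [0, 1]")


@dataclass(frozen=True)
class PlantedStop:
    """A premature stop codon abolishing performance on one trait.

    Carriers (indicator 0) take an additive shift of ``effect_sd`` within-sd
    units on the target trait; non-carriers keep the reference value (1).
    """

    gene: str = "STOP_GENE"
    chrom: str = "chr04"
    pos: int = 463_000
    carrier_population: str = "P1"
    n_carriers: int = 3
    effect_sd: float = -3.0
    environment_index: int = 0
    variable: str = "lag"

    def validate(self, populations) -> None:
        if self.carrier_population not in populations:
            raise ValueError(
                f"PlantedStop.carrier_population {self.carrier_population!r} not in panel"
            )
        if self.n_carriers < 1:
            raise ValueError("PlantedStop.n_carriers must be >= 1")


@dataclass(frozen=True)
class PlantedCNV:
    """A copy-number variant with a dose-dependent trait effect.

    Strains in the amplified population draw an integer copy number in
    ``amplified_copies``; everyone else has one copy.  The copy-number read
    ratio is ln(copies) plus measurement noise, and the target trait gains
    ``slope_sd`` within-sd units per unit of ratio.
    """

    gene: str = "CNV_GENE"
    chrom: str = "chr08"
    pos: int = 212_000
    amplified_population: str = "P2"
    amplified_copies: tuple = (2, 4, 6, 8)
    slope_sd: float = 2.5
    ratio_noise_sd: float = 0.05
    environment_index: int = 1
    variable: str = "efficiency"

    def validate(self, populations) -> None:
        if self.amplified_population not in populations:
            raise ValueError(
                f"PlantedCNV.amplified_population {self.amplified_population!r} not in panel"
            )


@dataclass(frozen=True)
class PlantedPresence:
    """A presence/absence gene enabling one trait for its carriers."""

    gene: str = "PRESENCE_GENE"
    chrom: str = "chr02"
    pos: int = 98_000
    carrier_population: str = "P3"
    effect_sd: float = 3.0
    environment_index: int = 2
    variable: str = "rate"

    def validate(self, populations) -> None:
        if self.carrier_population not in populations:
            raise ValueError(
                f"PlantedPresence.carrier_population {self.carrier_population!r} not in panel"
            )


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a synthetic strain panel.

    Effect sizes everywhere are expressed in units of :attr:`within_sd`, the
    within-population standard deviation of a replicate-averaged trait value,
    so a "2 sd shift" is 2 x within_sd on the log2 relative-fitness scale.
    """

    populations: dict = field(
        default_factory=lambda: {f"P{i}": 5 for i in range(1, 6)}
    )
    species: str = "S. synthetica"
    n_environments: int = 200
    environment_classes: tuple = ENVIRONMENT_CLASSES
    n_replicates: int = 2
    strain_sd: float = 0.3  # biological strain effect, log2 units
    noise_sd: float = 0.2  # per-replicate measurement noise, log2 units
    missing_rate: float = 0.0
    shifts: tuple = ()
    stop: PlantedStop | None = None
    cnv: PlantedCNV | None = None
    presence: PlantedPresence | None = None
    n_decoy_stops: int = 0
    n_decoy_cnvs: int = 0
    rate_efficiency_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("populations must be non-empty")
        for pop, n in self.populations.items():
            if n < 1:
                raise ValueError(f"populations[{pop!r}] must be >= 1")
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("strain_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not -1 <= self.rate_efficiency_coupling <= 1:
            raise ValueError("rate_efficiency_coupling must be in [-1, 1]")
        pops = set(self.populations)
        for shift in self.shifts:
            shift.validate(pops)
        for allele in (self.stop, self.cnv, self.presence):
            if allele is not None:
                allele.validate(pops)

    @property
    def n_strains(self) -> int:
        return sum(self.populations.values())

    @property
    def within_sd(self) -> float:
        """SD of a replicate-averaged trait value within a population."""
        return float(
            np.sqrt(self.strain_sd**2 + self.noise_sd**2 / self.n_replicates)
        )


def _panel_layout(config: PanelConfig):
    strains, pops = [], []
    for pop, n in config.populations.items():
        for k in range(1, n + 1):
            strains.append(f"{pop}_s{k:02d}")
            pops.append(pop)
    envs = [f"E{i:03d}" for i in range(1, config.n_environments + 1)]
    classes = {
        e: config.environment_classes[i % len(config.environment_classes)]
        for i, e in enumerate(envs)
    }
    tids = [trait_id(e, v) for e in envs for v in ("lag", "rate", "efficiency")]
    return strains, pops, envs, classes, tids


def simulate_panel(
    config: PanelConfig,
) -> tuple[TraitMatrix, StrainAnnotation, GenotypeFeatureSet, GroundTruth]:
    """Simulate a strain panel on the log2 relative-fitness scale.

    The trait value of strain *i* in trait *j* is the sum of its population's
    planted effect on *j*, any planted allele effect, a strain effect
    ~N(0, strain_sd) shared across replicates, and per-replicate noise
    ~N(0, noise_sd); replicates are averaged into the returned matrix.
    Missing cells are masked at ``missing_rate`` after averaging.
    """
    rng = np.random.default_rng(config.seed)
    strains, pops, envs, classes, tids = _panel_layout(config)
    n_s, n_t = len(strains), len(tids)
    pop_arr = np.array(pops)
    sd = config.within_sd

    truth = GroundTruth()
    effect = np.zeros((n_s, n_t))

    # population-wide shifts on a random subset of traits
    pop_rows = []
    for shift in config.shifts:
        n_shift = int(round(shift.fraction_of_traits * n_t))
        chosen = rng.choice(n_t, size=n_shift, replace=False)
        val = shift.direction * shift.effect_sd * sd
        effect[np.ix_(pop_arr == shift.population, chosen)] += val
        for j in chosen:
            pop_rows.append((shift.population, tids[j], val))
    truth.population_effects = pd.DataFrame(
        pop_rows, columns=["population", "trait_id", "effect"]
    )

    # genotype features: planted alleles plus inert decoys
    feat_rows, feat_vals, planted_rows = [], {}, []
    tindex = {t: j for j, t in enumerate(tids)}

    def _target(env_index: int, variable: str) -> str:
        return trait_id(envs[env_index % len(envs)], variable)

    if config.stop is not None:
        st = config.stop
        members = np.where(pop_arr == st.carrier_population)[0]
        carriers = members[: st.n_carriers]
        ind = np.ones(n_s)
        ind[carriers] = 0.0  # 0 = premature stop
        tid_ = _target(st.environment_index, st.variable)
        effect[carriers, tindex[tid_]] += st.effect_sd * sd
        feat_rows.append((st.gene, st.gene, st.chrom, st.pos, "stop"))
        feat_vals[st.gene] = ind
        planted_rows.append(
            (st.gene, "stop", st.chrom, st.pos, tid_, st.effect_sd * sd,
             ",".join(strains[i] for i in carriers))
        )
    if config.cnv is not None:
        cv = config.cnv
        copies = np.ones(n_s)
        amp = pop_arr == cv.amplified_population
        copies[amp] = rng.choice(cv.amplified_copies, size=int(amp.sum()))
        ratio = np.log(copies) + rng.normal(0, cv.ratio_noise_sd, n_s)
        tid_ = _target(cv.environment_index, cv.variable)
        effect[:, tindex[tid_]] += cv.slope_sd * sd * ratio
        feat_rows.append((cv.gene, cv.gene, cv.chrom, cv.pos, "cnv"))
        feat_vals[cv.gene] = ratio
        planted_rows.append(
            (cv.gene, "cnv", cv.chrom, cv.pos, tid_, cv.slope_sd * sd,
             ",".join(np.array(strains)[amp]))
        )
    if config.presence is not None:
        pr = config.presence
        ind = np.zeros(n_s)
        ind[pop_arr == pr.carrier_population] = 1.0
        tid_ = _target(pr.environment_index, pr.variable)
        effect[ind == 0, tindex[tid_]] -= pr.effect_sd * sd
        feat_rows.append((pr.gene, pr.gene, pr.chrom, pr.pos, "presence"))
        feat_vals[pr.gene] = ind
        planted_rows.append(
            (pr.gene, "presence", pr.chrom, pr.pos, tid_, pr.effect_sd * sd,
             ",".join(np.array(strains)[ind == 1]))
        )
    decoy_chroms = ["chr01", "chr03", "chr05", "chr07", "chr09", "chr11",
                    "chr13", "chr15"]
    for d in range(config.n_decoy_stops):
        gene = f"DECOY_STOP_{d+1}"
        n_minor = int(rng.integers(2, max(3, n_s // 4)))
        carriers = rng.choice(n_s, size=n_minor, replace=False)
        ind = np.ones(n_s)
        ind[carriers] = 0.0
        feat_rows.append(
            (gene, gene, decoy_chroms[d % len(decoy_chroms)],
             50_000 + 40_000 * d, "stop")
        )
        feat_vals[gene] = ind
    for d in range(config.n_decoy_cnvs):
        gene = f"DECOY_CNV_{d+1}"
        ratio = rng.normal(0, 0.15, n_s)
        feat_rows.append(
            (gene, gene, decoy_chroms[(d + 3) % len(decoy_chroms)],
             300_000 + 35_000 * d, "cnv")
        )
        feat_vals[gene] = ratio
    truth.planted_features = pd.DataFrame(
        planted_rows,
        columns=["feature_id", "kind", "chrom", "pos", "trait_id", "effect", "carriers"],
    )

    # strain effects, replicate noise, optional rate-efficiency coupling
    strain_eff = rng.normal(0, config.strain_sd, size=(n_s, n_t))
    rho = config.rate_efficiency_coupling
    if rho != 0.0:
        # share a latent component between each environment's rate and
        # efficiency traits so the panel reproduces their observed co-variation
        var_idx = {v: [tindex[trait_id(e, v)] for e in envs] for v in
                   ("rate", "efficiency")}
        latent = rng.normal(0, config.strain_sd, size=(n_s, len(envs)))
        for v in ("rate", "efficiency"):
            idx = var_idx[v]
            strain_eff[:, idx] = (
                np.sqrt(rho) * latent + np.sqrt(1 - rho) * strain_eff[:, idx]
            )
    reps = rng.normal(
        0, config.noise_sd, size=(config.n_replicates, n_s, n_t)
    )
    values = effect + strain_eff + reps.mean(axis=0)
    if config.missing_rate > 0:
        mask = rng.random((n_s, n_t)) < config.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = TraitMatrix(pd.DataFrame(values, index=strains, columns=tids))
    matrix.traits["environment_class"] = [
        classes[e] for e in matrix.traits["environment_id"]
    ]

    ann = StrainAnnotation(
        pd.DataFrame(
            {
                "strain_id": strains,
                "species": config.species,
                "population": pops,
                "source": [
                    ["wild", "clinical", "industrial", "fermentation", "lab"][
                        i % 5
                    ]
                    for i in range(n_s)
                ],
                "mosaic": False,
                "auxotroph": False,
                "clean_lineage": True,
            }
        )
    )

    if feat_rows:
        features = pd.DataFrame(
            feat_rows, columns=["feature_id", "gene", "chrom", "pos", "kind"]
        ).set_index("feature_id")
        fvalues = pd.DataFrame(feat_vals, index=strains)
    else:
        features = pd.DataFrame(
            columns=["gene", "chrom", "pos", "kind"],
            index=pd.Index([], name="feature_id"),
        )
        features["pos"] = features["pos"].astype(int)
        fvalues = pd.DataFrame(index=strains)
    featureset = GenotypeFeatureSet(features, fvalues)
    return matrix, ann, featureset, truth


def simulate_growth_curve(
    lag: float,
    doubling_time: float,
    efficiency: float,
    noise_sd: float = 0.0,
    dt: float = 1.0 / 3.0,
    duration: float = 72.0,
    initial_od: float = 0.005,
    blank: float = 0.0,
    seed: int | np.random.Generator = 0,
    strain_id: str = "sim",
    environment_id: str = "ENV",
    run_id: str = "run1",
    replicate: int = 1,
) -> GrowthCurve:
    """Simulate one well: flat at the inoculum until ``lag``, then logistic.

    The logistic is parameterized so its *analytic* maximal log-slope equals
    ln(2)/doubling_time, the tangent through that point intersects the
    baseline exactly at ``lag``, and the asymptotic rise above the inoculum
    equals ``efficiency``:  with N0 the inoculum and K = N0 + efficiency, the
    intrinsic rate is r = ln(2)/doubling_time / (1 - N0/K) so that
    d ln N/dt |_{t=lag} = r (1 - N0/K) = ln(2)/doubling_time.
    """
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    if lag < 0 or efficiency <= 0 or initial_od <= 0:
        raise ValueError("lag must be >= 0; efficiency and initial_od positive")
    if dt <= 0 or dt >= duration:
        raise ValueError("need 0 < dt < duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    n0 = initial_od
    k = n0 + efficiency
    r = (np.log(2.0) / doubling_time) / (1.0 - n0 / k)
    t = np.maximum(times - lag, 0.0)
    density = k * n0 / (n0 + (k - n0) * np.exp(-r * t))
    od = blank + density
    if noise_sd > 0:
        od = od + rng.normal(0, noise_sd, size=od.shape)
    return GrowthCurve(strain_id, environment_id, run_id, replicate, times, od)


def saturation_duration(
    lag: float,
    doubling_time: float,
    efficiency: float,
    initial_od: float = 0.005,
    margin_doublings: float = 10.0,
) -> float:
    """Cultivation time long enough for the curve to reach stationary phase."""
    k = initial_od + efficiency
    return lag + doubling_time * (np.log2(k / initial_od) + margin_doublings)


def default_marker_map(
    n_chromosomes: int = 16, n_markers: int = 130, spacing_bp: int = 60_000
) -> pd.DataFrame:
    """Evenly laid-out marker map: ~130 markers over 16 chromosomes."""
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    rows = []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        for m in range(per[c]):
            rows.append((f"{chrom}_m{m + 1:02d}", chrom, 30_000 + m * spacing_bp))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])


def simulate_cross(
    n_offspring: int = 96,
    marker_map: pd.DataFrame | None = None,
    causal_marker: str | None = None,
    effect_fraction_of_variance: float = 0.5,
    recomb_p: float = 0.3,
    seed: int = 0,
    cross_id: str = "cross1",
) -> tuple[Cross, GroundTruth]:
    """Simulate a haploid F1 cross: Markov recombination plus one causal QTL.

    Offspring haplotypes are generated per chromosome as a two-state Markov
    chain over the ordered markers (switch probability ``recomb_p`` between
    adjacent markers, parental origin A/B equally likely at the first marker).
    The trait is the causal-marker allele effect plus Gaussian noise scaled so
    the marker explains ``effect_fraction_of_variance`` of the trait variance
    (0 gives a pure-noise trait).
    """
    if not 0 <= effect_fraction_of_variance < 1:
        raise ValueError("effect_fraction_of_variance must be in [0, 1)")
    if marker_map is None:
        marker_map = default_marker_map()
    marker_map = marker_map.reset_index(drop=True)
    if causal_marker is None and effect_fraction_of_variance > 0:
        causal_marker = marker_map["marker_id"].iloc[len(marker_map) // 3]
    if causal_marker is not None and causal_marker not in set(marker_map["marker_id"]):
        raise ValueError(f"causal marker {causal_marker!r} not on the map")
    rng = np.random.default_rng(seed)
    n_m = len(marker_map)
    geno = np.empty((n_offspring, n_m), dtype=float)
    col = 0
    for _, chrom_map in marker_map.groupby("chrom", sort=False):
        m = len(chrom_map)
        h = np.empty((n_offspring, m), dtype=int)
        h[:, 0] = rng.random(n_offspring) < 0.5
        for j in range(1, m):
            switch = rng.random(n_offspring) < recomb_p
            h[:, j] = np.where(switch, 1 - h[:, j - 1], h[:, j - 1])
        geno[:, col : col + m] = h
        col += m
    offspring = [f"{cross_id}_o{i + 1:03d}" for i in range(n_offspring)]
    genotypes = pd.DataFrame(geno, index=offspring, columns=marker_map["marker_id"])

    f = effect_fraction_of_variance
    truth = GroundTruth()
    if f > 0 and causal_marker is not None:
        g = genotypes[causal_marker].to_numpy()
        a = 1.0  # allelic substitution effect; scale sits in the noise
        genetic = a * (g - 0.5)
        noise_var = (a**2 / 4.0) * (1 - f) / f
        trait = genetic + rng.normal(0, np.sqrt(noise_var), n_offspring)
        row = marker_map.set_index("marker_id").loc[causal_marker]
        truth.causal_markers = pd.DataFrame(
            [(cross_id, causal_marker, row["chrom"], int(row["pos"]), f)],
            columns=["cross_id", "marker_id", "chrom", "pos", "effect_fraction"],
        )
    else:
        trait = rng.normal(0, 1.0, n_offspring)
    cross = Cross(
        cross_id=cross_id,
        markers=marker_map,
        genotypes=genotypes,
        trait=pd.Series(trait, index=offspring, name="trait"),
    )
    return cross, truth
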