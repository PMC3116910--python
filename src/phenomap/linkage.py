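"""Single-marker linkage scans on haploid F1 crosses.

A panel of ~96 haploid F1 offspring genotyped at ~130 chromosomal markers is
scanned one marker at a time: the offspring trait is regressed on parental
origin and evidence for linkage is summarized as a LOD score,

    LOD = (n/2) * log10(RSS0 / RSS1),

with RSS0 the residual sum of squares around the grand mean and RSS1 around
the two parental-class means — the Gaussian likelihood-ratio statistic of a
single-marker regression.  Genome-wide significance comes from the standard
permutation device: the trait vector is permuted against the genotypes, the
maximal LOD of each permuted scan is recorded, and the (1 - alpha) quantile of
that null distribution is the threshold.  Runs of contiguous markers above the
threshold, expanded by a configurable flank, are the significant QTL regions
used to cross-check genotype-phenotype associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cross",
    "LodProfile",
    "marker_scan",
    "permutation_threshold",
    "qtl_regions",
]

#: Minimum informative offspring per marker for a LOD to be computed.
MIN_OFFSPRING = 20


@dataclass
class Cross:
    """A haploid F1 cross: marker map, parental-origin genotypes, trait.

    ``markers`` has columns ``marker_id``, ``chrom``, ``pos`` (bp, increasing
    within each chromosome).  ``genotypes`` is offspring x markers with values
    0 (parent A), 1 (parent B) or NaN.  ``trait`` is indexed by offspring id.
    """

    cross_id: str
    markers: pd.DataFrame
    genotypes: pd.DataFrame
    trait: pd.Series

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        for col in ("marker_id", "chrom", "pos"):
            if col not in self.markers.columns:
                raise ValueError(f"marker map missing column {col!r}")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("marker positions must increase within a chromosome")
        if list(self.genotypes.columns) != list(self.markers["marker_id"]):
            raise ValueError("genotype columns must match the marker map order")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("genotypes must be 0 (A), 1 (B) or missing")
        self.trait = self.trait.reindex(self.genotypes.index)

    @property
    def n_offspring(self) -> int:
        return len(self.genotypes.index)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class LodProfile:
    """Per-marker LOD scores of one scan, plus flags for skipped markers."""

    cross_id: str
    table: pd.DataFrame  # marker_id, chrom, pos, lod, n_used, flag
    threshold: float | None = None
    alpha: float | None = None

    @property
    def lod(self) -> pd.Series:
        return self.table.set_index("marker_id")["lod"]

    def peak(self) -> pd.Series:
        return self.table.loc[self.table["lod"].idxmax()]


def _lod_single(y: np.ndarray, g: np.ndarray) -> tuple[float, int, str]:
    """LOD of one marker; y and g aligned, no NaN handling here."""
    n = len(y)
    n1 = int(g.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        return 0.0, n, "monomorphic"
    ybar = y.mean()
    rss0 = float(np.sum((y - ybar) ** 2))
    m1 = y[g == 1].mean()
    m0 = y[g == 0].mean()
    between = n0 * n1 / n * (m1 - m0) ** 2
    rss1 = max(rss0 - between, 0.0)
    if rss1 <= 0 or rss0 <= 0:
        return 0.0 if rss0 <= 0 else np.inf, n, "degenerate"
    return float(n / 2.0 * np.log10(rss0 / rss1)), n, ""


def marker_scan(cross: Cross, min_offspring: int = MIN_OFFSPRING) -> LodProfile:
    """Scan every marker: LOD from single-marker regression on parental origin.

    Offspring with a missing genotype or trait are dropped marker-wise (no
    imputation).  Monomorphic markers and markers with fewer than
    ``min_offspring`` informative offspring get LOD 0 with a flag.
    """
    y_all = cross.trait.to_numpy(dtype=float)
    geno = cross.genotypes.to_numpy(dtype=float)
    rows = []
    for j, mrow in cross.markers.iterrows():
        g = geno[:, j]
        keep = ~(np.isnan(g) | np.isnan(y_all))
        n_used = int(keep.sum())
        if n_used < min_offspring:
            rows.append((mrow["marker_id"], mrow["chrom"], mrow["pos"], 0.0,
                         n_used, "too_few_offspring"))
            continue
        lod, n_used, flag = _lod_single(y_all[keep], g[keep])
        rows.append((mrow["marker_id"], mrow["chrom"], mrow["pos"], lod, n_used, flag))
    table = pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos", "lod", "n_used", "flag"]
    )
    return LodProfile(cross.cross_id, table)


def _max_lod_permutations(cross: Cross, n_perm: int, rng: np.random.Generator,
                          min_offspring: int = MIN_OFFSPRING) -> np.ndarray:
    """Max LOD of each permuted scan, vectorized over permutations."""
    y = cross.trait.to_numpy(dtype=float)
    geno = cross.genotypes.to_numpy(dtype=float)
    n = len(y)
    perms = np.empty((n_perm, n))
    for p in range(n_perm):
        perms[p] = y[rng.permutation(n)]
    max_lod = np.zeros(n_perm)
    for j in range(geno.shape[1]):
        g = geno[:, j]
        keep = ~np.isnan(g)
        yk = perms[:, keep]
        yk = yk[:, ~np.isnan(y[keep])] if np.isnan(y[keep]).any() else yk
        gk = g[keep][~np.isnan(y[keep])] if np.isnan(y[keep]).any() else g[keep]
        nk = yk.shape[1]
        if nk < min_offspring:
            continue
        n1 = gk.sum()
        n0 = nk - n1
        if n0 == 0 or n1 == 0:
            continue
        tot = yk.sum(axis=1)
        s1 = yk[:, gk == 1].sum(axis=1)
        m1 = s1 / n1
        m0 = (tot - s1) / n0
        ybar = tot / nk
        rss0 = np.sum(yk**2, axis=1) - nk * ybar**2
        between = n0 * n1 / nk * (m1 - m0) ** 2
        rss1 = np.maximum(rss0 - between, 1e-300)
        lod = nk / 2.0 * np.log10(np.maximum(rss0, 1e-300) / rss1)
        np.maximum(max_lod, lod, out=max_lod)
    return max_lod


def permutation_threshold(
    cross: Cross,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Genome-wide LOD threshold: (1 - alpha) quantile of permuted max LODs.

    Permuting the trait against the genotypes destroys all linkage while
    preserving the trait distribution and the marker correlation structure, so
    the threshold controls the genome-wide false-positive rate at ``alpha``.
    Seeded and reproducible; requires ``n_perm`` >= 100.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable threshold")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_lod = _max_lod_permutations(cross, n_perm, rng)
    return float(np.quantile(max_lod, 1.0 - alpha))


def qtl_regions(
    profile: LodProfile, threshold: float, flank_bp: int = 25_000
) -> pd.DataFrame:
    """Significant QTL intervals: maximal runs of markers with LOD >= threshold.

    Each run is expanded by ``flank_bp`` on both sides (clipped at 1) and
    reported with its peak (max-LOD) marker.  Columns: ``cross_id``, ``chrom``,
    ``start``, ``end`` (1-based inclusive), ``peak_marker``, ``lod``.  Empty
    output is allowed.
    """
    rows = []
    tab = profile.table
    for chrom, grp in tab.groupby("chrom", sort=False):
        sig = (grp["lod"] >= threshold).to_numpy()
        idx = grp.index.to_numpy()
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            run = grp.loc[idx[i : j + 1]]
            peak = run.loc[run["lod"].idxmax()]
            rows.append(
                (
                    profile.cross_id,
                    chrom,
                    max(1, int(run["pos"].min()) - flank_bp),
                    int(run["pos"].max()) + flank_bp,
                    peak["marker_id"],
                    float(peak["lod"]),
                )
            )
            i = j + 1
    return pd.DataFrame(
        rows, columns=["cross_id", "chrom", "start", "end", "peak_marker", "lod"]
    )
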