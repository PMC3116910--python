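"""Genotype-phenotype association with linkage cross-checking.

Traits are associated with three feature kinds:

* **binary features** (gene presence, premature stop codons): two-tailed
  equal-variance t-test with Bonferroni correction over the features tested
  per trait, *and* a two-sample Kolmogorov-Smirnov test — a candidate must
  pass both (default levels: corrected t p < 0.015, KS p < 0.15);
* **copy-number ratios**: the per-gene log read ratio
  ln((1 + observed) / (1 + expected)) is correlated (Pearson) with the trait,
  with the correlation-test p Bonferroni-corrected over the CNV family;
* candidates are **retained** only when the feature's locus falls inside a
  significant QTL interval of at least one experimental cross
  (:func:`qtl_crosscheck`) — association alone never suffices.

Coordinates are 1-based inclusive in files and converted to half-open
intervals internally through :func:`to_halfopen` (centralized so the
convention is applied exactly once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GenotypeFeatureSet, TraitMatrix

__all__ = [
    "cnv_ratio",
    "binary_feature_assoc",
    "cnv_assoc",
    "bin_summary",
    "qtl_crosscheck",
    "associate_features",
    "to_halfopen",
]

#: Default candidate levels for binary-feature association.
T_ALPHA = 0.015
KS_ALPHA = 0.15


def cnv_ratio(observed_reads, expected_reads):
    """Copy-number read ratio: ln((1 + observed) / (1 + expected)).

    Zero when observed equals expected (including the (0, 0) pseudo-count
    identity); strictly increasing in observed and decreasing in expected.
    Accepts scalars or arrays; negative counts raise.
    """
    obs = np.asarray(observed_reads, dtype=float)
    exp = np.asarray(expected_reads, dtype=float)
    if np.any(obs < 0) or np.any(exp < 0):
        raise ValueError("read counts must be >= 0")
    out = np.log1p(obs) - np.log1p(exp)
    return float(out) if out.ndim == 0 else out


def to_halfopen(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open [start, end)."""
    if end_1based < start_1based:
        raise ValueError("interval end before start")
    return start_1based - 1, end_1based


def binary_feature_assoc(
    feature: pd.Series,
    trait: pd.Series,
    t_alpha: float = T_ALPHA,
    ks_alpha: float = KS_ALPHA,
    bonferroni_m: int = 1,
    equal_var: bool = True,
) -> dict | None:
    """Associate a binary indicator with a trait: t-test AND KS test.

    ``feature`` holds 0/1 indicators over strains (for stop codons: 0 = stop,
    1 = reference), ``trait`` the log2 relative values.  The t p-value is
    Bonferroni-corrected by ``bonferroni_m`` (the number of features tested
    for this trait); candidacy requires corrected t p < ``t_alpha`` *and*
    KS p < ``ks_alpha``.  Monomorphic features (or a class with < 2 values)
    return None.
    """
    df = pd.DataFrame({"g": feature, "y": trait}).dropna()
    y0 = df.loc[df["g"] == 0, "y"].to_numpy()
    y1 = df.loc[df["g"] == 1, "y"].to_numpy()
    if len(y0) < 2 or len(y1) < 2:
        return None
    t_stat, t_p = sps.ttest_ind(y0, y1, equal_var=equal_var)
    if np.isnan(t_p):  # zero variance in both classes
        t_p = 1.0 if y0.mean() == y1.mean() else 0.0
    ks_stat, ks_p = sps.ks_2samp(y0, y1)
    t_p_corr = min(float(t_p) * bonferroni_m, 1.0)
    return {
        "n_class0": len(y0),
        "n_class1": len(y1),
        "mean_class0": float(y0.mean()),
        "mean_class1": float(y1.mean()),
        "t_p": float(t_p),
        "t_p_corrected": t_p_corr,
        "ks_p": float(ks_p),
        "direction": "class1_superior" if y1.mean() > y0.mean() else "class0_superior",
        "candidate": bool(t_p_corr < t_alpha and ks_p < ks_alpha),
    }


def cnv_assoc(
    ratios: pd.Series,
    trait: pd.Series,
    alpha: float = T_ALPHA,
    bonferroni_m: int = 1,
    min_strains: int = 5,
) -> dict | None:
    """Associate a copy-number ratio with a trait by linear correlation.

    Pearson r of ratio vs trait over strains with both values (>= 5 needed);
    the correlation-test p is Bonferroni-corrected by ``bonferroni_m`` and
    candidacy requires corrected p < ``alpha``.  Constant ratios return None.
    """
    df = pd.DataFrame({"x": ratios, "y": trait}).dropna()
    if len(df) < min_strains:
        return None
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return None
    r, p = sps.pearsonr(x, y)
    p_corr = min(float(p) * bonferroni_m, 1.0)
    return {
        "n": len(df),
        "correlation": float(r),
        "p": float(p),
        "p_corrected": p_corr,
        "direction": "dose_superior" if r > 0 else "dose_inferior",
        "candidate": bool(p_corr < alpha),
    }


def bin_summary(ratios: pd.Series, trait: pd.Series, n_bins: int) -> pd.DataFrame:
    """Equal-occupancy bins of strains by copy-number ratio, with trait means.

    Strains are ranked by ratio and split into ``n_bins`` near-equal bins;
    per bin the mean trait and its standard error are reported — the display
    convention for dose-dependent copy-number effects.
    """
    df = pd.DataFrame({"x": ratios, "y": trait}).dropna()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > len(df):
        raise ValueError(f"n_bins ({n_bins}) exceeds strain count ({len(df)})")
    order = df.sort_values(["x", "y"], kind="stable")
    chunks = [order.iloc[idx] for idx in
              np.array_split(np.arange(len(order)), n_bins)]
    rows = []
    for i, chunk in enumerate(chunks, start=1):
        y = chunk["y"].to_numpy()
        se = float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else np.nan
        rows.append(
            (i, len(chunk), float(chunk["x"].mean()), float(y.mean()), se)
        )
    return pd.DataFrame(
        rows, columns=["bin", "n", "mean_ratio", "mean_trait", "se_trait"]
    )


def qtl_crosscheck(
    candidates: pd.DataFrame, qtl_regions: pd.DataFrame
) -> pd.DataFrame:
    """Retain candidates whose locus falls inside a significant QTL region.

    ``candidates`` needs columns ``chrom`` and ``pos`` (1-based);
    ``qtl_regions`` has ``cross_id``, ``chrom``, ``start``, ``end`` (1-based
    inclusive).  A candidate is retained iff its locus lies within >= 1
    interval in >= 1 cross; loci on chromosomes absent from every region map
    are not retained and flagged with a warning.
    """
    out = candidates.copy()
    retained = []
    warnings = []
    region_chroms = set(qtl_regions["chrom"]) if len(qtl_regions) else set()
    for _, row in candidates.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in region_chroms:
            retained.append(False)
            warnings.append("chromosome_without_qtl")
            continue
        regs = qtl_regions[qtl_regions["chrom"] == chrom]
        hit = False
        for _, reg in regs.iterrows():
            start0, end_excl = to_halfopen(int(reg["start"]), int(reg["end"]))
            if start0 <= pos - 1 < end_excl:
                hit = True
                break
        retained.append(hit)
        warnings.append("")
    out["qtl_supported"] = retained
    out["warning"] = warnings
    if "candidate" in out.columns:
        out["retained"] = out["candidate"] & out["qtl_supported"]
    else:
        out["retained"] = out["qtl_supported"]
    return out


def associate_features(
    features: GenotypeFeatureSet,
    matrix: TraitMatrix,
    trait_id: str,
    t_alpha: float = T_ALPHA,
    ks_alpha: float = KS_ALPHA,
    cnv_alpha: float = T_ALPHA,
    family: str = "per_trait",
) -> pd.DataFrame:
    """Test every feature against one trait; Bonferroni family as configured.

    The Bonferroni family is kept separate per test kind — binary features
    (t + KS) form one family and CNV correlations another, since they use
    different statistics.  ``family`` scopes each: ``"per_trait"`` (m =
    testable features of that kind for this trait, the default) or
    ``"per_matrix"`` (m additionally multiplied by the trait count, the
    conservative alternative).  Returns one row per feature with the test
    outcomes, candidacy, and the feature's locus for cross-checking;
    monomorphic features are reported untested.
    """
    if trait_id not in matrix.trait_ids:
        raise ValueError(f"trait {trait_id!r} not in matrix")
    trait = matrix.values[trait_id]
    shared = features.values.index.intersection(trait.index)
    results = {}
    for fid in features.values.columns:
        kind = features.features.loc[fid, "kind"]
        vals = features.values.loc[shared, fid]
        if kind in ("presence", "stop"):
            results[fid] = ("binary", binary_feature_assoc(
                vals, trait.loc[shared], t_alpha, ks_alpha, bonferroni_m=1))
        else:
            results[fid] = ("cnv", cnv_assoc(
                vals, trait.loc[shared], cnv_alpha, bonferroni_m=1))
    n_testable = {
        mode: sum(1 for md, res in results.values() if md == mode and res is not None)
        for mode in ("binary", "cnv")
    }
    scale = 1 if family == "per_trait" else matrix.n_traits
    m_kind = {mode: max(n * scale, 1) for mode, n in n_testable.items()}
    rows = []
    for fid, (mode, res) in results.items():
        frow = features.features.loc[fid]
        m = m_kind[mode]
        base = {
            "feature_id": fid,
            "gene": frow["gene"],
            "kind": frow["kind"],
            "chrom": frow["chrom"],
            "pos": int(frow["pos"]),
            "trait_id": trait_id,
            "bonferroni_m": m,
        }
        if res is None:
            base.update(tested=False, candidate=False, p_corrected=np.nan,
                        ks_p=np.nan, correlation=np.nan, direction="")
        elif mode == "binary":
            p_corr = min(res["t_p"] * m, 1.0)
            base.update(
                tested=True,
                p_corrected=p_corr,
                ks_p=res["ks_p"],
                correlation=np.nan,
                direction=res["direction"],
                candidate=bool(p_corr < t_alpha and res["ks_p"] < ks_alpha),
            )
        else:
            p_corr = min(res["p"] * m, 1.0)
            base.update(
                tested=True,
                p_corrected=p_corr,
                ks_p=np.nan,
                correlation=res["correlation"],
                direction=res["direction"],
                candidate=bool(p_corr < cnv_alpha),
            )
        rows.append(base)
    return pd.DataFrame(rows)
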