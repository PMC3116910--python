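"""Group-level trait statistics.

Everything here operates on a :class:`~phenomap.containers.TraitMatrix` of
log2 relative fitness values and a grouping of strains (clades, species,
populations or source habitats):

* :func:`group_difference_test` — per-trait two-tailed equal-variance t-tests
  between two strain sets with Bonferroni correction (family = tested traits);
* :func:`call_specific_traits` — group-specific traits: each group tested
  against the union of all other groups, Benjamini-Hochberg step-up within
  the group's trait family, calls at q <= FDR;
* :func:`basal_normalize` — subtract each strain's basal-condition value per
  fitness component, isolating stress-specific from general defects;
* :func:`variance_profile` — within-group per-trait variances and their ratio
  between two groups, with leave-one-subpopulation-out robustness;
* :func:`pca_anova` — PCA of the complete-trait matrix followed by one-way
  ANOVA of each leading component against population and source;
* :func:`class_enrichment` — Fisher exact over/under-representation of trait
  calls among environment classes;
* :func:`atypicality_rank` — rank strains by Pearson similarity of their trait
  profile to the group mean profile (rank 1 = least typical);
* :func:`rate_efficiency_structure` — correlation structure between the
  doubling-time and efficiency components across environments.

Missing values are handled pairwise-complete for correlations and variances;
the PCA is complete-case (traits with any missing value are dropped), matching
common practice for ordination.  Degenerate t-tests (all values equal) return
p = 1 rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import TraitMatrix

__all__ = [
    "bh_reject",
    "group_difference_test",
    "call_specific_traits",
    "basal_normalize",
    "variance_profile",
    "pca_anova",
    "class_enrichment",
    "atypicality_rank",
    "rate_efficiency_structure",
]


def bh_reject(p_values, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: reject flags and q-values at level ``q``.

    The single FDR primitive used by every calling operation; rejection at
    level q is equivalent to q-value <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def _nan_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Vectorized two-sample two-tailed t-test per column, NaN-aware.

    Returns (p, direction, n_a, n_b, tested) arrays over columns; direction is
    +1 where group a's mean is higher.  Columns with fewer than two values in
    either group are untested.  All-equal columns get p = 1.
    """
    na = np.sum(~np.isnan(a), axis=0)
    nb = np.sum(~np.isnan(b), axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=0)
        mb = np.nanmean(b, axis=0)
        va = np.nanvar(a, axis=0, ddof=1)
        vb = np.nanvar(b, axis=0, ddof=1)
    tested = (na >= 2) & (nb >= 2)
    p = np.full(a.shape[1], np.nan)
    direction = np.where(ma > mb, 1, -1)
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / np.maximum(df, 1)
        se = np.sqrt(sp2 * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)))
    else:
        se = np.sqrt(va / np.maximum(na, 1) + vb / np.maximum(nb, 1))
        num = (va / np.maximum(na, 1) + vb / np.maximum(nb, 1)) ** 2
        den = (va / np.maximum(na, 1)) ** 2 / np.maximum(na - 1, 1) + (
            vb / np.maximum(nb, 1)
        ) ** 2 / np.maximum(nb - 1, 1)
        df = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    degenerate = tested & (se == 0)
    finite = tested & (se > 0)
    p[finite] = 2.0 * sps.t.sf(np.abs(t[finite]), df[finite])
    # all values identical: no evidence of difference
    p[degenerate & (ma == mb)] = 1.0
    p[degenerate & (ma != mb)] = 0.0
    return p, direction, na, nb, tested


def group_difference_test(
    matrix: TraitMatrix,
    group_a,
    group_b,
    alpha: float = 0.1,
    correction: str = "bonferroni",
    equal_var: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-trait t-tests between two strain sets, with multiplicity correction.

    The correction family is the number of *tested* traits (those with >= 2
    values in each group); skipped traits are counted in the summary.  Returns
    a tidy per-trait table and a summary with the significant fraction and
    direction tallies (which group was superior).
    """
    group_a = [s for s in group_a if s in matrix.strains]
    group_b = [s for s in group_b if s in matrix.strains]
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    a = matrix.values.loc[group_a].to_numpy(dtype=float)
    b = matrix.values.loc[group_b].to_numpy(dtype=float)
    p, direction, na, nb, tested = _nan_ttest(a, b, equal_var=equal_var)
    m = int(tested.sum())
    if correction == "bonferroni":
        p_corr = np.minimum(p * m, 1.0)
    elif correction == "none":
        p_corr = p.copy()
    else:
        raise ValueError(f"unknown correction {correction!r}")
    significant = tested & (p_corr < alpha)
    result = pd.DataFrame(
        {
            "trait_id": matrix.trait_ids,
            "n_a": na,
            "n_b": nb,
            "p": p,
            "p_corrected": p_corr,
            "significant": significant,
            "direction": np.where(significant, np.where(direction > 0, "a", "b"), ""),
            "tested": tested,
        }
    )
    n_sig = int(significant.sum())
    summary = {
        "n_traits": matrix.n_traits,
        "n_tested": m,
        "n_skipped": int(matrix.n_traits - m),
        "n_significant": n_sig,
        "fraction_significant": n_sig / m if m else np.nan,
        "n_superior_a": int((result["direction"] == "a").sum()),
        "n_superior_b": int((result["direction"] == "b").sum()),
        "alpha": alpha,
        "correction": correction,
    }
    return result, summary


def call_specific_traits(
    matrix: TraitMatrix,
    labels: pd.Series,
    fdr: float = 0.02,
    min_group: int = 2,
    equal_var: bool = True,
    fdr_grid=None,
) -> tuple[pd.DataFrame, dict]:
    """Group-specific traits at a given FDR.

    For each group, every trait is t-tested (two-tailed, equal variance)
    between the group's strains and all other labelled strains; the
    Benjamini-Hochberg step-up is applied *within each group's* trait family
    and traits with q <= ``fdr`` are called specific to that group.  Groups
    with fewer than ``min_group`` strains are excluded with a warning entry in
    the summary.  ``labels`` maps strain -> group; strains missing from it are
    ignored (use this to drop mosaics and auxotrophs).

    The summary reports per-group call counts, the union fraction of traits
    specific to at least one group, and (optionally) a sensitivity curve of
    call counts over ``fdr_grid``.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    labels = labels.dropna()
    labels = labels[labels.index.isin(matrix.strains)]
    groups = labels.groupby(labels).groups
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = [g for g, idx in groups.items() if len(idx) < min_group]
    rows = []
    grid_counts: dict = {}
    for g, members in groups.items():
        if g in small:
            continue
        others = labels.index[labels != g]
        a = matrix.values.loc[list(members)].to_numpy(dtype=float)
        b = matrix.values.loc[list(others)].to_numpy(dtype=float)
        p, direction, na, nb, tested = _nan_ttest(a, b, equal_var=equal_var)
        tids = matrix.trait_ids[tested]
        pt = p[tested]
        if len(pt) == 0:
            continue
        reject, q = bh_reject(pt, fdr)
        dirs = np.where(direction[tested] > 0, "superior", "inferior")
        for tid, pv, qv, rej, d in zip(tids, pt, q, reject, dirs):
            rows.append((g, tid, pv, qv, bool(rej), d if rej else ""))
        if fdr_grid is not None:
            grid_counts[g] = {
                level: int(bh_reject(pt, level)[0].sum()) for level in fdr_grid
            }
    calls = pd.DataFrame(
        rows, columns=["group", "trait_id", "p", "q", "significant", "direction"]
    )
    sig = calls[calls["significant"]]
    per_group = sig.groupby("group").size().to_dict()
    union_traits = set(sig["trait_id"])
    summary = {
        "fdr": fdr,
        "n_groups_tested": len(groups) - len(small),
        "excluded_small_groups": small,
        "calls_per_group": {g: per_group.get(g, 0) for g in groups if g not in small},
        "n_union_traits": len(union_traits),
        "union_fraction": len(union_traits) / matrix.n_traits if matrix.n_traits else np.nan,
    }
    if fdr_grid is not None:
        summary["sensitivity_curve"] = grid_counts
    return calls, summary


def basal_normalize(
    matrix: TraitMatrix, basal_environment: str
) -> tuple[TraitMatrix, dict]:
    """Subtract each strain's basal-condition value per fitness component.

    On the log2 scale this expresses every trait relative to the strain's own
    proliferation in the basal environment; the basal trait itself becomes 0.
    Strains missing a basal value get a missing row for that component,
    reported in the returned summary.
    """
    traits = matrix.traits
    if basal_environment not in set(traits["environment_id"]):
        raise ValueError(f"basal environment {basal_environment!r} not in matrix")
    values = matrix.values.copy()
    missing_report = {}
    for variable, var_traits in traits.groupby("variable"):
        basal_tids = var_traits.index[var_traits["environment_id"] == basal_environment]
        if len(basal_tids) == 0:
            raise ValueError(
                f"basal environment {basal_environment!r} missing for variable {variable!r}"
            )
        basal = matrix.values[basal_tids[0]]
        cols = var_traits.index
        values[cols] = values[cols].sub(basal, axis=0)
        missing_report[variable] = basal[basal.isna()].index.tolist()
    return TraitMatrix(values, matrix.traits.copy()), {
        "basal_environment": basal_environment,
        "strains_missing_basal": missing_report,
    }


def variance_profile(
    matrix: TraitMatrix,
    groups: pd.Series,
    pair: tuple[str, str] | None = None,
    leave_one_out: pd.Series | None = None,
) -> dict:
    """Within-group trait variances and the between-pair variance ratio.

    Per trait, the sample variance is computed within each group over
    non-missing values (>= 2 required); the group's trait variability is the
    mean over traits.  With ``pair = (g1, g2)``, the ratio mean_var(g1) /
    mean_var(g2) is reported.  With ``leave_one_out`` (strain -> subpopulation
    within the *first* pair group), the ratio is recomputed excluding one
    subpopulation at a time — a robustness check that the difference is not an
    artifact of population substructure.
    """
    groups = groups[groups.index.isin(matrix.strains)]
    if groups.empty:
        raise ValueError("no labelled strains in matrix")
    per_trait = {}
    mean_var = {}
    for g, members in groups.groupby(groups).groups.items():
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        sub = matrix.values.loc[list(members)]
        counts = sub.notna().sum(axis=0)
        var = sub.var(axis=0, ddof=1)
        var[counts < 2] = np.nan
        per_trait[g] = var
        mean_var[g] = float(var.mean())
    out = {"per_trait_variance": pd.DataFrame(per_trait), "mean_variance": mean_var}
    if pair is not None:
        g1, g2 = pair
        out["variance_ratio"] = mean_var[g1] / mean_var[g2]
        if leave_one_out is not None:
            ratios = {}
            for sub in leave_one_out.dropna().unique():
                drop = set(leave_one_out.index[leave_one_out == sub])
                keep = groups.index[(groups != g1) | (~groups.index.isin(drop))]
                sub_groups = groups.loc[keep]
                sub_res = variance_profile(
                    matrix.subset_strains(keep), sub_groups, pair=pair
                )
                ratios[sub] = sub_res["variance_ratio"]
            out["leave_one_out_ratios"] = ratios
    return out


def _anova_r2_p(component: np.ndarray, labels: pd.Series):
    """One-way ANOVA of a PC against a categorical regressor: R^2 and p."""
    groups = [component[labels.to_numpy() == g] for g in labels.unique()]
    groups = [g for g in groups if len(g) > 0]
    grand = component.mean()
    ss_tot = float(np.sum((component - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    r2 = 1.0 - ss_within / ss_tot if ss_tot > 0 else 0.0
    if len(groups) < 2 or ss_tot == 0:
        return r2, 1.0
    if ss_within == 0:
        return r2, 0.0
    f, p = sps.f_oneway(*groups)
    return r2, float(p)


def pca_anova(
    matrix: TraitMatrix,
    population_labels: pd.Series,
    source_labels: pd.Series,
    n_components: int = 5,
    p_threshold: float = 0.01,
) -> dict:
    """PCA of the complete-trait matrix, then ANOVA of PCs vs population/source.

    Traits with any missing value are removed; strains are centered and scaled
    to unit variance per trait before the decomposition.  For each of the
    first ``n_components`` components the fraction of trait variance it
    explains is reported together with one-way ANOVA R^2 and p against
    population and against source (significance at ``p_threshold``).
    """
    strains = [s for s in matrix.strains if s in population_labels.index and
               s in source_labels.index]
    sub = matrix.values.loc[strains]
    complete = sub.columns[sub.notna().all(axis=0)]
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete traits after removing missing values")
    x = sub[complete].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    x = (x[:, keep] - mu[keep]) / sd[keep]
    rank = min(x.shape[0] - 1, x.shape[1])
    truncated = n_components > rank
    k = min(n_components, rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    pops = population_labels.loc[strains]
    srcs = source_labels.loc[strains]
    rows = []
    for i in range(k):
        pc = scores[:, i]
        r2_pop, p_pop = _anova_r2_p(pc, pops)
        r2_src, p_src = _anova_r2_p(pc, srcs)
        rows.append(
            (
                i + 1,
                float(pca.explained_variance_ratio_[i]),
                r2_pop,
                p_pop,
                p_pop < p_threshold,
                r2_src,
                p_src,
                p_src < p_threshold,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "component",
            "variance_explained",
            "population_r2",
            "population_p",
            "population_significant",
            "source_r2",
            "source_p",
            "source_significant",
        ],
    )
    return {
        "components": table,
        "n_complete_traits": int(len(complete)),
        "n_strains": len(strains),
        "truncated": truncated,
    }


def class_enrichment(
    called_traits,
    all_traits,
    trait_classes: pd.Series,
) -> pd.DataFrame:
    """Fisher exact enrichment of trait calls per environment class.

    For each class, the 2x2 table (called vs not) x (in class vs not) is
    tested two-sided; ``direction`` is "over" when calls are enriched in the
    class (odds ratio > 1) and "under" when depleted.  An empty call set gives
    p = 1 for every class.
    """
    all_traits = pd.Index(all_traits)
    missing = all_traits.difference(trait_classes.index)
    if len(missing):
        raise ValueError(f"traits without a class: {missing.tolist()}")
    called = set(called_traits)
    rows = []
    for cls in trait_classes.loc[all_traits].unique():
        in_class = set(all_traits[trait_classes.loc[all_traits] == cls])
        a = len(called & in_class)
        b = len(called - in_class)
        c = len(in_class - called)
        d = len(all_traits) - a - b - c
        if not called:
            odds, p = np.nan, 1.0
        else:
            odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        expected = len(called) * len(in_class) / len(all_traits)
        rows.append(
            (cls, a, expected, p, "over" if a > expected else "under")
        )
    return pd.DataFrame(
        rows, columns=["environment_class", "n_called", "n_expected", "p", "direction"]
    )


def atypicality_rank(
    matrix: TraitMatrix,
    strains=None,
    exclude_from_mean=(),
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Rank strains by similarity of their trait profile to the mean profile.

    The mean profile is the per-trait mean over ``strains`` excluding
    ``exclude_from_mean`` (auxotrophs); every strain — including excluded
    ones — is then correlated (Pearson, pairwise-complete) with that profile
    and ranked ascending: rank 1 is the *least* similar, i.e. the most
    atypical.  Strains sharing fewer than ``min_overlap`` complete traits with
    the mean are dropped and reported with NaN correlation.  Ties rank stably
    by strain id.
    """
    if strains is None:
        strains = matrix.strains
    strains = [s for s in strains if s in matrix.strains]
    if len(strains) < 3:
        raise ValueError("need >= 3 strains")
    mean_members = [s for s in strains if s not in set(exclude_from_mean)]
    mean_profile = matrix.values.loc[mean_members].mean(axis=0)
    rows = []
    for s in strains:
        prof = matrix.values.loc[s]
        ok = prof.notna() & mean_profile.notna()
        if int(ok.sum()) < min_overlap:
            rows.append((s, np.nan, int(ok.sum())))
            continue
        r = float(np.corrcoef(prof[ok], mean_profile[ok])[0, 1])
        rows.append((s, r, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["strain_id", "correlation", "n_traits"])
    ranked = out.dropna(subset=["correlation"]).sort_values(
        ["correlation", "strain_id"], kind="stable"
    )
    out["rank"] = np.nan
    out.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)
    return out.sort_values(["rank"], na_position="last").reset_index(drop=True)


def rate_efficiency_structure(matrix: TraitMatrix, r_cutoff: float = 0.5) -> dict:
    """Correlation structure between fitness components across environments.

    For every environment with both a rate and an efficiency trait, strain
    values are paired (pairwise-complete).  Reported: the overall Pearson r
    pooling all pairs, per-environment r (>= 3 pairs), the fraction of
    environments with r > ``r_cutoff``, the per-environment slope of rate
    against the square root of efficiency (0.5 x the log2 efficiency value on
    this scale), and the pooled lag-rate / lag-efficiency correlations, which
    probe whether the adaptation time is physiologically distinct.
    """
    traits = matrix.traits
    envs = traits["environment_id"].unique()
    by_env = {
        (row["environment_id"], row["variable"]): tid
        for tid, row in traits.iterrows()
    }
    pooled = {("rate", "efficiency"): ([], []), ("lag", "rate"): ([], []),
              ("lag", "efficiency"): ([], [])}
    rows = []
    for env in envs:
        pairs = {}
        for v in ("lag", "rate", "efficiency"):
            tid = by_env.get((env, v))
            if tid is not None:
                pairs[v] = matrix.values[tid]
        for (v1, v2), (acc1, acc2) in pooled.items():
            if v1 in pairs and v2 in pairs:
                ok = pairs[v1].notna() & pairs[v2].notna()
                acc1.extend(pairs[v1][ok])
                acc2.extend(pairs[v2][ok])
        if "rate" in pairs and "efficiency" in pairs:
            ok = pairs["rate"].notna() & pairs["efficiency"].notna()
            n = int(ok.sum())
            if n >= 3:
                x = pairs["rate"][ok].to_numpy()
                y = pairs["efficiency"][ok].to_numpy()
                if x.std() > 0 and y.std() > 0:
                    r = float(np.corrcoef(x, y)[0, 1])
                    slope = float(np.polyfit(0.5 * y, x, 1)[0])
                else:
                    r, slope = np.nan, np.nan
            else:
                r, slope = np.nan, np.nan
            rows.append((env, r, slope, n))
    per_env = pd.DataFrame(
        rows, columns=["environment_id", "r", "slope_vs_sqrt_efficiency", "n_pairs"]
    )

    def _pooled_r(key):
        x, y = pooled[key]
        if len(x) < 3:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    valid = per_env["r"].dropna()
    return {
        "overall_r": _pooled_r(("rate", "efficiency")),
        "per_environment": per_env,
        "fraction_env_r_above_cutoff": float((valid > r_cutoff).mean())
        if len(valid)
        else np.nan,
        "r_cutoff": r_cutoff,
        "lag_rate_r": _pooled_r(("lag", "rate")),
        "lag_efficiency_r": _pooled_r(("lag", "efficiency")),
    }
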