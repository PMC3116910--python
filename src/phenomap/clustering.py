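"""Hierarchical clustering of trait profiles and distance concordance.

Strain trait profiles are compared with a centered Pearson metric: values are
centered per trait (column) over strains, and the distance between two strains
is 1 - r over their pairwise-complete traits, so distances live in [0, 2]
(0 = identical profile shape, 2 = perfectly anti-correlated).  Trees are built
by average linkage (UPGMA-style group averages); strains are pre-sorted
lexicographically so the result does not depend on input order.  Concordance
between a phenotypic and a genetic distance structure is the Pearson
correlation over the upper-triangle pair vector of the shared strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import TraitMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "centered_pearson_distance",
    "average_linkage",
    "distance_concordance",
]


@dataclass
class DistanceMatrix:
    """Symmetric strain-strain distances with a zero diagonal."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if list(t.index) != list(t.columns):
            raise ValueError("distance matrix index and columns must match")
        vals = t.to_numpy(dtype=float)
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12, equal_nan=False):
            raise ValueError("distance matrix diagonal must be zero")
        finite = ~np.isnan(vals)
        if not np.allclose(
            np.where(finite, vals, 0.0), np.where(finite.T, vals.T, 0.0), atol=1e-10
        ):
            raise ValueError("distance matrix must be symmetric")

    @property
    def strains(self) -> pd.Index:
        return self.table.index

    @property
    def is_complete(self) -> bool:
        return not self.table.isna().any().any()

    def shared_with(self, other: "DistanceMatrix") -> list:
        return sorted(set(self.strains) & set(other.strains))

    def pair_vector(self, strains=None) -> np.ndarray:
        """Upper-triangle distances over ``strains`` (default: all), row order."""
        ids = list(self.strains) if strains is None else list(strains)
        sub = self.table.loc[ids, ids].to_numpy(dtype=float)
        iu = np.triu_indices(len(ids), k=1)
        return sub[iu]


def centered_pearson_distance(
    matrix: TraitMatrix, min_overlap: int = 10
) -> DistanceMatrix:
    """1 - Pearson r over pairwise-complete, per-trait-centered values.

    A strain pair sharing fewer than ``min_overlap`` complete traits gets a
    missing distance (tree construction then fails loudly downstream).
    """
    centered = matrix.values - matrix.values.mean(axis=0)
    x = centered.to_numpy(dtype=float)
    strains = list(matrix.strains)
    n = len(strains)
    d = np.zeros((n, n))
    ok = ~np.isnan(x)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            if int(shared.sum()) < min_overlap:
                d[i, j] = d[j, i] = np.nan
                continue
            xi = x[i, shared]
            xj = x[j, shared]
            si = xi.std()
            sj = xj.std()
            if si == 0 or sj == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            dist = min(max(1.0 - r, 0.0), 2.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(pd.DataFrame(d, index=strains, columns=strains))


@dataclass
class Dendrogram:
    """Binary merge tree from average linkage over a distance matrix."""

    leaves: list
    linkage: np.ndarray  # scipy linkage matrix over ``leaves`` order

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")
        if self.linkage.shape[0] != len(self.leaves) - 1:
            raise ValueError("linkage does not cover all leaves")

    def leaf_order(self) -> list:
        """Leaves in dendrogram display order (heat-map row ordering)."""
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaves[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Flat clustering into k groups; strain -> cluster label."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaves)

    def to_newick(self) -> str:
        """Newick string with merge heights as cumulative branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.leaves[node.id]
            left = walk(node.left)
            right = walk(node.right)
            bl_left = node.dist - node.left.dist
            bl_right = node.dist - node.right.dist
            return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"

        return walk(tree) + ";"


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA-style agglomeration of a complete distance matrix.

    Strains are sorted lexicographically before linkage so that equal-distance
    ties break identically regardless of input order.
    """
    if not dist.is_complete:
        bad = dist.table.isna().any()
        raise ValueError(
            f"distance matrix has missing entries (e.g. strains "
            f"{dist.table.columns[bad].tolist()[:5]}); cannot build tree"
        )
    order = sorted(dist.strains)
    sub = dist.table.loc[order, order].to_numpy(dtype=float)
    condensed = squareform(sub, checks=False)
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(order, z)


def distance_concordance(
    pheno: DistanceMatrix,
    geno: DistanceMatrix,
    exclude=(),
) -> dict:
    """Pearson correlation between two distance structures over shared pairs.

    ``exclude`` removes strains (e.g. mosaics, whose genetic distances have no
    simple evolutionary meaning) before pairing.  Requires >= 4 shared strains.
    """
    shared = [s for s in pheno.shared_with(geno) if s not in set(exclude)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared strains, got {len(shared)}")
    pv = pheno.pair_vector(shared)
    gv = geno.pair_vector(shared)
    ok = ~(np.isnan(pv) | np.isnan(gv))
    if ok.sum() < 3:
        raise ValueError("too few complete distance pairs")
    r = float(np.corrcoef(pv[ok], gv[ok])[0, 1])
    return {"r": r, "n_strains": len(shared), "n_pairs": int(ok.sum())}
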