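"""All-pairs correlation structure of plasma and urine variables.

Pearson correlations over all pairs of log-transformed concentration
variables (pairwise-complete for missing samples), presented as a
clustered matrix: rows and columns are ordered by hierarchical clustering
on the distance ``1 - r`` (signed, average linkage), either over all
variables jointly or independently within the plasma and urine blocks.
The lower triangle can be masked to show only strong correlations
(|r| > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform

__all__ = ["CorrelationMatrix", "all_pairs_pearson", "cluster_order",
           "threshold_mask", "combine_materials"]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with material tags, cluster ordering and an
    optional lower-triangle threshold mask."""

    r: pd.DataFrame
    materials: dict[str, str]
    n: pd.DataFrame | None = None
    ordering: list | None = None
    linkage: np.ndarray | None = None
    mask: pd.DataFrame | None = None
    excluded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        M = self.r.to_numpy(dtype=float)
        if not np.allclose(M, M.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0, atol=1e-9):
            raise ValueError("correlation matrix must have a unit diagonal")

    def ordered(self) -> pd.DataFrame:
        if self.ordering is None:
            return self.r
        return self.r.loc[self.ordering, self.ordering]

    def top_clusters(self, k: int = 2) -> dict[str, int]:
        """Cut the dendrogram into ``k`` flat clusters (variable -> id)."""
        if self.linkage is None:
            raise ValueError("no clustering computed; call cluster_order first")
        ids = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.r.columns, ids))


def combine_materials(plasma: pd.DataFrame, urine: pd.DataFrame,
                      on: str = "index") -> tuple[pd.DataFrame, dict[str, str]]:
    """Join matched plasma and urine log-concentration frames on their
    index, prefixing variable names with the material tag."""
    p = plasma.add_prefix("plasma:")
    u = urine.add_prefix("urine:")
    joined = p.join(u, how="outer")
    materials = {c: ("plasma" if c.startswith("plasma:") else "urine")
                 for c in joined.columns}
    return joined, materials


def all_pairs_pearson(variables: pd.DataFrame,
                      materials: dict[str, str] | None = None,
                      min_pairs: int = 5) -> CorrelationMatrix:
    """Full symmetric Pearson matrix over all variable pairs.

    Missing samples are handled pairwise-complete; the per-cell number of
    complete pairs is recorded.  Variables with fewer than ``min_pairs``
    complete pairs against the rest are excluded (and listed).
    """
    if materials is None:
        materials = {c: "plasma" for c in variables.columns}
    counts = variables.notna().astype(int)
    n = counts.T @ counts
    enough = (n.to_numpy() >= min_pairs)
    np.fill_diagonal(enough, True)
    # zero-variance variables (e.g. creatinine after normalization) have no
    # defined correlation and are excluded outright; variables with too few
    # complete pairs are dropped greedily (worst offender first) so that a
    # single sparse variable does not take the whole panel with it
    with np.errstate(invalid="ignore"):
        ok_var = variables.std(ddof=0).to_numpy() > 0
    while True:
        bad_counts = (~enough[np.ix_(ok_var, ok_var)]).sum(axis=1)
        if bad_counts.size == 0 or bad_counts.max() == 0:
            break
        worst_local = int(np.argmax(bad_counts))
        worst_global = np.flatnonzero(ok_var)[worst_local]
        ok_var[worst_global] = False
    excluded = [c for c, k in zip(variables.columns, ok_var) if not k]
    keep = [c for c, k in zip(variables.columns, ok_var) if k]
    if len(keep) < 2:
        raise ValueError("fewer than two variables with enough complete pairs")
    sub = variables[keep]
    r = sub.corr(method="pearson", min_periods=min_pairs)
    # exactly symmetrize (pandas is symmetric up to float noise)
    M = r.to_numpy()
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 1.0)
    r = pd.DataFrame(M, index=r.index, columns=r.columns)
    return CorrelationMatrix(r=r, materials={c: materials[c] for c in keep},
                             n=n.loc[keep, keep], excluded=excluded)


def _leaf_order(r: pd.DataFrame) -> tuple[list, np.ndarray]:
    d = 1.0 - r.to_numpy()
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    Z = average(squareform(d, checks=False))
    leaves = leaves_list(Z)
    return [r.columns[i] for i in leaves], Z


def cluster_order(m: CorrelationMatrix, scope: str = "all") -> CorrelationMatrix:
    """Attach a hierarchical-cluster leaf ordering to the matrix.

    ``scope='all'`` clusters all variables jointly; ``scope='per-material'``
    clusters the plasma and urine blocks independently and concatenates
    their orderings (plasma first).  Values are never altered, only the
    ordering.
    """
    if scope == "all":
        ordering, Z = _leaf_order(m.r)
    elif scope == "per-material":
        ordering = []
        Z = None
        for material in ("plasma", "urine"):
            cols = [c for c, mat in m.materials.items() if mat == material]
            if len(cols) >= 2:
                sub_order, _ = _leaf_order(m.r.loc[cols, cols])
                ordering.extend(sub_order)
            else:
                ordering.extend(cols)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return CorrelationMatrix(r=m.r, materials=m.materials, n=m.n,
                             ordering=ordering, linkage=Z, mask=m.mask,
                             excluded=m.excluded)


def threshold_mask(m: CorrelationMatrix, cutoff: float = 0.5,
                   region: str = "lower") -> CorrelationMatrix:
    """Mask weak correlations (|r| <= cutoff) in one triangle only.

    The mask is boolean (True = hidden); the diagonal and the other
    triangle are untouched.
    """
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [0, 1)")
    order = m.ordering if m.ordering is not None else list(m.r.columns)
    R = m.r.loc[order, order].to_numpy()
    mask = np.zeros_like(R, dtype=bool)
    tri = np.tril_indices_from(R, k=-1) if region == "lower" \
        else np.triu_indices_from(R, k=1)
    weak = np.abs(R) <= cutoff
    mask[tri] = weak[tri]
    mask_df = pd.DataFrame(mask, index=order, columns=order)
    return CorrelationMatrix(r=m.r, materials=m.materials, n=m.n,
                             ordering=m.ordering, linkage=m.linkage,
                             mask=mask_df, excluded=m.excluded)


def to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch
    lengths (merge-height differences)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            clean = str(labels[i])
            for ch in " ,:;()[]":
                clean = clean.replace(ch, "_")
            return clean
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        h = float(Z[i - n, 2])
        heights[i] = h
        left = f"{node(a)}:{max(h - heights[a], 0.0):.6g}"
        right = f"{node(b)}:{max(h - heights[b], 0.0):.6g}"
        return f"({left},{right})"

    return node(2 * n - 2) + ";"
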