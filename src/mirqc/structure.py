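"""Sample-structure analysis: correlation distance, clustering, PCA.

Samples (conditions) are compared over their microRNA Ct profiles with the
one-minus-Pearson correlation distance ``d = 1 - r`` (0 for identical
profiles up to an affine increasing rescaling, 2 for perfect
anticorrelation).  Agglomerative hierarchical clustering (complete linkage
by default) and principal component analysis on the per-assay-centred
matrix reveal whether samples group by biology (disease state) or by
technical handling (FFPE vs fresh-frozen, extraction chemistry).
Analyses can be restricted to one abundance stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DomainError, ValidationError
from .io import CtMatrix
from .strata import StratumCutoffs, assign_strata

__all__ = [
    "Dendrogram",
    "PCAResult",
    "correlation_distance",
    "hierarchical_cluster",
    "pca",
]

Linkage = Literal["complete", "average", "single"]


def _profile_matrix(
    matrix: CtMatrix,
    conditions: Sequence[str] | None,
    stratum_filter: str | None,
    cutoffs: StratumCutoffs,
    include_censored: bool,
    min_assays: int,
) -> pd.DataFrame:
    conds = list(conditions) if conditions is not None else matrix.condition_ids
    if len(conds) < 2:
        raise ValidationError("need at least two conditions")
    vals = matrix.mir_values()[conds]
    if not include_censored:
        vals = vals.mask(matrix.mir_censored()[conds])
    if stratum_filter is not None:
        strata = assign_strata(vals.mean(axis=1), cutoffs)
        vals = vals.loc[strata == str(stratum_filter)]
    vals = vals.dropna(axis=0, how="any")
    if len(vals) < min_assays:
        raise ValidationError(
            f"only {len(vals)} complete assays available (need >= {min_assays})"
        )
    return vals


def correlation_distance(
    matrix: CtMatrix,
    conditions: Sequence[str] | None = None,
    stratum_filter: str | None = None,
    cutoffs: StratumCutoffs = StratumCutoffs(),
    include_censored: bool = True,
) -> pd.DataFrame:
    """Pairwise one-minus-Pearson distance between condition profiles.

    Censored wells enter at 40 by default so every condition shares the
    same assay support; ``stratum_filter`` restricts to assays whose mean
    Ct across the chosen conditions falls in that stratum.
    """
    vals = _profile_matrix(
        matrix, conditions, stratum_filter, cutoffs, include_censored, 3
    )
    arr = vals.to_numpy(float)
    if (arr.std(axis=0) == 0).any():
        raise DomainError("a condition has zero variance across assays")
    r = np.corrcoef(arr.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=vals.columns, columns=vals.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over conditions.

    ``linkage_matrix`` is the standard 4-column merge encoding (pair
    merged, merge height, cluster size); ``labels`` are condition ids in
    input order.  SciPy's agglomerative implementation is deterministic,
    breaking ties by the lowest condensed-distance index.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..k) from cutting the tree at k clusters."""
        flat = hierarchy.fcluster(
            self.linkage_matrix, t=n_clusters, criterion="maxclust"
        )
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        if len(self.labels) == 1:
            return f"{self.labels[0]}:0;"
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hierarchical_cluster(
    distance: pd.DataFrame, linkage: Linkage = "complete"
) -> Dendrogram:
    """Cluster conditions from a square symmetric distance matrix."""
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    arr = distance.to_numpy(float)
    if arr.shape[0] != arr.shape[1]:
        raise ValidationError("distance matrix must be square")
    if arr.shape[0] == 1:
        return Dendrogram(
            linkage_matrix=np.empty((0, 4)),
            labels=list(distance.index),
            method=linkage,
        )
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    condensed = squareform(arr, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(
        linkage_matrix=Z, labels=list(distance.index), method=linkage
    )


@dataclass
class PCAResult:
    """Principal components of conditions over their (centred) Ct profiles.

    ``scores``: conditions x components frame of coordinates.
    ``variance_ratio``: fraction of total variance per component (sums to 1
    at full rank).  Components are sign-fixed so the first nonzero loading
    is positive, making results reproducible across runs and BLAS builds.
    """

    scores: pd.DataFrame
    variance_ratio: np.ndarray
    loadings: pd.DataFrame


def pca(
    matrix: CtMatrix,
    conditions: Sequence[str] | None = None,
    n_components: int = 2,
    stratum_filter: str | None = None,
    cutoffs: StratumCutoffs = StratumCutoffs(),
    include_censored: bool = True,
) -> PCAResult:
    """PCA of conditions over per-assay-centred Ct profiles (via SVD).

    Each assay is centred across conditions, so a Ct offset common to all
    samples carries no weight; what remains is between-sample structure.
    """
    vals = _profile_matrix(
        matrix, conditions, stratum_filter, cutoffs, include_censored, 3
    )
    X = vals.to_numpy(float).T  # conditions x assays
    n_cond, n_assay = X.shape
    max_rank = min(n_cond - 1, n_assay)
    if not 1 <= n_components <= max_rank:
        raise ValidationError(
            f"n_components must be in [1, {max_rank}] for {n_cond} conditions"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise DomainError("zero-variance input: all condition profiles identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: first nonzero loading of each component positive
    for k in range(len(s)):
        row = Vt[k]
        nz = np.nonzero(np.abs(row) > 1e-12)[0]
        if nz.size and row[nz[0]] < 0:
            Vt[k] = -row
            U[:, k] = -U[:, k]
    var = s**2
    total = var.sum()
    scores = U[:, :n_components] * s[:n_components]
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=vals.columns, columns=comp_names),
        variance_ratio=var[:n_components] / total,
        loadings=pd.DataFrame(
            Vt[:n_components].T, index=vals.index, columns=comp_names
        ),
    )
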