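"""Signature validation and interpretation.

Variance-stabilised expression (``log2(K/s + 1)``), PCA, unsupervised
hierarchical clustering (default 1 - Pearson correlation, average linkage),
a cross-model preservation score for the interaction signature, and generic
hypergeometric over-representation analysis against user-supplied GMT gene
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix
from .de import InteractionSignature, adjust_bh, size_factors_median_of_ratios
from .errors import ConfigError, CoverageError, ValidationError

__all__ = [
    "vst",
    "pca",
    "ClusterResult",
    "hierarchical_cluster",
    "preservation_score",
    "PreservationResult",
    "GeneSetCollection",
    "ora_hypergeometric",
]


def vst(matrix: ExpressionMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Shifted-log variance-stabilising transform: ``log2(K_gj / s_j + 1)``."""
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(matrix)
    s = size_factors.reindex(matrix.sample_ids).to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2(matrix.counts.to_numpy(dtype=float) / s + 1.0),
        index=matrix.gene_ids,
        columns=matrix.sample_ids,
    )


def pca(data: pd.DataFrame, n_components: int = 2):
    """PCA over samples (columns of a genes x samples table).

    Returns (scores, loadings, variance_explained); features are centred
    internally, components ordered by decreasing variance.
    """
    X = data.to_numpy(dtype=float).T  # samples x genes
    if n_components > min(X.shape):
        raise ConfigError(
            f"n_components={n_components} exceeds min(n_samples, n_genes)={min(X.shape)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    scores_df = pd.DataFrame(
        scores, index=data.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    loadings = pd.DataFrame(
        model.components_.T, index=data.index, columns=scores_df.columns
    )
    return scores_df, loadings, model.explained_variance_ratio_.copy()


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    items: list[str]
    distance: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.items, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.items[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return walk(tree) + ";"


def hierarchical_cluster(
    data: pd.DataFrame,
    distance: str = "correlation",
    method: str = "average",
    axis: str = "columns",
) -> ClusterResult:
    """Agglomerative clustering of samples (columns) or genes (rows).

    Default distance is ``1 - Pearson r``; constant items are rejected by
    name since their correlation is undefined.
    """
    X = data.to_numpy(dtype=float)
    items = list(data.columns) if axis == "columns" else list(data.index)
    if axis == "columns":
        X = X.T
    if len(items) < 2:
        raise ValidationError("need at least 2 items to cluster")
    if distance == "correlation":
        const = np.flatnonzero(X.std(axis=1) == 0)
        if const.size:
            raise ValidationError(
                f"constant item under correlation distance: {items[const[0]]!r}"
            )
    D = pdist(X, metric=distance)
    Z = hierarchy.linkage(D, method=method)
    return ClusterResult(Z, items, distance, method)


@dataclass
class PreservationResult:
    score: float
    groups_separate: bool
    n_genes: int


def preservation_score(
    signature: InteractionSignature,
    external: ExpressionMatrix,
    target_group: str,
    reference_group: str,
    group_col: str = "role",
) -> PreservationResult:
    """How well the signature's directions replicate in an external cohort.

    Fraction of up-signature genes whose mean vst expression in the target
    group exceeds the reference group (and symmetrically for down genes),
    averaged over all measured signature genes; plus an indicator of whether
    a k=2 cut of the sample dendrogram on signature genes separates the two
    groups.
    """
    for g in (target_group, reference_group):
        if g not in set(external.samples[group_col]):
            raise ValidationError(f"group {g!r} absent from external metadata")
    genes = [g for g in signature.genes if g in external.gene_ids]
    if not genes:
        raise CoverageError("no signature gene measured in the external matrix")
    expr = vst(external).loc[genes]
    t_cols = external.samples.index[external.samples[group_col] == target_group]
    r_cols = external.samples.index[external.samples[group_col] == reference_group]
    mean_t = expr[list(t_cols)].mean(axis=1)
    mean_r = expr[list(r_cols)].mean(axis=1)
    hits = 0
    for g in signature.up_genes:
        if g in expr.index and mean_t[g] > mean_r[g]:
            hits += 1
    for g in signature.down_genes:
        if g in expr.index and mean_t[g] < mean_r[g]:
            hits += 1
    score = hits / len(genes)

    cols = list(t_cols) + list(r_cols)
    groups_separate = False
    sub = expr[cols]
    if len(cols) >= 2 and sub.to_numpy().std(axis=0).min() > 0:
        labels = hierarchical_cluster(sub).cut(2)
        t_labels = set(labels[list(t_cols)])
        r_labels = set(labels[list(r_cols)])
        groups_separate = len(t_labels) == 1 and len(r_labels) == 1 and t_labels != r_labels
    return PreservationResult(score, groups_separate, len(genes))


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a GMT file)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def validate(self) -> "GeneSetCollection":
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        return self


def ora_hypergeometric(
    query,
    universe,
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Each set is intersected with the universe before testing; with universe
    size M, intersected set size K, query size n and overlap k, the p-value
    is P(X >= k) for X hypergeometric(M, K, n). BH adjustment across the
    collection; rows ordered by adjusted then raw p.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ConfigError("query and universe must be non-empty")
    if not query <= universe:
        raise ConfigError("query must be a subset of the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        K = len(inset)
        overlap = sorted(query & inset)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {"set": name, "overlap": k, "set_size": K, "query_size": n,
             "universe_size": M, "pvalue": min(p, 1.0),
             "genes": ";".join(overlap),
             "description": collection.descriptions.get(name, "")}
        )
    table = pd.DataFrame(rows)
    table["padj"] = adjust_bh(table["pvalue"].to_numpy())
    return table.sort_values(["padj", "pvalue"], kind="mergesort").reset_index(drop=True)
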