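"""Unsupervised structure: t-SNE embeddings, k-means heatmap ordering and
hierarchical ordering of annotated metabolites.

All three operations are deterministic for a fixed seed. Inputs are
z-scored per feature within the displayed scope (log intensities for the
embedding), since raw LC-MS intensities span orders of magnitude.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .model import FeatureTable, ORGANS


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mean) / sd


def _scope_table(table: FeatureTable, scope: str) -> FeatureTable:
    if scope == "all":
        return table.drop_qc()
    if scope in ORGANS:
        return table.restrict_organ(scope)
    raise ValueError(f"unknown scope {scope!r}")


def tsne_embed(
    table: FeatureTable,
    scope: str = "all",
    perplexity: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of the biological injections in scope.

    Features are log-transformed and z-scored before embedding. Requires
    ``n_samples >= 3 * perplexity``; the error message reports the feasible
    maximum. Returns a DataFrame indexed by injection_id with columns
    ``x``, ``y``, ``scope``.
    """
    sub = _scope_table(table, scope)
    n = sub.n_injections
    if n < 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples; "
            f"feasible maximum is {n / 3:.1f}"
        )
    mat = sub.intensities.to_numpy(float)
    if np.isnan(mat).any():
        raise ValueError("tsne_embed expects a complete (imputed) table")
    X = _zscore_rows(np.log(np.maximum(mat, 1e-12))).T  # samples x features
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
        method="exact",  # exact gradients: sample counts here are tens
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = tsne.fit_transform(X)
    return pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "scope": scope},
        index=sub.intensities.columns.rename("injection_id"),
    )


def kmeans_rows(
    table: FeatureTable,
    organ: str,
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """k-means feature clustering within one organ, for heatmap row order.

    Profiles are z-scored per feature within the organ. Rows are ordered by
    cluster (clusters sorted by their mean profile's first principal
    direction of appearance, i.e. cluster index) and, within a cluster, by
    decreasing correlation with the cluster's mean profile. Returns a
    DataFrame indexed by feature_id with ``organ``, ``cluster_id`` (1..k)
    and ``row_order`` (a permutation within the organ).
    """
    sub = table.restrict_organ(organ) if organ in ORGANS else table.drop_qc()
    mat = sub.intensities.to_numpy(float)
    if np.isnan(mat).any():
        raise ValueError("kmeans_rows expects a complete (imputed) table")
    if k > mat.shape[0]:
        raise ValueError(f"k={k} exceeds the {mat.shape[0]} available features")
    Z = _zscore_rows(np.log(np.maximum(mat, 1e-12)))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)

    order_key = np.empty(len(labels), dtype=float)
    for c in range(k):
        members = np.where(labels == c)[0]
        centroid = Z[members].mean(axis=0)
        csd = centroid.std()
        for m in members:
            if csd == 0 or Z[m].std() == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(Z[m], centroid)[0, 1])
            order_key[m] = c * 10.0 - corr  # cluster block, best-correlated first
    row_order = np.empty(len(labels), dtype=int)
    row_order[np.argsort(order_key, kind="stable")] = np.arange(len(labels))
    return pd.DataFrame(
        {
            "organ": organ,
            "cluster_id": labels + 1,
            "row_order": row_order,
        },
        index=sub.intensities.index.rename("feature_id"),
    )


def hierarchical_order(table: FeatureTable) -> list[str]:
    """Average-linkage leaf order of features on correlation distance.

    Intended for the annotated-metabolite heatmap. Distance is 1 - Pearson r
    between feature profiles over biological injections. Constant (zero
    variance) features have undefined correlation; they are placed last and
    a warning is emitted. Deterministic: scipy's linkage and leaf traversal
    are tie-broken by index.
    """
    sub = table.drop_qc()
    if sub.n_features < 2:
        raise ValueError("hierarchical_order needs >= 2 features")
    mat = np.log(np.maximum(sub.intensities.to_numpy(float), 1e-12))
    ids = list(sub.intensities.index)
    constant = np.ptp(mat, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) placed last "
            "(correlation undefined)",
            stacklevel=2,
        )
    keep = np.where(~constant)[0]
    if len(keep) < 2:
        return [ids[i] for i in keep] + [ids[i] for i in np.where(constant)[0]]
    corr = np.corrcoef(mat[keep])
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(keep), k=1)]
    link = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(link)
    ordered = [ids[keep[i]] for i in leaves]
    ordered += [ids[i] for i in np.where(constant)[0]]
    return ordered
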