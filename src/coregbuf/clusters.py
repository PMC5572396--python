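"""k-means regulation groups per expression layer.

Genes are clustered by their expression profiles across samples (k = 4
for mRNA, k = 3 for protein in the reference analysis, chosen as the
smallest k whose clusters explain at least half the total variance).
Cluster labels are canonicalised by decreasing cluster size so runs are
reproducible and nameable (T1..Tk / P1..Pk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import ConfigError, DataError, ExpressionMatrix
from .coreg import pairwise_pcc


@dataclass
class RegulationClustering:
    layer: str
    k: int
    assignment: pd.Series  # gene -> cluster id (0-based, size-ordered)
    centroids: pd.DataFrame  # cluster x sample
    variance_explained: float
    seed: int


def _prepare(m: ExpressionMatrix, impute: bool) -> pd.DataFrame:
    """Missing values are imputed to 0 (= unchanged vs reference) or the
    genes dropped, flag-controlled."""
    vals = m.values
    if impute:
        return vals.fillna(0.0)
    return vals.dropna(axis=0)


def fit_regulation_clusters(
    m: ExpressionMatrix,
    k: int,
    n_starts: int = 5,
    seed: int = 0,
    impute_missing: bool = True,
) -> RegulationClustering:
    """Best-of-``n_starts`` Lloyd k-means on gene expression profiles.

    Deterministic given the seed. variance_explained is
    1 − within-cluster SS / total SS.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    X = _prepare(m, impute_missing)
    if k >= len(X):
        raise ConfigError(f"k={k} must be < number of genes ({len(X)})")
    arr = X.to_numpy(float)
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_starts,
        max_iter=300,
        algorithm="lloyd",
        random_state=seed % (2**32),
    ).fit(arr)
    tot_ss = float(((arr - arr.mean(axis=0)) ** 2).sum())
    ve = 1.0 - km.inertia_ / tot_ss if tot_ss > 0 else 0.0
    # canonical labels: decreasing cluster size, ties broken by original id
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(k), columns=X.columns
    )
    return RegulationClustering(
        layer=m.layer,
        k=k,
        assignment=pd.Series(labels, index=X.index, name="cluster"),
        centroids=centroids,
        variance_explained=float(np.clip(ve, 0.0, 1.0)),
        seed=seed,
    )


def choose_k(
    m: ExpressionMatrix,
    threshold: float = 0.5,
    k_max: int = 10,
    n_starts: int = 5,
    seed: int = 0,
    impute_missing: bool = True,
) -> int:
    """Smallest k whose best-of-starts fit explains >= threshold variance."""
    if not 0 < threshold < 1:
        if threshold <= 0:
            return 2
        raise ConfigError("threshold must be in (0, 1)")
    curve = {}
    for k in range(2, k_max + 1):
        fit = fit_regulation_clusters(m, k, n_starts=n_starts, seed=seed,
                                      impute_missing=impute_missing)
        curve[k] = fit.variance_explained
        if fit.variance_explained >= threshold:
            return k
    raise DataError(
        f"no k <= {k_max} reaches variance_explained >= {threshold}; curve: {curve}"
    )


def cluster_cross_correlation(
    c1: RegulationClustering,
    c2: RegulationClustering,
    m1: ExpressionMatrix,
    m2: ExpressionMatrix,
    rng: np.random.Generator | None = None,
    max_pairs_per_cell: int = 20_000,
) -> pd.DataFrame:
    """Median pairwise PCC between the genes of every cluster pair.

    Entry (i, j) is the median PCC over pairs with one gene in cluster i
    of ``c1`` and one in cluster j of ``c2``; when the clusterings are the
    same object, within-cluster entries use distinct pairs only. Cells
    with more than ``max_pairs_per_cell`` candidate pairs are subsampled
    reproducibly.
    """
    same = c1 is c2
    if list(m1.samples) != list(m2.samples):
        raise DataError("clusterings must share a sample space")
    rng = rng or np.random.default_rng(0)
    v1 = m1.values.to_numpy(float)
    v2 = m2.values.to_numpy(float)
    idx1 = pd.Index(m1.genes)
    idx2 = pd.Index(m2.genes)
    out = pd.DataFrame(np.nan, index=range(c1.k), columns=range(c2.k))
    for i in range(c1.k):
        gi = idx1.get_indexer(c1.assignment.index[c1.assignment == i])
        for j in range(c2.k):
            gj = idx2.get_indexer(c2.assignment.index[c2.assignment == j])
            if len(gi) == 0 or len(gj) == 0:
                continue
            A, B = np.meshgrid(gi, gj, indexing="ij")
            a, b = A.ravel(), B.ravel()
            if same:
                keep = a < b if i == j else np.ones(len(a), bool)
                a, b = a[keep], b[keep]
            if len(a) == 0:
                continue
            if len(a) > max_pairs_per_cell:
                sel = rng.choice(len(a), size=max_pairs_per_cell, replace=False)
                a, b = a[sel], b[sel]
            if same:
                r, _, _ = pairwise_pcc(v1, a, b, min_overlap=2)
            else:
                # cross-layer pair: correlate gene a (layer 1) with gene b (layer 2)
                stacked = np.vstack([v1[a], v2[b]])
                n = len(a)
                r, _, _ = pairwise_pcc(stacked, np.arange(n), np.arange(n, 2 * n),
                                       min_overlap=2)
            out.loc[i, j] = float(np.nanmedian(r))
    return out


def feature_enrichment(
    assignment: pd.Series,
    features: pd.DataFrame | pd.Series,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Cluster-wise feature enrichment relative to all genes.

    Numeric features (DataFrame): log2(median within cluster / overall
    median) per feature; a pseudocount can guard non-positive medians
    (without it they are flagged NaN). Categorical features (Series):
    observed % membership per category vs the dataset-wide %.
    """
    if isinstance(features, pd.Series):
        cats = features.dropna()
        overall = cats.value_counts(normalize=True) * 100.0
        rows = []
        for cl in sorted(assignment.unique()):
            members = cats.reindex(assignment.index[assignment == cl]).dropna()
            for cat, exp_pct in overall.items():
                obs = 100.0 * (members == cat).mean() if len(members) else np.nan
                rows.append({"cluster": cl, "feature": cat,
                             "observed_pct": obs, "expected_pct": float(exp_pct)})
        return pd.DataFrame(rows)
    feats = features.reindex(assignment.index)
    overall_med = feats.median(axis=0)
    rows = []
    for cl in sorted(assignment.unique()):
        med = feats.loc[assignment == cl].median(axis=0)
        num = med + pseudocount
        den = overall_med + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((num > 0) & (den > 0), num / den, np.nan)
        for feat, r in zip(feats.columns, ratio):
            rows.append({
                "cluster": cl,
                "feature": feat,
                "log2_median_ratio": float(np.log2(r)) if np.isfinite(r) else np.nan,
            })
    return pd.DataFrame(rows)
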