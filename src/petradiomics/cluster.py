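"""Cohort-level feature normalization, correlogram, and unsupervised
tumor clustering.

The feature matrix (patients x features) is z-scored per feature
(population SD), pairwise Pearson correlations are Bonferroni-masked,
and patients are grouped by agglomerative hierarchical clustering with
Euclidean distance.  The tree is cut to ``k`` clusters; branches smaller
than ``min_cluster_size`` are ejected as outliers and the cut is
re-taken among the remaining patients, mirroring the occasional single
case that fits no phenotype group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: label used for patients ejected from every cluster
OUTLIER = 0


@dataclass
class CorrelogramResult:
    corr: pd.DataFrame  # feature x feature Pearson r
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # bool, after Bonferroni
    feature_order: list[str]  # hierarchical leaf ordering
    alpha: float
    correction_denominator: int


@dataclass
class ClusterAssignment:
    labels: pd.Series  # per patient: 1..k or OUTLIER (0)
    k: int
    linkage_method: str
    n_outliers: int
    patient_order: list = field(default_factory=list)  # dendrogram leaf order
    feature_order: list = field(default_factory=list)


def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature column to mean 0, SD 1 (population SD).

    Zero-variance columns carry no clustering information and are
    dropped with a log record.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 patients to standardize")
    mat = features.astype(np.float64)
    sd = mat.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping %d zero-variance feature(s): %s", len(constant), constant)
        mat = mat.drop(columns=constant)
        sd = sd.drop(index=constant)
    if mat.shape[1] == 0:
        raise ValueError("all features are constant; nothing to standardize")
    return (mat - mat.mean(axis=0)) / sd


def correlogram(
    features: pd.DataFrame,
    alpha: float = 0.05,
    correction_denominator: int | None = None,
    linkage_method: str = "average",
) -> CorrelogramResult:
    """Pearson correlation matrix with Bonferroni-corrected significance.

    ``correction_denominator`` defaults to the number of features, which
    with alpha 0.05 and 109 features gives the conventional 4.6e-4
    threshold.  Features are reordered by hierarchical clustering of the
    correlation distance 1 - r.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 patients for correlation p-values")
    names = list(features.columns)
    if correction_denominator is None:
        correction_denominator = len(names)
    x = features.to_numpy(dtype=np.float64)
    n = x.shape[0]
    sd = x.std(axis=0, ddof=0)
    ok = sd > 0

    xc = x - x.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ xc) / n / np.outer(sd, sd)
    r = np.clip(r, -1.0, 1.0)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))

    # two-sided p from the t transform of r with n - 2 df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    p[~ok, :] = np.nan
    p[:, ~ok] = np.nan

    threshold = alpha / correction_denominator
    sig = np.where(np.isnan(p), False, p < threshold)
    np.fill_diagonal(sig, False)

    # hierarchical ordering on correlation distance, constant features last
    order_idx = list(np.flatnonzero(ok))
    if len(order_idx) > 2:
        sub = r[np.ix_(order_idx, order_idx)]
        dist = squareform(np.maximum(1.0 - sub, 0.0), checks=False)
        link = hierarchy.linkage(dist, method=linkage_method)
        leaves = hierarchy.leaves_list(link)
        order_idx = [order_idx[i] for i in leaves]
    order_idx += list(np.flatnonzero(~ok))
    feature_order = [names[i] for i in order_idx]

    as_df = lambda a: pd.DataFrame(a, index=names, columns=names)
    return CorrelogramResult(
        corr=as_df(r),
        pvalues=as_df(p),
        significant=as_df(sig),
        feature_order=feature_order,
        alpha=alpha,
        correction_denominator=correction_denominator,
    )


def hierarchical_clusters(
    standardized: pd.DataFrame,
    k: int = 3,
    linkage_method: str = "ward",
    min_cluster_size: int = 2,
) -> ClusterAssignment:
    """Agglomerative clustering with small-branch outlier ejection.

    The Euclidean-linkage tree is cut to ``k`` clusters; any resulting
    cluster smaller than ``min_cluster_size`` has its members labelled
    outliers (0) and the cut is re-taken among the rest.  Deterministic:
    ties in the dendrogram are resolved by patient index order.
    """
    n = len(standardized)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k + 1:
        raise ValueError(f"need more than k={k} patients, got {n}")
    index = standardized.index
    active = np.arange(n)
    outliers: list[int] = []
    link = None
    while True:
        x = standardized.to_numpy(dtype=np.float64)[active]
        link = hierarchy.linkage(x, method=linkage_method, metric="euclidean")
        cut = hierarchy.fcluster(link, t=k, criterion="maxclust")
        sizes = np.bincount(cut)[1:]
        small = np.flatnonzero(sizes < min_cluster_size) + 1
        if small.size == 0 or len(active) - sizes[small - 1].sum() < k + 1:
            break
        eject = np.isin(cut, small)
        outliers.extend(active[eject].tolist())
        active = active[~eject]

    labels = np.full(n, OUTLIER, dtype=int)
    # relabel clusters 1..k in order of first appearance for determinism
    relabel: dict[int, int] = {}
    for pos, c in enumerate(cut):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    labels[active] = [relabel[c] for c in cut]

    leaves = hierarchy.leaves_list(link)
    patient_order = [index[active[i]] for i in leaves] + [index[i] for i in outliers]
    return ClusterAssignment(
        labels=pd.Series(labels, index=index, name="cluster"),
        k=int(cut.max()),
        linkage_method=linkage_method,
        n_outliers=len(outliers),
        patient_order=patient_order,
        feature_order=list(standardized.columns),
    )


def cluster_feature_summary(
    features: pd.DataFrame,
    assignment: ClusterAssignment,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster median and range plus a Kruskal-Wallis p per feature.

    Outlier patients are excluded.  The KW test uses the tie-corrected
    rank statistic across the clusters.
    """
    if feature_names is None:
        feature_names = list(features.columns)
    labels = assignment.labels
    clusters = sorted(c for c in labels.unique() if c != OUTLIER)
    if len(clusters) < 2:
        raise ValueError("need at least 2 non-outlier clusters")
    rows = []
    for name in feature_names:
        row: dict[str, object] = {"feature": name}
        groups = []
        for c in clusters:
            vals = features.loc[labels[labels == c].index, name].to_numpy()
            groups.append(vals)
            row[f"median_c{c}"] = float(np.median(vals))
            row[f"min_c{c}"] = float(vals.min())
            row[f"max_c{c}"] = float(vals.max())
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            h, p = 0.0, 1.0  # identical values in all groups
        else:
            h, p = stats.kruskal(*groups)
        row["kw_H"] = float(h)
        row["kw_p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
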