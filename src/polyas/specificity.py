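"""Ploidy-, stage-, tissue- and cultivar-specific AS events.

Events are Z-scored across samples, grouped by k-means, and a cluster is
called specific to a sample group when its centroid correlates strongly
(|r| >= specificity_r_min, p < alpha) with the group's 0/1 indicator over
samples; member events inherit the call.  Cultivar-divergent events are found
directly from stage-matched PSI differences plus a Welch test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .config import AnalysisConfig
from .psi import stage_mean_psi

GROUPINGS = ("ploidy", "variety", "stage_tissue", "tissue_class")


def zscore_psi(psi: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a complete PSI submatrix (sample sd, ddof=1).

    Rows with any NA or zero variance are dropped.
    """
    complete = psi.dropna(axis=0)
    sd = complete.std(axis=1, ddof=1)
    kept = complete[sd > 0]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)


@dataclass
class ClusterResult:
    labels: pd.Series          # event -> cluster id
    centroids: pd.DataFrame    # cluster x samples (mean of z-scored rows)
    k: int
    source: pd.DataFrame       # the z-scored matrix that was clustered


def kmeans_psi(z: pd.DataFrame, k: int | str = "auto", seed: int = 0, max_k: int = 10) -> ClusterResult:
    """Cluster z-scored events; ``k="auto"`` maximizes mean silhouette over 2..max_k."""
    n = len(z)
    values = z.to_numpy()
    if k == "auto":
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(max_k, n - 1) + 1):
            labels = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(values)
            score = silhouette_score(values, labels)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    if not isinstance(k, int) or k < 1:
        raise ValueError(f"k must be a positive integer or 'auto', got {k!r}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of events ({n})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(values)
    labels = pd.Series(km.labels_, index=z.index, name="cluster")
    centroids = pd.DataFrame(
        [values[km.labels_ == c].mean(axis=0) for c in range(k)], columns=z.columns
    )
    return ClusterResult(labels=labels, centroids=centroids, k=k, source=z)


def call_specific_clusters(
    clusters: ClusterResult,
    samples: pd.DataFrame,
    grouping: str,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate cluster centroids with group indicators to call specificity.

    Returns (cluster_table, event_table).  The cluster table has one row per
    (cluster, group) with the centroid-indicator Pearson r, its p-value and
    the direction ("top" for positive, "bottom" for negative) when
    |r| >= specificity_r_min and p < alpha.  Events inherit their cluster's
    calls when their own z-profile correlates with the cluster centroid at
    r >= specificity_r_min (hard k-means assignment alone would let
    noise-dominated profiles inherit calls); every member's centroid
    correlation is reported.
    """
    config = config or AnalysisConfig()
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    cols = clusters.centroids.columns
    labels_per_sample = samples.loc[cols, grouping]
    groups = sorted(labels_per_sample.unique())
    if len(groups) < 2:
        raise ValueError("specificity calling needs at least two sample groups")
    rows = []
    for cid in range(clusters.k):
        centroid = clusters.centroids.loc[cid].to_numpy()
        for g in groups:
            indicator = (labels_per_sample == g).to_numpy(dtype=float)
            if indicator.std() == 0 or centroid.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(centroid, indicator)
            call = None
            if np.isfinite(r) and abs(r) >= config.specificity_r_min and p < config.alpha:
                call = "top" if r > 0 else "bottom"
            rows.append({"cluster": cid, "group": g, "r": r, "p": p, "call": call})
    cluster_table = pd.DataFrame(rows)
    return cluster_table, _event_table(clusters, cluster_table, config.specificity_r_min)


def _event_table(
    clusters: ClusterResult, cluster_table: pd.DataFrame, member_r_min: float
) -> pd.DataFrame:
    calls = cluster_table.dropna(subset=["call"])
    rows = []
    for eid, cid in clusters.labels.items():
        centroid = clusters.centroids.loc[cid]
        member_r = float(np.corrcoef(centroid, clusters.source.loc[eid].to_numpy())[0, 1])
        if member_r < member_r_min:
            continue
        for _, c in calls[calls["cluster"] == cid].iterrows():
            rows.append(
                {
                    "event_id": eid,
                    "cluster": cid,
                    "group": c["group"],
                    "direction": c["call"],
                    "centroid_r": member_r,
                }
            )
    return pd.DataFrame(rows, columns=["event_id", "cluster", "group", "direction", "centroid_r"])


def cluster_events(
    psi: pd.DataFrame,
    k: int | str = "auto",
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> ClusterResult:
    """Z-score + k-means convenience wrapper."""
    config = config or AnalysisConfig()
    z = zscore_psi(psi)
    return kmeans_psi(z, k=k, seed=seed, max_k=config.kmeans_max_k)


def cultivar_divergent_events(
    psi: pd.DataFrame,
    samples: pd.DataFrame,
    pair: tuple[str, str],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Events whose PSI differs between two cultivars of the same species.

    An event is listed when its stage-matched replicate-mean PSI differs by
    more than ``variant_delta`` in at least one shared stage and a two-sided
    Welch test across stage-matched mean PSI values rejects at ``alpha``.
    """
    config = config or AnalysisConfig()
    v1, v2 = pair
    means = stage_mean_psi(psi, samples)
    m1, m2 = means[v1], means[v2]
    shared = [s for s in m1.columns if s in m2.columns]
    if not shared:
        raise ValueError(f"varieties {v1} and {v2} share no stages")
    m1, m2 = m1[shared], m2[shared]
    rows = []
    for eid in psi.index:
        a, b = m1.loc[eid].to_numpy(), m2.loc[eid].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            continue
        diff = np.abs(a[ok] - b[ok])
        if diff.max() <= config.variant_delta:
            continue
        t, p = stats.ttest_ind(a[ok], b[ok], equal_var=False)
        if np.isfinite(p) and p < config.alpha:
            rows.append({"event_id": eid, "max_delta_psi": diff.max(), "p_value": p})
    return pd.DataFrame(rows, columns=["event_id", "max_delta_psi", "p_value"])
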