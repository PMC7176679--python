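"""Cluster markers, concise marker sets, and spatial mapping of clusters.

Each mesenchymal sub-cluster is characterized by one-vs-rest markers, then
distilled to a concise marker set (high expression, enough expressing
cells, >= 5-fold over the other clusters, top 20 by fold). Summing the LCM
zonation profiles of a cluster's concise markers and normalizing by the
maximum across zones places the cluster along the crypt-villus axis; the
Lgr5+ cell configuration is scored with a hypergeometric upper tail.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats
from .types import PipelineThresholds, ZonationProfile, ZONES


def find_cluster_markers(lognorm: pd.DataFrame, clusters: pd.Series,
                         min_pct: float = 0.2,
                         min_logfc: float = 0.25) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    A gene is tested for a cluster when it is detected in at least
    ``min_pct`` of cells inside the cluster or in the rest, and the absolute
    difference of mean log-normalized expression is at least ``min_logfc``.
    P-values are two-sided Wilcoxon rank-sum, Bonferroni-adjusted over the
    tested genes of each cluster.
    """
    cluster_ids = sorted(clusters.unique())
    if len(cluster_ids) < 2:
        raise ValueError("need at least two clusters")
    rows = []
    X = lognorm.to_numpy(dtype=float)
    cells = list(lognorm.columns)
    cl = clusters.reindex(cells)
    for cid in cluster_ids:
        inside = (cl == cid).to_numpy()
        if inside.sum() < 3:
            raise ValueError(f"cluster {cid} has fewer than 3 cells")
        xin, xout = X[:, inside], X[:, ~inside]
        pct_in = (xin > 0).mean(axis=1)
        pct_out = (xout > 0).mean(axis=1)
        logfc = xin.mean(axis=1) - xout.mean(axis=1)
        testable = ((pct_in >= min_pct) | (pct_out >= min_pct)) & \
            (np.abs(logfc) >= min_logfc)
        idx = np.flatnonzero(testable)
        pvals = np.array([stats.wilcoxon_rank_sum(xin[i], xout[i])
                          for i in idx])
        padj = np.minimum(pvals * idx.size, 1.0)
        for j, i in enumerate(idx):
            rows.append({"cluster": cid, "gene": lognorm.index[i],
                         "log_fc": logfc[i], "pct_in": pct_in[i],
                         "pct_out": pct_out[i], "p": pvals[j],
                         "p_adj": padj[j]})
    return pd.DataFrame(rows)


def select_concise_markers(fracs: pd.DataFrame, raw: pd.DataFrame,
                           clusters: pd.Series,
                           thresholds: PipelineThresholds
                           ) -> dict[int, pd.DataFrame]:
    """Concise, ordered marker set per cluster.

    Candidates must have mean fraction-of-UMI expression strictly above
    ``concise_min_expr`` and at least ``concise_min_cells`` expressing cells
    (raw count > 0) in the cluster. They are sorted by the linear fold
    change of the cluster mean over the maximal mean of the other clusters
    (zero denominators count as infinite fold), the top ``concise_top_n``
    kept, and members with fold below ``concise_min_fold`` removed.
    """
    cluster_ids = sorted(clusters.unique())
    cells_of = {cid: list(clusters.index[clusters == cid])
                for cid in cluster_ids}
    means = pd.DataFrame({cid: fracs[cells].mean(axis=1)
                          for cid, cells in cells_of.items()})
    out = {}
    for cid in cluster_ids:
        others = means.drop(columns=cid).max(axis=1)
        n_pos = (raw[cells_of[cid]] > 0).sum(axis=1)
        eligible = (means[cid] > thresholds.concise_min_expr) & \
            (n_pos >= thresholds.concise_min_cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = means[cid] / others
        fold = fold.where(others > 0, np.inf)
        tab = pd.DataFrame({"mean": means[cid], "fold": fold,
                            "n_pos": n_pos})[eligible]
        tab = tab.sort_values("fold", ascending=False, kind="mergesort")
        tab = tab.head(thresholds.concise_top_n)
        tab = tab[tab["fold"] >= thresholds.concise_min_fold]
        if tab.empty:
            warnings.warn(f"cluster {cid}: no qualifying concise markers")
        out[cid] = tab
    return out


def map_clusters_to_zones(marker_sets: dict, profile: ZonationProfile
                          ) -> pd.DataFrame:
    """Place each cluster on the crypt-villus axis via its summed markers.

    For every cluster the zone means of its markers are summed into a
    4-vector, normalized by its maximum; the argmax is the cluster's home
    zone, with exact ties flagged rather than broken.
    """
    rows = {}
    for cid, markers in marker_sets.items():
        genes = list(markers.index) if isinstance(markers, pd.DataFrame) \
            else list(markers)
        present = [g for g in genes if g in profile.mean.index]
        dropped = set(genes) - set(present)
        if dropped:
            warnings.warn(f"cluster {cid}: markers missing from zonation "
                          f"profile dropped: {sorted(dropped)[:5]}")
        if not present:
            raise ValueError(f"cluster {cid}: no marker in zonation profile")
        summed = profile.mean.loc[present].sum(axis=0)
        peak = summed.max()
        if peak <= 0:
            raise ValueError(f"cluster {cid}: all-zero summed marker profile")
        norm = summed / peak
        winners = [z for z in ZONES if norm[z] == 1.0]
        rows[cid] = {**{z: norm[z] for z in ZONES},
                     "home_zone": winners[0], "tie": len(winners) > 1,
                     "n_markers": len(present)}
    return pd.DataFrame.from_dict(rows, orient="index")


def gene_cluster_enrichment(clusters: pd.Series, positive_cells,
                            target_cluster) -> stats.EnrichmentResult:
    """Hypergeometric upper-tail enrichment of positive cells in a cluster."""
    positive = [c for c in positive_cells]
    missing = set(positive) - set(clusters.index)
    if missing:
        raise ValueError(f"positive cells not clustered: {sorted(missing)[:5]}")
    N = int(clusters.size)
    K = int((clusters == target_cluster).sum())
    n = len(positive)
    k = int((clusters.loc[positive] == target_cluster).sum())
    p = stats.hypergeometric_tail(N, K, n, k)
    return stats.EnrichmentResult(N=N, K=K, n=n, k=k, p=p)
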