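"""Plate-based single-cell RNA-seq processing.

The stages mirror the standard plate-based (MARS-Seq-style) workflow: ambient
background estimated per 384-well plate from its four empty control wells and
subtracted; QC gates on total UMI and detected genes; per-cell
log-normalization; regression of total-UMI and mitochondrial-fraction
covariates; variable-gene selection by binned dispersion z-scores; PCA plus
Jaccard-weighted kNN graph clustering with Leiden modularity optimization;
lineage gating of clusters on Epcam/Ptprc/Pdgfra; and reclustering of the
Pdgfra+ mesenchymal subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import MITO_PREFIXES
from .types import PipelineThresholds, UmiCountMatrix

#: lineage gate genes, cluster-level
LINEAGE_MARKERS = {"Epcam": "epithelial", "Ptprc": "immune",
                   "Pdgfra": "mesenchymal"}

#: neighbors in the cell-cell kNN graph
KNN_K = 20

#: residuals are clipped at this many SDs after covariate regression
SCALE_CLIP = 10.0


def subtract_plate_background(umis: UmiCountMatrix) -> UmiCountMatrix:
    """Subtract per-plate ambient background estimated from empty wells.

    Background per plate and gene is the mean count over that plate's empty
    wells; it is subtracted from every cell well, negatives are clipped to
    zero, and empty wells are dropped. The result is real-valued.
    """
    out = {}
    meta = umis.well_meta
    for plate in umis.plates():
        plate_wells = meta.index[meta["plate"] == plate]
        empties = umis.empty_wells(plate)
        if not empties:
            raise ValueError(f"plate {plate!r} has no empty control wells")
        bg = umis.counts[empties].mean(axis=1)
        cells = [w for w in plate_wells if w not in set(empties)]
        out[plate] = umis.counts[cells].sub(bg, axis=0).clip(lower=0)
    counts = pd.concat(out.values(), axis=1)
    counts = counts[[w for w in umis.wells if w in counts.columns]]
    return UmiCountMatrix(counts, meta.loc[list(counts.columns)],
                          subtracted=True)


def cell_qc_table(subtracted: UmiCountMatrix,
                  raw: UmiCountMatrix | None = None,
                  mito_prefixes=MITO_PREFIXES) -> pd.DataFrame:
    """Per-cell QC: total UMI, detected genes, mitochondrial fraction.

    The mitochondrial fraction is computed on pre-subtraction counts when
    the raw matrix is supplied.
    """
    total = subtracted.counts.sum(axis=0)
    genes = (subtracted.counts > 0).sum(axis=0)
    src = raw.counts[subtracted.wells] if raw is not None else subtracted.counts
    is_mt = src.index.str.startswith(tuple(mito_prefixes))
    denom = src.sum(axis=0).replace(0, np.nan)
    mito = (src.loc[is_mt].sum(axis=0) / denom).fillna(0.0)
    return pd.DataFrame({"total_umi": total, "n_genes": genes,
                         "mito_fraction": mito})


def qc_filter_cells(subtracted: UmiCountMatrix, qc: pd.DataFrame,
                    thresholds: PipelineThresholds
                    ) -> tuple[UmiCountMatrix, pd.DataFrame]:
    """Drop cells failing the QC gates.

    Gates are strict as stated: UMI < umi_min, UMI > umi_max, or detected
    genes < genes_min are removed; boundary values are retained.
    """
    keep = ~((qc["total_umi"] < thresholds.umi_min) |
             (qc["total_umi"] > thresholds.umi_max) |
             (qc["n_genes"] < thresholds.genes_min))
    kept = list(qc.index[keep])
    if not kept:
        raise ValueError("QC removed every cell")
    mat = UmiCountMatrix(subtracted.counts[kept],
                         subtracted.well_meta.loc[kept], subtracted=True)
    return mat, qc.loc[kept]


def to_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell fraction-of-UMI matrix (columns sum to 1)."""
    sums = counts.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("cell with zero total counts")
    return counts / sums


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log(1 + scale * x / column sum), natural log."""
    return np.log1p(scale * to_fractions(counts))


def regress_covariates(lognorm: pd.DataFrame, qc: pd.DataFrame,
                       clip: float = SCALE_CLIP) -> pd.DataFrame:
    """Per-gene residuals of expression on (total UMI, mito fraction).

    A linear fit with intercept is removed gene-wise; residuals are then
    standardized per gene (unit variance, clipped at ``clip`` SDs).
    Constant covariates are dropped, so with both constant this reduces to
    centering and scaling.
    """
    cells = lognorm.columns
    covs = [np.ones(len(cells))]
    for name in ("total_umi", "mito_fraction"):
        v = qc.loc[cells, name].to_numpy(dtype=float)
        if np.ptp(v) > 0:
            covs.append(v)
        else:
            warnings.warn(f"covariate {name} is constant; dropped")
    X = np.column_stack(covs)
    # rank check: drop collinear trailing columns
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear covariates; dropping redundant column")
        X = X[:, :np.linalg.matrix_rank(X)]
    Y = lognorm.to_numpy(dtype=float).T            # cells x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    resid = np.clip(resid / sd, -clip, clip)
    return pd.DataFrame(resid.T, index=lognorm.index, columns=cells)


def select_variable_genes(lognorm: pd.DataFrame, mean_lo: float = 0.25,
                          mean_hi: float = 4.0, disp_lo: float = 0.5,
                          n_bins: int = 20) -> pd.Index:
    """Variable genes by the binned dispersion z-score recipe.

    Per gene, the mean of the back-scaled expression (expm1 of the
    log-normalized values, re-logged for the mean cutoffs) and the
    dispersion (variance/mean of back-scaled expression) are computed;
    dispersions are z-scored within ``n_bins`` equal-frequency mean bins and
    genes with mean in (mean_lo, mean_hi) and dispersion z > disp_lo kept.
    """
    back = np.expm1(lognorm.to_numpy(dtype=float))
    gmean = back.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(gmean > 0, back.var(axis=1, ddof=1) / gmean, np.nan)
    log_mean = np.log1p(gmean)
    ok = np.isfinite(disp) & (disp > 0)
    n_bins = min(n_bins, max(1, ok.sum()))
    if n_bins < 20:
        warnings.warn(f"few usable genes; using {n_bins} dispersion bins")
    z = np.full(gmean.size, -np.inf)
    if ok.any():
        ranks = pd.Series(log_mean[ok]).rank(method="first")
        bins = np.ceil(ranks / (ok.sum() / n_bins)).clip(1, n_bins).astype(int)
        dser = pd.Series(disp[ok])
        grp = dser.groupby(bins.values)
        mu, sd = grp.transform("mean"), grp.transform("std").replace(0, np.nan)
        zval = ((dser - mu) / sd).fillna(0.0)
        z[np.flatnonzero(ok)] = zval.to_numpy()
    keep = (log_mean > mean_lo) & (log_mean < mean_hi) & (z > disp_lo)
    return lognorm.index[keep]


def pca_embedding(residuals: pd.DataFrame, var_genes, n_pcs: int,
                  seed: int = 0) -> pd.DataFrame:
    """Top principal components of the standardized residual matrix."""
    var_genes = [g for g in var_genes if g in residuals.index]
    X = residuals.loc[var_genes].to_numpy(dtype=float).T
    if n_pcs >= min(X.shape):
        raise ValueError("n_pcs must be below min(cells, genes)")
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(X)
    # fix component signs (largest-magnitude loading positive) for
    # reproducibility across BLAS builds
    max_idx = np.abs(pca.components_).argmax(axis=1)
    signs = np.sign(pca.components_[np.arange(n_pcs), max_idx])
    signs[signs == 0] = 1.0
    emb = emb * signs
    return pd.DataFrame(emb, index=residuals.columns,
                        columns=[f"PC{i+1}" for i in range(n_pcs)])


#: shared-neighbor edges with Jaccard overlap below this are pruned
SNN_PRUNE = 1.0 / 15.0


def _jaccard_knn_graph(emb: np.ndarray, k: int = KNN_K,
                       prune: float = SNN_PRUNE) -> igraph.Graph:
    """Shared-nearest-neighbor graph in PC space with Jaccard weights.

    Every pair of cells whose k-nearest-neighbor sets (self included)
    overlap with Jaccard index >= ``prune`` is connected, weighted by that
    index. Connecting all sharing pairs, not just kNN edges, keeps
    homogeneous groups densely wired so modularity optimization does not
    shatter them.
    """
    n = emb.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    B = np.zeros((n, n), dtype=np.int32)
    B[np.repeat(np.arange(n), k + 1), idx.ravel()] = 1
    inter = B @ B.T
    jac = inter / (2.0 * (k + 1) - inter)
    np.fill_diagonal(jac, 0.0)
    jac[jac < prune] = 0.0
    src, dst = np.nonzero(np.triu(jac))
    g = igraph.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = jac[src, dst].tolist()
    return g


def cluster_graph(emb: pd.DataFrame, resolution: float,
                  seed: int = 0, k: int = KNN_K) -> pd.Series:
    """Leiden modularity clustering of the Jaccard kNN graph."""
    g = _jaccard_knn_graph(emb.to_numpy(dtype=float), k=k)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"], resolution_parameter=resolution,
        seed=int(seed), n_iterations=2)
    return pd.Series(part.membership, index=emb.index, name="cluster")


def reduce_and_cluster(residuals: pd.DataFrame, var_genes, n_pcs: int,
                       resolution: float, seed: int = 0) -> pd.Series:
    """PCA -> kNN graph -> Leiden community detection."""
    if residuals.shape[1] <= n_pcs:
        raise ValueError("need more cells than principal components")
    if residuals.loc[list(var_genes)].to_numpy().std() == 0:
        # all cells identical in feature space: a single cluster
        return pd.Series(0, index=residuals.columns, name="cluster")
    emb = pca_embedding(residuals, var_genes, n_pcs, seed=seed)
    return cluster_graph(emb, resolution, seed=seed)


def assign_lineages(lognorm: pd.DataFrame, fracs: pd.DataFrame,
                    clusters: pd.Series,
                    pdgfra_cluster_mean_min: float = 1e-4,
                    markers: dict = LINEAGE_MARKERS) -> pd.Series:
    """Label each cluster by its strongest lineage gate gene.

    Clusters are labelled by the arg-max mean log-normalized expression among
    the gate genes; a mesenchymal call additionally requires the cluster
    mean Pdgfra fraction-of-UMI to strictly exceed
    ``pdgfra_cluster_mean_min``, otherwise the cluster is 'other'.
    """
    for g in markers:
        if g not in lognorm.index:
            raise KeyError(f"lineage marker {g!r} absent from matrix")
    gate = [g for g, lab in markers.items() if lab == "mesenchymal"][0]
    labels = {}
    for cl in sorted(clusters.unique()):
        cells = clusters.index[clusters == cl]
        means = {g: lognorm.loc[g, cells].mean() for g in markers}
        best = max(means, key=means.get)
        label = markers[best]
        if label == "mesenchymal" and \
                fracs.loc[gate, cells].mean() <= pdgfra_cluster_mean_min:
            label = "other"
        labels[cl] = label
    return clusters.map(labels).rename("lineage")


def recluster_mesenchyme(lognorm: pd.DataFrame, qc: pd.DataFrame,
                         mesenchymal_cells,
                         thresholds: PipelineThresholds,
                         seed: int = 0) -> pd.Series:
    """Re-run selection, PCA and clustering on the mesenchymal subset."""
    cells = [c for c in lognorm.columns if c in set(mesenchymal_cells)]
    if len(cells) < 20:
        raise ValueError("mesenchymal subset too small to recluster")
    sub = lognorm[cells]
    var = select_variable_genes(
        sub, thresholds.vargene_mean_lo, thresholds.vargene_mean_hi,
        thresholds.vargene_disp_lo_recluster)
    resid = regress_covariates(sub, qc)
    return reduce_and_cluster(resid, var, thresholds.pcs_recluster,
                              thresholds.resolution_recluster,
                              seed=seed).rename("subcluster")


@dataclass
class ScrnaResult:
    """Bundle of intermediate and final single-cell processing outputs."""

    qc: pd.DataFrame
    fractions: pd.DataFrame
    lognorm: pd.DataFrame
    clusters: pd.Series
    lineage: pd.Series
    subclusters: pd.Series = field(default=None)

    @property
    def mesenchymal_cells(self) -> list:
        return list(self.lineage.index[self.lineage == "mesenchymal"])

    def assignment_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.clusters, "lineage": self.lineage})
        if self.subclusters is not None:
            df["subcluster"] = self.subclusters.reindex(df.index)
        return df


def run_scrna(umis: UmiCountMatrix, thresholds: PipelineThresholds,
              seed: int = 0) -> ScrnaResult:
    """Full chain from raw plate UMIs to lineage-gated sub-clusters."""
    sub = subtract_plate_background(umis)
    qc = cell_qc_table(sub, raw=umis)
    sub, qc = qc_filter_cells(sub, qc, thresholds)
    fracs = to_fractions(sub.counts)
    logn = lognormalize(sub.counts, thresholds.lognorm_scale)
    resid = regress_covariates(logn, qc)
    var = select_variable_genes(
        logn, thresholds.vargene_mean_lo, thresholds.vargene_mean_hi,
        thresholds.vargene_disp_lo_main)
    clusters = reduce_and_cluster(resid, var, thresholds.pcs_main,
                                  thresholds.resolution_main, seed=seed)
    lineage = assign_lineages(logn, fracs, clusters,
                              thresholds.pdgfra_cluster_mean_min)
    result = ScrnaResult(qc, fracs, logn, clusters, lineage)
    mes = result.mesenchymal_cells
    if len(mes) >= 20:
        result.subclusters = recluster_mesenchyme(logn, qc, mes, thresholds,
                                                  seed=seed)
    return result
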