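"""Statistical kernels shared across the pipeline.

Wilcoxon rank-sum tests, Benjamini-Hochberg and Storey q-values, the
hypergeometric upper tail used for cluster-membership enrichment, and the
two-group single-cell differential-expression procedures (crypt-telocyte vs
villus-tip-telocyte style comparisons, and the within-cluster split on a
single gate gene such as Il18r1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "storey_pi0",
    "storey_qvalues",
    "hypergeometric_tail",
    "EnrichmentResult",
    "two_group_de",
    "split_de_geneset",
]

#: largest pooled sample size for which the exact Wilcoxon null is enumerated
EXACT_WILCOXON_MAX = 12


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the pooled sample is small
    (n + m <= 12) and tie-free; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size + y.size <= EXACT_WILCOXON_MAX and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(pvalues, lambdas=None) -> float:
    """Estimate the null proportion pi0 with the lambda-grid smoother.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    lambda = 0, 0.05, ..., 0.90, smoothed with a cubic polynomial in lambda,
    and the smoother value at the largest lambda is clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if p.size < 10:
        warnings.warn("fewer than 10 p-values; falling back to pi0 = 1")
        return 1.0
    pi0_lambda = np.array([(p > lam).sum() / (p.size * (1.0 - lam))
                           for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(min(max(pi0, 1.0 / p.size), 1.0))


def storey_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0 times the BH step-up adjustment.

    ``pi0=None`` estimates pi0 from the data; passing ``pi0=1`` reduces the
    result to plain Benjamini-Hochberg exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members among ``n`` draws without replacement from a
    population of ``N`` containing ``K`` category members. Computed by
    summing log-pmf terms for stability.
    """
    if not (0 <= K <= N):
        raise ValueError("need 0 <= K <= N")
    if not (0 <= k <= n <= N):
        raise ValueError("need 0 <= k <= n <= N")
    hi = min(n, K)
    if k > hi:
        return 0.0
    support = np.arange(k, hi + 1)
    logp = sps.hypergeom.logpmf(support, N, K, n)
    return float(min(np.exp(logsumexp(logp)), 1.0))


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of marker-positive cells in one cluster."""

    N: int  # clustered population size
    K: int  # target-cluster size
    n: int  # marker-positive cells
    k: int  # marker-positive cells inside the target cluster
    p: float

    def as_dict(self) -> dict:
        return {"N": self.N, "K": self.K, "n": self.n, "k": self.k,
                "p": self.p}


def _de_gene_filter(fracs: pd.DataFrame, raw: pd.DataFrame,
                    cells_a, cells_b, min_expr: float,
                    min_pos_cells: int) -> pd.Series:
    """Genes eligible for two-group DE.

    Kept when mean expression exceeds ``min_expr`` in at least one group and
    strictly more than ``min_pos_cells`` cells are positive (raw count > 0)
    in at least one group. Both thresholds are strict.
    """
    mean_a = fracs[cells_a].mean(axis=1)
    mean_b = fracs[cells_b].mean(axis=1)
    pos_a = (raw[cells_a] > 0).sum(axis=1)
    pos_b = (raw[cells_b] > 0).sum(axis=1)
    return ((mean_a > min_expr) | (mean_b > min_expr)) & \
        ((pos_a > min_pos_cells) | (pos_b > min_pos_cells))


def two_group_de(fracs: pd.DataFrame, raw: pd.DataFrame, cells_a, cells_b,
                 min_expr: float = 1e-5, min_pos_cells: int = 5,
                 volcano_q: float = 0.2,
                 volcano_fold: float = 2.0) -> pd.DataFrame:
    """Two-group single-cell differential expression.

    Parameters
    ----------
    fracs
        Genes x cells expression as fraction of cellular UMIs.
    raw
        Genes x cells background-subtracted counts; positivity (count > 0)
        is judged on these, not on normalized values.
    cells_a, cells_b
        Column labels of the two groups.

    Returns a per-gene table with group means, linear fold change (A/B, with
    a half-minimum pseudocount variant for silent-denominator genes),
    Wilcoxon p, Storey q, and a volcano flag at q < ``volcano_q`` and fold
    > ``volcano_fold`` or < 1/``volcano_fold``.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    keep = _de_gene_filter(fracs, raw, cells_a, cells_b, min_expr,
                           min_pos_cells)
    if not keep.any():
        raise ValueError("no genes pass the expression/positivity filter")
    sub = fracs.loc[keep]
    mean_a = sub[cells_a].mean(axis=1)
    mean_b = sub[cells_b].mean(axis=1)
    pvals = np.array([
        wilcoxon_rank_sum(row[: len(cells_a)], row[len(cells_a):])
        for row in sub[cells_a + cells_b].to_numpy()
    ])
    qvals = storey_qvalues(pvals)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_a / mean_b
    fold = fold.replace([np.inf, -np.inf], np.inf).fillna(np.inf)
    pseudo = mean_a[mean_a > 0].min() / 2 if (mean_a > 0).any() else 1.0
    fold_pseudo = (mean_a + pseudo) / (mean_b + pseudo)
    out = pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold": fold,
        "fold_pseudo": fold_pseudo,
        "log2fc_pseudo": np.log2(fold_pseudo),
        "n_pos_a": (raw.loc[keep, cells_a] > 0).sum(axis=1),
        "n_pos_b": (raw.loc[keep, cells_b] > 0).sum(axis=1),
        "p": pvals,
        "q": qvals,
    })
    out["volcano"] = (out["q"] < volcano_q) & \
        ((out["fold"] > volcano_fold) | (out["fold"] < 1.0 / volcano_fold))
    return out


def split_de_geneset(fracs: pd.DataFrame, cells, splitter: str,
                     min_expr: float = 5e-5, top_n: int = 200) -> pd.DataFrame:
    """Gene set distinguishing splitter-positive from -negative cells.

    Cells of one cluster are split by ``splitter`` expression > 0; each
    gene is tested with the Wilcoxon rank-sum test, genes with mean
    expression (over the cluster) above ``min_expr`` are ranked by the
    linear fold change positive/negative, and the top ``top_n`` returned.
    """
    cells = list(cells)
    if splitter not in fracs.index:
        raise KeyError(f"splitter gene {splitter!r} not in matrix")
    expr = fracs.loc[splitter, cells]
    pos = [c for c in cells if expr[c] > 0]
    neg = [c for c in cells if expr[c] <= 0]
    if not pos or not neg:
        raise ValueError("splitter gene yields a one-sided split")
    sub = fracs[cells]
    mean_all = sub.mean(axis=1)
    keep = mean_all > min_expr
    sub = sub.loc[keep]
    mean_pos = sub[pos].mean(axis=1)
    mean_neg = sub[neg].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (mean_pos / mean_neg).replace([np.inf, -np.inf],
                                             np.inf).fillna(np.inf)
    pvals = np.array([wilcoxon_rank_sum(sub.loc[g, pos], sub.loc[g, neg])
                      for g in sub.index])
    out = pd.DataFrame({"mean_pos": mean_pos, "mean_neg": mean_neg,
                        "fold": fold, "p": pvals})
    out = out.sort_values("fold", ascending=False, kind="mergesort")
    if top_n > len(out):
        warnings.warn(f"only {len(out)} genes qualify; returning all")
    return out.head(top_n)
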