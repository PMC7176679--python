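"""Bulk DE between ablated (DT) and mock epithelium, and zone correlation.

Counts are filtered on a per-sample expression fraction, scaled with TMM
(trimmed mean of M-values) factors, and tested gene-wise with a
negative-binomial model: method-of-moments dispersions shrunk toward a
mean-dispersion trend, and a quasi-likelihood-style F-test of the group
effect with an empirical-Bayes-squeezed deviance scale. The spatial readout
is the Spearman correlation between per-gene expression change and the
center of mass of the gene's six-zone epithelial profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .types import ExpressionMatrix

#: prior degrees of freedom for dispersion and QL-scale shrinkage
DISPERSION_PRIOR_DF = 10.0
QL_PRIOR_DF = 10.0

#: TMM trim fractions (each tail) for M- and A-values
TMM_M_TRIM = 0.30
TMM_A_TRIM = 0.05


def filter_ablation_genes(counts: pd.DataFrame,
                          min_fraction: float = 1e-5,
                          min_samples: int = 2) -> pd.DataFrame:
    """Keep genes whose per-sample fraction exceeds ``min_fraction``
    (strictly) in at least ``min_samples`` samples."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    fracs = counts / counts.sum(axis=0)
    keep = (fracs > min_fraction).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    return counts.loc[keep]


def tmm_factors(counts: pd.DataFrame) -> pd.DataFrame:
    """TMM scaling factors per the published trimmed-mean-of-M definition.

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the mean across samples. Per sample, log2 ratios (M) against
    the reference are trimmed 30% from each tail, average log intensities
    (A) 5% from each tail, and the factor is 2 to the inverse-variance
    weighted mean of the surviving M values. Factors are rescaled to
    geometric mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("sample with zero total counts")
    fr = counts / lib
    uq = fr.apply(lambda col: np.quantile(col[col > 0], 0.75), axis=0)
    ref = (uq - uq.mean()).abs().idxmin()
    yr, Nr = counts[ref].to_numpy(dtype=float), lib[ref]
    factors = {}
    for s in counts.columns:
        ys, Ns = counts[s].to_numpy(dtype=float), lib[s]
        if s == ref:
            factors[s] = 1.0
            continue
        ok = (ys > 0) & (yr > 0)
        y1, y2 = ys[ok], yr[ok]
        M = np.log2((y1 / Ns) / (y2 / Nr))
        A = 0.5 * np.log2((y1 / Ns) * (y2 / Nr))
        v = (Ns - y1) / (Ns * y1) + (Nr - y2) / (Nr * y2)
        n = M.size
        loM = np.floor(n * TMM_M_TRIM) + 1
        loA = np.floor(n * TMM_A_TRIM) + 1
        rM = sps.rankdata(M, method="ordinal")
        rA = sps.rankdata(A, method="ordinal")
        keep = (rM >= loM) & (rM <= n + 1 - loM) & \
            (rA >= loA) & (rA <= n + 1 - loA)
        if keep.sum() == 0 or not np.isfinite(v[keep]).all():
            factors[s] = 1.0
            continue
        f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
        factors[s] = float(2.0 ** f)
    fac = pd.Series(factors)[counts.columns]
    fac = fac / np.exp(np.log(fac).mean())
    return pd.DataFrame({"lib_size": lib, "tmm_factor": fac})


def _nb_solve_mean(y: np.ndarray, off: np.ndarray, phi: np.ndarray,
                   n_iter: int = 50) -> np.ndarray:
    """Vectorized Newton solve of the NB log-link intercept per gene.

    ``y`` is genes x samples, ``off`` per-sample log offsets, ``phi``
    per-gene dispersion. Returns beta with mu = exp(beta + off).
    """
    tot = y.sum(axis=1)
    eoff = np.exp(off)
    beta = np.log(np.maximum(tot, 0.5) / eoff.sum())
    for _ in range(n_iter):
        mu = np.exp(beta[:, None] + off[None, :])
        denom = 1.0 + phi[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + phi[:, None] * y) / denom ** 2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        r = 1.0 / np.maximum(phi[:, None], 1e-12)
        t2 = (y + r) * np.log((1.0 + phi[:, None] * y) /
                              (1.0 + phi[:, None] * mu))
    return 2.0 * (t1 - t2).sum(axis=1)


def ablation_de(counts: pd.DataFrame, factors: pd.DataFrame,
                groups: pd.Series) -> pd.DataFrame:
    """Negative-binomial quasi-likelihood DE between two sample groups.

    Per gene: Poisson fits give fitted means for a method-of-moments
    dispersion estimate, dispersions are shrunk toward the trend over
    expression strata, group and pooled means are re-fit at the shrunk
    dispersion, and the deviance drop of the group effect is referred to an
    F distribution with an empirical-Bayes-squeezed denominator. BH-adjusted
    q-values and DT-vs-mock log2 fold changes are reported.
    """
    groups = groups.reindex(counts.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("need exactly 2 groups")
    if (groups.value_counts() < 2).any():
        raise ValueError("each group needs at least 2 samples")
    ga = groups == levels[0]
    y = counts.to_numpy(dtype=float)
    off = np.log(factors["lib_size"].to_numpy() *
                 factors["tmm_factor"].to_numpy())
    n, p = y.shape[1], 2
    zero_phi = np.zeros(y.shape[0])

    def group_mu(phi):
        mu = np.empty_like(y)
        betas = {}
        for lev, mask in ((levels[0], ga.to_numpy()),
                          (levels[1], (~ga).to_numpy())):
            b = _nb_solve_mean(y[:, mask], off[mask], phi)
            mu[:, mask] = np.exp(b[:, None] + off[None, mask])
            betas[lev] = b
        return mu, betas

    # moment dispersion from the Poisson full fit
    mu0, _ = group_mu(zero_phi)
    num = ((y - mu0) ** 2 - mu0).sum(axis=1)
    den = (mu0 ** 2).sum(axis=1)
    phi_raw = np.maximum(num / np.maximum(den, 1e-12), 0.0)
    # trend over expression strata (deciles of mean count), then shrink
    mean_count = y.mean(axis=1)
    strata = pd.qcut(pd.Series(mean_count).rank(method="first"), 10,
                     labels=False)
    trend = pd.Series(phi_raw).groupby(strata).transform("mean").to_numpy()
    df_resid = n - p
    phi = (DISPERSION_PRIOR_DF * trend + df_resid * phi_raw) / \
        (DISPERSION_PRIOR_DF + df_resid)
    phi = np.maximum(phi, 1e-8)

    mu_full, betas = group_mu(phi)
    b_null = _nb_solve_mean(y, off, phi)
    mu_null = np.exp(b_null[:, None] + off[None, :])
    dev_full = _nb_deviance(y, mu_full, phi)
    dev_null = _nb_deviance(y, mu_null, phi)
    s2 = np.maximum(dev_full / df_resid, 1e-8)
    s2_0 = float(np.median(s2))
    s2_post = (QL_PRIOR_DF * s2_0 + df_resid * s2) / (QL_PRIOR_DF + df_resid)
    F = np.maximum(dev_null - dev_full, 0.0) / s2_post
    pvals = sps.f.sf(F, 1, df_resid + QL_PRIOR_DF)
    # DT vs mock orientation when those labels are present
    if set(levels) == {"DT", "mock"}:
        l2fc = (betas["DT"] - betas["mock"]) / np.log(2.0)
    else:
        l2fc = (betas[levels[0]] - betas[levels[1]]) / np.log(2.0)
    fracs = counts / counts.sum(axis=0)
    out = pd.DataFrame({
        "log2fc": l2fc,
        "p": pvals,
        "q": bh_adjust(pvals),
        "dispersion": phi,
        "max_sample_fraction": fracs.max(axis=1),
    }, index=counts.index)
    return out


def volcano_gate(results: pd.DataFrame, reference: pd.DataFrame,
                 volcano_q: float = 0.2,
                 maxexpr_min: float = 5e-6,
                 zonation_min: float = 5e-6) -> pd.DataFrame:
    """Flag genes for the volcano highlight.

    Highlighted when q < ``volcano_q``, maximal per-sample expression
    fraction > ``maxexpr_min``, and maximal six-zone reference expression >
    ``zonation_min`` (all strict). Genes absent from the reference are
    flagged False with a note.
    """
    out = results.copy()
    ref_max = reference.max(axis=1)
    out["zonation_max"] = ref_max.reindex(out.index)
    out["in_reference"] = out["zonation_max"].notna()
    out["highlight"] = (out["q"] < volcano_q) & \
        (out["max_sample_fraction"] > maxexpr_min) & \
        (out["zonation_max"].fillna(0.0) > zonation_min) & out["in_reference"]
    return out


def zone_center_of_mass(profile) -> float:
    """Expression-weighted mean zone index of a six-zone profile (1..6)."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("profile must be non-negative")
    if p.sum() <= 0:
        raise ValueError("all-zero profile")
    z = np.arange(1, p.size + 1)
    return float((z * p).sum() / p.sum())


def change_vs_zone_correlation(results: pd.DataFrame,
                               reference: pd.DataFrame,
                               volcano_q: float = 0.2,
                               maxexpr_min: float = 5e-6,
                               zonation_min: float = 5e-6) -> dict:
    """Spearman correlation of expression change with the expression zone.

    Genes passing the volcano expression gates (expression fraction and
    reference zonation; the q gate is not applied so null data keep their
    genes) contribute (zone center of mass, log2FC) pairs.
    """
    ref_max = reference.max(axis=1)
    genes = [g for g in results.index
             if results.at[g, "max_sample_fraction"] > maxexpr_min
             and ref_max.get(g, 0.0) > zonation_min]
    if len(genes) < 10:
        raise ValueError("fewer than 10 genes after gating")
    com = np.array([zone_center_of_mass(reference.loc[g]) for g in genes])
    l2fc = results.loc[genes, "log2fc"].to_numpy()
    if np.ptp(com) == 0 or np.ptp(l2fc) == 0:
        raise ValueError("constant ranks; correlation undefined")
    rho, pval = sps.spearmanr(com, l2fc)
    return {"spearman_r": float(rho), "p": float(pval), "n_genes": len(genes),
            "pairs": pd.DataFrame({"gene": genes, "zone_com": com,
                                   "log2fc": l2fc})}


def run_ablation(counts: ExpressionMatrix, reference: pd.DataFrame,
                 thresholds) -> tuple[pd.DataFrame, dict]:
    """Filter -> TMM -> DE -> volcano gate -> zone correlation."""
    if counts.unit != "UMI":
        raise ValueError("ablation counts must be raw UMI")
    groups = counts.sample_meta.loc[list(counts.samples), "condition"]
    filtered = filter_ablation_genes(counts.values,
                                     thresholds.ablation_filter_frac,
                                     thresholds.ablation_filter_samples)
    factors = tmm_factors(filtered)
    de = ablation_de(filtered, factors, groups)
    de = volcano_gate(de, reference, thresholds.volcano_q,
                      thresholds.ablation_maxexpr_min, thresholds.zonation_min)
    corr = change_vs_zone_correlation(de, reference, thresholds.volcano_q,
                                      thresholds.ablation_maxexpr_min,
                                      thresholds.zonation_min)
    return de, corr
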