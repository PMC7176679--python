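"""Stromal zonation reconstruction from laser-capture-microdissected RNA-seq.

Zone-microdissected bulk TPM samples (crypt, villus bottom/center/tip) carry
residual enterocyte transcripts. The pipeline removes the dominant
enterocyte genes identified from an epithelial zonation reference,
renormalizes to fractions, applies a second renormalization by the summed
expression of "small" genes (each below 1% of the sample) to damp remaining
highly expressed genes, and summarizes each gene as a per-zone mean +/- SEM.
The order is fixed: contaminant removal -> renormalize -> small-gene
renormalize -> zone means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ExpressionMatrix, ZonationProfile, ZONES

#: aggregation of the 6 epithelial villus zones onto the stromal villus zones
EPI_VILLUS_BINS = {"vb": (0, 1), "vc": (2, 3), "vt": (4, 5)}


def epithelial_max(reference: pd.DataFrame) -> pd.Series:
    """Per-gene maximal expression over the six epithelial zones."""
    if reference.shape[1] != 6:
        raise ValueError("epithelial reference must have 6 zone columns")
    if (reference.to_numpy() < 0).any():
        raise ValueError("epithelial reference must be non-negative")
    return reference.max(axis=1)


def identify_contaminant_genes(reference: pd.DataFrame,
                               annotation: pd.DataFrame,
                               cumulative_fraction: float = 0.5) -> list[str]:
    """Dominant enterocyte genes to strip from LCM samples.

    Genes are sorted by maximal epithelial expression (descending; ties by
    descending symbol) and the shortest prefix whose cumulative sum strictly
    exceeds ``cumulative_fraction`` of the total is taken. The returned list
    is the non-ribosomal, non-mitochondrial members of that prefix.
    """
    if reference.empty:
        raise ValueError("empty epithelial reference")
    mx = epithelial_max(reference)
    order = sorted(mx.index, key=lambda g: (-mx[g], tuple(-ord(ch) for ch in g)))
    total = float(mx.sum())
    cum = 0.0
    prefix = []
    for g in order:
        prefix.append(g)
        cum += float(mx[g])
        if cum > cumulative_fraction * total:
            break
    flags = annotation.reindex(prefix).fillna(False)
    return [g for g in prefix
            if not flags.at[g, "is_ribosomal"]
            and not flags.at[g, "is_mitochondrial"]]


def remove_and_renormalize(matrix: ExpressionMatrix,
                           contaminants) -> ExpressionMatrix:
    """Drop contaminant genes and renormalize each sample to sum 1."""
    if matrix.unit != "TPM":
        raise ValueError("expected a TPM matrix")
    kept = matrix.values.drop(index=[g for g in contaminants
                                     if g in matrix.values.index])
    sums = kept.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"samples with zero remaining expression: {bad}")
    return matrix.with_values(kept / sums, unit="fraction")


def smallgene_renormalize(matrix: ExpressionMatrix,
                          smallgene_fraction: float = 0.01) -> ExpressionMatrix:
    """Divide each sample by the summed expression of its small genes.

    A gene is "small" in a sample when it makes up less than
    ``smallgene_fraction`` of that sample's total. Applied once, not
    iterated, so the unit becomes fraction-of-small-gene mRNA (close to, but
    intentionally not exactly, a fraction summing to 1).
    """
    if matrix.unit != "fraction":
        raise ValueError("expected a fraction matrix")
    vals = matrix.values
    shares = vals / vals.sum(axis=0)
    small_sums = vals.where(shares < smallgene_fraction).sum(axis=0)
    if (small_sums <= 0).any():
        bad = list(small_sums.index[small_sums <= 0])
        raise ValueError(f"no gene below the small-gene threshold in: {bad}")
    return matrix.with_values(vals / small_sums, unit="fraction")


def compute_zonation(matrix: ExpressionMatrix) -> ZonationProfile:
    """Per-gene mean and SEM over samples of each of the four zones.

    SEM uses the n-1 sample standard deviation and is NaN (flagged) for
    zones with a single sample.
    """
    means, sems, ns = {}, {}, {}
    for zone in ZONES:
        cols = matrix.zone_samples(zone)
        if not cols:
            raise ValueError(f"no samples for zone {zone!r}")
        sub = matrix.values[cols]
        n = len(cols)
        means[zone] = sub.mean(axis=1)
        sems[zone] = sub.std(axis=1, ddof=1) / np.sqrt(n) if n >= 2 \
            else pd.Series(np.nan, index=sub.index)
        ns[zone] = n
    return ZonationProfile(pd.DataFrame(means), pd.DataFrame(sems),
                           pd.Series(ns))


def filter_zonated_genes(profile: ZonationProfile,
                         zonation_min: float = 5e-6) -> pd.Index:
    """Genes whose maximal zone mean strictly exceeds ``zonation_min``."""
    mx = profile.max_zone_mean()
    return profile.genes[mx > zonation_min]


def reconstruct_zonation(tpm: ExpressionMatrix, reference: pd.DataFrame,
                         annotation: pd.DataFrame,
                         contamination_cumulative_fraction: float = 0.5,
                         smallgene_fraction: float = 0.01) -> ZonationProfile:
    """Full LCM chain: contaminant filter, double renormalization, zone stats."""
    contaminants = identify_contaminant_genes(
        reference, annotation, contamination_cumulative_fraction)
    fracs = remove_and_renormalize(tpm, contaminants)
    fracs = smallgene_renormalize(fracs, smallgene_fraction)
    return compute_zonation(fracs)


def _epi_villus_profile(reference_row: pd.Series) -> np.ndarray:
    """Aggregate a 6-zone epithelial profile to the 3 stromal villus zones."""
    vals = reference_row.to_numpy(dtype=float)
    return np.array([vals[list(EPI_VILLUS_BINS[z])].mean()
                     for z in ("vb", "vc", "vt")])


def ligand_receptor_zonation(profile: ZonationProfile, pairs: pd.DataFrame,
                             reference: pd.DataFrame,
                             zonation_min: float = 5e-6) -> pd.DataFrame:
    """Spatial coupling of stromal genes with their epithelial partners.

    For each ligand-receptor pair with one member zonated in the stromal
    profile and the partner in the epithelial reference, reports both
    profiles, a Spearman correlation across the three aligned villus zones
    (epithelial zones averaged pairwise onto vb/vc/vt), and the stromal
    gene's home zone (argmax; 'crypt' when the crypt zone wins, otherwise
    'tip-ward').
    """
    stromal_ok = set(filter_zonated_genes(profile, zonation_min))
    epi_max = reference.max(axis=1)
    epi_ok = set(epi_max.index[epi_max > zonation_min])
    rows = []
    for _, pair in pairs.iterrows():
        for stromal, partner in ((pair["ligand"], pair["receptor"]),
                                 (pair["receptor"], pair["ligand"])):
            if stromal not in stromal_ok or partner not in epi_ok:
                continue
            sprof = profile.mean.loc[stromal]
            svillus = sprof[["vb", "vc", "vt"]].to_numpy(dtype=float)
            epi = _epi_villus_profile(reference.loc[partner])
            if np.ptp(svillus) == 0 or np.ptp(epi) == 0:
                rho = np.nan
            else:
                rho = sps.spearmanr(svillus, epi).statistic
            home = sprof.idxmax()
            rows.append({
                "stromal_gene": stromal, "epithelial_partner": partner,
                "ligand": pair["ligand"], "receptor": pair["receptor"],
                "spearman_r": rho,
                "home_zone": home,
                "zonation_class": "crypt" if home == "c" else "tip-ward",
                **{f"stromal_{z}": sprof[z] for z in ZONES},
                **{f"epi_{z}": v for z, v in zip(("vb", "vc", "vt"), epi)},
            })
    if not rows:
        raise ValueError("no pair has both members zonated")
    return pd.DataFrame(rows).drop_duplicates(
        subset=["stromal_gene", "epithelial_partner"], ignore_index=True)
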