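"""Per-cell smFISH transcript-density statistics.

Input records carry a dot count (already restricted to the first 3 µm of
the imaging z-stack upstream) and a segmented cell volume; the
concentration dots/volume is always recomputed here. Group comparisons use
the two-sided Wilcoxon rank-sum test on concentrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import wilcoxon_rank_sum

REQUIRED_COLUMNS = ("cell", "group", "dots", "volume")


def concentrations(records: pd.DataFrame) -> pd.DataFrame:
    """Attach concentration = dots / volume (mRNA per µm³) to each record."""
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    if (records["volume"] <= 0).any():
        raise ValueError("cell volumes must be positive")
    out = records.copy()
    out["concentration"] = out["dots"] / out["volume"]
    return out


def compare_groups(records: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """Wilcoxon comparison of per-cell concentrations between two groups.

    Reports the two-sided p-value plus each group's median and 25th-75th
    percentile box.
    """
    recs = concentrations(records)
    out = {}
    samples = {}
    for g in (group_a, group_b):
        conc = recs.loc[recs["group"] == g, "concentration"].to_numpy()
        if conc.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 cells")
        samples[g] = conc
        out[g] = {"n": int(conc.size), "median": float(np.median(conc)),
                  "q25": float(np.percentile(conc, 25)),
                  "q75": float(np.percentile(conc, 75)),
                  "mean": float(conc.mean())}
    out["p"] = wilcoxon_rank_sum(samples[group_a], samples[group_b])
    return out


def villi_foldchange(records: pd.DataFrame, positive_group: str,
                     negative_group: str) -> dict:
    """Ratio of mean (and, alongside, median) concentrations positive/negative."""
    recs = concentrations(records)
    pos = recs.loc[recs["group"] == positive_group, "concentration"]
    neg = recs.loc[recs["group"] == negative_group, "concentration"]
    if pos.empty or neg.empty:
        raise ValueError("both groups must be non-empty")
    if neg.mean() <= 0:
        raise ValueError("zero mean concentration in the denominator group")
    fold_means = float(pos.mean() / neg.mean())
    fold_medians = float(pos.median() / neg.median()) if neg.median() > 0 \
        else float("inf")
    return {"fold_means": fold_means, "fold_medians": fold_medians}


def percent_positive(k: int, n: int) -> int:
    """Share of positive observations as a nearest-integer percent."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return int(round(100.0 * k / n))
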