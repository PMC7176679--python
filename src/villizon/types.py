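"""Core data model: expression matrices, UMI plates, zonation profiles.

Containers are thin wrappers over pandas DataFrames so that every analysis
stage operates on plain genes x samples tables while the invariants the
pipeline relies on (non-negativity, unique symbols, labelled samples, unit
tags) are checked in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

#: stromal LCM zones along the crypt-villus axis, fixed column order
ZONES = ("c", "vb", "vc", "vt")

#: units an ExpressionMatrix may carry
UNITS = ("TPM", "fraction", "UMI", "lognorm")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with per-sample metadata.

    ``sample_meta`` is indexed by sample id and carries a ``zone`` column
    (one of c, vb, vc, vt) or a ``condition`` column (DT or mock) plus a
    ``mouse`` id.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups)[:5]}")
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("expression values must be non-negative")
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        if not ({"zone", "condition"} & set(self.sample_meta.columns)):
            raise ValueError("sample_meta needs a 'zone' or 'condition' column")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def zone_samples(self, zone: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.samples)]
        return list(meta.index[meta["zone"] == zone])

    def with_values(self, values: pd.DataFrame, unit: str | None = None
                    ) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.sample_meta, unit or self.unit)


@dataclass
class UmiCountMatrix:
    """Integer (or, after background subtraction, real) genes x wells counts.

    ``well_meta`` is indexed by a globally unique well id and carries
    ``plate`` (plate id), ``well`` (position within the plate) and
    ``is_empty`` (no-cell control well).
    """

    counts: pd.DataFrame
    well_meta: pd.DataFrame
    subtracted: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene symbols in UMI matrix")
        vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValueError("counts must be non-negative")
        if not self.subtracted and vals.size and \
                not np.allclose(vals, np.round(vals)):
            raise ValueError("raw UMI counts must be integral")
        missing = self.counts.columns.difference(self.well_meta.index)
        if len(missing):
            raise ValueError(f"wells missing from layout: {list(missing)[:5]}")
        for col in ("plate", "well", "is_empty"):
            if col not in self.well_meta.columns:
                raise ValueError(f"well_meta lacks column {col!r}")
        per_plate = self.well_meta.groupby("plate")["well"].nunique()
        sizes = self.well_meta.groupby("plate").size()
        if (per_plate != sizes).any():
            raise ValueError("well ids must be unique within a plate")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def wells(self) -> pd.Index:
        return self.counts.columns

    def empty_wells(self, plate=None) -> list[str]:
        meta = self.well_meta
        mask = meta["is_empty"].astype(bool)
        if plate is not None:
            mask &= meta["plate"] == plate
        return list(meta.index[mask])

    def plates(self) -> list:
        return list(pd.unique(self.well_meta["plate"]))


@dataclass
class ZonationProfile:
    """Per-gene mean and SEM across the four stromal zones.

    ``sem`` is NaN where a zone has a single sample (flagged in
    ``sem_defined``); units are fraction of sample mRNA after the
    contamination and small-gene renormalizations.
    """

    mean: pd.DataFrame   # genes x ZONES
    sem: pd.DataFrame    # genes x ZONES, NaN where n == 1
    n: pd.Series         # samples per zone
    sem_defined: pd.Series = field(default=None)  # per zone, n >= 2

    def __post_init__(self):
        self.mean = self.mean.reindex(columns=list(ZONES))
        self.sem = self.sem.reindex(columns=list(ZONES))
        if self.sem_defined is None:
            self.sem_defined = self.n >= 2
        if (self.mean.to_numpy() < 0).any():
            raise ValueError("zonation means must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.mean.index

    def max_zone_mean(self) -> pd.Series:
        return self.mean.max(axis=1)


@dataclass(frozen=True)
class PipelineThresholds:
    """Every numeric threshold used by the pipeline, in one place.

    Defaults are the values the analysis is defined with; a run serializes
    the instance it used so results are reproducible.
    """

    contamination_cumulative_fraction: float = 0.5
    smallgene_fraction: float = 0.01
    zonation_min: float = 5e-6
    umi_min: float = 400
    umi_max: float = 8000
    genes_min: int = 250
    lognorm_scale: float = 10000.0
    vargene_mean_lo: float = 0.25
    vargene_mean_hi: float = 4.0
    vargene_disp_lo_main: float = 0.5
    vargene_disp_lo_recluster: float = 1.0
    pcs_main: int = 11
    resolution_main: float = 2.0
    pcs_recluster: int = 5
    resolution_recluster: float = 0.7
    pdgfra_cluster_mean_min: float = 1e-4
    marker_min_pct: float = 0.2
    marker_min_logfc: float = 0.25
    concise_min_expr: float = 5e-6
    concise_min_cells: int = 10
    concise_top_n: int = 20
    concise_min_fold: float = 5.0
    de_min_expr: float = 1e-5
    de_min_pos_cells: int = 5
    volcano_q: float = 0.2
    volcano_fold: float = 2.0
    ablation_filter_frac: float = 1e-5
    ablation_filter_samples: int = 2
    ablation_maxexpr_min: float = 5e-6
    il18r1_min_expr: float = 5e-5
    il18r1_top_n: int = 200
    smfish_z_depth: float = 3.0  # µm, provenance only

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")

    def override(self, **kwargs) -> "PipelineThresholds":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown threshold overrides: {sorted(unknown)}")
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
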