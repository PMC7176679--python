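"""Synthetic study-condition generator with planted ground truth.

Emulates the statistical structure every pipeline stage assumes: a six-zone
epithelial reference dominated by a handful of enterocyte genes; zone-
microdissected stromal TPM samples contaminated by that epithelial program;
384-well plate UMI matrices with ambient background, four empty control
wells per plate, four planted mesenchymal cell types (crypt telocytes,
villus tip telocytes, myofibroblasts, mesothelial-like cells) with
zone-specific marker modules and a planted Lgr5+ configuration (10 positive
cells, 7 in the VTT type); ablation bulk counts where tip genes are
repressed; and per-cell smFISH dot tables. Every planted quantity is
recorded in a serializable truth object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import parse_sample_ids
from .types import ExpressionMatrix, UmiCountMatrix, ZONES

CELL_TYPES = ("crypt_telocyte", "VTT", "myofibroblast", "mesothelial")
HOME_ZONES = {"crypt_telocyte": "c", "myofibroblast": "vb",
              "mesothelial": "vc", "VTT": "vt"}

#: named genes planted into the universe
LINEAGE_GENES = ("Epcam", "Ptprc", "Pdgfra", "Lgr5")
DOMINANT_GENES = ("Fabp1", "Alb", "Apoa1", "Reg3g", "Gsta1")
DOMINANT_RIBO = ("Rps29x",)  # ribosomal-prefixed dominant, exercises the filter
TIP_MODULE_NAMED = ("Ada", "Nt5e", "Slc28a2")


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_genes: int = 2000
    n_mice: int = 5
    crypt_mice: int = 3                  # crypt samples exist for 3 of 5 mice
    cells_per_type: int = 100
    n_bycatch_epithelial: int = 50
    n_bycatch_immune: int = 50
    n_plates: int = 2
    depth_log_mean: float = float(np.log(2000.0))
    depth_log_sd: float = 0.35
    depth_min: int = 600                 # bounded away from the QC gates
    depth_max: int = 6500
    contamination_fraction: float = 0.3  # enterocyte share of an LCM sample
    lcm_noise_sd: float = 0.3            # multiplicative lognormal noise
    n_markers_per_type: int = 30
    marker_fold: float = 16.0            # planted fold over the other types
    n_ribosomal: int = 40
    n_mito: int = 13
    mito_fraction: float = 0.05
    ambient_total: float = 30.0          # expected ambient UMIs per well
    dominant_total_share: float = 0.55   # dominant genes' share of summed max
    home_zone_weight: float = 0.7        # zone mixing weight of the home type
    n_lr_pairs: int = 10
    ablation_slope: float = 0.5          # log2FC lost per zone of the CoM
    ablation_offset: float = 3.5
    ablation_noise_sd: float = 0.25
    ablation_dispersion: float = 0.05
    ablation_depth: float = 1e6
    n_strong_repressed: int = 30         # tip genes with planted log2FC = -2
    strong_log2fc: float = -2.0
    smfish_volume_log_mean: float = float(np.log(300.0))
    smfish_volume_log_sd: float = 0.3

    def validate(self) -> None:
        for name in ("n_genes", "n_mice", "cells_per_type", "n_plates",
                     "ambient_total", "ablation_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Everything planted by the generators, serializable beside the data."""

    seed: int
    cell_types: tuple = CELL_TYPES
    home_zones: dict = field(default_factory=lambda: dict(HOME_ZONES))
    markers: dict = field(default_factory=dict)        # type -> [genes]
    contaminant_genes: list = field(default_factory=list)   # non-ribo/mito
    dominant_genes: list = field(default_factory=list)      # full prefix
    lgr5_cells: dict = field(default_factory=dict)     # cell id -> type
    cell_labels: dict = field(default_factory=dict)    # cell id -> type/lineage
    ablation_effects: dict = field(default_factory=dict)    # gene -> log2FC
    strong_repressed: list = field(default_factory=list)
    plate_background_rates: dict = field(default_factory=dict)
    lr_true_pairs: list = field(default_factory=list)  # correlated pairs
    genes: list = field(default_factory=list)
    programs: dict = field(default_factory=dict, repr=False)  # runtime only

    def __post_init__(self):
        all_markers = [g for t in self.markers for g in self.markers[t]]
        if len(all_markers) != len(set(all_markers)):
            raise ValueError("marker sets must be disjoint across types")
        if set(self.contaminant_genes) & set(all_markers):
            raise ValueError("contaminants must be disjoint from markers")

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload.pop("programs")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["cell_types"] = tuple(payload["cell_types"])
        return cls(**payload)


def _gene_universe(params: GeneratorParams) -> list[str]:
    n = params.n_genes
    named = (list(LINEAGE_GENES) + list(DOMINANT_GENES) + list(DOMINANT_RIBO)
             + list(TIP_MODULE_NAMED)
             + [f"Rps{i+1}" for i in range(params.n_ribosomal // 2)]
             + [f"Rpl{i+1}" for i in range(params.n_ribosomal
                                           - params.n_ribosomal // 2)]
             + [f"mt-{i+1:02d}" for i in range(params.n_mito)])
    if n <= len(named):
        raise ValueError("n_genes too small for the named gene set")
    fillers = [f"Gene{i+1:04d}" for i in range(n - len(named))]
    return named + fillers


def _stromal_programs(genes: list[str], params: GeneratorParams,
                      rng: np.random.Generator
                      ) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Type-specific multinomial programs and disjoint marker assignments."""
    idx = {g: i for i, g in enumerate(genes)}
    fillers = [g for g in genes if g.startswith("Gene")]
    base = rng.lognormal(0.0, 1.0, size=len(genes))
    # silence planted special genes in the shared baseline
    for g in LINEAGE_GENES + DOMINANT_GENES + DOMINANT_RIBO:
        base[idx[g]] = 0.0
    mt_mask = np.array([g.startswith("mt-") for g in genes])
    markers: dict[str, list[str]] = {}
    pool = list(fillers)
    for t, lo in zip(CELL_TYPES, range(0, 4 * params.n_markers_per_type,
                                       params.n_markers_per_type)):
        markers[t] = pool[lo:lo + params.n_markers_per_type]
    programs = {}
    for t in CELL_TYPES:
        prog = base.copy()
        for g in markers[t]:
            prog[idx[g]] *= params.marker_fold
        # modest housekeeping for the other types' markers is already in base
        prog[idx["Pdgfra"]] = 0.0  # set after normalization below
        prog = prog / prog.sum()
        # reserve fixed fractions for the gate genes and mitochondria
        pdgfra_frac = 8e-4
        mito_target = params.mito_fraction * (1 + 0.2 * rng.standard_normal())
        mito_target = float(np.clip(mito_target, 0.02, 0.10))
        prog[mt_mask] = 0.0
        prog = prog / prog.sum() * (1.0 - pdgfra_frac - mito_target)
        prog[idx["Pdgfra"]] = pdgfra_frac
        prog[mt_mask] = mito_target / mt_mask.sum()
        programs[t] = prog
    # bycatch lineages
    epi = base.copy()
    epi[[idx[g] for g in DOMINANT_GENES + DOMINANT_RIBO]] = base.max() * 4
    epi[idx["Epcam"]] = 0.0
    epi = epi / epi.sum()
    epi[mt_mask] = 0.0
    epi = epi / epi.sum() * (1.0 - 2e-3 - params.mito_fraction)
    epi[idx["Epcam"]] = 2e-3
    epi[mt_mask] = params.mito_fraction / mt_mask.sum()
    imm = rng.lognormal(0.0, 1.0, size=len(genes))
    for g in LINEAGE_GENES + DOMINANT_GENES + DOMINANT_RIBO:
        imm[idx[g]] = 0.0
    imm = imm / imm.sum()
    imm[mt_mask] = 0.0
    imm = imm / imm.sum() * (1.0 - 2e-3 - params.mito_fraction)
    imm[idx["Ptprc"]] = 2e-3
    imm[mt_mask] = params.mito_fraction / mt_mask.sum()
    programs["epithelial_bycatch"] = epi
    programs["immune_bycatch"] = imm
    return programs, markers


def make_truth(params: GeneratorParams | None = None,
               seed: int = 0) -> SyntheticTruth:
    """Build the planted truth (programs, markers, contaminants) for a seed."""
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng([seed, 101])
    genes = _gene_universe(params)
    programs, markers = _stromal_programs(genes, params, rng)
    return SyntheticTruth(
        seed=seed,
        markers=markers,
        contaminant_genes=list(DOMINANT_GENES),
        dominant_genes=list(DOMINANT_GENES + DOMINANT_RIBO),
        genes=genes,
        programs={k: v.tolist() for k, v in programs.items()},
    )


def _program(truth: SyntheticTruth, name: str) -> np.ndarray:
    return np.asarray(truth.programs[name], dtype=float)


def gen_epithelial_reference(truth: SyntheticTruth,
                             params: GeneratorParams | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Six-zone enterocyte reference with planted dominant genes.

    A configurable set of dominant genes jointly owns
    ``dominant_total_share`` of the summed per-gene maxima (in equal
    shares), so the contamination filter's >50% prefix is exactly that set.
    Tip-induced genes, including the named purine-module genes, have
    monotone increasing profiles.
    """
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng([seed, 202])
    genes = truth.genes
    n = len(genes)
    base = rng.lognormal(0.0, 1.0, size=n)
    kind = rng.choice(3, size=n, p=[0.25, 0.25, 0.5])  # up, down, flat
    prof = np.empty((n, 6))
    zone_idx = np.arange(6)
    for i in range(n):
        if kind[i] == 0:
            r = rng.uniform(1.3, 1.9)
            shape = r ** zone_idx
        elif kind[i] == 1:
            r = rng.uniform(1.3, 1.9)
            shape = r ** zone_idx[::-1]
        else:
            shape = np.exp(0.15 * rng.standard_normal(6))
        prof[i] = base[i] * shape / shape.max()
    gi = {g: j for j, g in enumerate(genes)}
    for g in TIP_MODULE_NAMED:  # strictly increasing tip module
        r = rng.uniform(1.5, 1.9)
        prof[gi[g]] = base[gi[g]] * (r ** zone_idx) / (r ** 5)
    dom = list(truth.dominant_genes)
    dom_rows = [gi[g] for g in dom]
    prof[dom_rows] = 0.0
    rest_total = prof.max(axis=1).sum()
    share = params.dominant_total_share
    if dom:
        m = share * rest_total / (len(dom) * (1.0 - share))
        # tiny descending offsets keep the sort order among dominants stable
        for rank, row in enumerate(dom_rows):
            prof[row] = m * (1.0 - 1e-3 * rank)
    return pd.DataFrame(prof, index=genes,
                        columns=[f"z{i+1}" for i in range(6)])


def stromal_zone_profiles(truth: SyntheticTruth,
                          params: GeneratorParams | None = None
                          ) -> pd.DataFrame:
    """Expected stromal fraction profile of each LCM zone (genes x zones)."""
    params = params or GeneratorParams()
    w_home = params.home_zone_weight
    w_off = (1.0 - w_home) / 3.0
    cols = {}
    for z in ZONES:
        mix = np.zeros(len(truth.genes))
        for t in CELL_TYPES:
            w = w_home if truth.home_zones[t] == z else w_off
            mix = mix + w * _program(truth, t)
        cols[z] = mix / mix.sum()
    return pd.DataFrame(cols, index=truth.genes)


def gen_lcm_samples(truth: SyntheticTruth, reference: pd.DataFrame,
                    params: GeneratorParams | None = None,
                    seed: int = 0) -> ExpressionMatrix:
    """Zone x mouse LCM TPM samples with enterocyte contamination.

    Each sample is (1 - f) x zone-specific stromal mixture + f x epithelial
    contamination, under multiplicative lognormal noise, scaled to TPM.
    Crypt samples exist only for the first ``crypt_mice`` mice.
    """
    params = params or GeneratorParams()
    params.validate()
    f = params.contamination_fraction
    rng = np.random.default_rng([seed, 303])
    stromal = stromal_zone_profiles(truth, params)
    # epithelial contamination profiles aligned to the stromal zones
    epi_cols = {"c": ["z1"], "vb": ["z2", "z3"], "vc": ["z4", "z5"],
                "vt": ["z6"]}
    data = {}
    for z in ZONES:
        epi = reference[epi_cols[z]].mean(axis=1).to_numpy()
        epi = epi / epi.sum()
        mean = (1.0 - f) * stromal[z].to_numpy() + f * epi
        mice = range(1, (params.crypt_mice if z == "c" else params.n_mice) + 1)
        for m in mice:
            noisy = mean * np.exp(params.lcm_noise_sd *
                                  rng.standard_normal(mean.size))
            data[f"{z}_m{m}"] = 1e6 * noisy / noisy.sum()
    values = pd.DataFrame(data, index=truth.genes)
    return ExpressionMatrix(values, parse_sample_ids(values.columns), "TPM")


def gen_plate_umis(truth: SyntheticTruth,
                   params: GeneratorParams | None = None,
                   seed: int = 0) -> UmiCountMatrix:
    """Plate-structured UMI counts with ambient background and empty wells.

    Cell wells draw a multinomial from their type program at a lognormal
    depth bounded away from the QC gates; every well additionally receives
    Poisson ambient counts at per-plate rates; four wells per plate are
    empty controls. Ten cells carry Lgr5 counts, seven of them in the VTT
    type; the ambient Lgr5 rate is zero so the planted configuration is
    exact. Updates ``truth.lgr5_cells``, ``truth.cell_labels`` and
    ``truth.plate_background_rates`` in place.
    """
    params = params or GeneratorParams()
    params.validate()
    if params.cells_per_type <= 0:
        raise ValueError("cells_per_type must be positive")
    rng = np.random.default_rng([seed, 404])
    genes = truth.genes
    gi = {g: i for i, g in enumerate(genes)}
    labels = ([t for t in CELL_TYPES for _ in range(params.cells_per_type)]
              + ["epithelial_bycatch"] * params.n_bycatch_epithelial
              + ["immune_bycatch"] * params.n_bycatch_immune)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n_cells = len(labels)
    # ambient profile per plate: epithelial-tinged mixture with jitter
    ambient_base = 0.5 * _program(truth, "epithelial_bycatch") + \
        0.5 * np.mean([_program(truth, t) for t in CELL_TYPES], axis=0)
    ambient_base[gi["Lgr5"]] = 0.0
    counts = {}
    meta = {}
    truth.cell_labels = {}
    per_plate = int(np.ceil(n_cells / params.n_plates))
    for p in range(params.n_plates):
        plate = f"P{p+1}"
        jitter = np.exp(0.2 * rng.standard_normal(len(genes)))
        rates = ambient_base * jitter
        rates[gi["Lgr5"]] = 0.0
        rates = params.ambient_total * rates / rates.sum()
        truth.plate_background_rates[plate] = np.round(rates, 6).tolist()
        plate_cells = labels[p * per_plate:(p + 1) * per_plate]
        for w, lab in enumerate(plate_cells):
            uid = f"{plate}:W{w+1:03d}"
            depth = int(np.clip(rng.lognormal(params.depth_log_mean,
                                              params.depth_log_sd),
                                params.depth_min, params.depth_max))
            vec = rng.multinomial(depth, _program(truth, lab))
            vec = vec + rng.poisson(rates)
            counts[uid] = vec
            meta[uid] = {"plate": plate, "well": f"W{w+1:03d}",
                         "is_empty": False}
            truth.cell_labels[uid] = lab
        for e in range(4):
            uid = f"{plate}:E{e+1:02d}"
            counts[uid] = rng.poisson(rates)
            meta[uid] = {"plate": plate, "well": f"E{e+1:02d}",
                         "is_empty": True}
    # plant the Lgr5+ configuration: 7 VTT cells, 1 of each other type
    truth.lgr5_cells = {}
    by_type = {t: [c for c, lab in truth.cell_labels.items() if lab == t]
               for t in CELL_TYPES}
    chosen = list(rng.choice(by_type["VTT"], size=min(7, len(by_type["VTT"])),
                             replace=False))
    for t in CELL_TYPES:
        if t == "VTT":
            continue
        if by_type[t]:
            chosen.append(str(rng.choice(by_type[t])))
    for c in chosen:
        counts[c][gi["Lgr5"]] += rng.poisson(3) + 2
        truth.lgr5_cells[c] = truth.cell_labels[c]
    mat = pd.DataFrame(counts, index=genes).astype(np.int64)
    return UmiCountMatrix(mat, pd.DataFrame.from_dict(meta, orient="index"))


def gen_ablation_counts(truth: SyntheticTruth, reference: pd.DataFrame,
                        params: GeneratorParams | None = None,
                        seed: int = 0) -> ExpressionMatrix:
    """Bulk UMI counts for 4 mock and 4 DT samples after VTT ablation.

    The DT mean of each gene is scaled by 2^effect with effect =
    -slope * (zone center of mass - offset) + noise, so tip genes are
    repressed; a planted set of strongly repressed tip genes (including the
    named purine-module genes) gets exactly ``strong_log2fc``. Counts are
    negative binomial. Effects are recorded in ``truth.ablation_effects``.
    """
    params = params or GeneratorParams()
    params.validate()
    if params.ablation_dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng([seed, 505])
    ref = reference.loc[[g for g in truth.genes if g in reference.index]]
    prof = ref.to_numpy()
    totals = prof.sum(axis=1)
    ok = totals > 0
    com = np.full(len(ref), 3.5)
    z = np.arange(1, 7)
    com[ok] = (prof[ok] * z).sum(axis=1) / totals[ok]
    base = ref.mean(axis=1).to_numpy()
    base = base / base.sum()
    effect = -params.ablation_slope * (com - params.ablation_offset) + \
        params.ablation_noise_sd * rng.standard_normal(len(ref))
    strong = []
    if params.n_strong_repressed > 0:
        tip_rank = np.argsort(-com)
        pool = [ref.index[i] for i in tip_rank[:max(
            params.n_strong_repressed * 3, params.n_strong_repressed)]]
        named = [g for g in TIP_MODULE_NAMED if g in ref.index]
        strong = list(dict.fromkeys(
            named + pool))[:params.n_strong_repressed]
        gi = {g: i for i, g in enumerate(ref.index)}
        for g in strong:
            effect[gi[g]] = params.strong_log2fc
    truth.strong_repressed = list(strong)
    truth.ablation_effects = {g: float(e) for g, e in zip(ref.index, effect)}
    data = {}
    r = 1.0 / params.ablation_dispersion
    for cond, scale in (("mock", np.ones(len(ref))),
                        ("DT", 2.0 ** effect)):
        for s in range(1, 5):
            depth = params.ablation_depth * rng.uniform(0.8, 1.2)
            mu = np.maximum(base * scale * depth, 1e-8)
            data[f"{cond}_{s}"] = rng.negative_binomial(r, r / (r + mu))
    values = pd.DataFrame(data, index=ref.index)
    return ExpressionMatrix(values, parse_sample_ids(values.columns), "UMI")


def gen_smfish_table(groups: dict[str, tuple[int, float]] | None = None,
                     params: GeneratorParams | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Per-cell smFISH dot counts: Poisson(density x volume) per group.

    ``groups`` maps a label to (n cells, dot density per µm³); the default
    emulates a control vs ablated comparison at 30 cells per group.
    """
    params = params or GeneratorParams()
    groups = groups or {"Ctrl": (30, 0.10), "DT": (30, 0.05)}
    rng = np.random.default_rng([seed, 606])
    rows = []
    for label, (n, density) in groups.items():
        if density <= 0:
            raise ValueError("dot density must be positive")
        vols = rng.lognormal(params.smfish_volume_log_mean,
                             params.smfish_volume_log_sd, size=n)
        dots = rng.poisson(density * vols)
        for i in range(n):
            rows.append({"cell": f"{label}_{i+1:03d}", "group": label,
                         "dots": int(dots[i]), "volume": float(vols[i])})
    return pd.DataFrame(rows)


def gen_lr_pairs(truth: SyntheticTruth, reference: pd.DataFrame,
                 params: GeneratorParams | None = None) -> pd.DataFrame:
    """Ligand-receptor pair list with planted spatially correlated pairs.

    VTT markers are paired with monotone tip-increasing epithelial genes
    (correlated along the villus); crypt-telocyte markers with the same
    partners serve as anti-correlated decoys. The planted correlated pairs
    are recorded in ``truth.lr_true_pairs``.
    """
    params = params or GeneratorParams()
    n = params.n_lr_pairs
    all_markers = {g for t in truth.markers for g in truth.markers[t]}
    rising = [g for g in reference.index
              if g.startswith("Gene") and g not in all_markers
              and reference.loc[g].is_monotonic_increasing][:n]
    vtt = truth.markers["VTT"][:n]
    crypt = truth.markers["crypt_telocyte"][:n]
    pairs = [{"ligand": lig, "receptor": rec} for lig, rec in zip(vtt, rising)]
    truth.lr_true_pairs = [(p["ligand"], p["receptor"]) for p in pairs]
    pairs += [{"ligand": lig, "receptor": rec}
              for lig, rec in zip(crypt, rising)]
    return pd.DataFrame(pairs)
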