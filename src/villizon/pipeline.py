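"""Stage orchestration shared by the CLI and scripted runs.

Each stage is a pure function of (inputs, thresholds, seed) writing TSV/JSON
outputs; ``run_all`` chains simulate -> lcm -> scrna -> map -> de ->
ablation -> smfish on synthetic inputs and returns the run report.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ablation, io, lcm, mapping, scrna, smfish, stats
from . import synthetic
from .types import ExpressionMatrix, PipelineThresholds


def simulate(params: synthetic.GeneratorParams | None, seed: int,
             outdir: Path) -> synthetic.SyntheticTruth:
    """Generate every synthetic input plus the truth JSON into ``outdir``."""
    params = params or synthetic.GeneratorParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = synthetic.make_truth(params, seed)
    reference = synthetic.gen_epithelial_reference(truth, params, seed)
    reference.to_csv(outdir / "epithelial_reference.tsv", sep="\t",
                     index_label="gene")
    lcm_mat = synthetic.gen_lcm_samples(truth, reference, params, seed)
    io.write_expression_table(lcm_mat, outdir / "lcm_tpm.tsv")
    umis = synthetic.gen_plate_umis(truth, params, seed)
    io.write_umi_matrix(umis, outdir / "umis.mtx", outdir / "plate_layout.csv")
    abl = synthetic.gen_ablation_counts(truth, reference, params, seed)
    io.write_expression_table(abl, outdir / "ablation_counts.tsv")
    synthetic.gen_smfish_table(None, params, seed).to_csv(
        outdir / "smfish.csv", index=False)
    synthetic.gen_lr_pairs(truth, reference, params).to_csv(
        outdir / "lr_pairs.csv", index=False)
    truth.to_json(outdir / "truth.json")
    return truth


def lcm_stage(tpm: ExpressionMatrix, reference: pd.DataFrame,
              pairs: pd.DataFrame | None,
              thresholds: PipelineThresholds, outdir: Path | None = None
              ) -> dict:
    """Contamination filter, double renormalization, zonation, pair table."""
    annotation = io.build_gene_annotation(tpm.genes)
    contaminants = lcm.identify_contaminant_genes(
        reference, annotation, thresholds.contamination_cumulative_fraction)
    fracs = lcm.remove_and_renormalize(tpm, contaminants)
    fracs = lcm.smallgene_renormalize(fracs, thresholds.smallgene_fraction)
    profile = lcm.compute_zonation(fracs)
    zonated = lcm.filter_zonated_genes(profile, thresholds.zonation_min)
    out = {"contaminants": contaminants, "profile": profile,
           "zonated_genes": zonated}
    if pairs is not None:
        try:
            out["pair_table"] = lcm.ligand_receptor_zonation(
                profile, pairs, reference, thresholds.zonation_min)
        except ValueError:
            out["pair_table"] = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tab = pd.concat({"mean": profile.mean, "sem": profile.sem}, axis=1)
        tab.columns = [f"{a}_{z}" for a, z in tab.columns]
        tab.to_csv(outdir / "zonation.tsv", sep="\t", index_label="gene")
        if out.get("pair_table") is not None:
            out["pair_table"].to_csv(outdir / "lr_zonation.tsv", sep="\t",
                                     index=False)
    return out


def scrna_stage(umis, thresholds: PipelineThresholds, seed: int,
                outdir: Path | None = None) -> scrna.ScrnaResult:
    result = scrna.run_scrna(umis, thresholds, seed=seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.qc.to_csv(outdir / "cell_qc.tsv", sep="\t", index_label="cell")
        result.assignment_table().to_csv(outdir / "clusters.tsv", sep="\t",
                                         index_label="cell")
    return result


def map_stage(result: scrna.ScrnaResult, profile,
              thresholds: PipelineThresholds,
              outdir: Path | None = None) -> dict:
    """Markers, concise marker sets, zone mapping and Lgr5 enrichment."""
    mes = result.mesenchymal_cells
    sub = result.subclusters
    lognorm = result.lognorm[mes]
    fracs = result.fractions[mes]
    markers = mapping.find_cluster_markers(lognorm, sub,
                                           thresholds.marker_min_pct,
                                           thresholds.marker_min_logfc)
    concise = mapping.select_concise_markers(fracs, fracs, sub, thresholds)
    zone_map = mapping.map_clusters_to_zones(concise, profile)
    lgr5_pos = [c for c in mes if result.fractions.at["Lgr5", c] > 0] \
        if "Lgr5" in result.fractions.index else []
    enrichment = None
    if lgr5_pos:
        target = sub.loc[lgr5_pos].mode().iloc[0]
        enrichment = mapping.gene_cluster_enrichment(sub, lgr5_pos, target)
    out = {"markers": markers, "concise": concise, "zone_map": zone_map,
           "lgr5_positive": lgr5_pos, "enrichment": enrichment}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        markers.to_csv(outdir / "cluster_markers.tsv", sep="\t", index=False)
        zone_map.to_csv(outdir / "zone_mapping.tsv", sep="\t",
                        index_label="subcluster")
        if enrichment is not None:
            with open(outdir / "lgr5_enrichment.json", "w") as fh:
                json.dump(enrichment.as_dict(), fh, indent=1)
    return out


def de_stage(result: scrna.ScrnaResult, zone_map: pd.DataFrame,
             thresholds: PipelineThresholds,
             outdir: Path | None = None) -> pd.DataFrame | None:
    """Crypt-telocyte vs villus-tip-telocyte differential expression.

    The clusters mapped to the crypt and villus-tip zones are compared;
    returns None when either zone has no uniquely mapped cluster.
    """
    sub = result.subclusters
    by_zone = {z: list(zone_map.index[zone_map["home_zone"] == z])
               for z in ("vt", "c")}
    if len(by_zone["vt"]) != 1 or len(by_zone["c"]) != 1:
        return None
    mes = result.mesenchymal_cells
    cells_vt = [c for c in mes if sub.loc[c] == by_zone["vt"][0]]
    cells_c = [c for c in mes if sub.loc[c] == by_zone["c"][0]]
    raw = result.fractions[mes]  # positivity: fraction > 0 iff count > 0
    de = stats.two_group_de(result.fractions[mes], raw, cells_vt, cells_c,
                            thresholds.de_min_expr,
                            thresholds.de_min_pos_cells,
                            thresholds.volcano_q, thresholds.volcano_fold)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        de.to_csv(outdir / "vtt_vs_crypt_de.tsv", sep="\t",
                  index_label="gene")
    return de


def ablation_stage(counts: ExpressionMatrix, reference: pd.DataFrame,
                   thresholds: PipelineThresholds,
                   outdir: Path | None = None) -> tuple[pd.DataFrame, dict]:
    de, corr = ablation.run_ablation(counts, reference, thresholds)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        de.to_csv(outdir / "ablation_de.tsv", sep="\t", index_label="gene")
        with open(outdir / "zone_correlation.json", "w") as fh:
            json.dump({k: v for k, v in corr.items() if k != "pairs"},
                      fh, indent=1)
    return de, corr


def smfish_stage(records: pd.DataFrame, outdir: Path | None = None) -> dict:
    groups = list(pd.unique(records["group"]))
    if len(groups) < 2:
        raise ValueError("smFISH table needs at least two groups")
    comparison = smfish.compare_groups(records, groups[0], groups[1])
    fold = smfish.villi_foldchange(records, groups[0], groups[1])
    out = {"groups": groups[:2], "comparison": comparison, "fold": fold}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "smfish_comparison.json", "w") as fh:
            json.dump(out, fh, indent=1)
    return out


def run_all(params: synthetic.GeneratorParams | None = None,
            thresholds: PipelineThresholds | None = None,
            seed: int = 0, outdir: Path | None = None) -> dict:
    """Full pipeline on default synthetic inputs; returns the run report."""
    params = params or synthetic.GeneratorParams()
    thresholds = thresholds or PipelineThresholds()
    truth = synthetic.make_truth(params, seed)
    reference = synthetic.gen_epithelial_reference(truth, params, seed)
    tpm = synthetic.gen_lcm_samples(truth, reference, params, seed)
    umis = synthetic.gen_plate_umis(truth, params, seed)
    abl_counts = synthetic.gen_ablation_counts(truth, reference, params, seed)
    fish = synthetic.gen_smfish_table(None, params, seed)
    pairs = synthetic.gen_lr_pairs(truth, reference, params)

    lcm_out = lcm_stage(tpm, reference, pairs, thresholds, outdir)
    sc = scrna_stage(umis, thresholds, seed, outdir)
    map_out = map_stage(sc, lcm_out["profile"], thresholds, outdir)
    de = de_stage(sc, map_out["zone_map"], thresholds, outdir)
    abl_de, corr = ablation_stage(abl_counts, reference, thresholds, outdir)
    fish_out = smfish_stage(fish, outdir)

    zone_map = map_out["zone_map"]
    report = {
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "thresholds": thresholds.as_dict(),
        "n_cells_pass_qc": int(sc.qc.shape[0]),
        "n_mesenchymal": len(sc.mesenchymal_cells),
        "n_subclusters": int(sc.subclusters.nunique())
        if sc.subclusters is not None else 0,
        "populations": [
            {"subcluster": int(cid),
             "home_zone": zone_map.at[cid, "home_zone"],
             "tie": bool(zone_map.at[cid, "tie"]),
             "n_markers": int(zone_map.at[cid, "n_markers"]),
             "n_cells": int((sc.subclusters == cid).sum())}
            for cid in zone_map.index
        ],
        "lgr5_enrichment": map_out["enrichment"].as_dict()
        if map_out["enrichment"] else None,
        "n_de_genes_tested": int(de.shape[0]) if de is not None else 0,
        "n_de_volcano_hits": int(de["volcano"].sum()) if de is not None else 0,
        "ablation": {"spearman_r": corr["spearman_r"], "p": corr["p"],
                     "n_genes": corr["n_genes"]},
        "smfish": {"p": fish_out["comparison"]["p"],
                   "fold_means": fish_out["fold"]["fold_means"]},
        "truth_home_zones": truth.home_zones,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report
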