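"""Plate-based single-cell processing: hand oracles, gates and recovery."""

import numpy as np
import pandas as pd
import pytest

from villizon import scrna
from villizon.types import PipelineThresholds, UmiCountMatrix


def _plate(counts_dict, empties):
    counts = pd.DataFrame(counts_dict)
    meta = pd.DataFrame({
        "plate": ["P1"] * len(counts.columns),
        "well": [c.split(":")[1] for c in counts.columns],
        "is_empty": [c in empties for c in counts.columns]},
        index=list(counts.columns))
    return UmiCountMatrix(counts, meta)


class TestBackgroundSubtraction:
    def test_mean_of_empties_subtracted(self):
        umis = _plate({"P1:W1": [3], "P1:E1": [1], "P1:E2": [1],
                       "P1:E3": [1], "P1:E4": [1]},
                      {"P1:E1", "P1:E2", "P1:E3", "P1:E4"})
        out = scrna.subtract_plate_background(umis)
        assert out.counts.loc[0, "P1:W1"] == pytest.approx(2.0)

    def test_negatives_clipped_to_zero(self):
        umis = _plate({"P1:W1": [0], "P1:E1": [1]}, {"P1:E1"})
        out = scrna.subtract_plate_background(umis)
        assert out.counts.loc[0, "P1:W1"] == 0.0

    def test_zero_background_only_drops_empties(self):
        umis = _plate({"P1:W1": [5], "P1:W2": [2], "P1:E1": [0]}, {"P1:E1"})
        out = scrna.subtract_plate_background(umis)
        assert list(out.wells) == ["P1:W1", "P1:W2"]
        assert (out.counts.to_numpy() == [[5, 2]]).all()

    def test_no_empty_wells_rejected(self):
        umis = _plate({"P1:W1": [5]}, set())
        with pytest.raises(ValueError, match="empty"):
            scrna.subtract_plate_background(umis)

    def test_never_increases_counts(self, umis0):
        out = scrna.subtract_plate_background(umis0)
        common = out.wells
        assert (out.counts.to_numpy() <=
                umis0.counts[common].to_numpy()).all()
        assert out.counts.to_numpy().sum() <= umis0.counts.to_numpy().sum()


class TestQcGates:
    def _qc(self, umi, genes):
        return pd.DataFrame({"total_umi": umi, "n_genes": genes,
                             "mito_fraction": [0.05] * len(umi)},
                            index=[f"c{i}" for i in range(len(umi))])

    @pytest.mark.parametrize("umi,kept", [(399, False), (400, True),
                                          (8000, True), (8001, False)])
    def test_umi_boundaries_strict(self, umi, kept):
        qc = self._qc([umi, 1000], [300, 300])
        counts = pd.DataFrame(np.ones((5, 2)), columns=qc.index)
        meta = pd.DataFrame({"plate": "P1", "well": qc.index,
                             "is_empty": False}, index=qc.index)
        mat = UmiCountMatrix(counts, meta, subtracted=True)
        out, _ = scrna.qc_filter_cells(mat, qc, PipelineThresholds())
        assert ("c0" in out.wells) == kept

    @pytest.mark.parametrize("genes,kept", [(249, False), (250, True)])
    def test_gene_count_boundary_strict(self, genes, kept):
        qc = self._qc([1000, 1000], [genes, 300])
        counts = pd.DataFrame(np.ones((5, 2)), columns=qc.index)
        meta = pd.DataFrame({"plate": "P1", "well": qc.index,
                             "is_empty": False}, index=qc.index)
        mat = UmiCountMatrix(counts, meta, subtracted=True)
        out, _ = scrna.qc_filter_cells(mat, qc, PipelineThresholds())
        assert ("c0" in out.wells) == kept

    def test_mito_fraction_uses_raw_counts(self):
        raw = _plate({"P1:W1": [8, 2], "P1:E1": [0, 0]}, {"P1:E1"})
        raw.counts.index = ["Actb", "mt-01"]
        sub = scrna.subtract_plate_background(raw)
        qc = scrna.cell_qc_table(sub, raw=raw)
        assert qc.loc["P1:W1", "mito_fraction"] == pytest.approx(0.2)


class TestNormalization:
    def test_lognormalize_symbolic_values(self):
        counts = pd.DataFrame({"c1": [1.0, 0.0, 3.0]})
        out = scrna.lognormalize(counts, scale=1e4)
        np.testing.assert_allclose(
            out["c1"], [np.log(1 + 2500), 0.0, np.log(1 + 7500)])

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(5, size=(30, 4)).astype(float),
                              columns=list("abcd"))
        doubled = counts.copy()
        doubled["a"] = doubled["a"] * 2
        np.testing.assert_allclose(scrna.lognormalize(counts)["a"],
                                   scrna.lognormalize(doubled)["a"])

    def test_zero_sum_cell_rejected(self):
        counts = pd.DataFrame({"c1": [0.0, 0.0]})
        with pytest.raises(ValueError):
            scrna.lognormalize(counts)


class TestCovariateRegression:
    def _data(self, seed=0, n_cells=50, n_genes=30):
        rng = np.random.default_rng(seed)
        logn = pd.DataFrame(rng.normal(1, 0.5, size=(n_genes, n_cells)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"c{i}" for i in range(n_cells)]).abs()
        qc = pd.DataFrame({"total_umi": rng.uniform(500, 5000, n_cells),
                           "mito_fraction": rng.uniform(0, 0.2, n_cells)},
                          index=logn.columns)
        return logn, qc

    def test_residuals_orthogonal_to_covariates(self):
        logn, qc = self._data()
        resid = scrna.regress_covariates(logn, qc)
        for cov in ("total_umi", "mito_fraction"):
            c = qc[cov] - qc[cov].mean()
            corr = resid.to_numpy() @ c.to_numpy()
            assert np.abs(corr).max() < 1e-8

    def test_constant_covariates_reduce_to_scaling(self):
        logn, qc = self._data()
        qc["total_umi"] = 1000.0
        qc["mito_fraction"] = 0.1
        with pytest.warns(UserWarning):
            resid = scrna.regress_covariates(logn, qc)
        manual = logn.sub(logn.mean(axis=1), axis=0)
        manual = manual.div(manual.std(axis=1, ddof=1), axis=0)
        np.testing.assert_allclose(resid.to_numpy(), manual.to_numpy(),
                                   atol=1e-10)

    def test_perfectly_linear_gene_zero_residual(self):
        logn, qc = self._data()
        logn.iloc[0] = 0.001 * qc["total_umi"].to_numpy() + 0.3
        resid = scrna.regress_covariates(logn, qc)
        # standardized residuals of a perfect fit are numerically tiny noise
        raw = logn.iloc[0].to_numpy()
        fit = np.polyfit(qc["total_umi"], raw, 1)
        assert np.allclose(np.polyval(fit, qc["total_umi"]), raw)


class TestVariableGenes:
    def test_planted_overdispersed_recovered(self):
        """Genes overdispersed relative to same-mean Poisson background."""
        rng = np.random.default_rng(1)
        n_cells, n_genes = 200, 400
        lam = rng.uniform(1.0, 20.0, size=n_genes)
        counts = pd.DataFrame(
            rng.poisson(lam[:, None], size=(n_genes, n_cells)).astype(float),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"c{i}" for i in range(n_cells)])
        planted = [f"g{i}" for i in range(30)]
        # bimodal on/off expression at the same overall mean: high variance
        # inside a mean bin dominated by Poisson background genes
        m = rng.uniform(4.0, 18.0, size=30)
        bimodal = rng.poisson(2.0 * m[:, None], size=(30, n_cells))
        bimodal[:, ::2] = 0
        counts.loc[planted] = bimodal.astype(float)
        logn = scrna.lognormalize(counts)
        got = scrna.select_variable_genes(logn, 0.25, 6.0, 0.5)
        assert len(set(planted) & set(got)) >= 27

    def test_constant_gene_excluded(self):
        counts = pd.DataFrame(np.ones((10, 30)),
                              index=[f"g{i}" for i in range(10)])
        counts.iloc[0] = [1, 9] * 15
        logn = scrna.lognormalize(counts)
        got = scrna.select_variable_genes(logn, 0.0001, 10.0, 0.5)
        assert "g1" not in got

    def test_high_mean_cutoff_applies(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(3, size=(50, 100)).astype(float),
                              index=[f"g{i}" for i in range(50)])
        counts.iloc[0] = rng.poisson(4000, size=100) * rng.integers(0, 2, 100)
        logn = scrna.lognormalize(counts)
        got = scrna.select_variable_genes(logn, 0.25, 4.0, 0.5)
        assert "g0" not in got


class TestClustering:
    def test_identical_cells_single_cluster(self):
        resid = pd.DataFrame(np.ones((20, 30)),
                             index=[f"g{i}" for i in range(20)],
                             columns=[f"c{i}" for i in range(30)])
        labels = scrna.reduce_and_cluster(resid, resid.index, 3, 2.0, seed=0)
        assert labels.nunique() == 1

    def test_two_separated_blobs_two_clusters(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(25, 40))
        b = rng.normal(12, 1, size=(25, 40))
        resid = pd.DataFrame(np.hstack([a, b]),
                             index=[f"g{i}" for i in range(25)],
                             columns=[f"c{i}" for i in range(80)])
        labels = scrna.reduce_and_cluster(resid, resid.index, 3, 0.7, seed=0)
        assert labels.nunique() == 2
        assert labels.iloc[:40].nunique() == 1
        assert labels.iloc[40:].nunique() == 1

    def test_clustering_deterministic_at_fixed_seed(self, scrna0, umis0,
                                                    thresholds):
        again = scrna.run_scrna(umis0, thresholds, seed=0)
        assert (again.clusters == scrna0.clusters).all()
        assert (again.subclusters == scrna0.subclusters).all()

    def test_too_many_pcs_rejected(self):
        resid = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError):
            scrna.reduce_and_cluster(resid, resid.index, 4, 1.0)


class TestLineageGating:
    def _toy(self, pdgfra_frac):
        genes = ["Epcam", "Ptprc", "Pdgfra", "Other"]
        n = 10
        counts = pd.DataFrame(
            np.zeros((4, n)), index=genes,
            columns=[f"c{i}" for i in range(n)])
        counts.loc["Other"] = 1000.0
        counts.loc["Pdgfra"] = pdgfra_frac * 1000.0 / (1 - pdgfra_frac)
        fracs = counts / counts.sum(axis=0)
        logn = np.log1p(1e4 * fracs)
        clusters = pd.Series(0, index=counts.columns)
        return logn, fracs, clusters

    def test_pdgfra_gate_passes_above_threshold(self):
        logn, fracs, clusters = self._toy(2e-4)
        lin = scrna.assign_lineages(logn, fracs, clusters)
        assert (lin == "mesenchymal").all()

    def test_pdgfra_gate_strict_at_boundary(self):
        logn, fracs, clusters = self._toy(1e-4)
        lin = scrna.assign_lineages(logn, fracs, clusters)
        assert (lin == "other").all()

    def test_missing_marker_rejected(self):
        logn, fracs, clusters = self._toy(2e-4)
        with pytest.raises(KeyError):
            scrna.assign_lineages(logn.drop(index="Epcam"), fracs, clusters)

    def test_synthetic_bycatch_labelled_by_gates(self, scrna0, truth0):
        truth_lab = pd.Series({c: truth0.cell_labels[c]
                               for c in scrna0.lineage.index})
        epi = scrna0.lineage[truth_lab == "epithelial_bycatch"]
        imm = scrna0.lineage[truth_lab == "immune_bycatch"]
        mes = scrna0.lineage[truth_lab.isin(
            ["crypt_telocyte", "VTT", "myofibroblast", "mesothelial"])]
        assert (epi == "epithelial").mean() >= 0.9
        assert (imm == "immune").mean() >= 0.9
        assert (mes == "mesenchymal").mean() >= 0.9


class TestRecluster:
    def test_four_planted_types_recovered(self, scrna0, truth0):
        sub = scrna0.subclusters
        assert sub.nunique() == 4
        lab = pd.Series({c: truth0.cell_labels[c] for c in sub.index})
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(lab.values, sub.values) >= 0.9

    def test_single_type_subset_one_cluster(self, scrna0, truth0, thresholds):
        cells = [c for c in scrna0.mesenchymal_cells
                 if truth0.cell_labels[c] == "VTT"]
        labels = scrna.recluster_mesenchyme(scrna0.lognorm, scrna0.qc, cells,
                                            thresholds, seed=0)
        assert labels.nunique() == 1

    def test_small_subset_rejected(self, scrna0, thresholds):
        with pytest.raises(ValueError):
            scrna.recluster_mesenchyme(scrna0.lognorm, scrna0.qc,
                                       scrna0.mesenchymal_cells[:5],
                                       thresholds, seed=0)
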