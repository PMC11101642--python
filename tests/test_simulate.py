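"""Synthetic-data generator: latent state, tag counts, expression, round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elastomics.pore import PoreModelParams, default_species_catalogue
from elastomics.quantify import clr_tags, lognormalize_expression
from elastomics.screen import correlate_genes
from elastomics.simulate import (
    CellPopulationSpec,
    PlantedGene,
    expected_dtd_counts,
    read_dataset,
    simulate_cells,
    simulate_dataset,
    simulate_dtd_counts,
    simulate_expression,
    simulate_hashtag_counts,
    write_dataset,
)


def one_pop(n=100, mean=2.0, sd=0.35, **kw):
    return CellPopulationSpec(name="p", n_cells=n, tension_log10_mean=mean,
                              tension_log10_sd=sd, **kw)


class TestSimulateCells:
    def test_zero_variance_tensions_exact(self):
        truth = simulate_cells([one_pop(100, mean=2.0, sd=0.0)], seed=0)
        np.testing.assert_allclose(truth.cells["tension"], 100.0)

    def test_median_ratio_between_populations(self):
        specs = [
            CellPopulationSpec(name="lo", n_cells=2000, tension_log10_mean=1.7),
            CellPopulationSpec(name="hi", n_cells=2000, tension_log10_mean=2.0),
        ]
        truth = simulate_cells(specs, seed=1)
        med = truth.cells.groupby("population")["tension"].median()
        assert med["hi"] / med["lo"] == pytest.approx(10**0.3, rel=0.10)

    def test_deterministic_given_seed(self):
        a = simulate_cells([one_pop(50)], seed=42)
        b = simulate_cells([one_pop(50)], seed=42)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_tension_area_rank_correlation(self):
        truth = simulate_cells([one_pop(4000)], seed=2, tension_area_spearman=0.3)
        rho = stats.spearmanr(truth.cells["tension"], truth.cells["adhesion_area"]).statistic
        assert rho == pytest.approx(0.3, abs=0.05)

    def test_pore_count_from_area(self):
        truth = simulate_cells([one_pop(10)], seed=3, pore_density=6.04)
        np.testing.assert_array_equal(
            truth.cells["n_pores"], np.round(6.04 * truth.cells["adhesion_area"]).astype(int)
        )

    def test_tension_bounds_respected(self):
        truth = simulate_cells([one_pop(500, sd=2.0)], seed=4, tension_bounds=(1.0, 10_000.0))
        assert truth.cells["tension"].between(1.0, 10_000.0).all()

    def test_invalid_spec_named_in_error(self):
        with pytest.raises(ValueError, match="n_cells"):
            CellPopulationSpec(name="x", n_cells=0, tension_log10_mean=2.0)
        with pytest.raises(ValueError, match="tension_log10_sd"):
            CellPopulationSpec(name="x", n_cells=5, tension_log10_mean=2.0, tension_log10_sd=-1)


class TestDTDCounts:
    def test_empirical_mean_matches_expectation(self, catalogue):
        # constant tension: every cell shares the closed-form expectation
        truth = simulate_cells([one_pop(500, mean=2.0, sd=0.0, adhesion_area_cv=0.0)], seed=0)
        counts = simulate_dtd_counts(truth, catalogue, seed=1)
        expected = expected_dtd_counts(truth, catalogue)
        for bc in counts.index:
            mu = expected.loc[bc].iloc[0]
            se = np.sqrt(mu / counts.shape[1])
            assert abs(counts.loc[bc].mean() - mu) < 3 * se

    def test_monotone_in_tension_before_noise(self, catalogue):
        truth = simulate_cells([one_pop(300)], seed=5)
        expected = expected_dtd_counts(truth, catalogue)
        for bc in expected.index:
            rho = stats.spearmanr(
                truth.cells["tension"],
                expected.loc[bc] / truth.cells["n_pores"],
            ).statistic
            assert rho == pytest.approx(1.0)

    def test_tenser_cell_imports_more(self, catalogue):
        spec_lo = CellPopulationSpec(name="lo", n_cells=1000, tension_log10_mean=1.5,
                                     tension_log10_sd=0.0, adhesion_area_cv=0.0)
        spec_hi = CellPopulationSpec(name="hi", n_cells=1000, tension_log10_mean=2.5,
                                     tension_log10_sd=0.0, adhesion_area_cv=0.0)
        truth = simulate_cells([spec_lo, spec_hi], seed=6)
        counts = simulate_dtd_counts(truth, catalogue, seed=7)
        pop = truth.cells["population"]
        means = counts.loc[catalogue[0].barcode].groupby(pop).mean()
        assert means["hi"] > means["lo"]

    def test_zero_concentration_all_zero(self, catalogue):
        from dataclasses import replace

        truth = simulate_cells([one_pop(50)], seed=8)
        silent = [replace(catalogue[0], concentration=0.0)]
        counts = simulate_dtd_counts(truth, silent, seed=9)
        assert (counts.to_numpy() == 0).all()

    def test_deterministic(self, catalogue):
        truth = simulate_cells([one_pop(50)], seed=10)
        a = simulate_dtd_counts(truth, catalogue, seed=11)
        b = simulate_dtd_counts(truth, catalogue, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestHashtags:
    def test_own_hashtag_dominates(self):
        specs = [
            CellPopulationSpec(name="a", n_cells=50, tension_log10_mean=2.0),
            CellPopulationSpec(name="b", n_cells=50, tension_log10_mean=2.0),
        ]
        truth = simulate_cells(specs, seed=0)
        tags = simulate_hashtag_counts(truth, seed=1, depth=300, background=3)
        own = tags.loc["HTO-a", truth.cells["population"] == "a"]
        other = tags.loc["HTO-b", truth.cells["population"] == "a"]
        assert own.mean() > 50 * other.mean()


class TestExpression:
    def test_null_coupling_correlations_center_at_zero(self, catalogue):
        counts, truth = simulate_dataset(
            specs=[one_pop(4000)], planted=[], n_background_genes=150, seed=3
        )
        expr = lognormalize_expression(counts.gene_matrix)
        clr = clr_tags(
            counts.tag_matrix.loc[(counts.tag_metadata["kind"] == "dtd").to_numpy()],
            across="cells",
        )
        res = correlate_genes(expr, counts.gene_metadata["gene_id"], clr.iloc[0].to_numpy())
        assert abs(res["pearson_r"].median()) < 0.02

    def test_planted_gene_recovered(self):
        counts, truth = simulate_dataset(
            specs=[one_pop(4000)],
            planted=[PlantedGene("TENS1", coupling=1.0)],
            n_background_genes=100,
            seed=4,
        )
        expr = lognormalize_expression(counts.gene_matrix)
        clr = clr_tags(
            counts.tag_matrix.loc[(counts.tag_metadata["kind"] == "dtd").to_numpy()],
            across="cells",
        )
        res = correlate_genes(expr, counts.gene_metadata["gene_id"], clr.iloc[0].to_numpy())
        assert res.loc["TENS1", "pearson_r"] > 0.15

    def test_empty_gene_set_valid_dimensions(self):
        truth = simulate_cells([one_pop(20)], seed=5)
        matrix, meta = simulate_expression(truth, [], 0, seed=6)
        assert matrix.shape == (0, 20)
        assert len(meta) == 0

    def test_mito_fraction_near_target(self):
        truth = simulate_cells([one_pop(300)], seed=7)
        matrix, meta = simulate_expression(
            truth, [], 200, seed=8, mito_gene_fraction=0.05, target_mito_fraction=0.05
        )
        mito = meta["mito"].to_numpy()
        frac = matrix[mito].sum() / matrix.sum()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_library_size_honoured(self):
        truth = simulate_cells([one_pop(300, library_size_dispersion=0.0)], seed=9)
        matrix, _ = simulate_expression(truth, [], 100, seed=10)
        totals = np.asarray(matrix.sum(axis=0)).ravel()
        assert totals.mean() == pytest.approx(10_000, rel=0.05)


class TestDatasetRoundTrip:
    def test_write_then_read_identical(self, tmp_path, catalogue):
        counts, truth = simulate_dataset(
            specs=[one_pop(30)], planted=[PlantedGene("T1", 1.0)], n_background_genes=20, seed=0
        )
        write_dataset(counts, truth, tmp_path / "ds", species=catalogue)
        back = read_dataset(tmp_path / "ds")
        assert (back.gene_matrix != counts.gene_matrix).nnz == 0
        pd.testing.assert_frame_equal(
            back.tag_matrix.astype(np.int64), counts.tag_matrix.astype(np.int64)
        )
        assert back.cell_barcodes == counts.cell_barcodes
        assert list(back.gene_metadata["mito"]) == list(counts.gene_metadata["mito"])

    def test_empty_cells_refused(self, tmp_path):
        counts, truth = simulate_dataset(specs=[one_pop(5)], n_background_genes=5, seed=1)
        empty = counts.subset_cells(np.zeros(5, dtype=bool))
        with pytest.raises(ValueError):
            write_dataset(empty, None, tmp_path / "empty")
        assert not (tmp_path / "empty" / "tags.csv").exists()

    def test_barcodes_shared_and_ordered(self, tmp_path):
        counts, truth = simulate_dataset(specs=[one_pop(15)], n_background_genes=10, seed=2)
        write_dataset(counts, truth, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        assert list(back.tag_matrix.columns) == back.cell_barcodes

    def test_full_dataset_deterministic(self):
        a, _ = simulate_dataset(specs=[one_pop(40)], n_background_genes=30, seed=11)
        b, _ = simulate_dataset(specs=[one_pop(40)], n_background_genes=30, seed=11)
        assert (a.gene_matrix != b.gene_matrix).nnz == 0
        pd.testing.assert_frame_equal(a.tag_matrix, b.tag_matrix)
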