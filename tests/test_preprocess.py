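"""Cell QC, median-of-ratios size factors, gene floor, FC classes."""

import numpy as np
import pandas as pd
import pytest

from burstvar.preprocess import (
    CountMatrix,
    classify_fold_change,
    filter_cells,
    filter_genes,
    normalize,
    size_factors,
)

from conftest import make_count_matrix


def with_totals(m, totals):
    m.cell_meta["total_reads"] = totals
    return m


class TestFilterCells:
    def test_depth_window(self):
        m = with_totals(
            make_count_matrix(np.ones((3, 3), dtype=int)),
            [400_000, 600_000, 8_000_000],
        )
        assert filter_cells(m).n_cells == 1

    def test_bounds_are_inclusive(self):
        m = with_totals(
            make_count_matrix(np.ones((3, 4), dtype=int)),
            [500_000, 7_000_000, 499_999, 7_000_001],
        )
        kept = filter_cells(m)
        assert kept.n_cells == 2
        assert set(kept.cell_meta["total_reads"]) == {500_000, 7_000_000}

    def test_all_removed_is_an_error(self):
        m = with_totals(make_count_matrix(np.ones((2, 2), dtype=int)), [1, 2])
        with pytest.raises(ValueError, match="read-depth"):
            filter_cells(m)

    def test_empty_matrix_is_an_error(self):
        m = make_count_matrix(np.empty((3, 0), dtype=int))
        with pytest.raises(ValueError):
            filter_cells(m)


class TestSizeFactors:
    def test_recovers_exact_depth_multipliers(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 100, size=40).astype(float)
        s = np.array([0.5, 1.0, 2.0, 4.0])
        m = make_count_matrix(np.round(np.outer(base, s)))
        sf = size_factors(m).to_numpy()
        expected = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
        np.testing.assert_allclose(sf, expected, rtol=1e-6)

    def test_identical_cells_get_equal_factors(self):
        m = make_count_matrix(np.tile([[10], [20], [30]], (1, 5)))
        np.testing.assert_allclose(size_factors(m).to_numpy(), 1.0)

    def test_single_cell_convention(self):
        m = make_count_matrix(np.array([[10], [20]]))
        assert size_factors(m).to_numpy() == pytest.approx([1.0])

    def test_geometric_mean_one_within_replicate(self):
        rng = np.random.default_rng(1)
        m = make_count_matrix(rng.poisson(50, size=(60, 8)) + 1)
        sf = size_factors(m)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_computed_within_each_replicate(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, size=(60, 6)) + 1
        counts[:, 3:] *= 10  # replicate 2 sequenced 10x deeper
        m = make_count_matrix(counts)
        m.cell_meta["replicate"] = [1, 1, 1, 2, 2, 2]
        sf = size_factors(m)
        # factors normalized per replicate: deep replicate not penalized
        assert np.exp(np.mean(np.log(sf[:3]))) == pytest.approx(1.0)
        assert np.exp(np.mean(np.log(sf[3:]))) == pytest.approx(1.0)

    def test_empty_reference_is_an_error(self):
        counts = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="reference"):
            size_factors(make_count_matrix(counts))

    def test_matches_deseq_reference_implementation(self):
        """Independent oracle: the DESeq median-of-ratios implementation."""
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.uniform(5, 200, size=(80, 1)), size=(80, 10))
        m = make_count_matrix(counts)
        mine = size_factors(m).to_numpy()
        _, ref = pydeseq2.deseq2_norm(pd.DataFrame(counts.T))
        ref = np.asarray(ref).ravel()
        # equal up to the geometric-mean-1 rescaling convention
        np.testing.assert_allclose(
            mine / ref, np.exp(-np.mean(np.log(ref))), rtol=1e-8
        )


class TestFilterGenes:
    def test_floor_boundary(self):
        m = make_count_matrix(np.array([[10.0, 10.0], [9.99, 9.99], [11.0, 9.0]]))
        m.normalized = True
        kept = filter_genes(m, floor=10.0)
        assert list(kept.counts.index) == ["g0", "g2"]

    def test_zero_floor_is_identity(self):
        m = make_count_matrix(np.array([[0, 1], [2, 3]]))
        m.normalized = True
        assert filter_genes(m, floor=0.0).n_genes == 2

    def test_all_below_floor_warns_and_empties(self, caplog):
        m = make_count_matrix(np.ones((3, 2)))
        m.normalized = True
        kept = filter_genes(m, floor=10.0)
        assert kept.n_genes == 0


class TestClassifyFoldChange:
    def _pair(self, mean0, mean6):
        m0 = make_count_matrix(np.tile(np.asarray(mean0)[:, None], (1, 4)))
        m6 = make_count_matrix(np.tile(np.asarray(mean6)[:, None], (1, 4)))
        m0.normalized = m6.normalized = True
        return m0, m6

    @pytest.mark.parametrize(
        "mean0, mean6, threshold, expected",
        [
            (10.0, 30.0, 2.0, "up"),
            (10.0, 30.0, 3.0, "up"),
            (40.0, 10.0, 2.0, "down"),
            (40.0, 10.0, 4.0, "down"),
            (25.0, 25.0, 2.0, "unchanged"),
            (10.0, 19.9, 2.0, "unchanged"),
        ],
    )
    def test_threshold_classes(self, mean0, mean6, threshold, expected):
        m0, m6 = self._pair([mean0, 50.0], [mean6, 50.0])
        labels = classify_fold_change(m0, m6, threshold=threshold)
        assert labels.loc["g0", "class"] == expected

    def test_swapping_time_points_swaps_classes(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(1, 100, size=(30, 5))
        b = rng.uniform(1, 100, size=(30, 5))
        m0, m6 = make_count_matrix(a), make_count_matrix(b)
        m0.normalized = m6.normalized = True
        fwd = classify_fold_change(m0, m6, threshold=2.0)["class"]
        rev = classify_fold_change(m6, m0, threshold=2.0)["class"]
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert (rev == fwd.map(swap)).all()

    def test_zero_early_mean_handling(self):
        m0, m6 = self._pair([0.0, 0.0, 0.0], [50.0, 5.0, 0.0])
        labels = classify_fold_change(m0, m6, threshold=2.0, floor=10.0)
        assert labels.loc["g0", "class"] == "up"  # reaches the floor
        assert labels.loc["g1", "class"] == "unchanged"  # below the floor
        assert labels.loc["g2", "class"] == "unchanged"  # absent at both

    def test_replicate_averaging_weights_replicates_equally(self):
        # replicate 1 has 1 cell, replicate 2 has 3 cells; per-replicate
        # means must be averaged, not pooled over cells
        counts0 = np.array([[10.0, 40.0, 40.0, 40.0]])
        counts6 = np.array([[50.0, 50.0, 50.0, 50.0]])
        m0 = make_count_matrix(counts0)
        m6 = make_count_matrix(counts6)
        m0.cell_meta["replicate"] = [1, 2, 2, 2]
        m6.cell_meta["replicate"] = [1, 2, 2, 2]
        m0.normalized = m6.normalized = True
        labels = classify_fold_change(m0, m6, threshold=2.0)
        assert labels.loc["g0", "fc"] == pytest.approx(50.0 / 25.0)
        assert labels.loc["g0", "class"] == "up"

    def test_pipeline_order_matters(self):
        """QC before normalization is not the same as after: an overloaded
        cell distorts size factors if kept (regression guard)."""
        rng = np.random.default_rng(5)
        base = rng.integers(10, 100, size=50)
        counts = np.column_stack([base, base * 2, base * 200])
        m = make_count_matrix(counts)
        sf_after_qc = size_factors(
            filter_cells(m, min_reads=0, max_reads=base.sum() * 10)
        )
        sf_no_qc = size_factors(m)
        assert not np.allclose(
            sf_after_qc.to_numpy(), sf_no_qc.to_numpy()[: len(sf_after_qc)]
        )


class TestNormalize:
    def test_normalization_equalizes_exact_multiples(self):
        base = np.arange(1, 21).astype(float)
        m = make_count_matrix(np.outer(base, [1.0, 2.0, 4.0]))
        norm = normalize(m)
        ratios = norm.counts.iloc[:, 2] / norm.counts.iloc[:, 0]
        np.testing.assert_allclose(ratios, 1.0)

    def test_duplicate_gene_ids_rejected(self):
        counts = pd.DataFrame(
            np.ones((2, 2)), index=["g0", "g0"], columns=["c0", "c1"]
        )
        meta = pd.DataFrame(
            {"time_point": 0, "replicate": 1}, index=pd.Index(["c0", "c1"], name="cell_id")
        )
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(counts=counts, cell_meta=meta)
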