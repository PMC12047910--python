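"""I/O round trips, preprocessing recipe, and source combination."""

import numpy as np
import pytest

from transst.core_io import (
    DimensionError,
    ExpressionMatrix,
    FormatError,
    LabeledSource,
    align_and_combine_sources,
    harmonize_gene_spaces,
    preprocess,
    read_coords,
    read_expression,
    read_labels,
    write_expression,
)


def _em(values, prefix="r"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
    )


class TestReadWrite:
    def test_dense_csv_with_header(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("id,ACTB,GAPDH\ns1,1,2\ns2,3,4\ns3,5,6\n")
        em = read_expression(path, "csv")
        assert em.gene_ids == ["ACTB", "GAPDH"]
        assert em.row_ids == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(em.values, [[1, 2], [3, 4], [5, 6]])

    def test_duplicate_gene_names_get_suffixed(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("id,ACTB,ACTB\ns1,1,2\ns2,3,4\n")
        em = read_expression(path, "csv")
        assert em.gene_ids == ["ACTB", "ACTB.1"]

    def test_mtx_genes_by_spots_is_transposed(self, tmp_path):
        em = _em(np.arange(12).reshape(4, 3))  # 4 genes x 3 spots on disk
        write_expression(em, tmp_path / "e.mtx", fmt="mtx")
        back = read_expression(tmp_path / "e.mtx", "mtx", "genes_by_spots")
        assert back.values.shape == (3, 4)
        np.testing.assert_array_equal(back.values, em.values.T)

    @pytest.mark.parametrize("fmt", ["csv", "tsv", "mtx"])
    def test_round_trip_preserves_values(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        em = _em(rng.integers(0, 50, size=(7, 5)))
        path = tmp_path / f"e.{fmt}"
        write_expression(em, path, fmt=fmt)
        back = read_expression(path, fmt)
        np.testing.assert_array_equal(back.values, em.values)
        assert back.row_ids == em.row_ids and back.gene_ids == em.gene_ids

    def test_malformed_mtx_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.mtx"
        path.write_text("%%MatrixMarket matrix coordinate real general\nnot a header\n")
        with pytest.raises((FormatError, ValueError)):
            read_expression(path, "mtx")

    def test_name_file_dimension_mismatch(self, tmp_path):
        em = _em(np.ones((3, 2)))
        write_expression(em, tmp_path / "e.mtx", fmt="mtx")
        (tmp_path / "e.rownames.txt").write_text("a\nb\n")  # one too few
        with pytest.raises(DimensionError):
            read_expression(tmp_path / "e.mtx", "mtx")

    def test_labels_and_coords_reorder_to_row_ids(self, tmp_path):
        (tmp_path / "lab.tsv").write_text("s2\tB\ns1\tA\ns3\tA\n")
        labels = read_labels(tmp_path / "lab.tsv", ["s1", "s2", "s3"])
        np.testing.assert_array_equal(labels, [1, 2, 1])
        (tmp_path / "xy.tsv").write_text("s2\t1\t0\ns1\t0\t0\ns3\t2\t0\n")
        coords = read_coords(tmp_path / "xy.tsv", ["s1", "s2", "s3"])
        np.testing.assert_array_equal(coords.coords[:, 0], [0, 1, 2])


class TestInvariants:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            _em([[1.0, np.nan], [0.0, 1.0]])

    def test_duplicate_row_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ExpressionMatrix(np.ones((2, 2)), ["a", "a"], ["g1", "g2"])

    def test_label_length_checked(self):
        with pytest.raises(DimensionError):
            LabeledSource(_em(np.ones((3, 2))), [1, 2])


class TestPreprocess:
    def test_all_equal_counts_collapse_without_division_by_zero(self):
        em = _em(np.full((4, 3), 7.0))
        with pytest.warns(UserWarning, match="variance-zero"):
            out = preprocess(em, n_hvg=3, normalize=True)
        assert out.n_genes == 0  # every gene constant after normalization

    def test_n_hvg_equal_p_retains_all_genes(self):
        rng = np.random.default_rng(1)
        em = _em(rng.poisson(10, size=(20, 6)) + 1.0)
        out = preprocess(em, n_hvg=6, normalize=True)
        assert set(out.gene_ids) == set(em.gene_ids)

    def test_high_dispersion_gene_ranked_first(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(50, size=(50, 5)).astype(float) + 1.0
        X[:, 3] = rng.choice([5.0, 60.0], size=50)  # bimodal: high dispersion
        em = _em(X)
        # oracle: the documented HVG statistic is post-normalization
        # log-scale variance, computed here directly
        logged = np.log1p(X * (np.median(X.sum(1)) / X.sum(1))[:, None])
        assert np.argmax(logged.var(axis=0)) == 3
        out = preprocess(em, n_hvg=2, normalize=True)
        assert out.gene_ids[0] == "g3"

    def test_zero_count_row_is_an_error_naming_the_row(self):
        X = np.ones((3, 2))
        X[1] = 0.0
        with pytest.raises(ValueError, match="r1"):
            preprocess(_em(X), n_hvg=2, normalize=True)

    def test_idempotent_when_not_normalizing(self):
        rng = np.random.default_rng(3)
        em = _em(rng.standard_normal((30, 4)))
        once = preprocess(em, n_hvg=4, normalize=False)
        twice = preprocess(once, n_hvg=4, normalize=False)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


class TestCombineSources:
    def test_single_source_identity_up_to_scaling(self):
        rng = np.random.default_rng(4)
        em = _em(rng.standard_normal((10, 5)))
        combined, report = align_and_combine_sources(
            [LabeledSource(em, np.repeat([1, 2], 5))], em.gene_ids
        )
        assert combined.expr.gene_ids == em.gene_ids
        assert report.missing_genes == {}
        # column-standardized version of the same data
        np.testing.assert_allclose(combined.expr.values.mean(0), 0, atol=1e-12)

    def test_disjoint_label_vocabularies_reindexed(self):
        rng = np.random.default_rng(5)
        genes = [f"g{j}" for j in range(4)]
        a = ExpressionMatrix(rng.standard_normal((6, 4)), [f"a{i}" for i in range(6)], genes)
        b = ExpressionMatrix(rng.standard_normal((4, 4)), [f"b{i}" for i in range(4)], genes)
        combined, report = align_and_combine_sources(
            [(a, ["A", "B", "A", "B", "A", "B"]), (b, ["C"] * 4)], genes
        )
        assert sorted(set(combined.labels)) == [1, 2, 3]
        assert report.label_vocabulary == ["A", "B", "C"]
        assert combined.expr.n_spots == 10  # row counts add up

    def test_missing_genes_zero_filled_and_reported(self):
        rng = np.random.default_rng(6)
        target_genes = [f"g{j}" for j in range(20)]
        src = ExpressionMatrix(
            rng.standard_normal((8, 10)), [f"r{i}" for i in range(8)], target_genes[:10]
        )
        combined, report = align_and_combine_sources(
            [(src, [1, 2] * 4)], target_genes
        )
        assert combined.expr.n_genes == 20
        assert report.missing_genes[0] == target_genes[10:]
        np.testing.assert_array_equal(combined.expr.values[:, 10:], 0.0)

    def test_insufficient_overlap_raises(self):
        src = _em(np.ones((4, 3)))
        with pytest.raises(ValueError, match="overlap|shares"):
            align_and_combine_sources(
                [(src, [1, 1, 2, 2])], ["other1", "other2"], min_overlap=2
            )

    def test_harmonize_drops_zero_variance_from_both(self):
        rng = np.random.default_rng(7)
        genes = [f"g{j}" for j in range(5)]
        sv = rng.standard_normal((6, 5))
        tv = rng.standard_normal((8, 5))
        sv[:, 2] = 0.0  # constant in source only
        src = LabeledSource(ExpressionMatrix(sv, [f"s{i}" for i in range(6)], genes), [1, 1, 1, 2, 2, 2])
        tgt = ExpressionMatrix(tv, [f"t{i}" for i in range(8)], genes)
        with pytest.warns(UserWarning, match="zero variance"):
            src2, tgt2 = harmonize_gene_spaces(src, tgt)
        assert src2.expr.gene_ids == tgt2.gene_ids == ["g0", "g1", "g3", "g4"]
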