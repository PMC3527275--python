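import numpy as np
import pytest

from pertdeconv.data_io import (
    DigitalMixture,
    ExpressionTable,
    FormatError,
    GeneIndex,
    ValidationError,
    align_genes,
    discretize,
    log2_transform,
    read_expression_table,
    reference_to_distributions,
    write_expression_table,
    write_results,
)
from pertdeconv.models import (
    FitResult,
    MixtureProportions,
    NewPopulationEstimate,
    PerturbationEstimate,
)


class TestReadWrite:
    def test_tsv_round_trip(self, small_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_expression_table(small_table, path)
        again = read_expression_table(path, format="tsv")
        assert again.genes.ids == small_table.genes.ids
        assert again.sample_names == small_table.sample_names
        np.testing.assert_allclose(again.values, small_table.values, atol=1e-6)

    def test_gct_round_trip(self, small_table, tmp_path):
        path = tmp_path / "table.gct"
        lines = ["#1.2", "2\t2", "Name\tDescription\ts1\ts2"]
        for g, row in zip(small_table.genes.ids, small_table.values):
            lines.append(f"{g}\tna\t{row[0]}\t{row[1]}")
        path.write_text("\n".join(lines) + "\n")
        table = read_expression_table(path, format="gct")
        np.testing.assert_allclose(table.values, small_table.values)
        assert table.sample_names == ("s1", "s2")

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ng1\t1.0\ng1\t2.0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_expression_table(path)

    def test_gct_dimension_mismatch(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.2\n3\t2\nName\tDescription\ts1\ts2\ng1\tna\t1\t2\n")
        with pytest.raises(FormatError, match="declares"):
            read_expression_table(path, format="gct")

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ng1\t1.0\ng2\toops\n")
        with pytest.raises(ValidationError, match="g2"):
            read_expression_table(path)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            ExpressionTable(
                genes=GeneIndex(("g1",)), sample_names=("s1",),
                values=np.array([[-1.0]]),
            )


class TestAlignGenes:
    def test_identical_indices_unchanged(self, small_table):
        ref, mix = align_genes(small_table, small_table)
        assert ref is small_table and mix is small_table

    def test_intersection_in_reference_order(self):
        ref = ExpressionTable(
            genes=GeneIndex(("g1", "g2", "g3")), sample_names=("r",),
            values=np.array([[1.0], [2.0], [3.0]]),
        )
        mix = ExpressionTable(
            genes=GeneIndex(("g4", "g3", "g2")), sample_names=("m",),
            values=np.array([[9.0], [8.0], [7.0]]),
        )
        ref2, mix2 = align_genes(ref, mix)
        assert ref2.genes.ids == ("g2", "g3") == mix2.genes.ids
        np.testing.assert_allclose(ref2.values.ravel(), [2.0, 3.0])
        np.testing.assert_allclose(mix2.values.ravel(), [7.0, 8.0])

    def test_disjoint_indices_error(self):
        a = ExpressionTable(
            genes=GeneIndex(("g1",)), sample_names=("r",), values=[[1.0]]
        )
        b = ExpressionTable(
            genes=GeneIndex(("g2",)), sample_names=("m",), values=[[1.0]]
        )
        with pytest.raises(ValidationError, match="shared genes"):
            align_genes(a, b)


class TestDiscretize:
    @pytest.mark.parametrize(
        "intensities,target,expected",
        [
            ([1.0, 1.0, 2.0], 4, [1, 1, 2]),          # already integral
            ([0.5, 0.5], 10, [5, 5]),                  # symmetric split
            ([1.0, 1.0, 1.0], 10, [4, 3, 3]),          # largest-remainder tie -> lowest index
        ],
    )
    def test_apportionment(self, intensities, target, expected):
        table = ExpressionTable(
            genes=GeneIndex(tuple(f"g{i}" for i in range(len(intensities)))),
            sample_names=("s1",),
            values=np.array(intensities)[:, None],
        )
        dig = discretize(table, target_total=target)
        np.testing.assert_array_equal(dig.counts[0], expected)

    def test_all_zero_sample_error(self):
        table = ExpressionTable(
            genes=GeneIndex(("g1", "g2")), sample_names=("s1",),
            values=np.zeros((2, 1)),
        )
        with pytest.raises(ValidationError, match="zero total"):
            discretize(table)

    def test_default_depth_conserved(self, small_table):
        dig = discretize(small_table)
        np.testing.assert_array_equal(dig.totals, [10_000_000, 10_000_000])


class TestReferenceToDistributions:
    def test_uniform(self):
        table = ExpressionTable(
            genes=GeneIndex(tuple("abcd")), sample_names=("p",),
            values=np.full((4, 1), 2.0),
        )
        refs = reference_to_distributions(table)
        np.testing.assert_allclose(refs.beta[0], 0.25)
        assert refs.totals[0] == 8.0

    def test_zero_floor_off_is_plain_normalization(self):
        table = ExpressionTable(
            genes=GeneIndex(("a", "b", "c")), sample_names=("p",),
            values=np.array([[1.0], [0.0], [3.0]]),
        )
        refs = reference_to_distributions(table, zero_floor=0.0)
        np.testing.assert_array_equal(refs.beta[0], [0.25, 0.0, 0.75])

    def test_zero_floor_keeps_rows_positive(self):
        table = ExpressionTable(
            genes=GeneIndex(("a", "b", "c")), sample_names=("p",),
            values=np.array([[1.0], [0.0], [3.0]]),
        )
        refs = reference_to_distributions(table, zero_floor=1e-12)
        assert np.all(refs.beta > 0)
        assert abs(refs.beta[0].sum() - 1.0) < 1e-12
        assert np.abs(refs.beta[0] - [0.25, 0.0, 0.75]).max() < 1e-11

    def test_all_zero_reference_error(self):
        table = ExpressionTable(
            genes=GeneIndex(("a", "b")), sample_names=("p",),
            values=np.zeros((2, 1)),
        )
        with pytest.raises(ValidationError, match="zero total"):
            reference_to_distributions(table)


class TestWriteResults:
    @staticmethod
    def _result(model="nnml", **kw):
        props = MixtureProportions(
            theta=np.array([[1.0]]), population_names=("popA",),
            sample_names=("s1",),
        )
        return FitResult(
            model=model, proportions=props, loglik=-1.0, logpost=-1.0,
            n_iter=3, converged=True, n_obs=10, **kw,
        )

    def test_single_cell_proportions(self, tmp_path):
        write_results(self._result(), tmp_path / "out")
        text = (tmp_path / "out" / "proportions.tsv").read_text()
        assert "1.000000" in text

    def test_pert_emits_rho(self, tmp_path):
        res = self._result(
            model="pert",
            perturbation=PerturbationEstimate(
                rho=np.array([1.0, 2.0]), kappa=3.0, gene_ids=("g1", "g2")
            ),
        )
        write_results(res, tmp_path / "out")
        lines = (tmp_path / "out" / "rho.tsv").read_text().strip().splitlines()
        assert lines[0] == "gene\trho" and len(lines) == 3

    def test_nnml_emits_no_rho_or_gamma(self, tmp_path):
        write_results(self._result(), tmp_path / "out")
        names = {p.name for p in (tmp_path / "out").iterdir()}
        assert names == {"proportions.tsv", "run.yaml"}


def test_log2_transform_flags_and_offsets(small_table):
    out = log2_transform(small_table)
    assert out.is_log2 and not small_table.is_log2
    np.testing.assert_allclose(out.values, np.log2(1 + small_table.values))
    with pytest.raises(ValidationError):
        log2_transform(out)
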