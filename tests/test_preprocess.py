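import numpy as np
import pytest

from txrev.io import DesignTable, ExpressionMatrix
from txrev.preprocess import (
    average_replicates,
    collapse_to_genes,
    expression_mask,
    to_log2,
)


class TestToLog2:
    def test_elementwise_values(self):
        m = ExpressionMatrix(["p1", "p2"], ["s1"], np.array([[1.0], [16.0]]), scale="linear")
        out = to_log2(m)
        assert out.scale == "log2"
        np.testing.assert_allclose(out.values[:, 0], [0.0, 4.0])

    def test_already_log2_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="already"):
            to_log2(tiny_matrix)

    def test_non_positive_value_named(self):
        m = ExpressionMatrix(["p1"], ["sX"], np.array([[0.0]]), scale="linear")
        with pytest.raises(ValueError, match="p1.*sX"):
            to_log2(m)


class TestAverageReplicates:
    def test_pair_mean(self, tiny_matrix, tiny_design):
        avg = average_replicates(tiny_matrix, tiny_design)
        assert avg.condition_labels == ["0", "C"]
        assert avg.values[0, 0] == pytest.approx(5.1)  # (5.0 + 5.2) / 2
        assert avg.values[0, 1] == pytest.approx(7.2)
        assert avg.replicate_counts == {"0": 2, "C": 2}

    def test_single_replicate_passthrough(self):
        m = ExpressionMatrix(["p1"], ["s1"], np.array([[6.5]]), scale="log2")
        d = DesignTable({"s1": ("0", 1)})
        assert average_replicates(m, d).values[0, 0] == 6.5

    def test_sample_column_order_irrelevant(self, tiny_matrix, tiny_design):
        perm = [2, 0, 3, 1]
        shuffled = ExpressionMatrix(
            tiny_matrix.probe_ids,
            [tiny_matrix.sample_ids[i] for i in perm],
            tiny_matrix.values[:, perm],
            scale="log2",
        )
        np.testing.assert_allclose(
            average_replicates(shuffled, tiny_design).values,
            average_replicates(tiny_matrix, tiny_design).values,
        )

    def test_identical_replicates_are_identity(self, tiny_design):
        vals = np.tile(np.array([[4.0], [9.0]]), (1, 4))
        m = ExpressionMatrix(["p1", "p2"], ["c0_r1", "c0_r2", "cC_r1", "cC_r2"], vals, "log2")
        avg = average_replicates(m, tiny_design)
        np.testing.assert_allclose(avg.values, [[4.0, 4.0], [9.0, 9.0]])


class TestExpressionMask:
    def _matrix(self, a1, a2, b1, b2):
        return ExpressionMatrix(
            ["p"], ["a1", "a2", "b1", "b2"], np.array([[a1, a2, b1, b2]]), scale="log2"
        )

    _design = DesignTable({"a1": ("A", 1), "a2": ("A", 2), "b1": ("B", 1), "b2": ("B", 2)})

    def test_passes_when_one_condition_fully_expressed(self):
        m = self._matrix(4.5, 4.2, 1.0, 1.0)
        assert expression_mask(m, self._design, "A", "B", t=4.0)[0]

    def test_fails_when_no_condition_has_all_replicates_above(self):
        m = self._matrix(4.5, 3.9, 3.0, 5.0)
        assert not expression_mask(m, self._design, "A", "B", t=4.0)[0]

    def test_degenerate_threshold_admits_everything(self):
        m = self._matrix(0.1, 0.1, 0.1, 0.1)
        assert expression_mask(m, self._design, "A", "B", t=-np.inf)[0]

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 10, size=(200, 4))
        m = ExpressionMatrix([f"p{i}" for i in range(200)], ["a1", "a2", "b1", "b2"], vals, "log2")
        prev = None
        for t in (-1.0, 2.0, 4.0, 6.0, 11.0):
            cur = expression_mask(m, self._design, "A", "B", t=t)
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur


class TestCollapseToGenes:
    def test_probe_mean_per_symbol(self, tiny_design, tiny_annotation, tiny_matrix):
        avg = average_replicates(tiny_matrix, tiny_design)
        # remap both p1 and p2 to one gene: collapse averages them
        from txrev.io import ProbeAnnotation

        gm = collapse_to_genes(avg, ProbeAnnotation({"p1": "G", "p2": "G"}))
        assert gm.gene_symbols == ["G"]
        assert gm.values[0, 0] == pytest.approx((5.1 + 8.0) / 2)
        assert gm.probes_per_gene == {"G": 2}

    def test_unannotated_probes_dropped_single_probe_identity(
        self, tiny_matrix, tiny_design, tiny_annotation
    ):
        avg = average_replicates(tiny_matrix, tiny_design)
        gm = collapse_to_genes(avg, tiny_annotation)
        assert gm.gene_symbols == ["GENE1", "GENE2"]  # p3 dropped
        assert gm.values[0, 1] == pytest.approx(7.2)  # single-probe gene untouched

    def test_probe_order_permutation_invariant(self, tiny_design, tiny_annotation, tiny_matrix):
        avg = average_replicates(tiny_matrix, tiny_design)
        perm = [2, 0, 1]
        from txrev.preprocess import AveragedData

        shuffled = AveragedData(
            [avg.probe_ids[i] for i in perm],
            avg.condition_labels,
            avg.values[perm],
            avg.replicate_counts,
        )
        a = collapse_to_genes(avg, tiny_annotation)
        b = collapse_to_genes(shuffled, tiny_annotation)
        assert a.gene_symbols == b.gene_symbols
        np.testing.assert_allclose(a.values, b.values)

    def test_no_annotated_probes_is_error(self, tiny_matrix, tiny_design):
        from txrev.io import ProbeAnnotation

        avg = average_replicates(tiny_matrix, tiny_design)
        with pytest.raises(ValueError, match="no annotated"):
            collapse_to_genes(avg, ProbeAnnotation({}))
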