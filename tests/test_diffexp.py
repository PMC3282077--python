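import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txrev.diffexp import benjamini_hochberg, compare_conditions, to_gene_sets
from txrev.io import DesignTable, ExpressionMatrix, ProbeAnnotation
from txrev.noise import constant_noise_model
from txrev.preprocess import average_replicates, collapse_to_genes

from conftest import bh_oracle, make_null_matrix


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_equal_p_values_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_single_p_identity(self):
        np.testing.assert_allclose(benjamini_hochberg([0.42]), [0.42])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([-0.1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50)
    )
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)


def _planted_matrix(rng, n_probes=4_000, sd=0.2, shift=1.5, n_shifted=50):
    matrix, design, baseline = make_null_matrix(rng, n_probes=n_probes, sd=sd)
    # shift the first n_shifted probes upward in condition "C"
    c_cols = [matrix.sample_index(s) for s in design.samples_for("C")]
    matrix.values[np.ix_(range(n_shifted), c_cols)] += shift
    return matrix, design


class TestCompareConditions:
    def test_planted_shift_called_with_correct_direction(self):
        rng = np.random.default_rng(21)
        matrix, design = _planted_matrix(rng)
        res = compare_conditions(matrix, design, "C", "0", constant_noise_model(0.2))
        called = res.table["called"].to_numpy()
        assert (called[:50] == "up").mean() >= 0.9
        assert (called[50:] != "none").mean() <= 0.005

    def test_fc_filter_dominates_tiny_but_certain_shift(self):
        rng = np.random.default_rng(8)
        matrix, design = _planted_matrix(rng, sd=0.01, shift=0.5, n_shifted=20)
        res = compare_conditions(matrix, design, "C", "0", constant_noise_model(0.01))
        # log2 diff 0.5 -> |FC| ~ 1.41 < 1.5: never called despite p ~ 0
        assert (res.table["called"][:20] == "none").all()
        assert (res.table["q"][:20] < 1e-6).all()

    def test_swapping_conditions_negates_and_preserves(self):
        rng = np.random.default_rng(33)
        matrix, design = _planted_matrix(rng, n_probes=2_000)
        noise = constant_noise_model(0.2)
        ab = compare_conditions(matrix, design, "C", "0", noise)
        ba = compare_conditions(matrix, design, "0", "C", noise)
        np.testing.assert_allclose(ab.table["log2_diff"], -ba.table["log2_diff"])
        np.testing.assert_allclose(ab.table["signed_fc"], -ba.table["signed_fc"])
        np.testing.assert_allclose(ab.table["p"], ba.table["p"], atol=1e-12)
        np.testing.assert_allclose(ab.table["q"], ba.table["q"], atol=1e-12)
        assert ab.up_probes == ba.down_probes
        assert ab.down_probes == ba.up_probes

    def test_identical_condition_labels_rejected(self, tiny_matrix, tiny_design):
        with pytest.raises(ValueError):
            compare_conditions(tiny_matrix, tiny_design, "C", "C", constant_noise_model(0.2))

    def test_empty_mask_yields_no_calls(self, tiny_matrix, tiny_design):
        res = compare_conditions(
            tiny_matrix, tiny_design, "C", "0", constant_noise_model(0.2), t=100.0
        )
        assert res.n_called == 0
        assert res.table["p"].isna().all()


class TestToGeneSets:
    def _setup(self, values, annotation_map):
        probes = [f"p{i}" for i in range(values.shape[0])]
        matrix = ExpressionMatrix(probes, ["a1", "a2", "b1", "b2"], values, "log2")
        design = DesignTable(
            {"a1": ("C", 1), "a2": ("C", 2), "b1": ("0", 1), "b2": ("0", 2)}
        )
        annotation = ProbeAnnotation(annotation_map)
        res = compare_conditions(matrix, design, "C", "0", constant_noise_model(0.05))
        gm = collapse_to_genes(average_replicates(matrix, design), annotation)
        return to_gene_sets(res, annotation, gm)

    def test_probe_call_with_gene_fc_enters_set(self):
        values = np.array([[8.0, 8.0, 6.0, 6.0]])  # +2 log2 -> FC +4
        sets = self._setup(values, {"p0": "G1"})
        assert sets.up == {"G1"} and sets.down == set()

    def test_conflicting_probe_directions_drop_gene(self):
        values = np.array([[8.0, 8.0, 6.0, 6.0], [6.0, 6.0, 8.0, 8.0]])
        sets = self._setup(values, {"p0": "G1", "p1": "G1"})
        assert sets.up == set() and sets.down == set()

    def test_gene_level_fc_filter_excludes_weak_gene(self):
        # p0 called up (diff +3); p1 below the expression mask pulls the gene
        # average down to FC ~ 1.46 < 1.5 -> gene excluded
        values = np.array([[9.0, 9.0, 6.0, 6.0], [2.0, 2.0, 3.9, 3.9]])
        sets = self._setup(values, {"p0": "G1", "p1": "G1"})
        assert sets.up == set()
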