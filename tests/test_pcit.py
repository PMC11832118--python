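"""PCIT core: correlation, trio elimination, thresholding."""

import numpy as np
import pandas as pd
import pytest

from mitonet import (
    correlation_matrix,
    partial_correlation,
    pcit_brute_force,
    pcit_significance,
    threshold_edges,
    trio_epsilon,
)
from mitonet.pcit import CorrelationMatrix, PCITResult

from conftest import random_correlation

# hand-derived values for the trio r_xy=0.9, r_xz=0.8, r_yz=0.6:
#   r_xy.z = (0.9 - 0.48)/sqrt(0.36*0.64) = 0.875
#   r_xz.y = 0.26/sqrt(0.19*0.64)        = 0.745601...
#   r_yz.x = -0.12/sqrt(0.19*0.36)       = -0.458831...
#   eps    = (0.97222 + 0.93200 + 0.76472)/3 = 0.889647...
TRIO = (0.9, 0.8, 0.6)
TRIO_EPS = 0.8896475846577511


def corr_from_matrix(r) -> CorrelationMatrix:
    r = np.asarray(r, dtype=float)
    return CorrelationMatrix(tuple(f"g{i}" for i in range(len(r))), r)


class TestCorrelationMatrix:
    def test_affine_pair_is_perfectly_correlated(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        expr = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x}).T
        corr = correlation_matrix(expr)
        i = {g: k for k, g in enumerate(corr.genes)}
        assert corr.r[i["x"], i["y"]] == pytest.approx(1.0)
        assert corr.r[i["x"], i["z"]] == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        expr = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 3, 2, 4]}).T
        corr = correlation_matrix(expr)
        assert corr.r[0, 1] == pytest.approx(0.8)

    def test_zero_variance_gene_is_named(self):
        expr = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]}).T
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(expr)

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]}).T
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(expr)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            corr_from_matrix([[1, 0.5], [0.4, 1]])
        with pytest.raises(ValueError, match="diagonal"):
            corr_from_matrix([[0.9, 0.5], [0.5, 1]])


class TestTrioRule:
    def test_partial_correlation_hand_values(self):
        assert partial_correlation(*TRIO) == pytest.approx(0.875, abs=1e-12)
        assert partial_correlation(0.8, 0.9, 0.6) == pytest.approx(0.7456011350793258)
        assert partial_correlation(0.6, 0.9, 0.8) == pytest.approx(-0.45883146774112404)

    def test_trio_epsilon_hand_value(self):
        assert trio_epsilon(*TRIO) == pytest.approx(TRIO_EPS, abs=1e-12)

    @pytest.mark.parametrize("impl", [pcit_significance, pcit_brute_force])
    def test_worked_trio_elimination_pattern(self, impl):
        """x-y and x-z survive; y-z is explainable through x and is dropped."""
        corr = corr_from_matrix([[1.0, 0.9, 0.8], [0.9, 1.0, 0.6], [0.8, 0.6, 1.0]])
        result = impl(corr)
        assert result.significant[0, 1] and result.significant[0, 2]
        assert not result.significant[1, 2]

    @pytest.mark.parametrize("impl", [pcit_significance, pcit_brute_force])
    def test_all_zero_correlations_stay_significant(self, impl):
        """A zero tolerance is vacuous: orthogonal pairs are not eliminated."""
        corr = corr_from_matrix(np.eye(4))
        assert impl(corr).significant.sum() == 12

    @pytest.mark.parametrize("impl", [pcit_significance, pcit_brute_force])
    def test_two_genes_vacuously_significant(self, impl):
        corr = corr_from_matrix([[1.0, 0.3], [0.3, 1.0]])
        assert impl(corr).significant[0, 1]

    def test_perfect_collinearity_rejected(self):
        corr = corr_from_matrix([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        with pytest.raises(ValueError, match="collinear"):
            pcit_significance(corr)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_instances(self, seed):
        """Vectorized kernel and brute-force trio oracle agree bit-for-bit."""
        rng = np.random.default_rng(seed)
        corr = random_correlation(seed, int(rng.integers(3, 26)))
        fast = pcit_significance(corr).significant
        slow = pcit_brute_force(corr).significant
        assert np.array_equal(fast, slow)

    def test_permutation_equivariance(self):
        corr = random_correlation(42, 12)
        perm = np.random.default_rng(0).permutation(12)
        permuted = CorrelationMatrix(
            tuple(corr.genes[i] for i in perm), corr.r[np.ix_(perm, perm)]
        )
        base = pcit_significance(corr).significant
        shuffled = pcit_significance(permuted).significant
        assert np.array_equal(shuffled, base[np.ix_(perm, perm)])


class TestThreshold:
    def make_result(self, r_value: float) -> PCITResult:
        corr = corr_from_matrix([[1.0, r_value], [r_value, 1.0]])
        return pcit_significance(corr)

    @pytest.mark.parametrize(
        "r,included", [(0.69, False), (0.71, True), (0.7, True), (-0.9, True), (-0.69, False)]
    )
    def test_boundary_behaviour(self, r, included):
        edges = threshold_edges(self.make_result(r), 0.7)
        assert (len(edges) == 1) is included
        if included:
            assert edges["weight"].iloc[0] == pytest.approx(r)

    def test_strict_mode_excludes_exact_cutoff(self):
        assert len(threshold_edges(self.make_result(0.7), 0.7, inclusive=False)) == 0

    def test_drop_negative(self):
        assert len(threshold_edges(self.make_result(-0.9), 0.7, keep_negative=False)) == 0

    def test_all_false_mask_gives_empty_edge_list(self):
        result = self.make_result(0.9)
        silenced = PCITResult(result.correlation, np.zeros((2, 2), dtype=bool))
        assert len(threshold_edges(silenced)) == 0

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            threshold_edges(self.make_result(0.9), 0.0)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_raising_cutoff_never_adds_edges(self, seed):
        result = pcit_significance(random_correlation(seed, 15))
        previous = None
        for cutoff in (0.1, 0.3, 0.5, 0.7, 0.9):
            edges = threshold_edges(result, cutoff)
            pairs = set(zip(edges["gene_a"], edges["gene_b"]))
            assert all(abs(w) >= cutoff for w in edges["weight"])
            if previous is not None:
                assert pairs <= previous
            previous = pairs

    def test_canonical_edge_ordering(self):
        result = pcit_significance(random_correlation(11, 10))
        edges = threshold_edges(result, 0.05)
        assert (edges["gene_a"] < edges["gene_b"]).all()
        assert edges.equals(edges.sort_values(["gene_a", "gene_b"], ignore_index=True))
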