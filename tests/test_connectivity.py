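"""Cross-subject Pearson connectivity, seed maps, Fisher-z tests, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metconn.connectivity import (
    ConnectivityMatrix,
    compare_edge_correlations,
    correlation_matrix,
    fdr_adjust,
    permutation_edge_pvalue,
    seed_connectivity,
    seed_edge_tests,
)


def brute_force_bh(p):
    """min over j >= i of p_(j) * m / j, step-up, order restored."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q_sorted[rank - 1] = min(
            min(p[order[j - 1]] * m / j for j in range(rank, m + 1)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestCorrelationMatrix:
    def test_duplicated_column_r_one(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 2] = x[:, 0]
        c = correlation_matrix(x)
        assert c.r[0, 2] == pytest.approx(1.0)

    def test_negated_column_r_minus_one(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 1] = -x[:, 0] + 5.0
        c = correlation_matrix(x)
        assert c.r[0, 1] == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self, rng):
        x = rng.normal(size=(5, 3))
        c = correlation_matrix(x)
        for i in range(3):
            for j in range(3):
                xi = x[:, i] - x[:, i].mean()
                xj = x[:, j] - x[:, j].mean()
                ref = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(c.r[i, j] - ref) < 1e-12

    def test_zero_variance_column_maps_to_zero(self, rng):
        x = rng.normal(size=(8, 3))
        x[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            c = correlation_matrix(x)
        assert np.all(c.r[1, [0, 2]] == 0.0)
        assert c.r[1, 1] == 1.0

    def test_too_few_subjects_raises(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            correlation_matrix(rng.normal(size=(2, 4)))

    def test_invariants_on_cohort(self, small_cohort):
        c = correlation_matrix(small_cohort.group_suv("LS"), group="LS")
        assert np.allclose(c.r, c.r.T)
        assert np.allclose(np.diag(c.r), 1.0)
        assert np.abs(c.r).max() <= 1.0


class TestSeedConnectivity:
    def test_identity_matrix_gives_zeros(self):
        c = ConnectivityMatrix(np.eye(5), 10,
                               region_names=tuple("ABCDE"))
        s = seed_connectivity(c, "C")
        assert len(s) == 4
        assert (s == 0).all()

    def test_matches_matrix_row(self, small_cohort):
        c = correlation_matrix(small_cohort.group_suv("HC"))
        s = seed_connectivity(c, "R3")
        row = np.delete(c.r[3], 3)
        assert np.array_equal(s.to_numpy(), row)
        assert len(s) == c.r.shape[0] - 1

    def test_unknown_region_lists_valid_names(self, small_cohort):
        c = correlation_matrix(small_cohort.group_suv("HC"))
        with pytest.raises(KeyError, match="R0"):
            seed_connectivity(c, "NotARegion")


class TestCompareEdgeCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_edge_correlations(0.5, 70, 0.5, 70)
        assert z == 0.0
        assert p == 1.0

    def test_derived_value(self):
        # atanh(0.8) - atanh(0.2) over sqrt(2/67)
        z, p = compare_edge_correlations(0.8, 70, 0.2, 70)
        assert z == pytest.approx(5.1857, abs=1e-3)
        assert p < 1e-6

    def test_antisymmetry(self):
        z1, p1 = compare_edge_correlations(0.7, 50, 0.3, 60)
        z2, p2 = compare_edge_correlations(0.3, 60, 0.7, 50)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_perfect_correlation_raises(self):
        with pytest.raises(ValueError, match="infinite"):
            compare_edge_correlations(1.0, 20, 0.5, 20)

    def test_small_n_raises(self):
        with pytest.raises(ValueError, match="n >= 4"):
            compare_edge_correlations(0.5, 3, 0.5, 20)

    def test_agrees_with_permutation_on_equal_correlation(self, rng):
        cov = [[1, 0.5], [0.5, 1]]
        a = rng.multivariate_normal([0, 0], cov, 70)
        b = rng.multivariate_normal([0, 0], cov, 70)
        r1 = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
        r2 = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
        _, p_fisher = compare_edge_correlations(r1, 70, r2, 70)
        _, p_perm = permutation_edge_pvalue(
            a[:, 0], a[:, 1], b[:, 0], b[:, 1], n_perm=2000, rng=1
        )
        assert abs(p_fisher - p_perm) < 0.12


class TestFDRAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_known_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(q, brute_force_bh([0.01, 0.02, 0.03, 0.04]))

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=40)
    )
    def test_property_matches_brute_force(self, p):
        q = fdr_adjust(p)
        assert np.allclose(q, brute_force_bh(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0 + 1e-15).all()


class TestSeedEdgeTests:
    def test_columns_and_family_size(self, small_cohort):
        c1 = correlation_matrix(small_cohort.group_suv("LS"), group="LS")
        c2 = correlation_matrix(small_cohort.group_suv("HC"), group="HC")
        out = seed_edge_tests(c1, c2, "R0")
        assert len(out) == 9
        assert {"region", "r_LS", "r_HC", "z", "p", "q"} <= set(out.columns)
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_permutation_method_tracks_fisher(self, small_cohort):
        x1 = small_cohort.group_suv("LS")
        x2 = small_cohort.group_suv("HC")
        c1 = correlation_matrix(x1, group="LS")
        c2 = correlation_matrix(x2, group="HC")
        fisher = seed_edge_tests(c1, c2, "R0")
        perm = seed_edge_tests(c1, c2, "R0", method="permutation",
                               suv1=x1.to_numpy(), suv2=x2.to_numpy(),
                               n_perm=400, rng=0)
        # identical observed r's and z's; p-values broadly consistent
        assert np.allclose(perm["z"], fisher["z"])
        assert np.corrcoef(perm["p"], fisher["p"])[0, 1] > 0.8

    def test_permutation_method_requires_suv(self, small_cohort):
        c1 = correlation_matrix(small_cohort.group_suv("LS"), group="LS")
        c2 = correlation_matrix(small_cohort.group_suv("HC"), group="HC")
        with pytest.raises(ValueError, match="suv1"):
            seed_edge_tests(c1, c2, "R0", method="permutation")
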