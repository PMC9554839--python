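"""CLR, Aitchison distance, rho proportionality, ensemble and differential networks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vebakit.compositional_networks import (
    AssociationNetwork,
    aitchison_distance,
    clr_transform,
    differential_network,
    ensemble_network,
    prevalence_filter,
    rho_dissimilarity_linkage,
    rho_matrix,
    rho_proportionality,
)


def _counts(values, features=None):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=features or [f"f{i}" for i in range(arr.shape[1])],
    )


class TestClr:
    def test_constant_row_maps_to_zero(self):
        comp = clr_transform(_counts([[5, 5, 5]]))
        np.testing.assert_allclose(comp.clr.to_numpy(), 0.0, atol=1e-12)

    def test_direct_arithmetic_oracle(self):
        x = np.array([1.0, 2.0, 4.0])
        comp = clr_transform(_counts([x]))
        pseudo = 1.0 / 9.0
        logged = np.log(x + pseudo)
        expected = logged - logged.mean()
        np.testing.assert_allclose(comp.clr.to_numpy()[0], expected, atol=1e-12)
        assert comp.pseudo_count == pytest.approx(pseudo)

    def test_feature_permutation_equivariance(self):
        counts = _counts([[1, 2, 4], [3, 0, 7]])
        comp = clr_transform(counts)
        permuted = clr_transform(counts[["f2", "f0", "f1"]])
        np.testing.assert_allclose(
            permuted.clr[["f0", "f1", "f2"]].to_numpy(),
            comp.clr.to_numpy(),
            atol=1e-12,
        )

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(_counts([[1.0]]))

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000), m=st.integers(2, 20), n=st.integers(1, 10))
    def test_rows_sum_to_zero(self, seed, m, n):
        rng = np.random.default_rng(seed)
        comp = clr_transform(_counts(rng.integers(0, 1000, size=(n, m))))
        np.testing.assert_allclose(comp.clr.sum(axis=1).to_numpy(), 0.0, atol=1e-9)


class TestAitchison:
    def test_identity_and_symmetry(self):
        comp = clr_transform(_counts([[1, 2, 3], [4, 5, 6]]))
        a, b = comp.clr.iloc[0], comp.clr.iloc[1]
        assert aitchison_distance(a, a) == 0.0
        assert aitchison_distance(a, b) == aitchison_distance(b, a)

    def test_hand_computed_norm(self):
        a = np.array([1.0, -0.5, -0.5])
        b = np.array([0.0, 0.5, -0.5])
        assert aitchison_distance(a, b) == pytest.approx(np.sqrt(1.0 + 1.0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aitchison_distance([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_metric_axioms_on_random_compositions(self, seed):
        rng = np.random.default_rng(seed)
        comp = clr_transform(_counts(rng.integers(1, 100, size=(4, 6))))
        rows = [comp.clr.iloc[i].to_numpy() for i in range(4)]
        for i, j, k in itertools.permutations(range(4), 3):
            dij = aitchison_distance(rows[i], rows[j])
            assert dij >= 0
            assert dij == pytest.approx(aitchison_distance(rows[j], rows[i]))
            assert dij <= (
                aitchison_distance(rows[i], rows[k])
                + aitchison_distance(rows[k], rows[j])
                + 1e-9
            )


class TestRho:
    def test_self_proportionality_is_one(self):
        x = np.array([0.1, -0.4, 0.3, 0.2, -0.2])
        assert rho_proportionality(x, x) == pytest.approx(1.0)

    def test_anti_proportionality_is_minus_one(self):
        x = np.array([0.5, -0.5, 0.25, -0.25])
        assert rho_proportionality(x, -x) == pytest.approx(-1.0)

    def test_zero_total_variance_flagged(self):
        with pytest.raises(ValueError):
            rho_proportionality(np.zeros(5), np.zeros(5))

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_both_algebraic_forms_agree(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        variance_form = rho_proportionality(x, y)
        cov_form = 2.0 * np.cov(x, y, ddof=1)[0, 1] / (
            np.var(x, ddof=1) + np.var(y, ddof=1)
        )
        assert variance_form == pytest.approx(cov_form, abs=1e-12)
        assert -1.0 - 1e-12 <= variance_form <= 1.0 + 1e-12

    def test_matrix_matches_pairwise_scalar(self):
        rng = np.random.default_rng(3)
        clr = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        mat = rho_matrix(clr)
        for x, y in itertools.combinations(clr.columns, 2):
            assert mat.at[x, y] == pytest.approx(
                rho_proportionality(clr[x], clr[y]), abs=1e-12
            )
        np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0)


class TestEnsembleNetwork:
    def test_degenerate_ensemble_equals_plain_network(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng.integers(1, 500, size=(10, 6)))
        net = ensemble_network(counts, n_iterations=1, resample=False)
        plain = rho_matrix(clr_transform(counts).clr)
        np.testing.assert_allclose(net.rho.to_numpy(), plain.to_numpy(), atol=1e-12)

    def test_perfectly_proportional_features(self):
        # counts large enough that the 1/m^2 pseudo-count perturbs the exact
        # 2x proportionality negligibly
        rng = np.random.default_rng(1)
        base = rng.integers(10_000, 100_000, size=10).astype(float)
        counts = _counts(
            np.column_stack([base, 2 * base, rng.integers(10_000, 100_000, size=10),
                             rng.integers(10_000, 100_000, size=10)])
        )
        net = ensemble_network(counts, n_iterations=20, seed=0)
        assert net.rho.at["f0", "f1"] == pytest.approx(1.0, abs=1e-9)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        counts = _counts(rng.integers(0, 300, size=(8, 5)))
        a = ensemble_network(counts, n_iterations=25, seed=99)
        b = ensemble_network(counts, n_iterations=25, seed=99)
        pd.testing.assert_frame_equal(a.rho, b.rho)

    def test_ensemble_converges_to_plain_rho(self):
        rng = np.random.default_rng(4)
        counts = _counts(rng.integers(1, 1000, size=(60, 4)))
        plain = rho_matrix(clr_transform(counts).clr).to_numpy()
        net = ensemble_network(counts, n_iterations=400, seed=0)
        # bootstrap mean approaches the plain estimate (stochastic tolerance)
        assert np.nanmax(np.abs(net.rho.to_numpy() - plain)) < 0.15

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ensemble_network(_counts([[1, 2], [3, 4], [5, 6]]), n_iterations=5)


class TestDifferentialNetwork:
    def _net(self, rho, condition="x"):
        features = list("abc")[: rho.shape[0]]
        return AssociationNetwork(
            condition=condition,
            rho=pd.DataFrame(rho, index=features, columns=features),
            n_iterations=1,
        )

    def _pair_net(self, value, condition):
        return self._net(np.array([[1.0, value], [value, 1.0]]), condition)

    @pytest.mark.parametrize(
        "rho_a,rho_b,kept,diff",
        [
            (0.5, 0.3, True, 0.2),
            (0.5, -0.2, False, None),   # not positive in both
            (0.42, 0.38, False, None),  # |D| below cutoff
            (0.3, 0.5, True, -0.2),     # sign of D preserved
        ],
    )
    def test_edge_filter(self, rho_a, rho_b, kept, diff):
        table = differential_network(self._pair_net(rho_a, "a"), self._pair_net(rho_b, "b"))
        if kept:
            assert len(table) == 1
            assert table["diff"].iloc[0] == pytest.approx(diff)
        else:
            assert len(table) == 0

    def test_feature_set_mismatch_rejected(self):
        net2 = self._pair_net(0.5, "a")
        net3 = self._net(np.eye(3), "b")
        with pytest.raises(ValueError):
            differential_network(net2, net3)


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        vals = np.zeros((10, 2))
        vals[:4, 0] = 5  # f0 in 4/10 samples
        vals[:3, 1] = 5  # f1 in 3/10 samples
        out = prevalence_filter(_counts(vals), 0.4)
        assert list(out.columns) == ["f0"]

    def test_all_zero_feature_dropped(self):
        out = prevalence_filter(_counts([[0, 1], [0, 2]]), 0.1)
        assert list(out.columns) == ["f1"]


class TestRhoDissimilarityLinkage:
    def test_dissimilarity_bounds_and_first_merge(self):
        rho = np.array(
            [
                [1.0, 1.0, -1.0, 0.0],
                [1.0, 1.0, -0.9, 0.1],
                [-1.0, -0.9, 1.0, 0.2],
                [0.0, 0.1, 0.2, 1.0],
            ]
        )
        net = AssociationNetwork(
            "c", pd.DataFrame(rho, index=list("wxyz"), columns=list("wxyz")), 1
        )
        dissim, tree = rho_dissimilarity_linkage(net)
        assert dissim.at["w", "x"] == 0.0    # rho 1 -> distance 0, merged first
        assert dissim.at["w", "y"] == 2.0    # rho -1 -> distance 2
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}
        assert tree[0, 2] == pytest.approx(0.0)

    def test_four_feature_average_linkage_matches_hand_trace(self):
        # distances: wx=0.2, wy=0.9, wz=1.0, xy=0.8, xz=1.0, yz=0.3
        rho = 1.0 - np.array(
            [
                [0.0, 0.2, 0.9, 1.0],
                [0.2, 0.0, 0.8, 1.0],
                [0.9, 0.8, 0.0, 0.3],
                [1.0, 1.0, 0.3, 0.0],
            ]
        )
        np.fill_diagonal(rho, 1.0)
        net = AssociationNetwork(
            "c", pd.DataFrame(rho, index=list("wxyz"), columns=list("wxyz")), 1
        )
        _, tree = rho_dissimilarity_linkage(net)
        # hand trace: merge (w,x)@0.2, (y,z)@0.3, then clusters at
        # mean(wy, wz, xy, xz) = mean(0.9, 1.0, 0.8, 1.0) = 0.925
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}
        assert tree[0, 2] == pytest.approx(0.2)
        assert {int(tree[1, 0]), int(tree[1, 1])} == {2, 3}
        assert tree[1, 2] == pytest.approx(0.3)
        assert tree[2, 2] == pytest.approx(0.925)

    def test_non_finite_entries_rejected(self):
        rho = np.array([[1.0, np.nan], [np.nan, 1.0]])
        net = AssociationNetwork("c", pd.DataFrame(rho), 1)
        with pytest.raises(ValueError):
            rho_dissimilarity_linkage(net)
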