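"""Optimal matching, Ward clustering and cluster validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyadseq as dq
from dyadseq.om_cluster import CostMatrix, ward_cluster

UNIT_COSTS = CostMatrix(sub=2.0 * (1 - np.eye(4)), indel=1.0)


class TestCostMatrix:
    def test_trate_limits(self):
        # states 0 and 1 always follow each other -> cost 0;
        # states 2 and 3 never occur consecutively -> cost 2
        p = np.array(
            [
                [0.0, 1.0, 0.0, 0.0],
                [1.0, 0.0, 0.0, 0.0],
                [0.5, 0.5, 0.0, 0.0],
                [0.5, 0.5, 0.0, 0.0],
            ]
        )
        costs = dq.trate_costs(p)
        assert costs.sub[0, 1] == pytest.approx(0.0)
        assert costs.sub[2, 3] == pytest.approx(2.0)
        assert costs.sub[1, 0] == costs.sub[0, 1]

    def test_trate_formula_and_range(self, ref_transition):
        costs = dq.trate_costs(ref_transition)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert costs.sub[i, j] == 0.0
                else:
                    expected = 2 - ref_transition[i, j] - ref_transition[j, i]
                    assert costs.sub[i, j] == pytest.approx(expected)
                assert 0 <= costs.sub[i, j] <= 2

    def test_trate_accepts_model(self, ref_transition):
        model = dq.MarkovModel(np.full(4, 0.25), ref_transition)
        np.testing.assert_allclose(
            dq.trate_costs(model).sub, dq.trate_costs(ref_transition).sub
        )

    def test_asymmetric_sub_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            CostMatrix(sub=bad)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            CostMatrix(sub=np.ones((3, 3)))


class TestOMDistance:
    def test_deletion_toy_case(self):
        assert dq.om_distance([0, 1, 1, 1], [1, 1, 1], UNIT_COSTS) == pytest.approx(1.0)

    def test_identity(self):
        assert dq.om_distance([0, 1, 2, 3], [0, 1, 2, 3], UNIT_COSTS) == 0.0

    def test_single_substitution(self):
        costs = CostMatrix(sub=0.7 * (1 - np.eye(4)), indel=1.0)
        assert dq.om_distance([0, 1, 2], [0, 3, 2], costs) == pytest.approx(0.7)

    def test_prefers_cheaper_script(self):
        # substitution costs 2 > 2 indels? equal; make sub expensive: indel wins
        costs = CostMatrix(sub=3.0 * (1 - np.eye(4)), indel=1.0)
        assert dq.om_distance([0], [1], costs) == pytest.approx(2.0)

    def test_length_difference_lower_bound(self):
        d = dq.om_distance([0] * 6, [0] * 2, UNIT_COSTS)
        assert d == pytest.approx(4 * UNIT_COSTS.indel)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=10),
        st.lists(st.integers(0, 3), min_size=1, max_size=10),
        st.lists(st.integers(0, 3), min_size=1, max_size=10),
    )
    def test_metric_properties(self, a, b, c):
        d_ab = dq.om_distance(a, b, UNIT_COSTS)
        d_ba = dq.om_distance(b, a, UNIT_COSTS)
        assert d_ab == pytest.approx(d_ba)  # symmetry
        assert d_ab >= 0
        if a == b:
            assert d_ab == 0
        d_ac = dq.om_distance(a, c, UNIT_COSTS)
        d_cb = dq.om_distance(c, b, UNIT_COSTS)
        assert d_ab <= d_ac + d_cb + 1e-9  # triangle inequality

    def test_levenshtein_equivalence(self):
        # with unit indel and substitution costs, OM distance with indel 1 and
        # sub 1 is the plain Levenshtein distance on the state strings
        costs = CostMatrix(sub=1.0 * (1 - np.eye(4)), indel=1.0)

        def levenshtein(a, b):
            m, n = len(a), len(b)
            d = np.zeros((m + 1, n + 1))
            d[:, 0] = np.arange(m + 1)
            d[0, :] = np.arange(n + 1)
            for i in range(1, m + 1):
                for j in range(1, n + 1):
                    d[i, j] = min(
                        d[i - 1, j] + 1,
                        d[i, j - 1] + 1,
                        d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                    )
            return d[m, n]

        rng = np.random.default_rng(12)
        for _ in range(25):
            a = rng.integers(0, 4, rng.integers(1, 12))
            b = rng.integers(0, 4, rng.integers(1, 12))
            assert dq.om_distance(a, b, costs) == pytest.approx(levenshtein(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dq.om_distance([], [0, 1], UNIT_COSTS)


class TestDistanceMatrix:
    def test_matrix_properties(self, markov_dataset):
        sub = dq.Dataset(markov_dataset.pairs[:12])
        d = dq.distance_matrix(sub)
        assert d.n == 12
        np.testing.assert_allclose(d.values, d.values.T)
        np.testing.assert_allclose(np.diag(d.values), 0.0)
        assert (d.values >= 0).all()
        assert d.dyad_ids == [p.dyad_id for p in sub.pairs]

    def test_auto_costs_match_explicit_trate(self, markov_dataset):
        sub = dq.Dataset(markov_dataset.pairs[:8])
        model = dq.fit_markov(sub.state_sequences())
        costs = dq.trate_costs(np.nan_to_num(model.transition))
        np.testing.assert_allclose(
            dq.distance_matrix(sub).values, dq.distance_matrix(sub, costs).values
        )


class TestWardClustering:
    def test_matches_scipy_on_euclidean_data(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        pts = np.concatenate(
            [rng.normal(0, 1, (10, 2)), rng.normal(6, 1, (10, 2))]
        )
        d = squareform(pdist(pts))
        merge = ward_cluster(d)
        z = linkage(pdist(pts), method="ward")
        # heights agree (this implementation reports the squared scale)
        np.testing.assert_allclose(np.sqrt(merge[:, 2]), z[:, 2], rtol=1e-8)
        for k in (2, 3, 4):
            mine = dq.cut_tree(merge, k)
            ref = fcluster(z, k, criterion="maxclust")
            assert dq.agreement(mine, ref) == 100.0

    def test_merge_heights_monotone(self, markov_dataset):
        d = dq.distance_matrix(dq.Dataset(markov_dataset.pairs[:15]))
        merge = ward_cluster(d)
        assert (np.diff(merge[:, 2]) >= -1e-9).all()
        assert merge.shape == (14, 4)
        assert merge[-1, 3] == 15

    def test_cut_tree_extremes(self):
        d = np.array([[0, 1, 5.0], [1, 0, 5], [5, 5, 0]])
        merge = ward_cluster(d)
        assert len(np.unique(dq.cut_tree(merge, 1))) == 1
        assert len(np.unique(dq.cut_tree(merge, 3))) == 3
        labels = dq.cut_tree(merge, 2)
        assert labels[0] == labels[1] != labels[2]


class TestSilhouette:
    def test_matches_sklearn(self):
        from scipy.spatial.distance import pdist, squareform
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(5)
        pts = np.concatenate([rng.normal(0, 1, (8, 2)), rng.normal(5, 1, (8, 2))])
        d = squareform(pdist(pts))
        labels = np.repeat([0, 1], 8)
        np.testing.assert_allclose(
            dq.silhouette_widths(d, labels),
            silhouette_samples(d, labels, metric="precomputed"),
        )

    def test_values_in_range_and_singleton_zero(self):
        d = np.array(
            [[0, 1, 9, 9.0], [1, 0, 9, 9], [9, 9, 0, 9], [9, 9, 9, 0]]
        )
        labels = np.array([0, 0, 1, 2])
        widths = dq.silhouette_widths(d, labels)
        assert (widths >= -1).all() and (widths <= 1).all()
        assert widths[2] == 0.0 and widths[3] == 0.0  # singletons

    def test_selection_on_separated_data(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(2)
        pts = np.concatenate(
            [rng.normal(0, 0.5, (10, 2)), rng.normal(8, 0.5, (10, 2))]
        )
        d = squareform(pdist(pts))
        solution = dq.silhouette_select(d)
        assert solution.chosen_k == 2
        assert solution.reasonable_structure
        assert solution.labels.shape == (20,)
        assert solution.mds_coords.shape == (20, 2)
        assert (np.diff(solution.scree_heights) <= 1e-9).all()

    def test_mds_reconstructs_euclidean(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        coords = dq.classical_mds(d, 2)
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-8)


class TestValidation:
    def test_agreement_invariant_to_relabeling(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert dq.agreement(labels, 2 - labels) == 100.0
        assert dq.agreement(labels, labels) == 100.0

    def test_agreement_partial(self):
        l1 = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        l2 = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        # best matching: 0<->1 -> 7 of 8 agree
        assert dq.agreement(l1, l2) == pytest.approx(100 * 7 / 8)

    def test_agreement_too_many_groups(self):
        l1 = np.arange(7)
        with pytest.raises(ValueError, match="6 groups"):
            dq.agreement(l1, l1)

    def test_covariate_association_matches_pearson(self):
        from scipy import stats

        labels = np.array([0, 0, 0, 1, 1, 1])
        cov = np.array([1.0, 2.0, 1.5, 4.0, 5.0, 4.5])
        r, p = dq.covariate_association(labels, cov)
        r_ref, p_ref = stats.pearsonr((labels == 1).astype(float), cov)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref)

    def test_covariate_association_needs_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            dq.covariate_association([0, 0, 0], [1.0, 2.0, 3.0])
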