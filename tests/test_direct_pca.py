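"""Centering, JC69 compensation, the SVD core and its derived components."""

import numpy as np
import pytest

import directpca as dp
from directpca.direct_pca import Jc69SaturationError, _jc69_ratio

from conftest import random_alignment


class TestCenter:
    def test_worked_example_center(self, tagc_matrix):
        """{TAGC, GAGC} column means reproduce the printed center vector."""
        expected = [0,1,0,0, 0.5,0,0,0, 0.5,0,1,0, 0,0,0,1, 0,0,0,0]
        m = dp.compute_center(tagc_matrix)
        np.testing.assert_allclose(m.values, expected)
        assert m.source == "mean"

    def test_reference_subset_and_errors(self, tagc_matrix):
        m_ref = dp.compute_center(tagc_matrix, ["s1"])
        np.testing.assert_allclose(m_ref.values, tagc_matrix.values[0])
        m_all = dp.compute_center(tagc_matrix, ["s1", "s2"])
        np.testing.assert_allclose(
            m_all.values, dp.compute_center(tagc_matrix).values
        )
        with pytest.raises(ValueError, match="nope"):
            dp.compute_center(tagc_matrix, ["nope"])
        with pytest.raises(ValueError):
            dp.compute_center(tagc_matrix, [])

    def test_centered_rows_and_column_sums(self, tagc_matrix):
        D = dp.center_matrix(tagc_matrix, dp.compute_center(tagc_matrix))
        expected_row1 = np.zeros(20)
        expected_row1[4] = 0.5   # (T, pos 1)
        expected_row1[8] = -0.5  # (G, pos 1)
        np.testing.assert_allclose(D.values[0], expected_row1)
        np.testing.assert_allclose(D.values[1], -expected_row1)
        np.testing.assert_allclose(D.values.sum(axis=0), 0, atol=1e-15)
        assert not D.adjusted
        np.testing.assert_array_equal(D.compensation_ratios, 1.0)

    def test_centering_on_own_row_gives_zero(self):
        X = dp.encode_one_hot(dp.AlignedSequences(["s"], ["ACGT"]))
        D = dp.center_matrix(X, dp.compute_center(X))
        np.testing.assert_array_equal(D.values, 0.0)


class TestJc69Adjust:
    def test_zero_divergence_row_unchanged(self):
        X = dp.encode_one_hot(
            dp.AlignedSequences(["a", "b", "c"], ["ACGT", "ACGT", "AAGT"])
        )
        D = dp.jc69_adjust(dp.center_matrix(X, dp.compute_center(X, ["a"])))
        np.testing.assert_array_equal(D.values[0], 0.0)
        assert D.compensation_ratios[0] == 1.0
        assert D.adjusted

    def test_worked_ratio_value(self):
        # a row with sum |d| = 1 at l = 4: p = 1/8
        D = dp.CenteredMatrix(
            np.array([[0.5, -0.5, 0, 0, 0] + [0.0] * 15]), ["s"], 4, dp.DNA
        )
        adj = dp.jc69_adjust(D)
        assert adj.compensation_ratios[0] == pytest.approx(0.13674116759 / 0.125)
        np.testing.assert_allclose(
            adj.values, D.values * np.sqrt(1.0939293407), rtol=1e-9
        )

    def test_ratio_monotone_and_at_least_one(self):
        grid = np.linspace(0.0, 0.74, 200)
        ratios = _jc69_ratio(grid)
        assert np.all(ratios >= 1.0)
        assert np.all(np.diff(ratios) > 0)

    def test_saturation_names_sample(self):
        # completely different from the center at every position: p = 1
        row = np.zeros(20)
        row[:4] = [1, -1, 0, 0]
        D = dp.CenteredMatrix(np.tile(row, (2, 1)) * [[1], [2]], ["ok", "hot"], 1, dp.DNA)
        D.values[0] *= 0.1
        with pytest.raises(Jc69SaturationError, match="hot"):
            dp.jc69_adjust(D)

    def test_cluster_order_preserved_and_ratios_ge_one(self):
        aligned, labels = dp.simulate_clustered_population(
            (10, 10), 200, 0.03, 0.002, seed=5
        )
        X = dp.encode_one_hot(aligned)
        D = dp.center_matrix(X, dp.compute_center(X))
        raw = dp.run_direct_pca(D)
        adj_D = dp.jc69_adjust(D)
        adj = dp.run_direct_pca(adj_D)
        assert np.all(adj_D.compensation_ratios >= 1.0)
        raw1 = raw.scaled_sample_components[:, 0]
        adj1 = adj.scaled_sample_components[:, 0]
        d_raw = raw1[:, None] - raw1[None, :]
        d_adj = adj1[:, None] - adj1[None, :]
        informative = np.abs(d_raw) > 1e-9
        signs = np.sign(d_raw[informative] * d_adj[informative])
        assert (signs > 0).all() or (signs < 0).all()


class TestSvdCore:
    def test_worked_example_components(self, tagc_result):
        """{TAGC, GAGC}: one axis, sigma 1, scores ±0.35355, loadings ±0.5."""
        res = tagc_result
        assert res.rank == 1
        np.testing.assert_allclose(res.singular_values, [1.0], atol=1e-12)
        np.testing.assert_allclose(res.contributions, [100.0])
        np.testing.assert_allclose(
            np.sort(res.scaled_sample_components[:, 0]),
            [-0.35355339, 0.35355339],
            atol=1e-8,
        )
        n_hat = res.scaled_base_components[:, 0]
        np.testing.assert_allclose(n_hat[4], 0.5, atol=1e-12)   # (T, pos 1)
        np.testing.assert_allclose(n_hat[8], -0.5, atol=1e-12)  # (G, pos 1)
        assert np.abs(np.delete(n_hat, [4, 8])).max() < 1e-12

    def test_needs_two_samples(self):
        X = dp.encode_one_hot(dp.AlignedSequences(["s"], ["ACGT"]))
        with pytest.raises(ValueError):
            dp.run_direct_pca(dp.center_matrix(X, dp.compute_center(X)))

    def test_no_variation_returns_empty_with_warning(self):
        X = dp.encode_one_hot(dp.AlignedSequences(["a", "b"], ["ACGT", "ACGT"]))
        D = dp.center_matrix(X, dp.compute_center(X))
        with pytest.warns(UserWarning, match="no variation"):
            res = dp.run_direct_pca(D)
        assert res.rank == 0
        assert res.contributions.size == 0

    def test_duplicate_sequences_have_identical_scores(self):
        aligned = dp.AlignedSequences(
            ["a", "b", "c"], ["ACGTACGT", "TCGTACGA", "TCGTACGA"]
        )
        X = dp.encode_one_hot(aligned)
        res = dp.run_direct_pca(dp.center_matrix(X, dp.compute_center(X)))
        np.testing.assert_allclose(
            res.sample_components[1], res.sample_components[2], atol=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reconstruction_and_identities(self, seed):
        rng = np.random.default_rng(seed)
        aligned = random_alignment(rng, 12, 40)
        X = dp.encode_one_hot(aligned)
        D = dp.center_matrix(X, dp.compute_center(X))
        res = dp.run_direct_pca(D)
        recon = res.left_vectors @ np.diag(res.singular_values) @ res.right_vectors.T
        assert np.linalg.norm(recon - D.values) <= 1e-8 * np.linalg.norm(D.values)
        # S = DR and N = D^T L
        np.testing.assert_allclose(
            res.sample_components, D.values @ res.right_vectors, atol=1e-10
        )
        np.testing.assert_allclose(
            res.base_components, D.values.T @ res.left_vectors, atol=1e-10
        )
        # orthonormal factors
        np.testing.assert_allclose(
            res.left_vectors.T @ res.left_vectors, np.eye(res.rank), atol=1e-10
        )
        np.testing.assert_allclose(
            res.right_vectors.T @ res.right_vectors, np.eye(res.rank), atol=1e-10
        )
        assert res.contributions.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_rotation_preserves_sample_distances(self):
        rng = np.random.default_rng(9)
        aligned = random_alignment(rng, 10, 30)
        X = dp.encode_one_hot(aligned)
        D = dp.center_matrix(X, dp.compute_center(X))
        res = dp.run_direct_pca(D)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(res.sample_components), pdist(D.values), atol=1e-9
        )
        # distance between scaled scores = sqrt(2 * substitution rate)
        dm = dp.pairwise_distances(X)
        from scipy.spatial.distance import squareform

        np.testing.assert_allclose(
            squareform(pdist(res.scaled_sample_components)),
            np.sqrt(2.0 * dm.prate),
            atol=1e-9,
        )

    def test_effective_rank_at_most_n_minus_one(self):
        rng = np.random.default_rng(21)
        aligned = random_alignment(rng, 6, 100)
        X = dp.encode_one_hot(aligned)
        res = dp.run_direct_pca(dp.center_matrix(X, dp.compute_center(X)))
        assert res.rank <= aligned.n - 1


class TestProjection:
    def test_training_projection_reproduces_scores(self, clustered_fixture):
        aligned, _, X, result = clustered_fixture
        m = dp.compute_center(X)
        np.testing.assert_allclose(
            dp.project_samples(X, m, result),
            result.scaled_sample_components,
            atol=1e-9,
        )

    def test_center_projects_to_origin(self, tagc_matrix, tagc_result):
        m = dp.compute_center(tagc_matrix)
        center_as_matrix = dp.SequenceMatrix(
            m.values[None, :], ["center"], tagc_matrix.l, tagc_matrix.alphabet
        )
        np.testing.assert_allclose(
            dp.project_samples(center_as_matrix, m, tagc_result), 0.0, atol=1e-12
        )

    def test_length_mismatch_rejected(self, tagc_result):
        Xq = dp.encode_one_hot(dp.AlignedSequences(["q"], ["ACGTA"]))
        m = dp.CenterVector(np.zeros(25), "mean", 5, dp.DNA)
        with pytest.raises(ValueError):
            dp.project_samples(Xq, m, tagc_result)

    def test_held_out_sample_lands_in_its_cluster(self):
        aligned, labels = dp.simulate_clustered_population(seed=17)
        held_idx = 5  # a cluster1 member
        keep = [i for i in range(aligned.n) if i != held_idx]
        train = dp.AlignedSequences(
            [aligned.ids[i] for i in keep], [aligned.rows[i] for i in keep]
        )
        X = dp.encode_one_hot(train)
        m = dp.compute_center(X)
        result = dp.run_direct_pca(dp.center_matrix(X, m))
        held = dp.AlignedSequences(
            [aligned.ids[held_idx]], [aligned.rows[held_idx]]
        )
        score = dp.project_samples(dp.encode_one_hot(held), m, result)[0, :2]
        lab = np.array([labels[i] for i in keep])
        S = result.scaled_sample_components[:, :2]
        centroids = {g: S[lab == g].mean(axis=0) for g in set(lab)}
        nearest = min(centroids, key=lambda g: np.linalg.norm(score - centroids[g]))
        assert nearest == labels[held_idx]


class TestCharacteristicBases:
    def test_worked_example_sets(self, tagc_result):
        cb = dp.characteristic_bases(tagc_result, axis=1, threshold=0.05)
        assert [(p, s) for p, s, _ in cb.positive_bases] == [(1, "T")]
        assert [(p, s) for p, s, _ in cb.negative_bases] == [(1, "G")]
        assert cb.positive_bases[0][2] == pytest.approx(0.5)
        assert cb.negative_bases[0][2] == pytest.approx(-0.5)

    def test_threshold_above_max_gives_empty_sets(self, tagc_result):
        cb = dp.characteristic_bases(tagc_result, axis=1, threshold=0.9)
        assert cb.positive_bases == [] and cb.negative_bases == []

    def test_axis_out_of_range(self, tagc_result):
        with pytest.raises(ValueError):
            dp.characteristic_bases(tagc_result, axis=2, threshold=0.05)


class TestGroupDispersion:
    def test_identical_sequences_disperse_zero(self):
        X = dp.encode_one_hot(
            dp.AlignedSequences(["a", "b"], ["ACGT", "ACGT"])
        )
        per, total = dp.group_dispersion(X, {"a": "g", "b": "g"})
        assert per["g"] == 0.0 and total == 0.0

    def test_single_mismatch_pair_value(self):
        # two sequences differing at one of four positions: each 0.5 from
        # the center, scaled by sqrt(l) = 2 -> 0.25
        X = dp.encode_one_hot(dp.AlignedSequences(["a", "b"], ["ACGT", "TCGT"]))
        per, total = dp.group_dispersion(X, {"a": "g", "b": "g"})
        assert per["g"] == pytest.approx(0.25)
        assert total == pytest.approx(0.25)

    def test_invariant_to_relabeling_and_order(self, clustered_fixture):
        aligned, labels, X, _ = clustered_fixture
        groups = dict(zip(aligned.ids, labels))
        per1, total1 = dp.group_dispersion(X, groups)
        renamed = {k: "x" + v for k, v in groups.items()}
        per2, total2 = dp.group_dispersion(X, renamed)
        assert total1 == total2
        for g in per1:
            assert per1[g] == pytest.approx(per2["x" + g])

    def test_unassigned_sample_rejected(self, tagc_matrix):
        with pytest.raises(ValueError, match="s2"):
            dp.group_dispersion(tagc_matrix, {"s1": "g"})


class TestStructuralProperties:
    def test_cluster_count_readable_from_spectrum(self, clustered_fixture):
        """g well-separated clusters give exactly g-1 dominant axes."""
        _, labels, _, result = clustered_fixture
        s = result.singular_values
        assert s[0] > 5 * s[2] and s[1] > 5 * s[2]
        lab = np.array(labels)
        S = result.scaled_sample_components[:, :2]
        centroids = {g: S[lab == g].mean(axis=0) for g in set(labels)}
        assign = [
            min(centroids, key=lambda g: np.linalg.norm(row - centroids[g]))
            for row in S
        ]
        assert (np.array(assign) == lab).all()

    def test_outlier_leaves_leading_axis_and_motif_sinks(self):
        """A private-motif outlier barely moves sPC1; its motif loads lower."""
        report = dp.outlier_robustness_experiment(seed=23)
        assert report["direct_correlation"] > 0.99
        assert report["motif_axis"] > 2
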