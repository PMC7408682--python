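"""GGM estimation, EBIC selection, centrality, dietary scores, tertiles."""

import numpy as np
import pandas as pd
import pytest

from comorisk import reference
from comorisk.network import (
    CentralityWeights,
    PartialCorrelationNetwork,
    dietary_score,
    ebic,
    eigenvector_centrality,
    estimate_ggm,
    partial_correlations,
    score_cohort,
    tertile_classes,
)
from comorisk.simulate import INTAKE_COLUMNS


def _colored_data(rng, cov, n):
    """Data whose *sample* covariance equals ``cov`` exactly."""
    p = cov.shape[0]
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    S = (X.T @ X) / n
    W = np.linalg.inv(np.linalg.cholesky(S))
    return X @ W.T @ np.linalg.cholesky(cov).T


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-50.0, 200, 16, 7, 0.0) == pytest.approx(100 + 7 * np.log(200))

    def test_no_edges_leaves_only_deviance(self):
        assert ebic(-123.4, 500, 16, 0, 0.5) == pytest.approx(246.8)

    def test_hand_computed_value(self):
        # -2(-100) + 10 log 100 + 4*10*0.5 log 16
        expected = 200 + 10 * np.log(100) + 20 * np.log(16)
        assert ebic(-100.0, 100, 16, 10, 0.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(301.5035, abs=5e-4)

    def test_rejects_negative_gamma(self):
        with pytest.raises(ValueError):
            ebic(0.0, 10, 4, 1, -0.1)


class TestEstimateGgm:
    def test_penalty_zero_matches_covariance_inversion_oracle(self, rng):
        p = 6
        A = rng.standard_normal((p, p))
        cov = A @ A.T + p * np.eye(p)
        X = rng.multivariate_normal(np.zeros(p), cov, size=400)
        net = estimate_ggm(X, penalty_grid=np.array([0.0]))
        Z = (X - X.mean(0)) / X.std(0)
        oracle = partial_correlations((Z.T @ Z) / len(Z))
        assert np.abs(net.weights - oracle).max() < 1e-6

    def test_three_variable_exact_covariance_closed_form(self, rng):
        omega = np.array([[2.0, -0.6, 0.0], [-0.6, 1.5, -0.3], [0.0, -0.3, 1.0]])
        cov = np.linalg.inv(omega)
        X = _colored_data(rng, cov, 60)
        net = estimate_ggm(X, penalty_grid=np.array([0.0]))
        d = np.sqrt(np.diag(omega))
        expected = -omega / np.outer(d, d)
        np.fill_diagonal(expected, 0.0)
        assert np.abs(net.weights - expected).max() < 1e-6

    def test_independent_columns_get_no_edges(self):
        from comorisk.simulate import latent_pcor_to_covariance

        rng = np.random.default_rng(0)
        n = 1000
        sub = reference.reference_network_matrix().to_numpy()[:14, :14]
        L = np.linalg.cholesky(latent_pcor_to_covariance(sub))
        connected = rng.standard_normal((n, 14)) @ L.T
        X = np.column_stack([connected, rng.standard_normal((n, 2))])
        net = estimate_ggm(X, gamma=0.5)
        assert np.all(net.weights[:, 14:] == 0.0)
        assert net.n_edges > 0  # the dependent block keeps its structure

    def test_recovers_strong_reference_edges(self, clean_cohort):
        logx = pd.DataFrame(
            np.log(clean_cohort[INTAKE_COLUMNS].to_numpy()), columns=reference.FOOD_GROUPS
        )
        net = estimate_ggm(logx, gamma=0.5)
        true = reference.reference_network_matrix().to_numpy()
        strong = (np.abs(true) >= 0.10) & np.triu(np.ones_like(true, bool), 1)
        recovered = (net.weights != 0)[strong]
        assert recovered.mean() >= 0.80

    def test_edge_count_non_increasing_in_gamma(self, clean_cohort):
        logx = np.log(clean_cohort[INTAKE_COLUMNS].to_numpy()[:1200])
        edges = [estimate_ggm(logx, gamma=g, grid_size=40).n_edges
                 for g in (0.0, 0.25, 0.5, 1.0)]
        assert edges == sorted(edges, reverse=True)

    def test_permuting_columns_permutes_network(self, clean_cohort):
        logx = np.log(clean_cohort[INTAKE_COLUMNS].to_numpy()[:1500])
        perm = np.random.default_rng(3).permutation(16)
        net = estimate_ggm(logx, grid_size=30)
        net_p = estimate_ggm(logx[:, perm], grid_size=30)
        # coordinate descent tolerance bounds the column-order dependence
        assert np.allclose(net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-3)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError, match="more samples"):
            estimate_ggm(np.zeros((10, 16)))
        X = np.random.default_rng(0).standard_normal((50, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero variance"):
            estimate_ggm(X)


class TestEigenvectorCentrality:
    def test_matches_dense_eigendecomposition_oracle(self, reference_network, rng):
        nets = [reference_network]
        for _ in range(5):
            M = rng.uniform(-0.3, 0.3, (8, 8)) * (rng.random((8, 8)) < 0.4)
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            if not np.any(M > 0):
                continue
            nets.append(PartialCorrelationNetwork(labels=[f"v{i}" for i in range(8)], weights=M))
        for net in nets:
            for convention in ("positive", "absolute"):
                got = eigenvector_centrality(net, convention=convention).weight
                M = np.where(net.weights > 0, net.weights, 0) if convention == "positive" else np.abs(net.weights)
                evals, evecs = np.linalg.eigh(M)
                lead = np.abs(evecs[:, np.argmax(evals)])
                assert np.abs(got - lead / lead.max()).max() < 1e-8

    def test_path_graph_closed_form(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = M[1, 2] = M[2, 1] = 0.5
        net = PartialCorrelationNetwork(labels=["a", "b", "c"], weights=M)
        c = eigenvector_centrality(net).to_series()
        assert c["b"] == pytest.approx(1.0)
        assert c["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-8)
        assert c["c"] == pytest.approx(1 / np.sqrt(2), abs=1e-8)

    def test_reference_network_reproduces_published_weights(self, reference_weights):
        s = reference_weights.to_series()
        assert s["seasonings"] == pytest.approx(1.0)
        assert s.idxmax() == "seasonings"
        assert s["vegetables"] == pytest.approx(0.76, abs=0.05)
        assert s["fish_shellfish"] == pytest.approx(0.70, abs=0.05)

    def test_empty_network_fails(self):
        net = PartialCorrelationNetwork(labels=["a", "b"], weights=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="no usable edges"):
            eigenvector_centrality(net)

    def test_isolated_node_scores_zero(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 0.4
        net = PartialCorrelationNetwork(labels=["a", "b", "c"], weights=M)
        assert eigenvector_centrality(net).to_series()["c"] == pytest.approx(0.0, abs=1e-9)


class TestDietaryScore:
    def test_identity_weights_give_total_intake(self):
        w = CentralityWeights(labels=list("abc"), weight=np.ones(3))
        assert dietary_score(np.array([10.0, 20.0, 5.0]), w) == pytest.approx(35.0)

    def test_zero_intake_scores_zero(self, reference_weights):
        assert dietary_score(np.zeros(16), reference_weights) == pytest.approx(0.0)

    def test_max_weight_group_passes_through(self, reference_weights):
        intake = pd.Series(0.0, index=reference_weights.labels)
        intake["seasonings"] = 100.0
        assert dietary_score(intake, reference_weights) == pytest.approx(100.0)

    def test_label_mismatch_fails(self, reference_weights):
        intake = pd.Series(1.0, index=list(reversed(reference_weights.labels)))
        with pytest.raises(ValueError, match="match"):
            dietary_score(intake, reference_weights)

    def test_scale_equivariance_and_stable_tertiles(self, clean_cohort, reference_weights):
        intakes = clean_cohort[INTAKE_COLUMNS].iloc[:900].copy()
        intakes.columns = reference_weights.labels
        s1 = score_cohort(intakes, reference_weights)
        s3 = score_cohort(intakes * 3.0, reference_weights)
        assert np.allclose(s3["dietary_score"], 3 * s1["dietary_score"])
        assert (s1["eating_behavior"] == s3["eating_behavior"]).all()

    def test_permutation_equivariance_of_scores(self, clean_cohort, reference_weights):
        intakes = clean_cohort[INTAKE_COLUMNS].iloc[:200].copy()
        intakes.columns = reference_weights.labels
        perm = np.random.default_rng(8).permutation(16)
        labels_p = [reference_weights.labels[i] for i in perm]
        w_p = CentralityWeights(labels=labels_p, weight=reference_weights.weight[perm])
        assert np.allclose(
            dietary_score(intakes, reference_weights),
            dietary_score(intakes[labels_p], w_p),
        )


class TestTertiles:
    def test_one_through_nine(self):
        got = tertile_classes(np.arange(1.0, 10.0))
        assert list(got) == ["light"] * 3 + ["normal"] * 3 + ["heavy"] * 3

    def test_equal_thirds_for_distinct_scores(self, rng):
        scores = rng.permutation(3000).astype(float)
        got = pd.Series(tertile_classes(scores)).value_counts()
        assert got["light"] == got["normal"] == got["heavy"] == 1000

    def test_class_means_strictly_increase(self, clean_cohort, reference_weights):
        intakes = clean_cohort[INTAKE_COLUMNS].copy()
        intakes.columns = reference_weights.labels
        scored = score_cohort(intakes, reference_weights)
        means = scored.groupby("eating_behavior")["dietary_score"].mean()
        assert means["light"] < means["normal"] < means["heavy"]

    def test_identical_scores_fail(self):
        with pytest.raises(ValueError, match="identical"):
            tertile_classes(np.full(10, 7.0))
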