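"""Correlation input, graphical lasso, EBIC selection, fused estimation."""

import numpy as np
import pandas as pd
import pytest

from beliefnet import (
    BeliefDataset,
    EstimationConfig,
    correlation_matrix,
    ebic_select,
    fused_glasso,
    glasso,
    make_ground_truth,
    make_two_group,
    simulate_responses,
)
from beliefnet.estimation import ebic, refit_mle
from beliefnet.synthetic import partial_corr_from_precision


def _continuous_dataset(x: np.ndarray) -> BeliefDataset:
    cols = [f"v{i}" for i in range(x.shape[1])]
    return BeliefDataset(
        pd.DataFrame(x, columns=cols), {c: "continuous" for c in cols}
    )


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        data = _continuous_dataset(np.column_stack([a, a.copy(), rng.normal(size=100)]))
        s = correlation_matrix(data)
        assert s[0, 1] == pytest.approx(1.0)

    def test_antisymmetric_pair_correlates_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        s = correlation_matrix(_continuous_dataset(np.column_stack([a, -a])))
        assert s[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        s = correlation_matrix(_continuous_dataset(rng.normal(size=(5000, 6))))
        assert np.abs(s[np.triu_indices(6, 1)]).max() < 0.05

    def test_zero_variance_column_named_in_error(self):
        x = np.column_stack([np.ones(50), np.random.default_rng(3).normal(size=50)])
        with pytest.raises(ValueError, match="v0"):
            correlation_matrix(_continuous_dataset(x))

    def test_spearman_matches_pearson_on_monotone_data(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=2000)
        x = np.column_stack([a, a**3 + 0.01 * rng.normal(size=2000)])
        s = correlation_matrix(_continuous_dataset(x), method="spearman")
        assert s[0, 1] > 0.99

    def test_polychoric_recovers_latent_correlation(self):
        # 5-level discretization of a rho=0.6 bivariate normal
        rho = 0.6
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=3000)
        from scipy.stats import norm

        cuts = norm.ppf(np.arange(1, 5) / 5)
        codes = np.searchsorted(cuts, z) + 1
        cols = ["a", "b"]
        data = BeliefDataset(
            pd.DataFrame(codes, columns=cols), {c: "ordinal" for c in cols}
        )
        s = correlation_matrix(data, method="polychoric_auto")
        assert s[0, 1] == pytest.approx(rho, abs=0.07)

    def test_polyserial_recovers_latent_correlation(self):
        rho = 0.5
        rng = np.random.default_rng(6)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=4000)
        from scipy.stats import norm

        codes = np.searchsorted(norm.ppf(np.arange(1, 4) / 4), z[:, 1]) + 1
        data = BeliefDataset(
            pd.DataFrame({"cont": z[:, 0], "ord": codes}),
            {"cont": "continuous", "ord": "ordinal"},
        )
        s = correlation_matrix(data, method="polychoric_auto")
        assert s[0, 1] == pytest.approx(rho, abs=0.07)


class TestGlasso:
    def test_full_shrinkage_gives_diagonal_precision(self):
        s = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        theta, _ = glasso(s, 100, lam=0.6)
        off = theta - np.diag(np.diag(theta))
        assert np.abs(off).max() == 0.0

    def test_zero_penalty_equals_direct_inversion(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=(200, 6))
            s = np.corrcoef(x, rowvar=False)
            theta, _ = glasso(s, 200, lam=0.0)
            assert np.abs(theta - np.linalg.inv(s)).max() < 1e-6

    def test_edge_count_monotone_in_penalty(self):
        gt = make_ground_truth(8, edge_density=0.4, seed=11, levels="continuous")
        data = simulate_responses(gt, 500, seed=1)
        s = correlation_matrix(data)
        counts = []
        for lam in np.geomspace(0.01, 0.8, 12):
            theta, _ = glasso(s, 500, float(lam))
            iu = np.triu_indices(8, 1)
            counts.append(int((np.abs(theta[iu]) > 1e-8).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso(np.eye(3), 10, -0.1)


class TestRefit:
    def test_refit_satisfies_kkt_conditions(self):
        gt = make_ground_truth(6, edge_density=0.4, seed=5, levels="continuous")
        data = simulate_responses(gt, 400, seed=1)
        s = correlation_matrix(data)
        support = np.abs(gt.partial_corr) > 1e-12
        theta = refit_mle(s, support)
        w = np.linalg.inv(theta)
        mask = support | np.eye(6, dtype=bool)
        assert np.abs((w - s)[mask]).max() < 1e-8
        assert np.abs(theta[~mask]).max() == 0.0

    def test_full_support_is_plain_inverse(self):
        s = np.corrcoef(np.random.default_rng(8).normal(size=(100, 4)), rowvar=False)
        support = ~np.eye(4, dtype=bool)
        assert np.allclose(refit_mle(s, support), np.linalg.inv(s))


class TestEbicSelect:
    def test_empty_model_ebic_is_minus_two_loglik(self):
        theta = np.diag([1.2, 0.8, 1.0])
        ll = -123.4
        assert ebic(ll, theta, n=500, gamma=0.5) == pytest.approx(-2 * ll)

    def test_independent_data_selects_empty_network(self):
        gt = make_ground_truth(10, edge_density=0.0, seed=1, levels="continuous")
        data = simulate_responses(gt, 1000, seed=2)
        net = ebic_select(data, EstimationConfig(n_lambda=40))
        assert net.n_edges == 0

    def test_chain_structure_recovered_across_seeds(self, chain_truth10):
        true_pattern = np.abs(np.triu(chain_truth10.partial_corr, 1)) > 0
        config = EstimationConfig(n_lambda=40)
        hits = 0
        for seed in range(20):
            data = simulate_responses(chain_truth10, 2000, seed=seed)
            net = ebic_select(data, config)
            est = np.abs(np.triu(net.weights, 1)) > 0
            hits += bool((est == true_pattern).all())
        assert hits >= 18

    def test_meta_records_selection(self):
        gt = make_ground_truth(6, edge_density=0.3, seed=2, levels="continuous")
        net = ebic_select(simulate_responses(gt, 400, seed=0), EstimationConfig(n_lambda=20))
        assert net.meta["lambda"] > 0
        assert net.meta["ebic_gamma"] == 0.5
        assert net.meta["n_edges"] == net.n_edges

    def test_invalid_lambda_grid_rejected(self):
        with pytest.raises(ValueError):
            EstimationConfig(lambda_grid=np.array([0.3, 0.2, 0.1]))
        with pytest.raises(ValueError):
            EstimationConfig(lambda_grid=np.array([0.0, 0.1]))

    def test_network_invariants_hold_on_estimates(self):
        for seed in range(5):
            gt = make_ground_truth(7, edge_density=0.4, seed=seed)
            data = simulate_responses(gt, 300, seed=seed)
            net = ebic_select(data, EstimationConfig(n_lambda=20))
            assert np.allclose(net.weights, net.weights.T)
            assert np.all(np.diag(net.weights) == 0)
            assert np.abs(net.weights).max() < 1


@pytest.fixture(scope="module")
def two_corrs():
    gt = make_ground_truth(6, structure="chain", seed=3, levels="continuous")
    d1 = simulate_responses(gt, 300, seed=1)
    d2 = simulate_responses(gt, 400, seed=2)
    return correlation_matrix(d1), correlation_matrix(d2)


class TestFusedGlasso:
    def test_zero_fusion_equals_independent_fits(self, two_corrs):
        s1, s2 = two_corrs
        lam1 = 10.0
        n1, n2 = fused_glasso(s1, s2, 300, 400, lam1, 0.0)
        # FGL weights the likelihood by n_k, so the separate problems are
        # graphical lassos at per-observation penalty lam1 / n_k
        g1, _ = glasso(s1, 300, lam1 / 300)
        g2, _ = glasso(s2, 400, lam1 / 400)
        for net, g in ((n1, g1), (n2, g2)):
            rho = partial_corr_from_precision(g)
            rho[np.abs(rho) < 1e-8] = 0.0
            assert np.abs(net.weights - rho).max() < 1e-4

    def test_large_fusion_forces_equal_networks(self, two_corrs):
        s1, s2 = two_corrs
        f1, f2 = fused_glasso(s1, s2, 300, 400, 5.0, 1e5)
        assert np.abs(f1.weights - f2.weights).max() < 1e-4

    def test_perturbed_edge_differs_while_others_agree(self):
        gt = make_ground_truth(6, structure="chain", seed=3, levels="continuous")
        data = make_two_group(gt, {(0, 1): 0.3}, 2000, 2000, seed=9)
        x = data.to_numpy()
        s1 = np.corrcoef(x[data.group == 0], rowvar=False)
        s2 = np.corrcoef(x[data.group == 1], rowvar=False)
        f1, f2 = fused_glasso(s1, s2, 2000, 2000, 20.0, 80.0)
        diff = f2.weights - f1.weights
        assert diff[0, 1] > 0.15  # perturbed edge survives fusion
        mask = np.ones_like(diff, dtype=bool)
        mask[0, 1] = mask[1, 0] = False
        assert np.abs(diff[mask]).max() < 0.05

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            fused_glasso(np.eye(3), np.eye(4), 10, 10, 0.1, 0.1)
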