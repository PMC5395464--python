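import numpy as np
import pandas as pd
import pytest

from fastasr import (
    parse_newick,
    sim_tree,
    sim_traits,
    SimulationSpec,
)
from fastasr.models import edge_length_matrices
from fastasr.multivariate import (
    TraitData,
    anc_recon_mv,
    estimate_rate_matrix,
    impute_tip,
    postorder_pass_mv,
    preorder_pass_mv,
)
from fastasr.oracle import (
    conditional_impute_oracle,
    mv_gls_root,
    rerooted_mv_gls_estimates,
)
from fastasr.univariate import postorder_pass, preorder_pass


def random_pd(M, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((M, M))
    return A @ A.T + M * np.eye(M)


def mv_passes(tree, Y, Sigma, B=None):
    em = edge_length_matrices(tree, Sigma)
    tilde, g = postorder_pass_mv(tree, Y, em, B=B)
    g = preorder_pass_mv(tree, em, tilde, g)
    return em, tilde, g


class TestPostorderMV:
    def test_identity_sigma_decouples_traits(self):
        t = parse_newick("(A:1,B:1);")
        Y = np.array([[0.0, 4.0], [2.0, 6.0]])
        em = edge_length_matrices(t, np.eye(2))
        _, g = postorder_pass_mv(t, Y, em)
        assert np.allclose(g.mu_hat[t.root], [1.0, 5.0])
        assert np.allclose(g.p[t.root], 2 * np.eye(2))

    def test_missing_entry_subset_initialization(self):
        t = parse_newick("(A:1,B:1);")
        Y = np.array([[0.0, 4.0], [2.0, np.nan]])
        em = edge_length_matrices(t, np.eye(2))
        tilde, _ = postorder_pass_mv(t, Y, em)
        assert np.allclose(tilde.p[2], np.diag([1.0, 0.0]))
        assert tilde.logdet[2] == pytest.approx(0.0)  # log|T_kk| = log 1

    def test_fully_missing_trait_rejected(self):
        t = parse_newick("(A:1,B:1);")
        Y = np.array([[0.0, np.nan], [2.0, np.nan]])
        em = edge_length_matrices(t, np.eye(2))
        with pytest.raises(ValueError, match="unidentifiable"):
            postorder_pass_mv(t, Y, em)

    @pytest.mark.parametrize("seed,miss", [(0, 0.0), (1, 0.2), (2, 0.3)])
    def test_root_matches_dense_kronecker_gls(self, seed, miss):
        n, M = 25, 3
        tree = sim_tree(n, seed=seed)
        Sigma = random_pd(M, seed + 50)
        Y = sim_traits(
            tree,
            SimulationSpec(
                n_tips=n, M=M, sigma=Sigma, missing_rate=miss, seed=seed + 100
            ),
        )["Y"]
        em = edge_length_matrices(tree, Sigma)
        _, g = postorder_pass_mv(tree, Y, em)
        mu_o, ld_o = mv_gls_root(tree, Sigma, Y)
        assert np.abs(g.mu_hat[tree.root] - mu_o).max() < 1e-8
        assert abs(g.logdet[tree.root] - ld_o) < 1e-8 * max(1, abs(ld_o))


class TestPreorderMV:
    def test_m1_reduces_to_univariate(self, random_instance):
        tree, y = random_instance(30, seed=4)
        s2 = 1.7
        _, _, g = mv_passes(tree, y[:, None], np.array([[s2]]))
        tilde_u, gu = postorder_pass(tree, y)
        gu = preorder_pass(tree, tilde_u, gu)
        for v in gu.internal_nodes:
            assert abs(g.mu_hat[v][0] - gu.mu_hat[v]) < 1e-12
            # precision scales by 1/sigma2 when Sigma is embedded in T
            assert abs(g.p[v][0, 0] * s2 - gu.p[v]) < 1e-10

    def test_diagonal_sigma_matches_per_trait_univariate(self, random_instance):
        tree, y = random_instance(20, seed=5)
        rng = np.random.default_rng(9)
        Y = np.column_stack([y, rng.standard_normal(20)])
        _, _, g = mv_passes(tree, Y, np.diag([2.0, 0.5]))
        for m in range(2):
            tilde_u, gu = postorder_pass(tree, Y[:, m])
            gu = preorder_pass(tree, tilde_u, gu)
            for v in gu.internal_nodes:
                assert abs(g.mu_hat[v][m] - gu.mu_hat[v]) < 1e-10

    @pytest.mark.parametrize("seed,miss", [(3, 0.0), (4, 0.25)])
    def test_all_nodes_match_rerooted_kronecker_oracle(self, seed, miss):
        n, M = 16, 2
        tree = sim_tree(n, seed=seed)
        Sigma = random_pd(M, seed + 60)
        Y = sim_traits(
            tree,
            SimulationSpec(
                n_tips=n, M=M, sigma=Sigma, missing_rate=miss, seed=seed + 101
            ),
        )["Y"]
        _, _, g = mv_passes(tree, Y, Sigma)
        for v, (mu, P, ld) in rerooted_mv_gls_estimates(tree, Sigma, Y).items():
            assert np.abs(g.mu_hat[v] - mu).max() < 1e-8
            assert np.abs(g.p[v] - P).max() < 1e-8
            assert abs(g.logdet[v] - ld) < 1e-8 * max(1, abs(ld))

    def test_root_step_is_identity(self, random_instance):
        tree, y = random_instance(10, seed=7)
        em, tilde, g = mv_passes(tree, y[:, None], np.array([[1.0]]))
        # re-applying the preorder update with T = 0 at the root must
        # reproduce the root quantities
        r = tree.root
        assert np.allclose(g.p[r], tilde.p[r])
        assert np.allclose(g.Q[r], tilde.Q[r])


class TestImputeTip:
    def test_diagonal_sigma_gives_parent_estimate(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        Y = np.array([[0.0, 1.0], [1.0, np.nan], [2.0, 5.0]])
        em, tilde, g = mv_passes(t, Y, np.diag([1.0, 3.0]))
        u, mean, cov = impute_tip(t, 2, Y, em, tilde, g)
        a = int(t.parent[2])
        assert list(u) == [1]
        assert mean[0] == pytest.approx(g.mu_hat[a][1], abs=1e-12)

    def test_correlated_cherry_hand_algebra(self):
        # T = t Sigma with unit variances and correlation r, trait 1
        # observed: imputation = r (y1 - mu1(a)) + mu2(a); t cancels
        r = 0.6
        t = parse_newick("((A:2,B:2):1,C:2);")
        Sigma = np.array([[1.0, r], [r, 1.0]])
        Y = np.array([[0.5, np.nan], [1.0, 2.0], [3.0, 1.0]])
        em, tilde, g = mv_passes(t, Y, Sigma)
        u, mean, cov = impute_tip(t, 1, Y, em, tilde, g)
        a = int(t.parent[1])
        expect = r * (0.5 - g.mu_hat[a][0]) + g.mu_hat[a][1]
        assert mean[0] == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_conditional_normal_oracle(self, seed):
        n, M = 14, 2
        tree = sim_tree(n, seed=seed)
        Sigma = random_pd(M, seed + 70)
        Y = sim_traits(
            tree,
            SimulationSpec(
                n_tips=n, M=M, sigma=Sigma, missing_rate=0.3, seed=seed + 102
            ),
        )["Y"]
        if seed == 0:
            Y[3] = np.nan  # force one fully missing tip
        em, tilde, g = mv_passes(tree, Y, Sigma)
        mean_o, _, cov_pred, mis = conditional_impute_oracle(tree, Sigma, Y)
        pos = {int(i): j for j, i in enumerate(mis)}
        for v in range(1, n + 1):
            u, mean, cov = impute_tip(tree, v, Y, em, tilde, g)
            idx = [pos[m * n + (v - 1)] for m in u]
            assert np.abs(mean - mean_o[idx]).max() < 1e-8 if u.size else True
            if u.size:
                assert (
                    np.abs(cov - cov_pred[np.ix_(idx, idx)]).max() < 1e-8
                )
                assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_mask_then_unmask_recovers_conditional_mean(self):
        # deliberately hide one observed value; the imputation must equal
        # the conditional-normal mean given the remaining data
        n = 10
        tree = sim_tree(n, seed=5)
        Sigma = random_pd(2, 8)
        Y = sim_traits(
            tree, SimulationSpec(n_tips=n, M=2, sigma=Sigma, seed=55)
        )["Y"]
        Ym = Y.copy()
        Ym[4, 1] = np.nan
        em, tilde, g = mv_passes(tree, Ym, Sigma)
        u, mean, cov = impute_tip(tree, 5, Ym, em, tilde, g)
        mean_o, _, _, mis = conditional_impute_oracle(tree, Sigma, Ym)
        assert mean[0] == pytest.approx(mean_o[0], abs=1e-8)

    def test_complete_tip_is_noop(self, random_instance):
        tree, y = random_instance(8, seed=9)
        em, tilde, g = mv_passes(tree, y[:, None], np.array([[1.0]]))
        u, mean, cov = impute_tip(tree, 1, y[:, None], em, tilde, g)
        assert u.size == 0 and mean.size == 0


class TestEstimateRateMatrix:
    def test_star_tree_is_sample_crossproduct(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((4, 2))
        S = estimate_rate_matrix(t, Y, reml=0)
        # C = I: GLS mean = plain mean, Sigma = centered crossproduct / N
        Yc = Y - Y.mean(axis=0)
        assert np.allclose(S, Yc.T @ Yc / 4, atol=1e-10)

    def test_m1_equals_univariate_rate(self, random_instance):
        from fastasr import anc_recon

        tree, y = random_instance(25, seed=11)
        S = estimate_rate_matrix(tree, y, reml=1)
        assert S[0, 0] == pytest.approx(
            anc_recon(tree, y, reml=1).sigma2, abs=1e-12
        )

    def test_matches_dense_gls(self):
        n, M = 40, 2
        tree = sim_tree(n, seed=12)
        Sigma = random_pd(M, 13)
        Y = sim_traits(
            tree, SimulationSpec(n_tips=n, M=M, sigma=Sigma, seed=14)
        )["Y"]
        from fastasr.oracle import build_covariance

        S = estimate_rate_matrix(tree, Y, reml=0)
        C = build_covariance(tree)
        Ci = np.linalg.inv(C)
        ones = np.ones(n)
        mu = (ones @ Ci @ Y) / (ones @ Ci @ ones)
        R = Y - mu
        assert np.abs(S - R.T @ Ci @ R / n).max() < 1e-8

    def test_missing_data_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="supply"):
            estimate_rate_matrix(t, np.array([[1.0], [np.nan]]))


class TestAncReconMV:
    def test_means_se_with_zero_B_identical_to_means(self):
        n, M = 15, 2
        tree = sim_tree(n, seed=2)
        Sigma = random_pd(M, 3)
        Y = sim_traits(
            tree, SimulationSpec(n_tips=n, M=M, sigma=Sigma, seed=4)
        )["Y"]
        td = TraitData(
            Y=Y,
            species=tree.tip_labels,
            traits=("x", "z"),
            B=np.zeros((n, M, M)),
        )
        r1 = anc_recon_mv(tree, Y, sigma=Sigma, mode="means")
        r2 = anc_recon_mv(tree, td, sigma=Sigma, mode="means_se")
        assert np.abs(r1.estimates - r2.estimates).max() < 1e-12
        assert np.abs(r1.covariances - r2.covariances).max() < 1e-12

    def test_raw_single_obs_tiny_B_converges_to_means(self):
        n, M = 12, 2
        tree = sim_tree(n, seed=6)
        Sigma = random_pd(M, 7)
        Y = sim_traits(
            tree, SimulationSpec(n_tips=n, M=M, sigma=Sigma, seed=8)
        )["Y"]
        td = TraitData(
            Y=Y,
            species=tree.tip_labels,
            traits=("x", "z"),
            B=np.tile(1e-10 * np.eye(M), (n, 1, 1)),
        )
        r_raw = anc_recon_mv(tree, td, sigma=Sigma, mode="raw")
        r_means = anc_recon_mv(tree, Y, sigma=Sigma, mode="means")
        raw_internal = np.array(
            sorted(
                map(
                    tuple,
                    (
                        e
                        for e, ty in zip(r_raw.estimates, r_raw.node_types)
                        if ty == "internal"
                    ),
                )
            )
        )
        means_internal = np.array(sorted(map(tuple, r_means.estimates)))
        assert np.abs(raw_internal - means_internal).max() < 1e-4

    def test_raw_shrinkage_toward_ancestor(self):
        # species A has two observations (1, 3); with within-species
        # variance the species-mean estimate lies between the observation
        # mean (2) and the ancestral estimate, verified against dense GLS
        # on the explicit individual-level model
        tree = parse_newick("((A:1,B:1):1,C:2);")
        raw = pd.DataFrame(
            {"species": ["A", "A", "B", "C"], "x": [1.0, 3.0, 3.0, 6.0]}
        )
        td = TraitData.from_frame(tree, raw)
        td.B = np.ones((3, 1, 1))
        res = anc_recon_mv(tree, td, sigma=np.array([[1.0]]), mode="raw")
        est = {
            lab: e[0]
            for lab, e, ty in zip(res.node_labels, res.estimates, res.node_types)
            if ty == "species"
        }
        # dense check: individuals i,j have cov C_sp(i)sp(j) + B delta_ij
        from fastasr.oracle import build_covariance

        C = build_covariance(tree)
        sp = [0, 0, 1, 2]
        y = np.array([1.0, 3.0, 3.0, 6.0])
        Caug = C[np.ix_(sp, sp)] + np.eye(4)
        Ci = np.linalg.inv(Caug)
        ones = np.ones(4)
        mu = ones @ Ci @ y / (ones @ Ci @ ones)
        cA = C[0, sp]
        blup_A = mu + cA @ Ci @ (y - mu)
        assert est["A"] == pytest.approx(blup_A, abs=1e-10)
        anc = {
            int(v): e[0]
            for v, e, ty in zip(res.node_ids, res.estimates, res.node_types)
            if ty == "internal"
        }
        parent_est = min(anc.values(), key=lambda m: abs(m - est["A"]))
        assert min(2.0, parent_est) <= est["A"] <= max(2.0, parent_est)

    def test_raw_permutation_invariance(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        raw1 = pd.DataFrame(
            {"species": ["A", "A", "B", "C"], "x": [1.0, 3.0, 3.0, 6.0]}
        )
        raw2 = pd.DataFrame(
            {"species": ["A", "A", "B", "C"], "x": [3.0, 1.0, 3.0, 6.0]}
        )
        out = []
        for raw in (raw1, raw2):
            td = TraitData.from_frame(tree, raw)
            td.B = np.ones((3, 1, 1))
            res = anc_recon_mv(tree, td, sigma=np.array([[1.0]]), mode="raw")
            out.append(np.sort(res.estimates, axis=0))
        assert np.abs(out[0] - out[1]).max() < 1e-12

    def test_unknown_species_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        df = pd.DataFrame({"species": ["A", "Z"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="Z"):
            TraitData.from_frame(tree, df)

    def test_non_psd_B_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        td = TraitData(
            Y=np.array([[1.0], [2.0]]),
            species=("A", "B"),
            traits=("x",),
            B=np.array([[[-1.0]], [[0.0]]]),
        )
        with pytest.raises(ValueError, match="semidefinite"):
            anc_recon_mv(tree, td, sigma=np.array([[1.0]]), mode="means_se")

    def test_long_format_output_schema(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        Y = np.array([[1.0, 2.0], [3.0, np.nan], [6.0, 1.0]])
        res = anc_recon_mv(tree, Y, sigma=np.eye(2), mode="means")
        df = res.to_frame()
        assert set(df.columns) == {
            "node",
            "label",
            "trait",
            "estimate",
            "variance",
            "ci_lower",
            "ci_upper",
            "node_type",
        }
        assert set(df.node_type) == {"internal", "imputed"}
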