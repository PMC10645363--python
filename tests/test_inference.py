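"""Variational fitting, responsibilities, scores and model selection."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from cnaclone.inference import (
    FitConfig,
    assignment_entropy,
    compute_scores,
    count_parameters,
    fit,
    map_copy_numbers,
    responsibilities,
    save_fit,
    select_model,
)
from cnaclone.model import ModelParams, default_prior, joint_loglik
from cnaclone.evaluation import adjusted_rand_index, evaluate_fit


class TestObjectiveGradients:
    def test_analytic_gradients_match_numerical(self):
        """Every analytic ELBO gradient agrees with central differences."""
        from cnaclone.inference import _build_pack, _objective
        from cnaclone.segdata import SegmentedCounts

        rng = np.random.default_rng(0)
        N, I, K, H = 5, 3, 2, 4

        def make(name, n):
            counts = rng.integers(0, 40, size=(n, I))
            rho = np.exp(rng.normal(0, 0.2, n))
            return SegmentedCounts(
                name, counts, [f"{name}{j}" for j in range(n)],
                [f"s{i}" for i in range(I)], rho / rho.mean(),
            )

        prior = default_prior([2, 2, 3], H=H)
        for mode, lam in [("flat", 0.6), ("multiome", 0.3)]:
            rna, atac = make("RNA", N), make("ATAC", N)
            if mode == "multiome":
                atac.barcodes = list(rna.barcodes)
            cfg = FitConfig(mode=mode, lam=lam, K_range=[K])
            pack = _build_pack(rna, atac, cfg)
            params = {"phi": rng.normal(size=(K, I, H))}
            if mode == "flat":
                params["pi:RNA"] = rng.normal(size=K)
                params["pi:ATAC"] = rng.normal(size=K)
            else:
                params["pi"] = rng.normal(size=K)
            for name in pack["data"]:
                params[f"log_theta:{name}"] = rng.normal(np.log(10), 0.3, I)
                params[f"log_r:{name}"] = rng.normal(np.log(5), 0.3, I)
            gumbel = rng.gumbel(size=params["phi"].shape)
            tau = 0.7
            _, grads, _ = _objective(params, pack, prior, cfg, gumbel, tau)
            eps = 1e-6
            for key, value in params.items():
                it = np.nditer(value, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = value[idx]
                    value[idx] = orig + eps
                    up, _, _ = _objective(params, pack, prior, cfg, gumbel,
                                          tau, want_grads=False)
                    value[idx] = orig - eps
                    dn, _, _ = _objective(params, pack, prior, cfg, gumbel,
                                          tau, want_grads=False)
                    value[idx] = orig
                    numeric = (up - dn) / (2 * eps)
                    assert grads[key][idx] == pytest.approx(
                        numeric, rel=1e-4, abs=1e-6
                    ), (mode, key, idx)


class TestCountParameters:
    def test_multiome_convention(self):
        # K*I*(H-1) states + 2I rates + 2I overdispersions, K=1: no mixing
        assert count_parameters(1, 3, 4, 2, "multiome") == 21

    def test_flat_single_modality(self):
        assert count_parameters(2, 1, 2, 1, "flat") == 5

    @pytest.mark.parametrize("K", [2, 3, 5])
    def test_shared_pi_saves_k_minus_one(self, K):
        flat = count_parameters(K, 4, 4, 2, "flat")
        shared = count_parameters(K, 4, 4, 2, "flat_shared_pi")
        assert flat - shared == K - 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            count_parameters(0, 3, 4, 2)


class TestScores:
    def test_formula_arithmetic(self):
        resp = np.ones((100, 1))
        scores = compute_scores(-50.0, 2, 100, resp)
        assert scores["AIC"] == pytest.approx(104.0)
        assert scores["BIC"] == pytest.approx(2 * np.log(100) + 100)
        assert scores["ICL"] == pytest.approx(scores["BIC"])

    def test_hard_assignments_have_zero_entropy(self):
        resp = np.eye(3)[np.array([0, 1, 2, 0, 1])]
        assert assignment_entropy(resp) == 0.0

    def test_uniform_assignments_have_max_entropy(self):
        n = 40
        resp = np.full((n, 2), 0.5)
        assert assignment_entropy(resp) == pytest.approx(n * np.log(2))

    def test_icl_exceeds_bic_by_entropy(self):
        rng = np.random.default_rng(0)
        resp = rng.dirichlet(np.ones(3), size=25)
        scores = compute_scores(-123.4, 7, 50, resp)
        ent = assignment_entropy(resp)
        assert ent >= 0
        assert scores["ICL"] == pytest.approx(scores["BIC"] + ent)

    def test_entropy_sums_over_modalities(self):
        resp = {"RNA": np.full((4, 2), 0.5), "ATAC": np.eye(2)}
        assert assignment_entropy(resp) == pytest.approx(4 * np.log(2))


@pytest.fixture(scope="module")
def quick_cfg():
    return FitConfig(K_range=[2], steps=250, polish_steps=150,
                     restarts=2, seed=7)


@pytest.fixture(scope="module")
def two_clone_fit(two_clone_sim, two_clone_prior, quick_cfg):
    return fit(two_clone_sim.rna, two_clone_sim.atac, two_clone_prior, 2,
               quick_cfg)


class TestFit:
    def test_strong_signal_recovers_clones_exactly(self, two_clone_sim,
                                                   two_clone_fit):
        hard = np.concatenate(
            [two_clone_fit.assignments["RNA"],
             two_clone_fit.assignments["ATAC"]]
        )
        true = np.concatenate(
            [two_clone_sim.labels_rna, two_clone_sim.labels_atac]
        )
        assert adjusted_rand_index(true, hard) == 1.0

    def test_recovered_copy_numbers_match_truth(self, two_clone_sim,
                                                two_clone_fit):
        rep = evaluate_fit(two_clone_sim, two_clone_fit)
        assert rep.mae == 0.0

    def test_k1_is_degenerate(self, two_clone_sim, two_clone_prior):
        cfg = FitConfig(K_range=[1], steps=150, polish_steps=100,
                        restarts=1, seed=0)
        res = fit(two_clone_sim.rna, two_clone_sim.atac, two_clone_prior, 1,
                  cfg)
        for R in responsibilities(res).values():
            np.testing.assert_allclose(R, 1.0)
        np.testing.assert_array_equal(
            map_copy_numbers(res),
            np.argmax(res.params.Phi, axis=2) + 1,
        )
        # reported loglik equals the joint likelihood at the fitted params
        assert res.loglik == pytest.approx(
            joint_loglik(two_clone_sim.rna, two_clone_sim.atac, res.params)
        )

    def test_same_seed_bitwise_identical(self, two_clone_sim,
                                         two_clone_prior, quick_cfg):
        a = fit(two_clone_sim.rna, two_clone_sim.atac, two_clone_prior, 2,
                quick_cfg)
        b = fit(two_clone_sim.rna, two_clone_sim.atac, two_clone_prior, 2,
                quick_cfg)
        np.testing.assert_array_equal(a.elbo_trace, b.elbo_trace)
        np.testing.assert_array_equal(a.map_cn, b.map_cn)
        for key in a.assignments:
            np.testing.assert_array_equal(a.assignments[key],
                                          b.assignments[key])

    def test_best_restart_wins(self, two_clone_fit):
        final = max(two_clone_fit.restart_elbos)
        assert all(final >= e for e in two_clone_fit.restart_elbos)

    def test_k_larger_than_cells_rejected(self, two_clone_sim,
                                          two_clone_prior):
        with pytest.raises(ValueError, match="exceeds"):
            fit(two_clone_sim.rna, two_clone_sim.atac, two_clone_prior, 9999,
                FitConfig(K_range=[2]))

    def test_multiome_requires_paired_barcodes(self, two_clone_sim,
                                               two_clone_prior):
        cfg = FitConfig(K_range=[2], mode="multiome", steps=50)
        with pytest.raises(ValueError, match="paired"):
            fit(two_clone_sim.rna, two_clone_sim.atac, two_clone_prior, 2,
                cfg)

    def test_single_modality_boundaries(self, two_clone_sim,
                                        two_clone_prior):
        cfg = FitConfig(K_range=[2], lam=1.0, steps=200, polish_steps=100,
                        restarts=1, seed=3)
        res = fit(two_clone_sim.rna, None, two_clone_prior, 2, cfg)
        assert set(res.responsibilities) == {"RNA"}
        ari = adjusted_rand_index(two_clone_sim.labels_rna,
                                  res.assignments["RNA"])
        assert ari > 0.9
        with pytest.raises(ValueError, match="lam"):
            fit(two_clone_sim.rna, None, two_clone_prior, 2,
                FitConfig(K_range=[2], lam=0.5))


class TestResponsibilities:
    def test_rows_sum_to_one(self, two_clone_fit):
        for R in responsibilities(two_clone_fit).values():
            np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-12)

    def test_match_bayes_rule_oracle(self, two_clone_sim, two_clone_fit):
        """Responsibilities equal the brute-force posterior at MAP params."""
        params = two_clone_fit.params
        data = two_clone_sim.atac
        h = np.arange(1, params.H + 1)
        rho = data.effective_library_factors()
        expected = np.zeros((5, params.K))
        for n in range(5):
            for k in range(params.K):
                lp = np.log(params.pi["ATAC"][k])
                for i in range(data.n_segments):
                    c = float(params.Phi[k, i] @ h)
                    mu = rho[n] * params.theta["ATAC"][i] * c
                    r = params.overdispersion["ATAC"][i]
                    lp += stats.nbinom.logpmf(data.counts[n, i], r,
                                              r / (r + mu))
                expected[n, k] = lp
        expected = np.exp(expected - logsumexp(expected, 1, keepdims=True))
        np.testing.assert_allclose(
            two_clone_fit.responsibilities["ATAC"][:5], expected, atol=1e-8
        )

    def test_label_permutation_leaves_scores_unchanged(self, two_clone_sim,
                                                       two_clone_fit):
        p = two_clone_fit.params
        perm = [1, 0]
        permuted = ModelParams(
            K=2,
            Phi=p.Phi[perm],
            pi={m: v[perm] for m, v in p.pi.items()},
            theta=p.theta,
            overdispersion=p.overdispersion,
            lam=p.lam,
        )
        assert joint_loglik(
            two_clone_sim.rna, two_clone_sim.atac, permuted
        ) == pytest.approx(two_clone_fit.loglik, rel=1e-12)


class TestMultiomeMode:
    def test_shared_assignments_recover_truth(self, paired_sim):
        prior = default_prior(np.full(5, 2), H=4)
        cfg = FitConfig(K_range=[2], mode="multiome", steps=250,
                        polish_steps=150, restarts=2, seed=2)
        res = fit(paired_sim.rna, paired_sim.atac, prior, 2, cfg)
        assert set(res.responsibilities) == {"cells"}
        ari = adjusted_rand_index(paired_sim.labels_rna,
                                  res.assignments["cells"])
        assert ari == 1.0

    def test_flat_shared_pi_uses_one_mixing_vector(self, paired_sim):
        prior = default_prior(np.full(5, 2), H=4)
        cfg = FitConfig(K_range=[2], mode="flat_shared_pi", steps=200,
                        polish_steps=100, restarts=1, seed=2)
        res = fit(paired_sim.rna, paired_sim.atac, prior, 2, cfg)
        np.testing.assert_array_equal(res.params.pi["RNA"],
                                      res.params.pi["ATAC"])


class TestSelectModel:
    def test_selects_true_k_with_strong_signal(self, two_clone_sim,
                                               two_clone_prior):
        cfg = FitConfig(K_range=range(1, 4), steps=250, polish_steps=150,
                        restarts=2, seed=7)
        best, table = select_model(two_clone_sim.rna, two_clone_sim.atac,
                                   two_clone_prior, cfg)
        assert best.K == 2
        assert len(table) == 3
        assert set(table["K"]) == {1, 2, 3}
        assert (table["ICL"] >= table["BIC"] - 1e-9).all()

    def test_singleton_range(self, two_clone_sim, two_clone_prior):
        cfg = FitConfig(K_range=[2], steps=150, polish_steps=50,
                        restarts=1, seed=0)
        best, table = select_model(two_clone_sim.rna, two_clone_sim.atac,
                                   two_clone_prior, cfg)
        assert best.K == 2
        assert len(table) == 1

    def test_save_fit_writes_results(self, two_clone_fit, tmp_path):
        save_fit(two_clone_fit, tmp_path)
        assert (tmp_path / "assignments.tsv").exists()
        assert (tmp_path / "map_cn.tsv").exists()
        assert (tmp_path / "phi_posterior.npz").exists()
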