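"""Configuration enumeration, Bayes factors vs oracles, EM, posteriors."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mceqtl import pipeline
from mceqtl.bma import (
    BmaGeneResult,
    Grid,
    abf_single,
    bayes_fdr,
    config_log_bfs,
    default_grid,
    enumerate_configurations,
    fit_hierarchical_em,
    log_abf_single,
    permutation_negative_control,
    posteriors,
    run_bma,
    subgroup_summaries,
    SubgroupSummaries,
)
from mceqtl.cis_scan import cis_window
from mceqtl.preprocess import quantile_normal_transform
from mceqtl.simulate import SimConfig, make_annotation, simulate_cohort, simulate_genotypes


class TestConfigurations:
    @pytest.mark.parametrize("s", [1, 2, 3, 4, 5, 6])
    def test_count_is_2s_minus_1(self, s):
        configs = enumerate_configurations(s)
        assert configs.shape == (2**s - 1, s)
        assert len({tuple(c) for c in configs}) == 2**s - 1
        assert not (~configs).all(axis=1).any()

    def test_sorted_by_sparsity(self):
        configs = enumerate_configurations(4)
        sizes = configs.sum(axis=1)
        assert (np.diff(sizes) >= 0).all()


class TestAbfSingle:
    def test_zero_prior_variance_gives_one(self):
        assert abf_single(0.5, 0.2, 0.0) == pytest.approx(1.0)

    def test_zero_z_shrinks_below_one(self):
        v = 0.04
        w = 0.5
        assert abf_single(0.0, np.sqrt(v), w) == pytest.approx(np.sqrt(v / (v + w)))

    def test_matches_quadrature_oracle(self):
        # BF = int N(beta_hat; b, V) N(b; 0, W) db / N(beta_hat; 0, V)
        beta_hat, se, w = 3.0, 1.0, 1.0
        v = se**2

        def integrand(b):
            return stats.norm.pdf(beta_hat, b, np.sqrt(v)) * stats.norm.pdf(b, 0, np.sqrt(w))

        num, _ = integrate.quad(integrand, -10, 10)
        oracle = num / stats.norm.pdf(beta_hat, 0, np.sqrt(v))
        assert abf_single(beta_hat, se, w) == pytest.approx(oracle, rel=0.01)

    def test_se_nonpositive_errors(self):
        with pytest.raises(ValueError):
            log_abf_single(1.0, 0.0, 1.0)


def _summaries(beta, se, probesets=None, snps=None, subgroups=None):
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    p, s = beta.shape
    pairs = pd.DataFrame(
        {"probeset": probesets or [f"g{i}" for i in range(p)],
         "snp": snps or [f"s{i}" for i in range(p)]}
    )
    return SubgroupSummaries(pairs, beta, se, subgroups or [f"T{k}" for k in range(s)])


class TestConfigBf:
    def test_s1_reduces_to_abf_grid_average(self):
        grid = default_grid()
        summ = _summaries([[0.5]], [[0.2]])
        log_bf, configs = config_log_bfs(summ, grid)
        expected = np.log(np.mean([
            abf_single(0.5, 0.2, grid.phi2[k] + grid.omega2[k])
            for k in range(len(grid.lam))
        ]))
        assert log_bf[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_shared_strong_signal_favours_joint_config(self):
        # identical z=5 in two subgroups: under a low-heterogeneity grid
        # point the both-active configuration beats single-active
        grid = Grid(np.array([0.0]), np.array([0.4]), np.array([1.0]))
        summ = _summaries([[0.5, 0.5]], [[0.1, 0.1]])
        log_bf, configs = config_log_bfs(summ, grid)
        labels = ["".join(str(int(b)) for b in c) for c in configs]
        bf = dict(zip(labels, log_bf[0]))
        assert bf["11"] > bf["10"]
        assert bf["11"] > bf["01"]

    def test_fixed_effect_meta_analysis_oracle(self):
        # phi2 = 0, equal V: joint BF equals the single ABF of the
        # inverse-variance-weighted meta-analytic estimate with prior
        # variance omega2 (on the mean effect)
        omega2 = 0.3
        grid = Grid(np.array([0.0]), np.array([omega2]), np.array([1.0]))
        beta = np.array([[0.4, 0.6, 0.5]])
        v = 0.04
        se = np.full((1, 3), np.sqrt(v))
        summ = _summaries(beta, se)
        log_bf, configs = config_log_bfs(summ, grid)
        all_active = np.flatnonzero(configs.sum(axis=1) == 3)[0]

        w_inv = 1.0 / v
        beta_meta = (beta[0] * w_inv).sum() / (3 * w_inv)
        se_meta = np.sqrt(1.0 / (3 * w_inv))
        oracle = log_abf_single(beta_meta, se_meta, omega2)
        assert log_bf[0, all_active] == pytest.approx(oracle, rel=1e-9)

    def test_missing_subgroup_contributes_factor_one(self):
        grid = Grid(np.array([0.1]), np.array([0.2]), np.array([1.0]))
        both = _summaries([[0.5, np.nan]], [[0.1, np.nan]])
        solo = _summaries([[0.5]], [[0.1]])
        log_bf2, configs2 = config_log_bfs(both, grid)
        log_bf1, _ = config_log_bfs(solo, grid)
        labels = ["".join(str(int(b)) for b in c) for c in configs2]
        assert log_bf2[0, labels.index("11")] == pytest.approx(log_bf1[0, 0], rel=1e-9)
        assert log_bf2[0, labels.index("01")] == pytest.approx(0.0, abs=1e-12)


def _sim_for_bma(seed, n=200, n_genes=60, beta=0.8, config="11111",
                 eqtl_frac=0.2, **kw):
    s = 5
    probs = {"0" * s: 1 - eqtl_frac, config: eqtl_frac}
    cfg = SimConfig(
        n_individuals=n, n_genes=n_genes, seed=seed,
        config_probs=probs, effect_sd_range=(beta, beta),
        dropout_per_cell_type=0.0, batch_sd=0.0, **kw,
    )
    geno = simulate_genotypes(cfg)
    exprs, truth = simulate_cohort(cfg, geno)
    windows = cis_window(make_annotation(cfg), geno.snp_meta)
    exprs_t = [quantile_normal_transform(e, seed=seed) for e in exprs]
    return cfg, geno, exprs_t, truth, windows


class TestSubgroupSummaries:
    def test_identical_subgroups_identical_summaries(self):
        cfg, geno, exprs, truth, windows = _sim_for_bma(1, n=80, n_genes=10)
        twice = [exprs[0], exprs[0]]
        summ = subgroup_summaries(twice, geno, windows, covariates=("disease",))
        np.testing.assert_allclose(summ.beta_hat[:, 0], summ.beta_hat[:, 1])
        np.testing.assert_allclose(summ.se[:, 0], summ.se[:, 1])

    def test_null_z_scores_standard_normal(self):
        cfg = SimConfig(
            n_individuals=150, n_genes=200, snps_per_gene=10, ld_block_size=1,
            config_probs={"0" * 5: 1.0}, dropout_per_cell_type=0.0,
            batch_sd=0.0, seed=2,
        )
        geno = simulate_genotypes(cfg)
        exprs, _ = simulate_cohort(cfg, geno)
        windows = cis_window(make_annotation(cfg), geno.snp_meta)
        e = quantile_normal_transform(exprs[0], seed=2)
        summ = subgroup_summaries([e], geno, windows)
        z = (summ.beta_hat / summ.se).ravel()
        z = z[np.isfinite(z)]
        assert len(z) == 2000
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_planted_beta_recovered(self):
        cfg, geno, exprs, truth, windows = _sim_for_bma(
            3, n=200, n_genes=20, beta=0.5, eqtl_frac=1.0, noise_sd=1.0
        )
        summ = subgroup_summaries([exprs[0]], geno, windows)
        idx = summ.pairs.set_index(["probeset", "snp"]).index
        # quantile transform rescales y to sd ~1; compare standardized truth
        hits = 0
        for probeset, row in truth.table.iterrows():
            k = idx.get_loc((probeset, row["causal_snp"]))
            b, s_ = summ.beta_hat[k, 0], summ.se[k, 0]
            g = geno.dosage[:, geno.snp_meta.index.get_loc(row["causal_snp"])]
            y_sd = np.sqrt(row["beta_CD4"] ** 2 * g.var() + 1.0)
            if abs(b - row["beta_CD4"] / y_sd) <= 3 * s_:
                hits += 1
        assert hits >= 18

    def test_small_subgroup_errors(self):
        cfg, geno, exprs, truth, windows = _sim_for_bma(4, n=80, n_genes=5)
        tiny = exprs[0].subset_samples(exprs[0].sample_ids[:5])
        with pytest.raises(ValueError, match="samples"):
            subgroup_summaries([tiny], geno, windows)


class TestHierarchicalEm:
    def test_all_unit_bfs_flat_likelihood(self):
        pairs = pd.DataFrame({"probeset": ["g1", "g1", "g2", "g2"],
                              "snp": ["a", "b", "c", "d"]})
        configs = enumerate_configurations(2)
        log_bf = np.zeros((4, 3))
        hp = fit_hierarchical_em(log_bf, configs, pairs)
        assert hp.pi0 == 1.0

    def test_loglik_monotone_nondecreasing(self):
        cfg, geno, exprs, truth, windows = _sim_for_bma(5, n=120, n_genes=40)
        summ = subgroup_summaries(exprs, geno, windows)
        log_bf, configs = config_log_bfs(summ)
        hp = fit_hierarchical_em(log_bf, configs, summ.pairs)
        assert (np.diff(hp.loglik_trace) >= -1e-9).all()
        assert hp.converged

    def test_parameter_recovery_shared_config(self):
        cfg, geno, exprs, truth, windows = _sim_for_bma(
            6, n=200, n_genes=300, beta=0.8, eqtl_frac=0.2
        )
        summ = subgroup_summaries(exprs, geno, windows)
        log_bf_grid, configs = config_log_bfs(summ, per_grid_point=True)
        hp = fit_hierarchical_em(log_bf_grid, configs, summ.pairs, update_lambda=True)
        assert abs(hp.pi0 - 0.8) <= 0.1
        labels = ["".join(str(int(b)) for b in c) for c in configs]
        assert hp.eta[labels.index("11111")] >= 0.5

    def test_null_simulation_pi0_high(self):
        cfg, geno, exprs, truth, windows = _sim_for_bma(
            7, n=150, n_genes=100, eqtl_frac=0.0, config="11111"
        )
        summ = subgroup_summaries(exprs, geno, windows)
        log_bf, configs = config_log_bfs(summ)
        hp = fit_hierarchical_em(log_bf, configs, summ.pairs)
        assert hp.pi0 >= 0.9


class TestPosteriors:
    def _toy_results(self, log_bf, configs, pairs, pi0=0.5):
        from mceqtl.bma import HyperParams

        c = configs.shape[0]
        hp = HyperParams(pi0, np.full(c, 1 / c), configs, 0.0, 1, True)
        subgroups = [f"T{k}" for k in range(configs.shape[1])]
        return posteriors(log_bf, configs, pairs, hp, subgroups)

    def test_overwhelming_bf_limit(self):
        pairs = pd.DataFrame({"probeset": ["g"], "snp": ["s"]})
        configs = enumerate_configurations(2)
        log_bf = np.array([[500.0, -np.inf, -np.inf]])
        log_bf[log_bf == -np.inf] = -500.0
        res = self._toy_results(log_bf, configs, pairs)
        r = res[0]
        assert r.pp_gene == pytest.approx(1.0, abs=1e-6)
        assert r.pp_config[0] == pytest.approx(1.0, abs=1e-6)
        assert r.entropy == pytest.approx(0.0, abs=1e-4)

    def test_uniform_posterior_max_entropy(self):
        s = 5
        pairs = pd.DataFrame({"probeset": ["g"], "snp": ["s"]})
        configs = enumerate_configurations(s)
        log_bf = np.zeros((1, 2**s - 1))
        res = self._toy_results(log_bf, configs, pairs)
        assert res[0].entropy == pytest.approx(np.log2(2**s - 1), rel=1e-9)

    def test_normalization_invariants_random_inputs(self):
        rng = np.random.default_rng(8)
        snps = 7
        pairs = pd.DataFrame({"probeset": ["g"] * snps,
                              "snp": [f"s{i}" for i in range(snps)]})
        configs = enumerate_configurations(3)
        log_bf = rng.normal(0, 3, size=(snps, 7))
        res = self._toy_results(log_bf, configs, pairs)
        r = res[0]
        assert r.pp_snp.sum() == pytest.approx(1.0, abs=1e-6)
        assert r.pp_config.sum() == pytest.approx(1.0, abs=1e-6)
        for sg, pp in r.activity_pp.items():
            assert 0.0 <= pp <= 1.0 + 1e-9

    def test_map_recovery_on_simulation(self):
        correct = total = 0
        for seed in range(5):
            cfg, geno, exprs, truth, windows = _sim_for_bma(
                10 + seed, n=200, n_genes=60, beta=0.6, eqtl_frac=0.3
            )
            summ = subgroup_summaries(exprs, geno, windows)
            log_bf_grid, configs = config_log_bfs(summ, per_grid_point=True)
            hp = fit_hierarchical_em(log_bf_grid, configs, summ.pairs, update_lambda=True)
            from scipy.special import logsumexp
            log_bf = logsumexp(
                log_bf_grid + np.log(np.clip(hp.lam, 1e-300, None))[:, None, None], axis=0
            )
            res = posteriors(log_bf, configs, summ.pairs, hp, summ.subgroups)
            truth_cfg = truth.table["configuration"]
            for r in res:
                t = truth_cfg[r.probeset]
                if t == "00000":
                    continue
                total += 1
                if r.map_config == t:
                    correct += 1
        assert correct / total >= 0.70


class TestBayesFdr:
    def _res(self, pps):
        return [
            BmaGeneResult(f"g{i}", "s", 0.0, pp, pd.Series(dtype=float),
                          np.array([1.0]), "1", {}, 0.0)
            for i, pp in enumerate(pps)
        ]

    def test_prefix_enumeration_example(self):
        declared = bayes_fdr(self._res([1.0, 1.0, 0.8]), target=0.05)
        assert declared == {"g0", "g1"}  # adding 0.8 gives mean 0.0667 > 0.05

    def test_all_certain_all_declared(self):
        declared = bayes_fdr(self._res([1.0, 1.0, 1.0]), target=0.05)
        assert len(declared) == 3

    def test_target_zero_only_exact_ones(self):
        declared = bayes_fdr(self._res([1.0, 0.999999]), target=0.0)
        assert declared == {"g0"}


class TestPermutationControl:
    def test_identity_and_permutation_behaviour(self):
        cfg, geno, exprs, truth, windows = _sim_for_bma(
            20, n=200, n_genes=60, beta=0.8, eqtl_frac=0.3
        )
        res, hp, declared = run_bma(exprs, geno, windows)
        base_tbl = {r.probeset: r for r in res}
        base_active = sum(
            1 for g in declared if base_tbl[g].activity_pp["CD4"] > 0.5
        )
        assert base_active >= 10  # sanity: there is signal to destroy

        pres, php, pdeclared = permutation_negative_control(
            exprs, geno, windows, permute_subgroup="CD4", seed=99
        )
        perm_tbl = {r.probeset: r for r in pres}
        perm_active = sum(
            1 for g in pdeclared if perm_tbl[g].activity_pp["CD4"] > 0.5
        )
        assert perm_active <= 0.05 * base_active + 1
        # other subgroups survive
        base_cd8 = sum(1 for g in declared if base_tbl[g].activity_pp["CD8"] > 0.5)
        perm_cd8 = sum(1 for g in pdeclared if perm_tbl[g].activity_pp["CD8"] > 0.5)
        assert abs(perm_cd8 - base_cd8) <= 0.2 * base_cd8 + 1
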