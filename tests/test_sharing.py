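"""Jaccard sharing, opposite-direction eQTLs, LD, GWAS overlap, clustering."""

import numpy as np
import pandas as pd
import pytest

from mceqtl.bma import BmaGeneResult, bayes_fdr, run_bma
from mceqtl.cis_scan import cis_window, plugin_fdr, scan_cell_type, scan_with_permutation
from mceqtl.ioformats import GenotypeMatrix
from mceqtl.preprocess import quantile_normal_transform
from mceqtl.sharing import (
    bma_sharing_summary,
    cluster_scores,
    gwas_overlap,
    jaccard,
    ld_r2,
    naive_sharing_summary,
    opposite_direction_pairs,
)
from mceqtl.simulate import SimConfig, make_annotation, simulate_cohort, simulate_genotypes


class TestJaccard:
    def test_direct_count(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_identity_and_empty(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, set()) == 0.0
        assert jaccard(set(), set()) == 0.0


class TestNaiveSharing:
    def test_identical_sets_fully_shared(self):
        s = naive_sharing_summary({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert s.jaccard_matrix.loc["A", "B"] == 1.0
        assert s.histogram[2] == 2
        assert s.shared_fraction() == 1.0

    def test_singleton_breakdown(self):
        s = naive_sharing_summary({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert s.singleton_breakdown["A"] == 1
        assert s.singleton_breakdown["B"] == 1
        assert s.histogram[1] == 2 and s.histogram[2] == 1


def _shared_truth_study(seed, n, beta=0.6):
    s = 5
    cfg = SimConfig(
        n_individuals=n, n_genes=60, seed=seed,
        config_probs={"0" * s: 0.6, "1" * s: 0.4},
        effect_sd_range=(beta, beta), dropout_per_cell_type=0.0, batch_sd=0.0,
    )
    geno = simulate_genotypes(cfg)
    exprs, truth = simulate_cohort(cfg, geno)
    windows = cis_window(make_annotation(cfg), geno.snp_meta)
    return cfg, geno, exprs, truth, windows


def _naive_sets(exprs, geno, windows, seed):
    out = {}
    for e in exprs:
        rec = scan_cell_type(e, geno, windows)
        closure = scan_with_permutation(e, geno, windows)
        f = plugin_fdr(rec, closure, 2, 0.05, seed=seed)
        out[e.cell_type] = set(f.declared["probeset"])
    return out


class TestJointVsNaive:
    def test_joint_recovers_more_sharing_than_lists(self):
        # truth 100% shared: the naive per-cell-type comparison of lists
        # under-calls sharing; the joint model does not
        cfg, geno, exprs, truth, windows = _shared_truth_study(1, n=100)
        naive = naive_sharing_summary(_naive_sets(exprs, geno, windows, 1))
        exprs_t = [quantile_normal_transform(e, seed=1) for e in exprs]
        res, hp, declared = run_bma(exprs_t, geno, windows)
        joint = bma_sharing_summary(res, declared, [e.cell_type for e in exprs])
        assert joint.shared_fraction() >= naive.shared_fraction()
        assert naive.shared_fraction(1) > joint.shared_fraction(1)

    def test_naive_jaccard_decreases_with_sample_size(self):
        # truly identical eQTL profiles, but J drops as power drops; effect
        # 0.45 sits where halving n visibly costs power (5-seed average)
        js = {}
        for n in (200, 100):
            vals = []
            for seed in range(5):
                cfg, geno, exprs, truth, windows = _shared_truth_study(
                    20 + seed, n=n, beta=0.45
                )
                naive = naive_sharing_summary(_naive_sets(exprs, geno, windows, seed))
                vals.append(naive.jaccard_matrix.loc["CD4", "CD8"])
            js[n] = np.mean(vals)
        assert js[100] < js[200]


class TestBmaSharingModes:
    def _results(self):
        cfg, geno, exprs, truth, windows = _shared_truth_study(3, n=150)
        exprs_t = [quantile_normal_transform(e, seed=3) for e in exprs]
        res, hp, declared = run_bma(exprs_t, geno, windows)
        return res, declared, [e.cell_type for e in exprs]

    def test_concentrated_gene_counted_in_full_bin(self):
        res, declared, subgroups = self._results()
        s = bma_sharing_summary(res, declared, subgroups, mode="map")
        conc = [r for r in res if r.probeset in declared and r.pp_config.max() > 0.99]
        for r in conc:
            assert s.presence[r.probeset] == {
                sg for sg, b in zip(subgroups, r.map_config) if b == "1"
            }

    def test_map_and_activity_agree_at_low_entropy(self):
        res, declared, subgroups = self._results()
        m = bma_sharing_summary(res, declared, subgroups, mode="map")
        a = bma_sharing_summary(res, declared, subgroups, mode="activity")
        low = [r.probeset for r in res if r.probeset in declared and r.entropy < 0.5]
        agree = sum(1 for g in low if m.presence.get(g) == a.presence.get(g))
        assert agree / max(len(low), 1) >= 0.8

    def test_invalid_mode_errors(self):
        res, declared, subgroups = self._results()
        with pytest.raises(ValueError, match="mode"):
            bma_sharing_summary(res, declared, subgroups, mode="bogus")


class TestOppositeDirection:
    def test_planted_opposite_pair_detected(self):
        s = 5
        cfg = SimConfig(
            n_individuals=200, n_genes=30, seed=4,
            config_probs={"0" * s: 0.5, "1" * s: 0.5},
            effect_sd_range=(0.8, 0.8), opposite_sign_fraction=0.5,
            dropout_per_cell_type=0.0, batch_sd=0.0,
        )
        geno = simulate_genotypes(cfg)
        exprs, truth = simulate_cohort(cfg, geno)
        windows = cis_window(make_annotation(cfg), geno.snp_meta)
        recs, sets = {}, {}
        for e in exprs:
            rec = scan_cell_type(e, geno, windows)
            f = plugin_fdr(rec, scan_with_permutation(e, geno, windows), 2, 0.05, seed=4)
            recs[e.cell_type] = rec
            sets[e.cell_type] = set(zip(f.declared["probeset"], f.declared["snp"]))
        beta_cols = truth.table[[f"beta_{c}" for c in cfg.cell_types]]
        flipped = truth.table.index[
            (np.sign(beta_cols).nunique(axis=1) > 1) & (beta_cols.abs().sum(axis=1) > 0)
        ]
        found_opposite = set()
        cells = list(cfg.cell_types)
        for i, a in enumerate(cells):
            for b in cells[i + 1:]:
                table = opposite_direction_pairs(recs[a], recs[b], sets[a], sets[b])
                if len(table):
                    found_opposite |= set(table.loc[table["opposite"], "probeset"])
        assert len(set(flipped) & found_opposite) >= len(flipped) * 0.5
        # identical records in both members -> nothing opposite
        same = opposite_direction_pairs(recs["CD4"], recs["CD4"], sets["CD4"], sets["CD4"])
        assert not same["opposite"].any()


def _ld_geno(seed=5):
    cfg = SimConfig(n_individuals=1000, n_genes=10, ld_block_size=5,
                    ld_flip_prob=0.1, seed=seed)
    return cfg, simulate_genotypes(cfg)


class TestLd:
    def test_duplicate_and_flipped_copy(self):
        rng = np.random.default_rng(6)
        a = rng.binomial(2, 0.4, 200).astype(float)
        dosage = np.column_stack([a, a, 2 - a])
        meta = pd.DataFrame(
            {"chrom": "chr1", "pos": [1, 2, 3], "ref": "A", "alt": "G"},
            index=pd.Index(["s1", "s2", "s3"], name="snp_id"),
        )
        g = GenotypeMatrix(dosage, meta, [f"I{i}" for i in range(200)])
        assert ld_r2(g, "s1", "s2") == pytest.approx(1.0)
        assert ld_r2(g, "s1", "s3") == pytest.approx(1.0)  # sign-invariant
        assert ld_r2(g, "s1", "s1") == pytest.approx(1.0)

    def test_independent_snps_low_r2(self):
        cfg, geno = _ld_geno()
        # heads of different blocks are independent draws
        hits = 0
        pairs = [(f"rs{5*i+1:06d}", f"rs{5*j+1:06d}") for i, j in
                 [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10), (10, 12),
                  (12, 14), (14, 16), (16, 18), (1, 3)]]
        for a, b in pairs:
            if ld_r2(geno, a, b) < 0.02:
                hits += 1
        assert hits >= 9  # 95% of independent pairs at n=1000

    def test_monomorphic_errors(self):
        dosage = np.column_stack([np.zeros(10), np.arange(10) % 3])
        meta = pd.DataFrame(
            {"chrom": "chr1", "pos": [1, 2], "ref": "A", "alt": "G"},
            index=pd.Index(["s1", "s2"], name="snp_id"),
        )
        g = GenotypeMatrix(dosage.astype(float), meta, [f"I{i}" for i in range(10)])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(g, "s1", "s2")


class TestGwasOverlap:
    def _setup(self):
        cfg = SimConfig(
            n_individuals=200, n_genes=10, seed=7, ld_flip_prob=0.02,
            config_probs={"00000": 0.3, "11111": 0.7},
            effect_sd_range=(1.0, 1.0), dropout_per_cell_type=0.0, batch_sd=0.0,
        )
        geno = simulate_genotypes(cfg)
        exprs, truth = simulate_cohort(cfg, geno)
        windows = cis_window(make_annotation(cfg), geno.snp_meta)
        e = exprs[0]
        rec = scan_cell_type(e, geno, windows)
        f = plugin_fdr(rec, scan_with_permutation(e, geno, windows), 2, 0.05, seed=7)
        fdr_sets = {"CD4": set(zip(f.declared["probeset"], f.declared["snp"]))}
        return cfg, geno, truth, rec, fdr_sets

    def test_causal_gwas_snp_reported_both_criteria(self):
        cfg, geno, truth, rec, fdr_sets = self._setup()
        declared_genes = {p for p, _ in fdr_sets["CD4"]}
        hit_gene = truth.table.index[
            truth.table.index.isin(declared_genes)
            & (truth.table["configuration"] == "11111")
        ][0]
        causal = truth.table.loc[hit_gene, "causal_snp"]
        assert (hit_gene, causal) in fdr_sets["CD4"]
        gwas = pd.DataFrame({"rsid": [causal], "trait": ["IBD"]})
        for criterion in ("basic", "stringent"):
            out = gwas_overlap({"CD4": rec}, fdr_sets, gwas, geno, criterion=criterion)
            if criterion == "basic":
                assert (out["probeset"] == hit_gene).any()
        # stringent subset of basic
        basic = gwas_overlap({"CD4": rec}, fdr_sets, gwas, geno, criterion="basic")
        strin = gwas_overlap({"CD4": rec}, fdr_sets, gwas, geno, criterion="stringent")
        b = set(map(tuple, basic[["gwas_snp", "esnp", "probeset"]].to_numpy()))
        s = set(map(tuple, strin[["gwas_snp", "esnp", "probeset"]].to_numpy()))
        assert s <= b

    def test_unknown_rsid_skipped(self):
        cfg, geno, truth, rec, fdr_sets = self._setup()
        gwas = pd.DataFrame({"rsid": ["rsUNKNOWN"], "trait": ["IBD"]})
        out = gwas_overlap({"CD4": rec}, fdr_sets, gwas, geno)
        assert out.empty

    def test_weak_proxy_not_reported(self):
        cfg, geno, truth, rec, fdr_sets = self._setup()
        # a SNP from a distant LD-independent block cannot proxy the eSNP
        declared = next(iter(fdr_sets["CD4"]))
        esnp_idx = geno.snp_meta.index.get_loc(declared[1])
        far = geno.snp_meta.index[(esnp_idx + 50) % geno.n_snps]
        from mceqtl.sharing import ld_r2 as _r2
        assert _r2(geno, far, declared[1]) < 0.8
        gwas = pd.DataFrame({"rsid": [far], "trait": ["IBD"]})
        out = gwas_overlap({"CD4": rec}, fdr_sets, gwas, geno)
        assert not (out["esnp"] == declared[1]).any()


class TestClusterScores:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=100)
        mat = pd.DataFrame({
            "A": base, "B": base, "C": rng.normal(size=100), "D": rng.normal(size=100),
        })
        res = cluster_scores(mat)
        first = res.col_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("ABCD"))
        scaled = mat * [1.0, 10.0, 0.1, 5.0]
        a = cluster_scores(mat)
        b = cluster_scores(scaled)
        np.testing.assert_allclose(a.col_linkage, b.col_linkage, atol=1e-10)

    def test_lineage_block_structure_recovered(self):
        # lymphoid-like pair shares signal, myeloid-like pair shares signal:
        # within-lineage columns merge before cross-lineage
        rng = np.random.default_rng(10)
        n = 200
        lymph = rng.normal(size=n)
        myel = rng.normal(size=n)
        mat = pd.DataFrame({
            "CD4": lymph + 0.3 * rng.normal(size=n),
            "CD8": lymph + 0.3 * rng.normal(size=n),
            "CD14": myel + 0.3 * rng.normal(size=n),
            "CD16": myel + 0.3 * rng.normal(size=n),
        })
        res = cluster_scores(mat)
        merges = [
            {int(res.col_linkage[i][0]), int(res.col_linkage[i][1])} for i in range(2)
        ]
        assert {0, 1} in merges and {2, 3} in merges

    def test_single_column_errors(self):
        with pytest.raises(ValueError, match="2 columns"):
            cluster_scores(pd.DataFrame({"A": [1.0, 2.0]}))
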