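"""Evaluation framework: QQ/lambda, genomic control, concordance,
cross-method ROC/AUC, MAF bins, error-rate harness."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

import longgwas as lg
from longgwas.compare import (
    PVALUE_BINS,
    cross_method_roc,
    error_rate_harness,
    genomic_control,
    maf_stratified_bins,
    pvalue_correlation,
    qq_data,
)


class TestQQ:
    def test_exact_uniform_grid_gives_lambda_one(self):
        m = 10001
        p = (np.arange(1, m + 1) - 0.5) / m
        _, lam = qq_data(p)
        assert lam == pytest.approx(1.0, abs=0.002)

    def test_halving_pvalues_inflates_lambda(self):
        p = (np.arange(1, 2001) - 0.5) / 2000
        _, lam0 = qq_data(p)
        _, lam1 = qq_data(p / 2)
        assert lam1 > lam0

    def test_pairs_sorted_and_matched(self):
        p = np.array([0.9, 0.1, 0.5])
        df, _ = qq_data(p)
        np.testing.assert_allclose(df["observed"], -np.log10(np.sort(p)))
        # both columns run from the extreme tail downward together
        assert (df["observed"].diff().dropna() <= 0).all()
        assert (df["expected"].diff().dropna() <= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qq_data([])


class TestGenomicControl:
    def test_lambda_one_identity(self):
        p = np.array([0.01, 0.2, 0.8])
        np.testing.assert_array_equal(genomic_control(p, 1.0), p)

    def test_known_adjustment(self):
        # chi2(0.05) = 3.8415; /2 -> 1.9207; upper tail = 0.1659
        adj = genomic_control(np.array([0.05]), 2.0)
        assert adj[0] == pytest.approx(
            st.chi2.sf(st.chi2.isf(0.05, 1) / 2.0, 1), rel=1e-12
        )
        assert adj[0] == pytest.approx(0.1659, abs=2e-4)

    def test_no_anti_deflation(self):
        p = np.array([0.01, 0.2])
        np.testing.assert_array_equal(genomic_control(p, 0.7), p)

    @given(lam=hst.floats(1.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_rank_preserving(self, lam):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-8, 1, 50)
        adj = genomic_control(p, lam)
        np.testing.assert_array_equal(np.argsort(p), np.argsort(adj))


class TestPvalueCorrelation:
    def test_identical_vectors_r_one(self):
        p = np.random.default_rng(1).uniform(0.001, 1, 20)
        out = pvalue_correlation(p, p)
        assert out["r"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_anti_ranked_negative(self):
        p = np.linspace(0.05, 0.95, 10)
        out = pvalue_correlation(p, p[::-1])
        assert out["r"] < 0

    def test_hand_fixture_matches_textbook_pearson(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
        b = np.array([0.12, 0.25, 0.28, 0.35, 0.55, 0.5, 0.77, 0.8, 0.85, 0.99])
        out = pvalue_correlation(a, b)
        ref = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert out["r"] == pytest.approx(ref, rel=1e-12)

    def test_too_few_snps_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            pvalue_correlation([0.1, 0.2], [0.3, 0.4])


class TestCrossMethodROC:
    def test_self_prediction_perfect(self):
        p = np.random.default_rng(2).uniform(1e-5, 1, 200)
        for t in (0.5, 0.1, 0.01):
            roc = cross_method_roc(p, p, t)
            assert roc.auc == pytest.approx(1.0)

    def test_permuted_scores_near_half(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(1e-4, 1, 5000)
        roc = cross_method_roc(rng.permutation(p), p, 0.1)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_hand_enumerated_auc(self):
        # labels from p_b < 0.05: positives at p_a = .01, .2; negatives .03, .1, .5, .9
        p_a = np.array([0.01, 0.2, 0.03, 0.1, 0.5, 0.9])
        p_b = np.array([0.01, 0.04, 0.2, 0.3, 0.4, 0.5])
        roc = cross_method_roc(p_a, p_b, 0.05)
        # scores -log10 p_a; count of (pos score > neg score) pairs:
        # pos .01 beats all 4 negs; pos .2 beats .5, .9 -> U = 6 of 8
        assert roc.auc == pytest.approx(6 / 8)

    def test_degenerate_labels_undefined_not_raised(self):
        p = np.array([0.2, 0.3, 0.4])
        roc = cross_method_roc(p, p, 1e-6)
        assert np.isnan(roc.auc)

    @given(seed=hst.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_mann_whitney_equals_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        p_a = rng.uniform(1e-6, 1, 60)
        # induce ties in scores
        p_a = np.minimum(np.round(p_a, 2) + 1e-9, 1.0)
        p_b = rng.uniform(1e-6, 1, 60)
        roc = cross_method_roc(p_a, p_b, 0.3)
        if not roc.defined:
            return
        trap = np.trapezoid(roc.points["tpr"], roc.points["fpr"])
        assert roc.auc == pytest.approx(trap, abs=1e-12)


class TestMafBins:
    def test_all_rare_gives_unit_fractions(self):
        p = np.random.default_rng(5).uniform(1e-6, 1, 300)
        maf = np.full(300, 0.02)
        bins = maf_stratified_bins(p, maf)
        occupied = bins[bins["n_snps"] > 0]
        assert (occupied["rare_fraction"] == 1.0).all()

    def test_bins_partition_panel(self):
        p = np.random.default_rng(6).uniform(1e-6, 1, 500)
        maf = np.random.default_rng(7).uniform(0.01, 0.5, 500)
        bins = maf_stratified_bins(p, maf)
        assert bins["n_snps"].sum() == 500

    def test_hand_counted_fixture(self):
        p = np.array([0.5] * 10 + [0.05] * 5 + [0.005] * 3 + [5e-4] * 2)
        maf = np.array([0.01] * 5 + [0.3] * 5 + [0.02, 0.3, 0.3, 0.3, 0.3]
                       + [0.02, 0.02, 0.3] + [0.02, 0.3])
        bins = maf_stratified_bins(p, maf).set_index("bin")
        assert bins.loc["p>0.1", "rare_fraction"] == pytest.approx(0.5)
        assert bins.loc["0.01<p<=0.1", "rare_fraction"] == pytest.approx(1 / 5)
        assert bins.loc["0.001<p<=0.01", "rare_fraction"] == pytest.approx(2 / 3)
        assert bins.loc["0.0001<p<=0.001", "rare_fraction"] == pytest.approx(1 / 2)


class TestErrorRateHarness:
    def test_alpha_one_rejects_everything(self):
        out = error_rate_harness(
            [{"maf": 0.3, "beta": 0.0, "n_snps": 5}],
            methods=["pc_lmem"], alphas=[1.0], n_reps=2, seed=1,
            n_subjects=60,
        )
        assert out["rate"].iloc[0] == 1.0

    def test_power_monotone_in_beta_and_maf(self):
        grid = [{"maf": m, "beta": b} for m in (0.1, 0.3, 0.5)
                for b in (0.02, 0.08, 0.2)]
        out = error_rate_harness(grid, methods=["pc_lmem"], alphas=[0.05],
                                 n_reps=60, seed=2, n_subjects=300)
        pivot = out.pivot_table(index="maf", columns="beta", values="rate")
        # non-decreasing along both axes of the 3x3 grid
        assert (pivot.diff(axis=0).iloc[1:] >= 0).all().all()
        assert (pivot.diff(axis=1).iloc[:, 1:] >= 0).all().all()

    def test_kin_power_not_above_pc_power(self):
        # matched nominal type-I level, same simulated data per replicate
        nrep = 60
        rej_k = rej_p = 0
        for rep in range(nrep):
            seed = int(np.random.SeedSequence([55, rep]).generate_state(1)[0]
                       % (2**31 - 1))
            cfg = lg.SimConfig(n_subjects=600, n_snps=300,
                               maf_range=(0.05, 0.5),
                               snp_effects={0: 0.05}, seed=seed)
            g, _ = lg.simulate_genotypes(cfg)
            ph, _ = lg.simulate_phenotype(g, None, cfg)
            kin = lg.compute_kinship(g)
            x = g.dosage_float()[:, 0]
            rej_k += lg.KinLMEM(ph, x, kinship=kin).fit().p_value <= 0.05
            rej_p += lg.PCLMEM(ph, x, n_pcs=0).fit().p_value <= 0.05
        assert rej_k <= rej_p


class TestCompareMethods:
    def test_report_assembles(self, small_cohort):
        _, g, _, pheno, _ = small_cohort
        res_l = lg.run_gwas(g, pheno, "pc_lmem", n_pcs=0)
        res_g = lg.run_gwas(g, pheno, "pc_gee", n_pcs=0)
        report = lg.compare_methods({"pc_lmem": res_l, "pc_gee": res_g})
        assert set(report.lambdas) == {"pc_lmem", "pc_gee"}
        assert len(report.correlations) == 1
        assert report.correlations["r"].iloc[0] > 0.9
        aucs = report.auc.dropna(subset=["auc"])
        assert ((aucs["auc"] >= 0) & (aucs["auc"] <= 1)).all()
        assert report.to_json().startswith("{")
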