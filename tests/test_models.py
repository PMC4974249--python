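"""Association-engine correctness: GLS closed forms, dense-likelihood
oracles, GEE identities, independent statsmodels cross-checks, and
component estimation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import longgwas as lg
from longgwas.models import (
    KinLMEM,
    PCGEE,
    PCLMEM,
    VarianceComponents,
    estimate_null_components,
    exchangeable_D,
)


def _cohort(n=40, seed=0, complete=True, **cfg_kw):
    kw = dict(sigma_u2=0.3, sigma_v2=0.4, sigma2=0.3, d_rho=0.5)
    kw.update(cfg_kw)
    cfg = lg.SimConfig(n_subjects=n, n_snps=4, seed=seed, **kw)
    g, _ = lg.simulate_genotypes(cfg)
    pheno, _ = lg.simulate_phenotype(g, None, cfg)
    if not complete:
        pheno = lg.apply_missingness(pheno, "MCAR", {"rate": 0.15}, seed=seed)
        keep = np.isin(g.subject_ids, pheno.subject_ids)
        g = g.select_subjects(np.flatnonzero(keep))
    return g, pheno


def _long_frame(pheno, snp):
    rows = []
    for i, sid in enumerate(pheno.subject_ids):
        for j in range(pheno.n_courses):
            if np.isfinite(pheno.values[i, j]):
                rows.append((sid, j + 1, pheno.values[i, j], snp[i]))
    df = pd.DataFrame(rows, columns=["sid", "course", "y", "snp"])
    df = pd.get_dummies(df, columns=["course"], drop_first=True, dtype=float)
    return df


class TestPCLMEM:
    def test_gls_closed_form_at_fixed_components(self):
        g, pheno = _cohort(n=40, seed=1)
        snp = g.dosage_float()[:, 0]
        vc = VarianceComponents(sigma_v2=0.35, sigma2=0.3, d_rho=1.0)
        res = PCLMEM(pheno, snp, n_pcs=0).fit(components=vc)
        # direct dense GLS oracle
        d = PCLMEM(pheno, snp, n_pcs=0).design
        same = d.subj[:, None] == d.subj[None, :]
        V = 0.35 * same + 0.3 * np.eye(d.n_obs)
        Vi = np.linalg.inv(V)
        xtx = d.X.T @ Vi @ d.X
        beta = np.linalg.solve(xtx, d.X.T @ Vi @ d.y)
        np.testing.assert_allclose(res.params, beta, rtol=1e-10)
        np.testing.assert_allclose(
            res.cov_params, np.linalg.inv(xtx), rtol=1e-8, atol=1e-12
        )

    def test_loglike_matches_dense_mvn(self):
        g, pheno = _cohort(n=25, seed=2, complete=False)
        snp = g.dosage_float()[:, 1]
        m = PCLMEM(pheno, snp, n_pcs=0)
        vc = VarianceComponents(sigma_v2=0.4, sigma2=0.25, d_rho=1.0)
        params = np.linspace(-0.2, 0.2, m.design.X.shape[1]) + 3.5
        d = m.design
        same = d.subj[:, None] == d.subj[None, :]
        V = 0.4 * same + 0.25 * np.eye(d.n_obs)
        ref = st.multivariate_normal(mean=d.X @ params, cov=V).logpdf(d.y)
        assert m.loglike(params, vc) == pytest.approx(ref, abs=1e-8)

    def test_reml_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        g, pheno = _cohort(n=150, seed=3, complete=False)
        snp = g.dosage_float()[:, 0]
        res = PCLMEM(pheno, snp, n_pcs=0).fit()
        df = _long_frame(pheno, snp)
        exog = sm.add_constant(df[["snp", "course_2", "course_3", "course_4"]])
        ref = sm.MixedLM(df["y"], exog, groups=df["sid"]).fit(reml=True)
        assert res.beta == pytest.approx(ref.params["snp"], rel=1e-5, abs=1e-8)
        assert res.se_beta == pytest.approx(ref.bse["snp"], rel=1e-4)
        assert res.components.sigma_v2 == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-4
        )

    def test_zero_icc_truth_recovered(self):
        g, pheno = _cohort(n=500, seed=4, sigma_u2=0.0, sigma_v2=0.0,
                           sigma2=1.0)
        res = PCLMEM(pheno, g.dosage_float()[:, 0], n_pcs=0).fit()
        vc = res.components
        icc = vc.sigma_v2 / (vc.sigma2 + vc.sigma_v2)
        assert icc == pytest.approx(0.0, abs=0.02)

    def test_null_pvalues_uniform(self):
        cfg = lg.SimConfig(n_subjects=300, n_snps=2000, seed=5)
        g, _ = lg.simulate_genotypes(cfg)
        pheno, _ = lg.simulate_phenotype(g, None, cfg)
        res = lg.run_gwas(g, pheno, "pc_lmem", n_pcs=0)
        ks = st.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_snp_rejected(self, tiny_pheno):
        with pytest.raises(lg.MonomorphicSNPError):
            PCLMEM(tiny_pheno, np.ones(tiny_pheno.n_subjects), n_pcs=0)


class TestPCGEE:
    def test_balanced_complete_equals_pooled_ols(self):
        # balanced compound symmetry: the design space is invariant under
        # the working covariance, so GEE point estimates equal pooled OLS
        g, pheno = _cohort(n=60, seed=6)
        snp = g.dosage_float()[:, 0]
        res = PCGEE(pheno, snp, n_pcs=0).fit()
        d = PCGEE(pheno, snp, n_pcs=0).design
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(res.params, ols, rtol=1e-8)

    def test_balanced_complete_equals_gls_at_moment_rho(self):
        g, pheno = _cohort(n=60, seed=7)
        snp = g.dosage_float()[:, 1]
        res = PCGEE(pheno, snp, n_pcs=0).fit()
        rho = res.components.rho
        d = PCGEE(pheno, snp, n_pcs=0).design
        same = d.subj[:, None] == d.subj[None, :]
        R = np.where(same, rho, 0.0) + (1 - rho) * np.eye(d.n_obs)
        Ri = np.linalg.inv(R)
        beta = np.linalg.solve(d.X.T @ Ri @ d.X, d.X.T @ Ri @ d.y)
        np.testing.assert_allclose(res.params, beta, rtol=1e-8)

    def test_matches_statsmodels_gee(self):
        import statsmodels.api as sm

        g, pheno = _cohort(n=150, seed=8, complete=False)
        snp = g.dosage_float()[:, 2]
        res = PCGEE(pheno, snp, n_pcs=0).fit()
        df = _long_frame(pheno, snp)
        exog = sm.add_constant(df[["snp", "course_2", "course_3", "course_4"]])
        ref = sm.GEE(df["y"], exog, groups=df["sid"],
                     cov_struct=sm.cov_struct.Exchangeable()).fit()
        assert res.beta == pytest.approx(ref.params["snp"], rel=1e-6, abs=1e-10)
        assert res.se_beta == pytest.approx(ref.bse["snp"], rel=1e-6)
        assert res.components.rho == pytest.approx(
            float(ref.cov_struct.dep_params), rel=1e-6
        )


class TestKinLMEM:
    def _family_kinship(self, n, fam=2, r=0.5):
        block = (1 - r) * np.eye(fam) + r * np.ones((fam, fam))
        return lg.KinshipMatrix(np.kron(np.eye(n // fam), block))

    def test_loglike_matches_dense_mvn(self):
        g, pheno = _cohort(n=20, seed=9, complete=False)
        kin = self._family_kinship(20)
        snp = g.dosage_float()[:, 0]
        m = KinLMEM(pheno, snp, kinship=kin, d_rho=0.5)
        vc = VarianceComponents(sigma_u2=0.25, sigma_v2=0.3, sigma2=0.2,
                                d_rho=0.5)
        params = np.full(m.design.X.shape[1], 0.1)
        d = m.design
        K = kin.values[np.ix_(d.used_subjects, d.used_subjects)]
        D = exchangeable_D(4, 0.5)
        same = d.subj[:, None] == d.subj[None, :]
        V = (0.25 * K[np.ix_(d.subj, d.subj)]
             + 0.3 * np.where(same, D[np.ix_(d.course, d.course)], 0.0)
             + 0.2 * np.eye(d.n_obs))
        ref = st.multivariate_normal(mean=d.X @ params, cov=V).logpdf(d.y)
        assert m.loglike(params, vc) == pytest.approx(ref, abs=1e-8)

    def test_spectral_reml_matches_dense_reml(self):
        # same objective through the fast complete-data path and a dense
        # Cholesky evaluation
        g, pheno = _cohort(n=16, seed=10)
        kin = self._family_kinship(16, fam=4)
        snp = g.dosage_float()[:, 0]
        fast = KinLMEM(pheno, snp, kinship=kin, d_rho=0.5)
        assert fast._spectral_ok
        slow = KinLMEM(pheno, snp, kinship=kin, d_rho=0.5)
        slow._spectral_ok = False
        slow._prepare_dense()
        for theta in ([0.3, 0.4, 0.3], [0.05, 1.0, 0.2], [1.0, 0.01, 0.5]):
            t = np.log(theta)
            assert fast._reml_neg(t) == pytest.approx(slow._reml_neg(t),
                                                      abs=1e-8)

    def test_identity_kinship_identity_D_equivalent_to_random_intercept(self):
        # K = I and D = I collapse onto the random-intercept model with
        # sigma_v2_pc = sigma_u2 and sigma2_pc = sigma_v2 + sigma2
        g, pheno = _cohort(n=30, seed=11)
        snp = g.dosage_float()[:, 0]
        kin_res = KinLMEM(pheno, snp, kinship=None, d_rho=0.0).fit()
        pc_res = PCLMEM(pheno, snp, n_pcs=0).fit()
        assert kin_res.beta == pytest.approx(pc_res.beta, rel=1e-4, abs=1e-7)
        assert kin_res.se_beta == pytest.approx(pc_res.se_beta, rel=1e-3)
        kc, pc = kin_res.components, pc_res.components
        assert kc.sigma_u2 == pytest.approx(pc.sigma_v2, rel=2e-2, abs=1e-4)
        assert kc.sigma_v2 + kc.sigma2 == pytest.approx(pc.sigma2, rel=2e-2)

    def test_zero_genetic_variance_recovered_at_boundary(self):
        cfg = lg.SimConfig(n_subjects=500, n_snps=2, seed=12, sigma_u2=0.0,
                           sigma_v2=0.3, sigma2=0.7, d_rho=0.0)
        g, _ = lg.simulate_genotypes(cfg)
        pheno, _ = lg.simulate_phenotype(g, None, cfg)
        kin = self._family_kinship(500)
        vc = estimate_null_components(pheno, kinship=kin, model="kin_lmem",
                                      d_rho=0.0)
        total = vc.sigma_u2 + vc.sigma_v2 + vc.sigma2
        assert vc.sigma_u2 / total == pytest.approx(0.0, abs=0.05)

    def test_missing_data_dense_fit_runs(self):
        g, pheno = _cohort(n=30, seed=13, complete=False)
        res = KinLMEM(pheno, g.dosage_float()[:, 0], kinship=None,
                      d_rho=0.5).fit()
        assert res.converged
        assert 0 < res.p_value <= 1


class TestNullComponents:
    def test_reuse_vs_exact_pvalue_concordance(self):
        cfg = lg.SimConfig(n_subjects=250, n_snps=200, seed=14)
        g, _ = lg.simulate_genotypes(cfg)
        pheno, _ = lg.simulate_phenotype(g, None, cfg)
        approx = lg.run_gwas(g, pheno, "pc_lmem", n_pcs=0, mode="approx")
        exact = lg.run_gwas(g, pheno, "pc_lmem", n_pcs=0, mode="exact")
        r = st.pearsonr(approx["p"], exact["p"]).statistic
        assert r > 0.99

    def test_flagged_as_reusable(self, small_cohort):
        _, g, _, pheno, _ = small_cohort
        vc = estimate_null_components(pheno, model="pc_lmem", n_pcs=0)
        assert "reusable" in vc.method
        assert vc.sigma_v2 >= 0 and vc.sigma2 > 0
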