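"""Per-SNP longitudinal association models.

Three engines test a SNP's additive effect on repeated log course
durations in an (assumed unrelated) cohort:

``PCLMEM``
    Linear mixed model with a subject random intercept and principal
    components as fixed ancestry covariates.  Within-subject correlation
    is sigma_v2 / (sigma2 + sigma_v2).
``PCGEE``
    Marginal model with the same mean structure, an exchangeable working
    correlation rho, and a robust (sandwich) covariance.
``KinLMEM``
    Mixed model with a subject genetic random effect whose covariance is
    sigma_u2 * K for a kinship/GRM matrix K, plus a course-level random
    effect with within-subject correlation structure D and variance
    sigma_v2.

All engines fit by (restricted) maximum likelihood / estimating
equations on the stacked observed cells, drop subjects with a missing
genotype for that SNP (casewise deletion), and report a Wald test of the
SNP effect against chi-square(1).  Likelihood fits remain valid under
missing-at-random phenotype dropout; the GEE requires missing completely
at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import MISSING_DOSAGE
from .kinship import KinshipMatrix
from .pca import PrincipalComponents
from .phenotype import LongitudinalPhenotype

__all__ = [
    "VarianceComponents",
    "LongitudinalResults",
    "PCLMEM",
    "PCGEE",
    "KinLMEM",
    "MonomorphicSNPError",
    "estimate_null_components",
    "kinship_eigendecomposition",
]

_VAR_FLOOR = 1e-10


class MonomorphicSNPError(ValueError):
    """The SNP dosage is constant among the usable subjects."""


def exchangeable_D(n_courses: int, d_rho: float) -> np.ndarray:
    """Exchangeable course-correlation structure: 1 on the diagonal,
    ``d_rho`` off it."""
    if not (-1.0 / (n_courses - 1) <= d_rho <= 1.0):
        raise ValueError("d_rho outside the positive-semidefinite range")
    return (1.0 - d_rho) * np.eye(n_courses) + d_rho * np.ones(
        (n_courses, n_courses)
    )


@dataclass
class VarianceComponents:
    """Variance components sigma_u2 (subject genetic), sigma_v2
    (course-level random effect), sigma2 (residual), with the
    within-subject structure D (exchangeable parameter ``d_rho`` or an
    explicit matrix) and, for the GEE, the working correlation ``rho``.
    """

    sigma_u2: float = 0.0
    sigma_v2: float = 0.0
    sigma2: float = 1.0
    d_rho: float | None = None
    D: np.ndarray | None = None
    rho: float | None = None
    method: str = ""

    def __post_init__(self):
        if self.sigma_u2 < 0 or self.sigma_v2 < 0:
            raise ValueError("variance components must be nonnegative")
        if self.sigma2 <= 0:
            raise ValueError("residual variance must be positive")
        if self.D is not None:
            self.D = np.asarray(self.D, dtype=float)

    def D_matrix(self, n_courses: int) -> np.ndarray:
        if self.D is not None:
            if self.D.shape != (n_courses, n_courses):
                raise ValueError("D matrix does not match the course count")
            return self.D
        d = 1.0 if self.d_rho is None else self.d_rho
        return exchangeable_D(n_courses, d)

    def within_subject_correlation(self, n_courses: int) -> np.ndarray:
        """Implied Corr(Y_ij, Y_ik) = (sigma_v2 D_jk + sigma_u2) / total
        (diagonal K assumed)."""
        total = self.sigma2 + self.sigma_v2 + self.sigma_u2
        corr = (self.sigma_v2 * self.D_matrix(n_courses) + self.sigma_u2) / total
        np.fill_diagonal(corr, 1.0)
        if np.any(np.abs(corr) > 1 + 1e-12):
            raise ValueError("implied correlation outside [-1, 1]")
        return corr


# ---------------------------------------------------------------------------
# stacked design


@dataclass
class _StackedDesign:
    y: np.ndarray            # (N,) observed log durations
    X: np.ndarray            # (N, p)
    names: list
    subj: np.ndarray         # (N,) 0-based index into used subjects
    course: np.ndarray       # (N,) 0-based course index
    group_start: np.ndarray  # reduceat offsets (rows sorted by subject)
    n_per_subject: np.ndarray
    used_subjects: np.ndarray  # indices into the phenotype's subject axis
    n_courses: int

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_used(self) -> int:
        return self.used_subjects.size

    def snp_column(self) -> int | None:
        return self.names.index("snp") if "snp" in self.names else None


def _build_design(
    pheno: LongitudinalPhenotype,
    snp,
    pcs,
    n_pcs: int,
    include_course: bool = True,
) -> _StackedDesign:
    """Stack observed cells row-major by subject; drop subjects with a
    missing genotype."""
    Y = pheno.values
    n, J = Y.shape
    obs = np.isfinite(Y)
    used = np.ones(n, dtype=bool)
    snp_vec = None
    if snp is not None:
        snp_vec = np.asarray(snp, dtype=float).copy()
        if snp_vec.shape != (n,):
            raise ValueError("snp vector length must match subject count")
        snp_vec[snp_vec == MISSING_DOSAGE] = np.nan
        used &= np.isfinite(snp_vec)
    used &= obs.any(axis=1)
    used_idx = np.flatnonzero(used)
    if used_idx.size == 0:
        raise ValueError("no usable subjects")
    obs_u = obs[used_idx]
    subj, course = np.nonzero(obs_u)  # row-major: sorted by subject
    y = Y[used_idx][obs_u]
    cols = [np.ones(y.size)]
    names = ["const"]
    if snp_vec is not None:
        x = snp_vec[used_idx]
        if np.ptp(x) == 0:
            raise MonomorphicSNPError(
                "SNP is constant among usable subjects"
            )
        cols.append(x[subj])
        names.append("snp")
    if include_course:
        for j in range(1, J):
            cols.append((course == j).astype(float))
            names.append(f"course_{j + 1}")
    if pcs is not None and n_pcs:
        scores = pcs.scores if isinstance(pcs, PrincipalComponents) else np.asarray(pcs)
        if scores.shape[0] != n:
            raise ValueError("PC scores must match subject count")
        if n_pcs > scores.shape[1]:
            raise ValueError("n_pcs exceeds available components")
        for c in range(n_pcs):
            cols.append(scores[used_idx, c][subj])
            names.append(f"PC{c + 1}")
    X = np.column_stack(cols)
    n_per = obs_u.sum(axis=1)
    group_start = np.concatenate(([0], np.cumsum(n_per)[:-1]))
    return _StackedDesign(
        y=y,
        X=X,
        names=names,
        subj=subj,
        course=course,
        group_start=group_start,
        n_per_subject=n_per,
        used_subjects=used_idx,
        n_courses=J,
    )


# ---------------------------------------------------------------------------
# results


@dataclass
class LongitudinalResults:
    """Fit of one per-SNP longitudinal association model.

    Exposes statsmodels-style ``params`` / ``bse`` / ``pvalues`` plus the
    SNP-specific Wald statistic and the estimated variance components.
    """

    model_name: str
    names: list
    params: np.ndarray
    cov_params: np.ndarray
    components: VarianceComponents
    n_used: int
    n_obs: int
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (self.params / self.bse) ** 2
        return stats.chi2.sf(w, 1)

    def _named(self, name):
        if name not in self.names:
            return None
        return float(self.params[self.names.index(name)])

    @property
    def alpha(self):
        return self._named("const")

    @property
    def beta(self):
        return self._named("snp")

    @property
    def se_beta(self):
        if "snp" not in self.names:
            return None
        return float(self.bse[self.names.index("snp")])

    @property
    def gamma(self) -> dict:
        return {
            n: float(self.params[i])
            for i, n in enumerate(self.names)
            if n.startswith("course_")
        }

    @property
    def delta(self) -> dict:
        return {
            n: float(self.params[i])
            for i, n in enumerate(self.names)
            if n.startswith("PC")
        }

    @property
    def wald(self):
        if "snp" not in self.names:
            return None
        b, se = self.beta, self.se_beta
        return float(b * b / (se * se))

    @property
    def p_value(self):
        if "snp" not in self.names:
            return None
        return float(stats.chi2.sf(self.wald, 1))

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "wald": (self.params / self.bse) ** 2,
                "p": self.pvalues,
            },
            index=self.names,
        )

    def summary(self) -> str:
        c = self.components
        lines = [
            f"{self.model_name} longitudinal association fit",
            f"  subjects used: {self.n_used}   observations: {self.n_obs}"
            f"   converged: {self.converged}",
            (
                "  components: sigma_u2={:.6g} sigma_v2={:.6g} sigma2={:.6g}"
                .format(c.sigma_u2, c.sigma_v2, c.sigma2)
                + (f" rho={c.rho:.6g}" if c.rho is not None else "")
            ),
            self.params_frame().to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        if "snp" in self.names:
            lines.append(
                f"  SNP Wald chi2(1) = {self.wald:.6g}, p = {self.p_value:.6g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# PC-LMEM


class PCLMEM:
    """Random-intercept linear mixed model with PC covariates.

    Y_ij = alpha + beta x_i + gamma_j + sum_c delta_c PC_ci + v_i + e_ij,
    v_i ~ N(0, sigma_v2), e_ij ~ N(0, sigma2).  Variance components by
    REML (profiled over the ratio sigma_v2/sigma2); fixed effects by GLS
    at the estimated (or supplied) components.
    """

    name = "pc_lmem"

    def __init__(self, pheno, snp=None, pcs=None, n_pcs=3, include_course=True):
        self.design = _build_design(pheno, snp, pcs, n_pcs, include_course)

    # -- REML machinery ----------------------------------------------------

    def _group_sums(self):
        d = self.design
        sx = np.add.reduceat(d.X, d.group_start, axis=0)
        sy = np.add.reduceat(d.y, d.group_start)
        return sx, sy

    def _gls_pieces(self, gamma_ratio):
        """X'Sigma^-1 X, X'Sigma^-1 y, y'Sigma^-1 y, log|Sigma| for
        Sigma_i = I + gamma_ratio * J_{n_i} (per-subject blocks)."""
        d = self.design
        sx, sy = self._sums
        c = gamma_ratio / (1.0 + d.n_per_subject * gamma_ratio)
        xtx = d.X.T @ d.X - (sx * c[:, None]).T @ sx
        xty = d.X.T @ d.y - sx.T @ (c * sy)
        yty = d.y @ d.y - c @ (sy * sy)
        logdet = np.log1p(d.n_per_subject * gamma_ratio).sum()
        return xtx, xty, yty, logdet

    def _reml_neg(self, gamma_ratio):
        d = self.design
        xtx, xty, yty, logdet = self._gls_pieces(gamma_ratio)
        p = d.X.shape[1]
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            return np.inf
        rss = yty - beta @ xty
        if rss <= 0:
            return np.inf
        df = d.n_obs - p
        sign, ld_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        return 0.5 * (df * np.log(rss / df) + logdet + ld_xtx)

    def _fit_components(self) -> VarianceComponents:
        self._sums = self._group_sums()
        obj = lambda t: self._reml_neg(np.exp(t))
        res = optimize.minimize_scalar(
            obj, bounds=(-25.0, 12.0), method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = float(np.exp(res.x))
        if self._reml_neg(0.0) <= res.fun:  # boundary sigma_v2 = 0
            gamma = 0.0
        d = self.design
        xtx, xty, yty, _ = self._gls_pieces(gamma)
        beta = np.linalg.solve(xtx, xty)
        rss = yty - beta @ xty
        sigma2 = max(rss / (d.n_obs - d.X.shape[1]), _VAR_FLOOR)
        return VarianceComponents(
            sigma_u2=0.0,
            sigma_v2=gamma * sigma2,
            sigma2=sigma2,
            d_rho=1.0,
            method=self.name,
        )

    def fit(self, components: VarianceComponents | None = None) -> LongitudinalResults:
        d = self.design
        if components is None:
            vc = self._fit_components()
            reused = False
        else:
            vc = components
            reused = True
            self._sums = self._group_sums()
        gamma = vc.sigma_v2 / vc.sigma2
        xtx, xty, _, _ = self._gls_pieces(gamma)
        params = np.linalg.solve(xtx, xty)
        cov = vc.sigma2 * np.linalg.inv(xtx)
        return LongitudinalResults(
            model_name=self.name,
            names=d.names,
            params=params,
            cov_params=cov,
            components=vc,
            n_used=d.n_used,
            n_obs=d.n_obs,
            converged=True,
            extra={"components_reused": reused},
        )

    def loglike(self, params, components: VarianceComponents) -> float:
        """Dense multivariate-normal log-likelihood at the given fixed
        effects and components (oracle-checkable)."""
        return _dense_loglike_random_intercept(self.design, params, components)


def _dense_loglike_random_intercept(d, params, vc):
    V = np.zeros((d.n_obs, d.n_obs))
    same = d.subj[:, None] == d.subj[None, :]
    V[same] += vc.sigma_v2
    V[np.diag_indices(d.n_obs)] += vc.sigma2
    r = d.y - d.X @ np.asarray(params, dtype=float)
    return _mvn_loglike(r, V)


def _mvn_loglike(r, V):
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    sol = np.linalg.solve(V, r)
    return float(
        -0.5 * (r.size * np.log(2 * np.pi) + logdet + r @ sol)
    )


# ---------------------------------------------------------------------------
# PC-GEE


class PCGEE:
    """Marginal model with exchangeable working correlation and robust
    (sandwich) standard errors.

    The mean structure matches :class:`PCLMEM`; the working correlation
    rho is moment-estimated from Pearson residual cross-products and the
    coefficients iterated to convergence.  Valid only under MCAR
    phenotype missingness.
    """

    name = "pc_gee"

    def __init__(self, pheno, snp=None, pcs=None, n_pcs=3, include_course=True):
        self.design = _build_design(pheno, snp, pcs, n_pcs, include_course)

    def fit(self, max_iter: int = 50, tol: float = 1e-10) -> LongitudinalResults:
        d = self.design
        X, y = d.X, d.y
        p = X.shape[1]
        sx = np.add.reduceat(X, d.group_start, axis=0)
        params = np.linalg.lstsq(X, y, rcond=None)[0]
        rho = 0.0
        fallback = False
        converged = False
        rho_min = -1.0 / max(d.n_per_subject.max() - 1, 1) + 1e-6
        for _ in range(max_iter):
            e = y - X @ params
            phi = (e @ e) / (d.n_obs - p)
            te = np.add.reduceat(e, d.group_start)
            pair_sums = 0.5 * ((te * te) - np.add.reduceat(e * e, d.group_start))
            n_pairs = (d.n_per_subject * (d.n_per_subject - 1) / 2.0).sum()
            denom = n_pairs - p
            if denom <= 0 or phi <= 0:
                rho_new, fallback = 0.0, True
            else:
                rho_new = float(pair_sums.sum() / (denom * phi))
                if not (rho_min < rho_new < 1.0 - 1e-6):
                    fallback = rho_new >= 1.0 - 1e-6 or rho_new <= rho_min
                    rho_new = float(np.clip(rho_new, rho_min, 1.0 - 1e-6))
            c = rho_new / (1.0 + (d.n_per_subject - 1) * rho_new)
            xtrx = (X.T @ X - (sx * c[:, None]).T @ sx) / (1.0 - rho_new)
            xtry = (X.T @ y - sx.T @ (c * np.add.reduceat(y, d.group_start))) / (
                1.0 - rho_new
            )
            new = np.linalg.solve(xtrx, xtry)
            delta = np.max(np.abs(new - params)) / (1.0 + np.max(np.abs(new)))
            params, rho = new, rho_new
            if delta < tol:
                converged = True
                break
        # sandwich covariance at the final (params, rho)
        e = y - X @ params
        phi = (e @ e) / (d.n_obs - p)
        c = rho / (1.0 + (d.n_per_subject - 1) * rho)
        te = np.add.reduceat(e, d.group_start)
        # g_i = X_i' R_i^{-1} e_i = (X_i'e_i - c_i t_i s_i) / (1 - rho)
        xe = np.add.reduceat(X * e[:, None], d.group_start, axis=0)
        g = (xe - sx * (c * te)[:, None]) / (1.0 - rho)
        xtrx = (X.T @ X - (sx * c[:, None]).T @ sx) / (1.0 - rho)
        bread = np.linalg.inv(xtrx)
        meat = g.T @ g
        cov = bread @ meat @ bread
        vc = VarianceComponents(
            sigma_u2=0.0,
            sigma_v2=0.0,
            sigma2=max(float(phi), _VAR_FLOOR),
            rho=float(rho),
            method=self.name,
        )
        if fallback:
            warnings.warn(
                "exchangeable working correlation out of range; clipped "
                "toward independence",
                stacklevel=2,
            )
        return LongitudinalResults(
            model_name=self.name,
            names=d.names,
            params=params,
            cov_params=cov,
            components=vc,
            n_used=d.n_used,
            n_obs=d.n_obs,
            converged=converged,
            extra={"rho_fallback": fallback},
        )


# ---------------------------------------------------------------------------
# KIN-LMEM


def kinship_eigendecomposition(kinship: KinshipMatrix):
    """Eigendecomposition of K, reusable across SNP fits on the same
    subject set."""
    lam, U = np.linalg.eigh(kinship.values)
    return U, np.maximum(lam, 0.0)


def _course_basis(J: int) -> np.ndarray:
    """Orthonormal course basis whose first vector is constant; spans
    the eigenspaces shared by the all-ones matrix and any exchangeable
    D."""
    A = np.column_stack([np.ones(J), np.eye(J)[:, : J - 1]])
    Q, _ = np.linalg.qr(A)
    if Q[0, 0] < 0:
        Q = -Q
    return Q


class KinLMEM:
    """Mixed model with a kinship-structured subject random effect.

    Y_ij = alpha + beta x_i (+ gamma_j) + u_i + v_ij + e_ij with
    cov(u) = sigma_u2 K, cov(v_ij, v_ik) = sigma_v2 D_jk, e iid
    N(0, sigma2).  The course fixed effect is included by default so the
    mean structure matches the competing PC models; pass
    ``include_course=False`` for the bare form.

    With complete phenotype data and an exchangeable D the stacked
    covariance diagonalizes in the product of K's eigenbasis and a
    constant-vector course basis, giving an O(nJ) likelihood per
    evaluation after one n x n eigendecomposition.  Incomplete data fall
    back to a dense multivariate-normal evaluation (small cohorts).
    """

    name = "kin_lmem"

    def __init__(
        self,
        pheno,
        snp=None,
        kinship: KinshipMatrix | None = None,
        d_rho: float = 0.5,
        D: np.ndarray | None = None,
        include_course: bool = True,
        pcs=None,
        n_pcs: int = 0,
        kinship_eig=None,
    ):
        self.design = _build_design(pheno, snp, pcs, n_pcs, include_course)
        d = self.design
        n = pheno.n_subjects
        if kinship is None:
            K = np.eye(n)
        else:
            if kinship.n_subjects != n:
                raise ValueError("kinship dimension must match phenotype")
            K = kinship.values
        self._K = K[np.ix_(d.used_subjects, d.used_subjects)]
        self.d_rho = None if D is not None else float(d_rho)
        self._D = (
            np.asarray(D, dtype=float)
            if D is not None
            else exchangeable_D(d.n_courses, float(d_rho))
        )
        complete = bool(
            d.n_obs == d.n_used * d.n_courses
        )
        self._spectral_ok = complete and D is None
        if self._spectral_ok:
            if (
                kinship_eig is not None
                and d.used_subjects.size == n
                and kinship_eig[0].shape[0] == n
            ):
                self._U, self._lam = kinship_eig
            else:
                self._lam, self._U = np.linalg.eigh(self._K)
                self._lam = np.maximum(self._lam, 0.0)
            self._prepare_spectral()
        else:
            self._prepare_dense()

    # -- spectral path -----------------------------------------------------

    def _prepare_spectral(self):
        d = self.design
        J = d.n_courses
        W = _course_basis(J)
        n_u = d.n_used
        # reshape stacked rows (complete, row-major) into (n, J)
        Ymat = d.y.reshape(n_u, J)
        self._yt = (self._U.T @ Ymat @ W).ravel()
        Xt = np.empty((n_u * J, d.X.shape[1]))
        for c in range(d.X.shape[1]):
            M = d.X[:, c].reshape(n_u, J)
            Xt[:, c] = (self._U.T @ M @ W).ravel()
        self._Xt = Xt
        dv = np.full(J, 1.0 - (self.d_rho or 0.0))
        dv[0] = 1.0 + (J - 1) * (self.d_rho or 0.0)
        self._d_eigs = dv
        # u-term weight per (subject-mode a, course-mode b)
        uw = np.zeros((n_u, J))
        uw[:, 0] = J * self._lam
        self._u_weights = uw.ravel()
        self._v_weights = np.tile(dv, n_u)

    def _spectral_weights(self, su2, sv2, s2):
        return s2 + sv2 * self._v_weights + su2 * self._u_weights

    # -- dense path --------------------------------------------------------

    def _prepare_dense(self):
        d = self.design
        if d.n_obs > 6000:
            raise ValueError(
                "dense covariance path limited to 6000 observations; "
                "complete data with exchangeable D uses the fast path"
            )
        same = d.subj[:, None] == d.subj[None, :]
        self._Vu = self._K[np.ix_(d.subj, d.subj)]
        self._Vv = np.where(same, self._D[np.ix_(d.course, d.course)], 0.0)

    def _dense_V(self, su2, sv2, s2):
        V = su2 * self._Vu + sv2 * self._Vv
        V[np.diag_indices_from(V)] += s2
        return V

    # -- REML --------------------------------------------------------------

    def _reml_neg(self, log_theta):
        su2, sv2, s2 = np.exp(log_theta)
        d = self.design
        X, p = d.X, d.X.shape[1]
        if self._spectral_ok:
            w = self._spectral_weights(su2, sv2, s2)
            if np.any(w <= 0):
                return np.inf
            Xw = self._Xt / w[:, None]
            xtx = self._Xt.T @ Xw
            xty = Xw.T @ self._yt
            logdet = np.log(w).sum()
            quad_y = (self._yt * self._yt / w).sum()
        else:
            V = self._dense_V(su2, sv2, s2)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                try:
                    L = np.linalg.cholesky(V + 1e-8 * np.eye(V.shape[0]))
                except np.linalg.LinAlgError:
                    return np.inf
            from scipy.linalg import solve_triangular

            Xs = solve_triangular(L, d.X, lower=True)
            ys = solve_triangular(L, d.y, lower=True)
            xtx = Xs.T @ Xs
            xty = Xs.T @ ys
            logdet = 2.0 * np.log(np.diag(L)).sum()
            quad_y = ys @ ys
            X = d.X
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            return np.inf
        quad = quad_y - beta @ xty
        sign, ld_xtx = np.linalg.slogdet(xtx)
        if sign <= 0 or quad <= 0:
            return np.inf
        return 0.5 * (logdet + ld_xtx + quad)

    def _fit_components(self) -> VarianceComponents:
        d = self.design
        s_tot = float(np.var(d.y)) or 1.0
        x0 = np.log(np.array([s_tot / 4, s_tot / 4, s_tot / 2]))
        res = optimize.minimize(
            self._reml_neg,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        su2, sv2, s2 = np.exp(res.x)
        floor = _VAR_FLOOR * s_tot
        return VarianceComponents(
            sigma_u2=float(max(su2, 0.0) if su2 > floor else 0.0),
            sigma_v2=float(max(sv2, 0.0) if sv2 > floor else 0.0),
            sigma2=float(max(s2, floor)),
            d_rho=self.d_rho,
            D=self._D if self.d_rho is None else None,
            method=self.name,
        ), bool(res.success)

    def fit(self, components: VarianceComponents | None = None) -> LongitudinalResults:
        d = self.design
        converged = True
        if components is None:
            vc, converged = self._fit_components()
            reused = False
        else:
            vc, reused = components, True
        su2, sv2, s2 = vc.sigma_u2, vc.sigma_v2, vc.sigma2
        if self._spectral_ok:
            w = self._spectral_weights(su2, sv2, s2)
            Xw = self._Xt / w[:, None]
            xtx = self._Xt.T @ Xw
            xty = Xw.T @ self._yt
        else:
            V = self._dense_V(su2, sv2, s2)
            Vi_X = np.linalg.solve(V, d.X)
            xtx = d.X.T @ Vi_X
            xty = Vi_X.T @ d.y
        params = np.linalg.solve(xtx, xty)
        cov = np.linalg.inv(xtx)
        return LongitudinalResults(
            model_name=self.name,
            names=d.names,
            params=params,
            cov_params=cov,
            components=vc,
            n_used=d.n_used,
            n_obs=d.n_obs,
            converged=converged,
            extra={"components_reused": reused, "spectral": self._spectral_ok},
        )

    def loglike(self, params, components: VarianceComponents) -> float:
        """Dense multivariate-normal log-likelihood at the given fixed
        effects and components.  Always evaluated densely so it can serve
        as an independent check of the spectral path."""
        d = self.design
        su2, sv2, s2 = (
            components.sigma_u2,
            components.sigma_v2,
            components.sigma2,
        )
        D = components.D_matrix(d.n_courses) if components.D is not None or \
            components.d_rho is not None else self._D
        same = d.subj[:, None] == d.subj[None, :]
        V = su2 * self._K[np.ix_(d.subj, d.subj)] + sv2 * np.where(
            same, D[np.ix_(d.course, d.course)], 0.0
        )
        V[np.diag_indices_from(V)] += s2
        r = d.y - d.X @ np.asarray(params, dtype=float)
        return _mvn_loglike(r, V)

    def reml_criterion(self, components: VarianceComponents) -> float:
        """-2-free REML log criterion (up to an additive constant) at the
        given components, matching the internal objective."""
        th = np.log(
            np.array(
                [
                    max(components.sigma_u2, _VAR_FLOOR),
                    max(components.sigma_v2, _VAR_FLOOR),
                    components.sigma2,
                ]
            )
        )
        return -self._reml_neg(th)


# ---------------------------------------------------------------------------


def estimate_null_components(
    pheno,
    pcs=None,
    kinship=None,
    model: str = "pc_lmem",
    n_pcs: int = 3,
    include_course: bool = True,
    d_rho: float = 0.5,
) -> VarianceComponents:
    """REML variance components of the covariate-only (no-SNP) model,
    for EMMAX-style reuse across a genome scan."""
    if model == "pc_lmem":
        m = PCLMEM(pheno, None, pcs=pcs, n_pcs=n_pcs, include_course=include_course)
    elif model == "kin_lmem":
        m = KinLMEM(
            pheno,
            None,
            kinship=kinship,
            d_rho=d_rho,
            include_course=include_course,
            pcs=pcs,
            n_pcs=n_pcs,
        )
    else:
        raise ValueError("model must be 'pc_lmem' or 'kin_lmem'")
    res = m.fit()
    if not res.converged:
        raise RuntimeError(
            f"null-model REML did not converge: components={res.components!r}"
        )
    vc = res.components
    vc.method = model + " (null, reusable)"
    return vc
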