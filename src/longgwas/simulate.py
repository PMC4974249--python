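"""Synthetic longitudinal GWAS cohort generator.

Emulates a cohort of unrelated subjects with four repeated chemotherapy
course lengths per subject: genotypes under the Balding-Nichols
population-structure model, log-normal course durations with a subject
genetic random effect (covariance sigma_u2 * K), a course-level random
effect with within-subject correlation structure D, independent
residual noise, and optional MCAR / MAR phenotype missingness.

Default calibration targets an overall median course length of 36 days
with an interquartile range of roughly 32-42 days: on the log scale the
marginal standard deviation tau satisfies IQR_ratio = exp(2 * 0.6745 *
tau), giving tau ~ 0.20, split half into the subject effect and half
into course-level plus residual noise (within-subject correlation 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING_DOSAGE, GenotypeMatrix
from .kinship import KinshipMatrix
from .models import exchangeable_D
from .phenotype import LongitudinalPhenotype

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotype",
    "apply_missingness",
]


@dataclass
class SimConfig:
    """Generator settings; identical config (including seed) yields
    bit-identical output.

    Variance parameters are on the natural-log-days scale: ``sigma_u2``
    (subject genetic effect), ``sigma_v2`` (course-level random effect
    with correlation structure D), ``sigma2`` (residual).  ``snp_effects``
    may be an array of per-SNP betas (log-days per minor allele) or a
    ``{snp_index: beta}`` dict; default all zero (null).
    """

    n_subjects: int = 624
    n_courses: int = 4
    n_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    maf_list: np.ndarray | None = None
    n_subpops: int = 1
    fst: float = 0.0
    baseline_log_duration: float = float(np.log(36.0))
    course_effects: np.ndarray | None = None
    snp_effects: object = None
    sigma_u2: float = 0.020
    sigma_v2: float = 0.008
    sigma2: float = 0.012
    d_rho: float = 0.5
    D: np.ndarray | None = None
    geno_missing_rate: float = 0.0
    missing_mechanism: str = "none"
    missing_params: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be positive")
        if self.n_courses < 2:
            raise ValueError("need at least 2 courses")
        if min(self.sigma_u2, self.sigma_v2, self.sigma2) < 0:
            raise ValueError("variance parameters must be nonnegative")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.n_subpops > 1 and self.fst <= 0:
            raise ValueError("n_subpops > 1 requires fst > 0")
        if self.maf_list is not None:
            self.maf_list = np.asarray(self.maf_list, dtype=float)
            if len(self.maf_list) != self.n_snps:
                raise ValueError("maf_list length must equal n_snps")
            mafs = self.maf_list
        else:
            mafs = np.asarray(self.maf_range, dtype=float)
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if not (0 <= self.geno_missing_rate < 1):
            raise ValueError("geno_missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("none", "MCAR", "MAR"):
            raise ValueError("missing_mechanism must be none, MCAR or MAR")

    def beta_vector(self) -> np.ndarray:
        beta = np.zeros(self.n_snps)
        if self.snp_effects is None:
            return beta
        if isinstance(self.snp_effects, dict):
            for j, b in self.snp_effects.items():
                beta[int(j)] = float(b)
        else:
            arr = np.asarray(self.snp_effects, dtype=float)
            if arr.shape != (self.n_snps,):
                raise ValueError("snp_effects array must have length n_snps")
            beta = arr
        return beta

    def course_effect_vector(self) -> np.ndarray:
        if self.course_effects is None:
            return np.zeros(self.n_courses)
        g = np.asarray(self.course_effects, dtype=float)
        if g.shape != (self.n_courses,):
            raise ValueError("course_effects must have length n_courses")
        return g

    def D_matrix(self) -> np.ndarray:
        if self.D is not None:
            D = np.asarray(self.D, dtype=float)
            if D.shape != (self.n_courses, self.n_courses):
                raise ValueError("D must be n_courses x n_courses")
            return D
        return exchangeable_D(self.n_courses, self.d_rho)


@dataclass
class SimTruth:
    """Realized latent quantities behind one simulated dataset."""

    subpop: np.ndarray | None = None
    ancestral_maf: np.ndarray | None = None
    realized_maf: np.ndarray | None = None
    beta: np.ndarray | None = None
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    eps: np.ndarray | None = None


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(config: SimConfig):
    """Draw a subjects x SNPs dosage panel under Balding-Nichols
    structure.

    Each SNP gets an ancestral MAF p (uniform on ``maf_range`` or from
    ``maf_list``); with ``n_subpops > 1`` each subpopulation draws its
    own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) and genotypes are
    Binomial(2, p_sub).  Returns ``(GenotypeMatrix, SimTruth)``.
    """
    rng = _rng(config, 1)
    n, m, s = config.n_subjects, config.n_snps, config.n_subpops
    if config.maf_list is not None:
        p = config.maf_list.copy()
    else:
        lo, hi = config.maf_range
        p = rng.uniform(lo, hi, size=m)
    subpop = np.arange(n) % s
    if s > 1:
        F = config.fst
        a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
        p_sub = rng.beta(a[None, :], b[None, :], size=(s, m))
        p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
    else:
        p_sub = p[None, :]
    dosage = rng.binomial(2, p_sub[subpop, :]).astype(np.int8)
    if config.geno_missing_rate > 0:
        miss = rng.random(dosage.shape) < config.geno_missing_rate
        dosage[miss] = MISSING_DOSAGE
    g = GenotypeMatrix(dosage)
    truth = SimTruth(
        subpop=subpop,
        ancestral_maf=p,
        realized_maf=g.maf,
        beta=config.beta_vector(),
    )
    return g, truth


def _psd_sqrt(M: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Lower-triangular (or symmetric) square root; Cholesky with a
    diagonal jitter fallback for semidefinite inputs, eigenvalue
    clipping as a last resort."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        pass
    try:
        return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
    except np.linalg.LinAlgError as exc:
        lam, Q = np.linalg.eigh(M)
        if lam.min() < -1e-6 * max(lam.max(), 1.0):
            raise np.linalg.LinAlgError(
                f"matrix is not positive semidefinite (min eigenvalue "
                f"{lam.min():.3g})"
            ) from exc
        return Q * np.sqrt(np.clip(lam, 0.0, None))


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix | None,
    config: SimConfig,
):
    """Generate log course durations.

    Y_ij = alpha + sum_k beta_k x_ik + gamma_j + u_i + v_ij + eps_ij
    with u ~ N(0, sigma_u2 K) (K = identity when ``kinship`` is None),
    per-subject v ~ N(0, sigma_v2 D), eps iid N(0, sigma2).  Returns
    ``(LongitudinalPhenotype, SimTruth)`` with a complete observation
    mask; apply :func:`apply_missingness` afterwards for MCAR/MAR.
    """
    rng = _rng(config, 2)
    n, J = genotypes.n_subjects, config.n_courses
    if kinship is not None and kinship.n_subjects != n:
        raise ValueError("kinship dimension must match genotypes")
    beta = config.beta_vector()
    gamma = config.course_effect_vector()
    x = genotypes.dosage_float()
    if np.isnan(x).any():
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = col_mean[idx[1]]
    genetic = x @ beta
    if config.sigma_u2 > 0:
        if kinship is None:
            u = rng.standard_normal(n) * np.sqrt(config.sigma_u2)
        else:
            L = _psd_sqrt(kinship.values)
            u = np.sqrt(config.sigma_u2) * (L @ rng.standard_normal(n))
    else:
        u = np.zeros(n)
    if config.sigma_v2 > 0:
        LD = _psd_sqrt(config.D_matrix())
        v = np.sqrt(config.sigma_v2) * rng.standard_normal((n, J)) @ LD.T
    else:
        v = np.zeros((n, J))
    eps = (
        rng.standard_normal((n, J)) * np.sqrt(config.sigma2)
        if config.sigma2 > 0
        else np.zeros((n, J))
    )
    Y = (
        config.baseline_log_duration
        + genetic[:, None]
        + gamma[None, :]
        + u[:, None]
        + v
        + eps
    )
    pheno = LongitudinalPhenotype(Y, genotypes.subject_ids)
    truth = SimTruth(beta=beta, u=u, v=v, eps=eps)
    return pheno, truth


def apply_missingness(
    pheno: LongitudinalPhenotype,
    mechanism: str,
    params: dict | None = None,
    seed: int = 0,
) -> LongitudinalPhenotype:
    """Impose a phenotype missingness mechanism.

    MCAR drops each observed cell independently with probability
    ``params['rate']`` (default 0.1).  MAR is monotone logistic dropout:
    starting from course 2, a still-observed subject drops out of course
    j with probability ``expit(intercept + slope * (Y_{i,j-1} -
    center))`` where the centering constant defaults to the mean
    observed first-course outcome, and stays out for all later courses
    — so missingness depends only on observed history.  Observed values
    are never altered; subjects losing all courses are removed.
    """
    from scipy.special import expit

    rng = np.random.default_rng([seed, 3])
    Y = pheno.values.copy()
    n, J = Y.shape
    if mechanism == "none":
        return LongitudinalPhenotype(Y, pheno.subject_ids)
    if mechanism == "MCAR":
        rate = float((params or {}).get("rate", 0.1))
        if not (0 <= rate < 1):
            raise ValueError("MCAR rate must lie in [0, 1)")
        drop = rng.random((n, J)) < rate
        Y[drop] = np.nan
    elif mechanism == "MAR":
        params = params or {}
        intercept = float(params.get("intercept", -1.4))
        slope = float(params.get("slope", 2.0))
        center = params.get("center")
        first = Y[:, 0]
        if not np.isfinite(first).any():
            raise ValueError(
                "MAR dropout requires observed first-course outcomes"
            )
        if center is None:
            center = float(np.nanmean(first))
        dropped = np.zeros(n, dtype=bool)
        for j in range(1, J):
            prev = Y[:, j - 1]
            # subjects already out, or with unobserved previous course,
            # cannot inform dropout off observed history
            at_risk = ~dropped & np.isfinite(prev)
            prob = expit(intercept + slope * (prev[at_risk] - center))
            new_drop = np.zeros(n, dtype=bool)
            new_drop[at_risk] = rng.random(at_risk.sum()) < prob
            dropped |= new_drop
            Y[dropped, j] = np.nan
    else:
        raise ValueError("mechanism must be 'none', 'MCAR' or 'MAR'")
    keep = np.isfinite(Y).any(axis=1)
    return LongitudinalPhenotype(Y[keep], pheno.subject_ids[keep])
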