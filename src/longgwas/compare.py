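"""Between-method evaluation: QQ/genomic-control diagnostics, p-value
concordance, threshold-wise cross-method ROC/AUC, MAF-stratified p-value
bins, and a replicated type-I-error / power harness.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "qq_data",
    "genomic_control",
    "pvalue_correlation",
    "cross_method_roc",
    "maf_stratified_bins",
    "compare_methods",
    "error_rate_harness",
    "MethodComparisonReport",
    "ROC_THRESHOLDS",
    "PVALUE_BINS",
]

# chi-square(1) median; lambda = median(observed chi2) / this
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

ROC_THRESHOLDS = (0.5, 0.1, 0.01, 0.001, 0.0001)

# p-value strata used for the rare-SNP distribution panels
PVALUE_BINS = (
    ("p>0.1", 0.1, 1.0),
    ("0.01<p<=0.1", 0.01, 0.1),
    ("0.001<p<=0.01", 0.001, 0.01),
    ("0.0001<p<=0.001", 0.0001, 0.001),
    ("p<=0.0001", 0.0, 0.0001),
)


def _check_pvalues(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def qq_data(pvalues):
    """Expected-vs-observed -log10 p pairs and the genomic inflation
    factor lambda.

    Returns ``(df, lam)`` where ``df`` has columns ``expected`` and
    ``observed`` (-log10 scale, ascending) and lambda is the median
    observed chi-square(1) statistic divided by the chi-square(1)
    median.
    """
    p = _check_pvalues(pvalues)
    m = p.size
    obs = np.sort(p)
    exp = (np.arange(1, m + 1) - 0.5) / m
    df = pd.DataFrame(
        {"expected": -np.log10(exp), "observed": -np.log10(obs)}
    )
    lam = float(np.median(stats.chi2.isf(p, 1)) / CHI2_1_MEDIAN)
    return df, lam


def genomic_control(pvalues, lam: float):
    """Deflate inflated association statistics by lambda.

    Each p-value is converted to its chi-square(1) statistic, divided by
    lambda, and converted back.  With lambda <= 1 the input is returned
    unchanged (no anti-deflation); the transform is monotone, so p-value
    ranks are preserved.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p = _check_pvalues(pvalues)
    if lam <= 1.0:
        return p.copy()
    chi = stats.chi2.isf(p, 1) / lam
    return stats.chi2.sf(chi, 1)


def pvalue_correlation(p_a, p_b) -> dict:
    """Pearson concordance of two methods' p-values on the same SNPs.

    Returns r and r^2 on the raw scale (primary) and on the -log10
    scale.
    """
    p_a, p_b = _check_pvalues(p_a), _check_pvalues(p_b)
    if p_a.size != p_b.size:
        raise ValueError("p-value vectors must cover the same SNP set")
    if p_a.size < 3:
        raise ValueError("need at least 3 shared SNPs")
    r = float(stats.pearsonr(p_a, p_b).statistic)
    r_log = float(stats.pearsonr(-np.log10(p_a), -np.log10(p_b)).statistic)
    return {"r": r, "r2": r * r, "r_log10": r_log, "r2_log10": r_log * r_log}


@dataclass
class ROCResult:
    auc: float
    threshold: float
    n_pos: int
    n_neg: int
    points: pd.DataFrame = field(repr=False, default=None)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.auc)


def cross_method_roc(p_scores, p_labels, threshold: float) -> ROCResult:
    """How well one method's evidence predicts another's sub-threshold
    calls.

    Labels are ``p_labels < threshold``; scores are ``-log10(p_scores)``.
    AUC uses the Mann-Whitney identity with midranks for ties; the ROC
    points (fpr, tpr) are returned for plotting.  Degenerate labels (all
    positive or all negative) yield ``auc = nan`` rather than an error.
    """
    p_scores, p_labels = _check_pvalues(p_scores), _check_pvalues(p_labels)
    if p_scores.size != p_labels.size:
        raise ValueError("score and label vectors must match")
    labels = p_labels < threshold
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    scores = -np.log10(p_scores)
    if n_pos == 0 or n_neg == 0:
        return ROCResult(np.nan, threshold, n_pos, n_neg, pd.DataFrame())
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "score_threshold": thr})
    return ROCResult(auc, threshold, n_pos, n_neg, points)


def maf_stratified_bins(pvalues, maf, rare_cutoff: float = 0.05) -> pd.DataFrame:
    """Fraction of rare SNPs (MAF < cutoff) in each p-value stratum.

    The strata partition (0, 1], so the per-bin counts sum to the panel
    size.
    """
    p = _check_pvalues(pvalues)
    maf = np.asarray(maf, dtype=float)
    if maf.shape != p.shape:
        raise ValueError("maf must align with p-values")
    rare = maf < rare_cutoff
    rows = []
    for name, lo, hi in PVALUE_BINS:
        inbin = (p > lo) & (p <= hi)
        n = int(inbin.sum())
        nr = int((inbin & rare).sum())
        rows.append(
            {
                "bin": name,
                "n_snps": n,
                "n_rare": nr,
                "rare_fraction": nr / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MethodComparisonReport:
    """Aggregate between-method comparison.

    ``lambdas``: per-method genomic inflation; ``correlations``: pairwise
    Pearson r / r^2 of p-values; ``auc``: rows (predictor, target,
    threshold, auc); ``rare_bins``: per-method MAF-stratified p-value
    bins.
    """

    lambdas: dict
    correlations: pd.DataFrame
    auc: pd.DataFrame
    rare_bins: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambdas": self.lambdas,
                "correlations": self.correlations.to_dict(orient="records"),
                "auc": self.auc.to_dict(orient="records"),
                "rare_bins": {
                    k: v.to_dict(orient="records")
                    for k, v in self.rare_bins.items()
                },
            },
            indent=2,
        )


def compare_methods(
    results: dict,
    maf=None,
    thresholds=ROC_THRESHOLDS,
    rare_cutoff: float = 0.05,
) -> MethodComparisonReport:
    """Build the full comparison report from per-method result tables.

    ``results`` maps method name to a scan DataFrame (needs columns
    ``p`` and, if ``maf`` is not given, ``maf``); only SNPs converged in
    every method enter the comparison.
    """
    names = list(results)
    ok = None
    for df in results.values():
        conv = df["converged"].to_numpy() & np.isfinite(df["p"].to_numpy())
        ok = conv if ok is None else (ok & conv)
    pvals = {k: df["p"].to_numpy()[ok] for k, df in results.items()}
    if maf is None:
        maf = next(iter(results.values()))["maf"].to_numpy()
    maf = np.asarray(maf)[ok]
    lambdas = {k: qq_data(v)[1] for k, v in pvals.items()}
    corr_rows = []
    for a, b in itertools.combinations(names, 2):
        c = pvalue_correlation(pvals[a], pvals[b])
        corr_rows.append({"method_a": a, "method_b": b, **c})
    auc_rows = []
    for a, b in itertools.permutations(names, 2):
        for t in thresholds:
            roc = cross_method_roc(pvals[a], pvals[b], t)
            auc_rows.append(
                {
                    "predictor": a,
                    "target": b,
                    "threshold": t,
                    "auc": roc.auc,
                    "n_pos": roc.n_pos,
                    "n_neg": roc.n_neg,
                }
            )
    bins = {
        k: maf_stratified_bins(v, maf, rare_cutoff) for k, v in pvals.items()
    }
    return MethodComparisonReport(
        lambdas=lambdas,
        correlations=pd.DataFrame(corr_rows),
        auc=pd.DataFrame(auc_rows),
        rare_bins=bins,
    )


def error_rate_harness(
    grid,
    methods,
    alphas,
    n_reps: int,
    seed: int,
    n_subjects: int = 600,
    n_courses: int = 4,
    base_config: dict | None = None,
) -> pd.DataFrame:
    """Replicated empirical type-I error / power over a simulation grid.

    ``grid`` is an iterable of dicts with keys ``maf`` and ``beta``
    (plus optional SimConfig overrides).  For null cells (beta == 0) each
    replicate simulates one phenotype and ``n_snps`` independent null
    SNPs, all of which count as SNP-replicates; for power cells each
    replicate simulates a single causal SNP.  Rejection is ``p <= alpha``;
    95% Wilson intervals accompany each rate.
    """
    from statsmodels.stats.proportion import proportion_confint

    from .models import PCGEE, PCLMEM, KinLMEM
    from .simulate import SimConfig, simulate_genotypes, simulate_phenotype

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    rng_root = np.random.SeedSequence(seed)
    for cell_i, cell in enumerate(grid):
        cell = dict(cell)
        maf = cell.pop("maf")
        beta = cell.pop("beta")
        n_snps = cell.pop("n_snps", 1 if beta != 0 else 50)
        if beta != 0:
            n_snps = 1
        overrides = dict(base_config or {})
        overrides.update(cell)
        pvals = {m: [] for m in methods}
        for rep in range(n_reps):
            sub = np.random.SeedSequence([seed, cell_i, rep]).generate_state(1)[0]
            cfg = SimConfig(
                n_subjects=n_subjects,
                n_courses=n_courses,
                n_snps=n_snps,
                maf_range=(maf, maf),
                snp_effects=np.full(n_snps, beta),
                seed=int(sub % (2**31 - 1)),
                **overrides,
            )
            g, _ = simulate_genotypes(cfg)
            pheno, _ = simulate_phenotype(g, None, cfg)
            dos = g.dosage_float()
            for m in methods:
                for j in range(n_snps):
                    try:
                        if m == "pc_lmem":
                            res = PCLMEM(pheno, dos[:, j], n_pcs=0).fit()
                        elif m == "pc_gee":
                            res = PCGEE(pheno, dos[:, j], n_pcs=0).fit()
                        elif m == "kin_lmem":
                            res = KinLMEM(pheno, dos[:, j]).fit()
                        else:
                            raise ValueError(f"unknown method {m!r}")
                    except Exception:
                        continue
                    if res.converged and res.p_value is not None:
                        pvals[m].append(res.p_value)
        for m in methods:
            p = np.asarray(pvals[m])
            for a in alphas:
                n_rej = int((p <= a).sum())
                lo, hi = proportion_confint(n_rej, p.size, method="wilson")
                rows.append(
                    {
                        "maf": maf,
                        "beta": beta,
                        "method": m,
                        "alpha": a,
                        "n_tests": p.size,
                        "n_reject": n_rej,
                        "rate": n_rej / p.size if p.size else np.nan,
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                    }
                )
    return pd.DataFrame(rows)
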