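"""Genome-wide per-SNP scan driver.

Runs one of the three longitudinal engines over every SNP of a genotype
panel and returns a tidy results table.  The default scan mode estimates
the variance components once from the covariate-only null model and
reuses them for every SNP's GLS test (the standard mixed-model-GWAS
approximation); ``mode='exact'`` refits components per SNP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .models import (
    KinLMEM,
    MonomorphicSNPError,
    PCGEE,
    PCLMEM,
    estimate_null_components,
    kinship_eigendecomposition,
)
from .phenotype import LongitudinalPhenotype

__all__ = ["run_gwas", "METHODS"]

METHODS = ("pc_lmem", "pc_gee", "kin_lmem")

RESULT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "maf",
    "beta",
    "se",
    "wald",
    "p",
    "n_used",
    "converged",
    "method",
]


def _align(genotypes: GenotypeMatrix, pheno: LongitudinalPhenotype):
    gid = list(genotypes.subject_ids)
    pid = list(pheno.subject_ids)
    if gid == pid:
        return genotypes, pheno
    common = [s for s in pid if s in set(gid)]
    if not common:
        raise ValueError("no shared subjects between genotypes and phenotype")
    gpos = {s: i for i, s in enumerate(gid)}
    ppos = {s: i for i, s in enumerate(pid)}
    g_idx = np.array([gpos[s] for s in common])
    p_idx = np.array([ppos[s] for s in common])
    return (
        genotypes.select_subjects(g_idx),
        LongitudinalPhenotype(pheno.values[p_idx], pheno.subject_ids[p_idx]),
    )


def run_gwas(
    genotypes: GenotypeMatrix,
    pheno: LongitudinalPhenotype,
    method: str,
    pcs=None,
    kinship=None,
    n_pcs: int = 3,
    mode: str = "approx",
    d_rho: float = 0.5,
    include_course: bool = True,
    components=None,
) -> pd.DataFrame:
    """Scan every SNP with the chosen method.

    Parameters
    ----------
    method : {'pc_lmem', 'pc_gee', 'kin_lmem'}
    mode : {'approx', 'exact'}
        'approx' reuses null-model variance components across SNPs
        (ignored for the GEE, which is refit per SNP either way).
    components : VarianceComponents, optional
        Precomputed null components; overrides the internal null fit.

    Returns a DataFrame with one row per input SNP, columns
    ``snp_id chrom pos maf beta se wald p n_used converged method``.
    Non-converged or monomorphic fits keep their row with NaN statistics
    and ``converged=False``.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if mode not in ("approx", "exact"):
        raise ValueError("mode must be 'approx' or 'exact'")
    if genotypes.n_snps == 0:
        raise ValueError("no SNPs to scan")
    genotypes, pheno = _align(genotypes, pheno)
    if pcs is not None and pcs.scores.shape[0] != pheno.n_subjects:
        raise ValueError("PC scores do not match the aligned subject set")

    vc = components
    kin_eig = None
    if method in ("pc_lmem", "kin_lmem") and mode == "approx" and vc is None:
        vc = estimate_null_components(
            pheno,
            pcs=pcs,
            kinship=kinship,
            model=method,
            n_pcs=n_pcs,
            include_course=include_course,
            d_rho=d_rho,
        )
    if method == "kin_lmem" and kinship is not None:
        kin_eig = kinship_eigendecomposition(kinship)

    dosage = genotypes.dosage_float()
    maf = genotypes.maf
    rows = []
    for j in range(genotypes.n_snps):
        snp = dosage[:, j]
        meta = genotypes.snp_meta.iloc[j]
        row = {
            "snp_id": meta["id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "maf": maf[j],
            "beta": np.nan,
            "se": np.nan,
            "wald": np.nan,
            "p": np.nan,
            "n_used": 0,
            "converged": False,
            "method": method,
        }
        try:
            if method == "pc_lmem":
                m = PCLMEM(pheno, snp, pcs=pcs, n_pcs=n_pcs,
                           include_course=include_course)
                res = m.fit(components=vc if mode == "approx" else None)
            elif method == "pc_gee":
                m = PCGEE(pheno, snp, pcs=pcs, n_pcs=n_pcs,
                          include_course=include_course)
                res = m.fit()
            else:
                m = KinLMEM(
                    pheno,
                    snp,
                    kinship=kinship,
                    d_rho=d_rho,
                    include_course=include_course,
                    pcs=pcs,
                    n_pcs=n_pcs,
                    kinship_eig=kin_eig,
                )
                res = m.fit(components=vc if mode == "approx" else None)
        except MonomorphicSNPError:
            rows.append(row)
            continue
        row["n_used"] = res.n_used
        row["converged"] = bool(res.converged)
        if res.converged:
            row.update(
                beta=res.beta, se=res.se_beta, wald=res.wald, p=res.p_value
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
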