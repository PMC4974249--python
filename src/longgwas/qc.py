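"""Per-SNP genotype quality control.

Filters follow standard GWAS practice: SNPs are removed when the call
rate is below 95%, the minor allele frequency is below 1% (which removes
monomorphic SNPs), or an exact Hardy-Weinberg equilibrium test rejects
at p < 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING_DOSAGE, GenotypeMatrix

__all__ = ["QCReport", "snp_qc", "hwe_test", "hwe_test_matrix"]


@dataclass
class QCReport:
    """Counts of SNPs failing each filter (overlapping and union)."""

    n_input: int
    n_retained: int
    fail_call_rate: int
    fail_maf: int
    fail_hwe: int
    fail_multiple: int
    fail_any: int

    def __str__(self):
        return (
            f"SNP QC: {self.n_input} in, {self.n_retained} retained "
            f"(call-rate fails {self.fail_call_rate}, MAF fails "
            f"{self.fail_maf}, HWE fails {self.fail_hwe}; "
            f"{self.fail_multiple} failed more than one rule, "
            f"union {self.fail_any})"
        )


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg equilibrium test for one biallelic SNP.

    Computes the exact conditional p-value: the probability, under HWE
    and conditional on the observed allele counts, of a heterozygote
    count as or less probable than the one observed (Wigginton-style
    enumeration over all heterozygote counts of matching parity).

    Returns a p-value in (0, 1].
    """
    counts = (int(n_aa), int(n_ab), int(n_bb))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("zero genotype total")
    n_aa, n_ab, n_bb = counts
    # rare-allele homozygote orientation is immaterial; enumerate over het
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    # het counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    # unnormalized log-probabilities of the conditional het distribution:
    # P(het) proportional to n! / (aa! het! bb!) * 2^het  with
    # aa = (n_rare - het)/2, bb = n - aa - het
    from scipy.special import gammaln

    aa = (n_rare - hets) // 2
    bb = n - aa - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(aa + 1)
        - gammaln(hets + 1)
        - gammaln(bb + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_ab]
    if obs.size == 0:  # inconsistent parity cannot happen for valid counts
        raise ValueError("heterozygote count inconsistent with allele total")
    # small relative slack guards equal-probability ties against rounding
    p = prob[prob <= obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_test_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value for every SNP in a genotype matrix."""
    out = np.empty(g.n_snps)
    d = g.dosage
    for j in range(g.n_snps):
        col = d[:, j]
        col = col[col != MISSING_DOSAGE]
        n_bb = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 2).sum())
        if n_aa + n_ab + n_bb == 0:
            out[j] = 1.0
        else:
            out[j] = hwe_test(n_aa, n_ab, n_bb)
    return out


def snp_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
):
    """Apply the three per-SNP filters; returns (filtered matrix, QCReport).

    A SNP is removed when its call rate is strictly below ``call_rate_min``,
    its MAF strictly below ``maf_min``, or its exact HWE p-value strictly
    below ``hwe_p_min``.
    """
    for name, t in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                    ("hwe_p_min", hwe_p_min)):
        if not (0 < t <= 1):
            raise ValueError(f"{name} must be in (0, 1]")
    fail_cr = g.call_rate < call_rate_min
    fail_maf = g.maf < maf_min
    fail_hwe = hwe_test_matrix(g) < hwe_p_min
    n_fail = fail_cr.astype(int) + fail_maf.astype(int) + fail_hwe.astype(int)
    fail_any = n_fail > 0
    report = QCReport(
        n_input=g.n_snps,
        n_retained=int((~fail_any).sum()),
        fail_call_rate=int(fail_cr.sum()),
        fail_maf=int(fail_maf.sum()),
        fail_hwe=int(fail_hwe.sum()),
        fail_multiple=int((n_fail > 1).sum()),
        fail_any=int(fail_any.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("all SNPs removed by QC; no panel left to analyze")
    return g.select_snps(np.flatnonzero(~fail_any)), report
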