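"""Genotype dosage container.

Dosages count copies of the minor (A1) allele, stored as int8 with -1 for
missing.  SNP metadata follows the BIM column convention (1-based
positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "MISSING_DOSAGE"]

MISSING_DOSAGE = -1


def _default_meta(m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": np.ones(m, dtype=int),
            "id": [f"snp{j+1}" for j in range(m)],
            "pos": np.arange(1, m + 1, dtype=int),
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix.

    Parameters
    ----------
    dosage : ndarray (n, m), int8
        Values in {0, 1, 2}; -1 codes a missing genotype.
    snp_meta : DataFrame with columns chrom, id, pos, a1, a2
    subject_ids : ndarray of str
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame = field(default=None)
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (subjects x SNPs)")
        n, m = self.dosage.shape
        if n == 0 or m == 0:
            raise ValueError("genotype matrix needs >=1 subject and >=1 SNP")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING_DOSAGE))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        if self.snp_meta is None:
            self.snp_meta = _default_meta(m)
        else:
            self.snp_meta = self.snp_meta.reset_index(drop=True)
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length mismatch")
        if self.subject_ids is None:
            self.subject_ids = np.array(
                [f"S{i+1}" for i in range(n)], dtype=object
            )
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing."""
        x = self.dosage.astype(float)
        x[self.dosage == MISSING_DOSAGE] = np.nan
        return x

    @property
    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        return 1.0 - (self.dosage == MISSING_DOSAGE).mean(axis=0)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-SNP sample frequency of the coded (A1) allele."""
        x = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def oriented_to_minor(self) -> "GenotypeMatrix":
        """Flip SNPs whose coded-allele frequency exceeds 0.5.

        After orientation the dosage counts the minor allele, so MAF equals
        the coded-allele frequency by construction.
        """
        p = self.allele_freq
        flip = p > 0.5
        if not flip.any():
            return self
        dosage = self.dosage.copy()
        cols = dosage[:, flip]
        miss = cols == MISSING_DOSAGE
        cols = (2 - cols).astype(np.int8)
        cols[miss] = MISSING_DOSAGE
        dosage[:, flip] = cols
        meta = self.snp_meta.copy()
        a1 = meta["a1"].to_numpy().copy()
        a2 = meta["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip], a1[flip].copy()
        meta["a1"], meta["a2"] = a1, a2
        return GenotypeMatrix(dosage, meta, self.subject_ids)

    def standardized(self) -> np.ndarray:
        """Mean-imputed, HWE-standardized dosage matrix.

        Column j is centered at 2 p_j and scaled by sqrt(2 p_j (1-p_j))
        using the sample allele frequency p_j; missing genotypes become 0
        after centering (mean imputation).  Monomorphic SNPs yield
        all-zero columns.
        """
        x = self.dosage_float()
        p = self.allele_freq
        x = x - 2.0 * p
        x[~np.isfinite(x)] = 0.0
        denom = np.sqrt(2.0 * p * (1.0 - p))
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(denom > 0, x / denom, 0.0)
        return x

    def select_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosage[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            self.subject_ids,
        )

    def select_subjects(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosage[index, :], self.snp_meta, self.subject_ids[index]
        )
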