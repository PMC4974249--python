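"""PLINK 1 binary genotype (.bed/.bim/.fam) reader and writer.

SNP-major .bed layout: three magic bytes 0x6c 0x1b 0x01, then for each
SNP ceil(n/4) bytes holding 2-bit genotype codes, sample order running
from the least-significant bit pair:

    00 = homozygous A1 (dosage 2)    01 = missing
    10 = heterozygous  (dosage 1)    11 = homozygous A2 (dosage 0)

A1 is conventionally the minor allele, so the decoded dosage counts
minor alleles; positions are 1-based as in the BIM.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import MISSING_DOSAGE, GenotypeMatrix

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage and inverse
_CODE_TO_DOSAGE = np.array([2, MISSING_DOSAGE, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = np.zeros(4, dtype=np.uint8)
_DOSAGE_TO_CODE[(MISSING_DOSAGE + 1, 0 + 1, 1 + 1, 2 + 1),] = (0b01, 0b11, 0b10, 0b00)

BIM_COLUMNS = ["chrom", "id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a genotype matrix as a .bed/.bim/.fam triplet."""
    prefix = str(prefix)
    n, m = g.n_subjects, g.n_snps
    codes = _DOSAGE_TO_CODE[g.dosage.astype(np.int16) + 1]  # (n, m)
    n_pad = (-n) % 4
    if n_pad:
        # pad with homozygous A2 (code 0b11 is ignored on read)
        codes = np.vstack([codes, np.full((n_pad, m), 0b11, dtype=np.uint8)])
    quads = codes.T.reshape(m, -1, 4)  # SNP-major
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": g.snp_meta["chrom"],
            "id": g.snp_meta["id"],
            "cm": 0,
            "pos": g.snp_meta["pos"],
            "a1": g.snp_meta["a1"],
            "a2": g.snp_meta["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.subject_ids,
            "iid": g.subject_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_plink(prefix, orient: str = "none") -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triplet.

    ``orient='minor'`` flips any SNP whose coded-allele frequency
    exceeds 0.5 so dosages count the observed minor allele;
    ``orient='none'`` (default) preserves the file's A1 coding exactly,
    which keeps write-then-read round trips bit-identical.
    """
    prefix = str(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing PLINK file: {prefix + ext}")
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None, names=BIM_COLUMNS,
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None, names=FAM_COLUMNS,
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _MAGIC:
        raise ValueError(
            f"{prefix + '.bed'}: bad magic bytes {raw[:3]!r} "
            "(expected 0x6c 0x1b 0x01, SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + m * bytes_per_snp
    if len(raw) != expected:
        raise ValueError(
            f"{prefix + '.bed'}: size {len(raw)} does not match "
            f"{n} samples x {m} SNPs (expected {expected} bytes)"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(
        m, bytes_per_snp
    )
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)
    meta = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "id": bim["id"],
            "pos": bim["pos"].astype(int),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    g = GenotypeMatrix(dosage, meta, fam["iid"].to_numpy(dtype=object))
    if orient == "minor":
        g = g.oriented_to_minor()
    elif orient != "none":
        raise ValueError("orient must be 'none' or 'minor'")
    return g
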