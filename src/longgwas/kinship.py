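"""Genetic relationship matrix (GRM) estimation and relatedness pruning.

The kinship estimate for subjects i, l is the standard GRM

    K_il = (1/m) * sum_j (x_ij - 2 p_j)(x_lj - 2 p_j) / (2 p_j (1 - p_j)),

using sample allele frequencies p_j; under HWE the diagonal is ~1 in
expectation.  Missing dosages are mean-imputed per SNP for this
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "compute_kinship",
    "detect_related",
    "read_kinship",
    "write_kinship",
]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    subject_ids: np.ndarray = field(default=None)
    estimator: str = "grm"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric (atol 1e-12)")
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
        return self.values.shape[0]

    def select_subjects(self, index) -> "KinshipMatrix":
        index = np.asarray(index)
        return KinshipMatrix(
            self.values[np.ix_(index, index)],
            self.subject_ids[index],
            self.estimator,
        )

    @classmethod
    def identity(cls, subject_ids) -> "KinshipMatrix":
        subject_ids = np.asarray(subject_ids, dtype=object)
        return cls(np.eye(len(subject_ids)), subject_ids, estimator="identity")


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Estimate the GRM from standardized dosages.

    Monomorphic SNPs are excluded (their standardization would divide by
    zero) with a warning.
    """
    if g.n_subjects < 2:
        raise ValueError("kinship needs at least 2 subjects")
    maf = g.maf
    poly = maf > 0
    if poly.sum() == 0:
        raise ValueError("no polymorphic SNPs; cannot estimate kinship")
    if (~poly).any():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNPs from the GRM",
            stacklevel=2,
        )
        g = g.select_snps(np.flatnonzero(poly))
    z = g.standardized()
    k = (z @ z.T) / g.n_snps
    k = (k + k.T) / 2.0  # enforce exact symmetry
    return KinshipMatrix(k, g.subject_ids, estimator="grm")


def detect_related(k: KinshipMatrix, threshold: float = 0.125) -> list:
    """Greedily select subjects to exclude so no pair exceeds ``threshold``.

    While any off-diagonal kinship exceeds the threshold, the subject
    with the most super-threshold partners is dropped; ties break toward
    the larger off-diagonal row sum, then the lexicographically smaller
    subject id.  The default 0.125 corresponds to third-degree
    relatives.

    Returns the list of excluded subject ids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = k.values.copy()
    np.fill_diagonal(v, 0.0)
    active = np.ones(k.n_subjects, dtype=bool)
    excluded = []
    ids = k.subject_ids
    while True:
        over = (v > threshold) & active[:, None] & active[None, :]
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        best = np.flatnonzero(counts == counts.max())
        if len(best) > 1:
            rowsums = np.where(active[None, :], np.abs(v), 0.0).sum(axis=1)[best]
            best = best[rowsums == rowsums.max()]
        if len(best) > 1:
            order = np.argsort([str(ids[i]) for i in best])
            best = best[order[:1]]
        drop = int(best[0])
        active[drop] = False
        excluded.append(ids[drop])
    return excluded


def write_kinship(k: KinshipMatrix, path_prefix) -> None:
    """Write the lower triangle (row-major, diagonal included) plus an
    ``.id`` sidecar listing subject ids."""
    prefix = str(path_prefix)
    with open(prefix + ".kin", "w") as fh:
        for i in range(k.n_subjects):
            fh.write(
                " ".join(f"{k.values[i, j]:.10g}" for j in range(i + 1)) + "\n"
            )
    pd.Series(k.subject_ids).to_csv(prefix + ".kin.id", index=False, header=False)


def read_kinship(path_prefix) -> KinshipMatrix:
    prefix = str(path_prefix)
    ids = pd.read_csv(prefix + ".kin.id", header=None)[0].astype(str).to_numpy()
    n = len(ids)
    v = np.zeros((n, n))
    with open(prefix + ".kin") as fh:
        for i, line in enumerate(fh):
            row = [float(t) for t in line.split()]
            if len(row) != i + 1:
                raise ValueError(
                    f"kinship row {i} has {len(row)} entries, expected {i + 1}"
                )
            v[i, : i + 1] = row
    v = v + np.tril(v, -1).T
    return KinshipMatrix(v, ids)
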