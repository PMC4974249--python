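"""Principal components of the standardized genotype matrix for ancestry
adjustment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["PrincipalComponents", "compute_pcs"]


@dataclass
class PrincipalComponents:
    """Subject scores on the top-k genotype principal axes.

    ``scores`` is n x k with columns ordered by decreasing eigenvalue of
    the GRM (equivalently of the standardized genotype covariance);
    column c equals sqrt(eigenvalue_c) times the c-th GRM eigenvector.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if self.scores.shape[1] != len(self.eigenvalues):
            raise ValueError("eigenvalues length must match score columns")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        if self.subject_ids is None:
            self.subject_ids = np.array(
                [f"S{i+1}" for i in range(self.scores.shape[0])], dtype=object
            )
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def select_subjects(self, index) -> "PrincipalComponents":
        index = np.asarray(index)
        return PrincipalComponents(
            self.scores[index], self.eigenvalues, self.subject_ids[index]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{c+1}" for c in range(self.k)]
        )
        df.insert(0, "subject_id", self.subject_ids)
        return df


def compute_pcs(g: GenotypeMatrix, k: int) -> PrincipalComponents:
    """Top-k principal component scores of the standardized genotypes.

    SNPs are centered at 2p and scaled by sqrt(2p(1-p)) (missing -> 0
    after centering); scores come from the SVD of that matrix divided by
    sqrt(m), so the reported eigenvalues are those of the GRM.  Signs
    are fixed by making each score column's largest-magnitude entry
    positive, which renders the decomposition deterministic.
    """
    n, m = g.n_subjects, g.n_snps
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_subjects, n_snps)={min(n, m)}")
    z = g.standardized() / np.sqrt(m)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    eigenvalues = s[:k] ** 2
    for c in range(k):
        col = scores[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, c] = -col
    return PrincipalComponents(scores, eigenvalues, g.subject_ids)
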