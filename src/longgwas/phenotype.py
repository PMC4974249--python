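"""Longitudinal phenotype container and course-length quality control.

The outcome is the log-transformed length (in days) of each of J repeated
chemotherapy courses per subject.  Values are stored as an ``n_subjects x
n_courses`` array with NaN marking unobserved cells; course labels are
1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalPhenotype",
    "apply_course_qc",
    "read_phenotype_long",
    "write_phenotype_long",
    "COURSE_MIN_DAYS",
    "COURSE_MAX_DAYS",
]

# Course lengths outside [20, 100] days are treated as data errors
# (relapse, censoring, recording problems) and set to missing.
COURSE_MIN_DAYS = 20.0
COURSE_MAX_DAYS = 100.0

# Relative tolerance so that exp(log(20)) survives a second QC pass.
_QC_RTOL = 1e-9


@dataclass
class LongitudinalPhenotype:
    """Log-duration outcomes ``Y_ij`` for subjects i and courses j.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_courses)
        Natural-log course durations; NaN where missing.
    subject_ids : ndarray of str
    """

    values: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x courses)")
        if self.values.shape[1] < 2:
            raise ValueError("at least 2 courses are required")
        if self.subject_ids is None:
            self.subject_ids = np.array(
                [f"S{i+1}" for i in range(self.values.shape[0])]
            )
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")
        obs = np.isfinite(self.values)
        if np.any(np.isinf(self.values)):
            raise ValueError("observed outcomes must be finite")
        if obs.size and not obs.any(axis=1).all():
            # retained subjects must have >= 1 observed course
            bad = self.subject_ids[~obs.any(axis=1)]
            raise ValueError(
                f"subjects with no observed course: {list(bad[:5])!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_courses(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean observed-cell mask."""
        return np.isfinite(self.values)

    @property
    def course_labels(self) -> np.ndarray:
        return np.arange(1, self.n_courses + 1)

    def durations_days(self) -> np.ndarray:
        """Back-transform to the day scale (NaN preserved)."""
        return np.exp(self.values)

    def drop_empty_subjects(self) -> "LongitudinalPhenotype":
        keep = np.isfinite(self.values).any(axis=1)
        return LongitudinalPhenotype(self.values[keep], self.subject_ids[keep])


def _qc_mask_days(days: np.ndarray) -> np.ndarray:
    """True where a duration passes the [20, 100]-day filter (inclusive)."""
    days = np.asarray(days, dtype=float)
    lo = COURSE_MIN_DAYS * (1.0 - _QC_RTOL)
    hi = COURSE_MAX_DAYS * (1.0 + _QC_RTOL)
    with np.errstate(invalid="ignore"):
        return np.isfinite(days) & (days >= lo) & (days <= hi)


def apply_course_qc(durations, subject_ids=None) -> LongitudinalPhenotype:
    """Mask implausible course lengths and log-transform the remainder.

    Durations below 20 or above 100 days are set to missing (the bounds
    themselves are retained); surviving values are natural-log
    transformed.  Idempotent: feeding a :class:`LongitudinalPhenotype`
    back in reproduces it.

    Parameters
    ----------
    durations : ndarray (n, J) of days, or LongitudinalPhenotype
        NaN marks already-missing cells.  Non-missing values must be
        positive (a non-positive duration cannot be log-transformed and
        indicates corrupted input).
    """
    if isinstance(durations, LongitudinalPhenotype):
        if subject_ids is None:
            subject_ids = durations.subject_ids
        durations = durations.durations_days()
    days = np.asarray(durations, dtype=float)
    if days.ndim != 2:
        raise ValueError("durations must be 2-D (subjects x courses)")
    observed = np.isfinite(days)
    if np.any(days[observed] <= 0):
        raise ValueError("non-positive course durations cannot be log-transformed")
    keep = _qc_mask_days(days)
    y = np.full(days.shape, np.nan)
    y[keep] = np.log(days[keep])
    pheno = LongitudinalPhenotype.__new__(LongitudinalPhenotype)
    # bypass the no-empty-subject check until after dropping
    pheno.values = y
    pheno.subject_ids = (
        np.asarray(subject_ids, dtype=object)
        if subject_ids is not None
        else np.array([f"S{i+1}" for i in range(days.shape[0])], dtype=object)
    )
    keep_subj = keep.any(axis=1)
    return LongitudinalPhenotype(y[keep_subj], pheno.subject_ids[keep_subj])


def read_phenotype_long(path_or_buf, n_courses: int | None = None) -> LongitudinalPhenotype:
    """Read a long-format phenotype table into a :class:`LongitudinalPhenotype`.

    Expects a tab-separated table with header ``subject_id course
    duration_days`` or, alternatively, ``subject_id course start_date
    end_date`` with ISO-8601 dates, in which case the duration is the day
    difference end - start.  Durations pass through :func:`apply_course_qc`
    (and are therefore log-transformed); subjects left with no valid
    course are dropped.
    """
    try:
        df = pd.read_csv(path_or_buf, sep="\t", dtype={"subject_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty phenotype file: {path_or_buf!r}") from exc
    if df.empty:
        raise ValueError(f"phenotype file has no data rows: {path_or_buf!r}")
    required = {"subject_id", "course"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"phenotype header must contain {sorted(required)}; got {list(df.columns)}"
        )
    if "duration_days" in df.columns:
        dur = pd.to_numeric(df["duration_days"], errors="coerce")
        bad = dur.isna() & df["duration_days"].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"non-numeric duration_days at line {line}")
        df = df.assign(duration_days=dur)
    elif {"start_date", "end_date"}.issubset(df.columns):
        start = pd.to_datetime(df["start_date"], format="ISO8601")
        end = pd.to_datetime(df["end_date"], format="ISO8601")
        df = df.assign(duration_days=(end - start).dt.days.astype(float))
    else:
        raise ValueError(
            "phenotype table needs either a duration_days column or "
            "start_date/end_date columns"
        )
    df["course"] = pd.to_numeric(df["course"], errors="raise").astype(int)
    if df.duplicated(subset=["subject_id", "course"]).any():
        dup = df[df.duplicated(subset=["subject_id", "course"], keep=False)]
        raise ValueError(
            f"duplicate (subject_id, course) rows, e.g. {dup.iloc[0].to_dict()!r}"
        )
    J = int(n_courses or df["course"].max())
    if df["course"].min() < 1 or df["course"].max() > J:
        raise ValueError(f"course labels must lie in 1..{J}")
    subjects = pd.unique(df["subject_id"])
    wide = np.full((len(subjects), J), np.nan)
    sidx = {s: i for i, s in enumerate(subjects)}
    for s, c, d in zip(df["subject_id"], df["course"], df["duration_days"]):
        if pd.notna(d):
            wide[sidx[s], c - 1] = d
    return apply_course_qc(wide, subject_ids=np.asarray(subjects, dtype=object))


def write_phenotype_long(pheno: LongitudinalPhenotype, path) -> None:
    """Write the day-scale long table ``subject_id course duration_days``."""
    days = pheno.durations_days()
    rows = []
    for i, sid in enumerate(pheno.subject_ids):
        for j in range(pheno.n_courses):
            if np.isfinite(days[i, j]):
                rows.append((sid, j + 1, f"{days[i, j]:.10g}"))
    df = pd.DataFrame(rows, columns=["subject_id", "course", "duration_days"])
    df.to_csv(path, sep="\t", index=False)
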