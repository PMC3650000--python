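"""Data model and I/O for longitudinal binary-detection cohorts.

A cohort is a table of subjects with a stratum label (typically infant sex),
a continuous growth outcome (change in weight-for-age Z-score between birth
and ~6 months, ΔZ), and a J x T array of binary detection indicators: for
each of J microbial taxa, whether the taxon was detected in the subject's
fecal sample at each of T ordered sampling days.  Missing samples are kept
as missing (NaN) and never imputed.

On-disk format is delimited text (TSV by default), one row per subject, with
columns ``subject_id``, ``stratum``, ``outcome`` followed by one column per
taxon x day named ``<taxon>_d<day>`` (e.g. ``probe13_d30``) holding 0, 1 or
an empty/NA cell.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DETECTION_COL_RE = re.compile(r"^(?P<taxon>.+)_d(?P<day>\d+)$")

#: stratum label assigned to subjects whose stratum cell is empty/missing
UNLABELLED_STRATUM = "unlabelled"


class CohortError(Exception):
    """Base class for cohort construction/parsing problems."""


class CohortParseError(CohortError):
    """A file could not be parsed into a cohort table."""


class CohortValidationError(CohortError):
    """Parsed data violate the cohort contract (values, uniqueness, shape)."""


@dataclass(frozen=True)
class CohortTable:
    """Subjects x (stratum, outcome, J x T detections).

    Attributes
    ----------
    subject_ids : (n,) array of str, unique identifiers.
    stratum : (n,) array of str stratum labels.
    outcome : (n,) float array, ΔZ; NaN marks a missing outcome.
    detections : (n, J, T) float array with values 0.0, 1.0 or NaN.
    taxon_names : list of J taxon labels.
    timepoint_days : list of T sampling days, strictly increasing.
    """

    subject_ids: np.ndarray
    stratum: np.ndarray
    outcome: np.ndarray
    detections: np.ndarray
    taxon_names: tuple[str, ...]
    timepoint_days: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids, dtype=object))
        object.__setattr__(self, "stratum", np.asarray(self.stratum, dtype=object))
        object.__setattr__(self, "outcome", np.asarray(self.outcome, dtype=float))
        object.__setattr__(self, "detections", np.asarray(self.detections, dtype=float))
        object.__setattr__(self, "taxon_names", tuple(self.taxon_names))
        object.__setattr__(self, "timepoint_days", tuple(int(d) for d in self.timepoint_days))
        self._validate()

    # -- contract ---------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.subject_ids)
        J, T = len(self.taxon_names), len(self.timepoint_days)
        if T < 2:
            raise CohortValidationError("at least two time points are required")
        if any(b <= a for a, b in zip(self.timepoint_days, self.timepoint_days[1:])):
            raise CohortValidationError(
                f"time point days must be strictly increasing, got {self.timepoint_days}"
            )
        if self.detections.shape != (n, J, T):
            raise CohortValidationError(
                f"detections shape {self.detections.shape} != {(n, J, T)}"
            )
        if self.outcome.shape != (n,) or self.stratum.shape != (n,):
            raise CohortValidationError("outcome/stratum length mismatch with subjects")
        if len(set(self.subject_ids)) != n:
            dupes = pd.Series(self.subject_ids).value_counts()
            dupes = list(dupes[dupes > 1].index[:5])
            raise CohortValidationError(f"duplicate subject ids: {dupes}")
        d = self.detections
        bad = np.isfinite(d) & (d != 0.0) & (d != 1.0)
        if bad.any():
            i, j, t = map(int, np.argwhere(bad)[0])
            raise CohortValidationError(
                f"detection value {d[i, j, t]!r} for subject "
                f"{self.subject_ids[i]!r}, taxon {self.taxon_names[j]!r}, "
                f"day {self.timepoint_days[t]} is not 0/1/NA"
            )
        if np.isinf(self.outcome).any():
            raise CohortValidationError("outcome contains non-finite (inf) values")

    # -- convenience ------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_days)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxon_names.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row subset (boolean or index array) as a new cohort."""
        return replace(
            self,
            subject_ids=self.subject_ids[mask],
            stratum=self.stratum[mask],
            outcome=self.outcome[mask],
            detections=self.detections[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "subject_id": self.subject_ids,
            "stratum": self.stratum,
            "outcome": self.outcome,
        }
        for j, taxon in enumerate(self.taxon_names):
            for t, day in enumerate(self.timepoint_days):
                cols[f"{taxon}_d{day}"] = self.detections[:, j, t]
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tuning knobs shared by the time-specific and pattern analyses.

    alpha : mdFDR level for the primary analysis (default 0.05).
    alpha_relaxed : secondary, exploratory level for the time-specific
        analysis (default 0.20).
    delta : equivalence margin in ΔZ units; |ΔZ| < delta defines growth
        "as expected" (default 0.67).
    min_pattern_freq : minimum observed frequency for a detection pattern
        to be testable (default 0.15; frequency exactly at the floor is
        still testable).
    screen_alpha_contrast : level of the crude-contrast difference-from-zero
        screen (default 0.05).
    screen_alpha_welch : relaxed level for the pattern-vs-contrast Welch
        test (default 0.10); must be >= screen_alpha_contrast.
    stratify : analyse strata separately (default True).
    """

    alpha: float = 0.05
    alpha_relaxed: float = 0.20
    delta: float = 0.67
    min_pattern_freq: float = 0.15
    screen_alpha_contrast: float = 0.05
    screen_alpha_welch: float = 0.10
    stratify: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_relaxed", "min_pattern_freq",
                     "screen_alpha_contrast", "screen_alpha_welch"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.screen_alpha_welch < self.screen_alpha_contrast:
            raise ValueError(
                "screen_alpha_welch must be >= screen_alpha_contrast "
                "(the Welch screen is the relaxed one)"
            )


# ---------------------------------------------------------------------------
# I/O


def load_cohort(
    path,
    sep: str = "\t",
    subject_col: str = "subject_id",
    stratum_col: str = "stratum",
    outcome_col: str = "outcome",
) -> CohortTable:
    """Read a delimited cohort file into a validated :class:`CohortTable`.

    Detection columns are recognised by the ``<taxon>_d<day>`` naming
    convention; every other column besides the three named ones is an error.
    Missing cells stay missing.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype={subject_col: str, stratum_col: str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortParseError(f"could not parse {path}: {exc}") from exc

    for col in (subject_col, stratum_col, outcome_col):
        if col not in df.columns:
            raise CohortParseError(f"required column {col!r} missing from {path}")

    taxa: list[str] = []
    days: list[int] = []
    det_cols: dict[tuple[str, int], str] = {}
    for col in df.columns:
        if col in (subject_col, stratum_col, outcome_col):
            continue
        m = _DETECTION_COL_RE.match(col)
        if m is None:
            raise CohortParseError(
                f"column {col!r} is neither a required column nor a "
                f"'<taxon>_d<day>' detection column"
            )
        taxon, day = m["taxon"], int(m["day"])
        if taxon not in taxa:
            taxa.append(taxon)
        if day not in days:
            days.append(day)
        det_cols[(taxon, day)] = col
    if not det_cols:
        raise CohortParseError(f"no detection columns found in {path}")
    days = sorted(days)
    missing_cols = [
        f"{taxon}_d{day}" for taxon in taxa for day in days if (taxon, day) not in det_cols
    ]
    if missing_cols:
        raise CohortParseError(f"incomplete taxon x day grid; missing {missing_cols}")

    n = len(df)
    det = np.full((n, len(taxa), len(days)), np.nan)
    for j, taxon in enumerate(taxa):
        for t, day in enumerate(days):
            col = pd.to_numeric(df[det_cols[(taxon, day)]], errors="coerce")
            raw = df[det_cols[(taxon, day)]]
            unparsed = col.isna() & raw.notna() & (raw.astype(str).str.strip() != "") \
                & ~raw.astype(str).str.upper().isin({"NA", "NAN"})
            if unparsed.any():
                row = int(np.flatnonzero(unparsed)[0])
                raise CohortParseError(
                    f"non-numeric detection value {raw.iloc[row]!r} in column "
                    f"{det_cols[(taxon, day)]!r}, data row {row + 1}"
                )
            det[:, j, t] = col.to_numpy(dtype=float)

    stratum = df[stratum_col].fillna("").astype(str).str.strip().to_numpy(dtype=object)
    blank = stratum == ""
    if blank.any():
        logger.warning(
            "%d subject(s) with empty stratum label assigned to %r",
            int(blank.sum()), UNLABELLED_STRATUM,
        )
        stratum[blank] = UNLABELLED_STRATUM

    return CohortTable(
        subject_ids=df[subject_col].to_numpy(dtype=object),
        stratum=stratum,
        outcome=pd.to_numeric(df[outcome_col], errors="coerce").to_numpy(dtype=float),
        detections=det,
        taxon_names=tuple(taxa),
        timepoint_days=tuple(days),
    )


def write_cohort(cohort: CohortTable, path, sep: str = "\t") -> None:
    """Write a cohort in the same dialect :func:`load_cohort` reads.

    ``load_cohort(write_cohort(c))`` is the identity, missingness included;
    detections are written as integer 0/1 with empty cells for NA.
    """
    df = cohort.to_dataframe()
    det_cols = df.columns[3:]
    df[det_cols] = df[det_cols].astype("Int64")  # nullable int: "0"/"1"/""
    df.to_csv(path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Operations


def dichotomise(intensities: np.ndarray, thresholds) -> np.ndarray:
    """Turn continuous probe intensities into detection calls.

    ``intensities`` has taxa on its second-to-last axis ((J, T) per subject
    or (n, J, T) for a cohort); ``thresholds`` is one detection limit per
    taxon (sequence or mapping-free array).  Strictly above the threshold is
    detected (1), at or below is non-detected (0), missing stays missing.
    """
    intensities = np.asarray(intensities, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    n_taxa = intensities.shape[-2]
    if thresholds.shape != (n_taxa,):
        raise ValueError(
            f"need exactly one threshold per taxon ({n_taxa}), got shape {thresholds.shape}"
        )
    if not np.isfinite(thresholds).all():
        j = int(np.flatnonzero(~np.isfinite(thresholds))[0])
        raise ValueError(f"threshold for taxon index {j} is missing/non-finite")
    thr = thresholds[..., :, None]
    out = np.where(intensities > thr, 1.0, 0.0)
    out[np.isnan(intensities)] = np.nan
    return out


def split_strata(cohort: CohortTable) -> dict[str, CohortTable]:
    """Partition a cohort by stratum label.

    Returns ``{label: sub-cohort}`` with labels sorted; the sub-cohorts
    partition the input exactly.  Strata too small for inference (< 2
    subjects) are still returned — analysis drivers skip them with a logged
    reason — so the partition property holds unconditionally.
    """
    labels = sorted(set(cohort.stratum))
    out: dict[str, CohortTable] = {}
    for label in labels:
        sub = cohort.subset(cohort.stratum == label)
        if sub.n_subjects < 2:
            logger.warning(
                "stratum %r has only %d subject(s); it will be excluded from inference",
                label, sub.n_subjects,
            )
        out[label] = sub
    return out
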