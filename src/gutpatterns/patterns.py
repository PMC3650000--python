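"""Longitudinal detection patterns: enumeration, matching, filtering, reduction.

A pattern assigns one of three symbols to each sampling day of one taxon:
``+`` (detected), ``-`` (non-detected) or ``X`` (irrelevant — the day does
not constrain membership).  Irrelevant days can only appear as a contiguous
right-hand suffix: time points are dropped from the late end only, because a
later exposure cannot confound an earlier one, whereas an early exposure can
influence a later one.

Subjects enter pattern analysis for a taxon only when their detection data
for that taxon are complete at every day (complete-case per taxon), so that
membership in a T-day pattern is well defined and the 2^T full patterns
partition the analysable subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from .cohort import CohortTable

logger = logging.getLogger(__name__)

DET = "+"
NON = "-"
IRR = "X"
_SYMBOLS = (DET, NON, IRR)


class PatternError(ValueError):
    """Invalid pattern construction or reduction."""


@dataclass(frozen=True)
class Pattern:
    """An exposure history over the taxon's sampling days.

    ``symbols`` is a length-T tuple over {``+``, ``-``, ``X``}; any ``X``
    symbols form a contiguous suffix and at least one symbol is relevant.
    """

    symbols: tuple[str, ...]
    taxon: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if not self.symbols:
            raise PatternError("empty pattern")
        for s in self.symbols:
            if s not in _SYMBOLS:
                raise PatternError(f"invalid pattern symbol {s!r}")
        k = self.n_relevant
        if k == 0:
            raise PatternError("pattern must have at least one relevant day")
        if any(s == IRR for s in self.symbols[:k]):
            raise PatternError(
                f"irrelevant days must form a right-hand suffix: {''.join(self.symbols)}"
            )

    @classmethod
    def from_string(cls, text: str, taxon: str | None = None) -> "Pattern":
        """Parse e.g. ``"+--X"`` (one character per day)."""
        return cls(tuple(text), taxon=taxon)

    def __str__(self) -> str:
        return "".join(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_relevant(self) -> int:
        """Number of non-irrelevant days."""
        return sum(s != IRR for s in self.symbols)

    @property
    def is_full(self) -> bool:
        return self.n_relevant == len(self.symbols)

    def crude_contrast(self) -> "Pattern":
        """Flip detected <-> non-detected at every relevant day.

        The contrast of a significant pattern defines the post-hoc
        comparison population (e.g. the contrast of ``++XX`` is ``--XX``).
        An involution that never maps a pattern to itself.
        """
        flip = {DET: NON, NON: DET, IRR: IRR}
        return Pattern(tuple(flip[s] for s in self.symbols), taxon=self.taxon)

    def reduce_right(self) -> "Pattern":
        """Drop the rightmost relevant day (mark it irrelevant)."""
        k = self.n_relevant
        if k < 2:
            raise PatternError(
                f"cannot reduce {self}: a pattern must keep at least one relevant day"
            )
        symbols = list(self.symbols)
        symbols[k - 1] = IRR
        return Pattern(tuple(symbols), taxon=self.taxon)


def crude_contrast(pattern: Pattern) -> Pattern:
    return pattern.crude_contrast()


def reduce_right(pattern: Pattern) -> Pattern:
    return pattern.reduce_right()


def enumerate_patterns(n_timepoints: int, taxon: str | None = None) -> list[Pattern]:
    """All 2^T full patterns in lexicographic order with detected first.

    With T = 4 this is the 16-pattern catalogue; pattern 8 (1-based) is
    ``+---``: detection at the first day followed by non-detection.
    """
    if n_timepoints < 1:
        raise ValueError(f"n_timepoints must be >= 1, got {n_timepoints}")
    return [Pattern(sym, taxon=taxon) for sym in product((DET, NON), repeat=n_timepoints)]


@dataclass(frozen=True)
class PatternGroup:
    """The subjects matching one pattern, with their outcome summary.

    ``mean``/``se`` are NaN when undefined (n = 0, or n < 2 for the se).
    """

    pattern: Pattern
    subject_ids: tuple[str, ...]
    outcomes: np.ndarray
    n: int
    mean: float
    se: float

    @property
    def estimable(self) -> bool:
        """True when the group supports a one-sample t-based test."""
        return self.n >= 2 and np.isfinite(self.se) and self.se > 0


def _complete_case_mask(cohort: CohortTable, taxon_idx: int) -> np.ndarray:
    """Subjects with detection observed at every day for the taxon, and a
    non-missing outcome (the outcome is the quantity under test)."""
    det_ok = np.isfinite(cohort.detections[:, taxon_idx, :]).all(axis=1)
    return det_ok & np.isfinite(cohort.outcome)


def _group_from_mask(cohort: CohortTable, pattern: Pattern, mask: np.ndarray) -> PatternGroup:
    outcomes = cohort.outcome[mask]
    n = outcomes.size
    mean = float(outcomes.mean()) if n else float("nan")
    if n >= 2:
        sd = float(outcomes.std(ddof=1))
        se = sd / float(np.sqrt(n)) if sd > 0 else float("nan")
    else:
        se = float("nan")
    return PatternGroup(
        pattern=pattern,
        subject_ids=tuple(cohort.subject_ids[mask]),
        outcomes=outcomes,
        n=int(n),
        mean=mean,
        se=se,
    )


def match_subjects(cohort: CohortTable, pattern: Pattern) -> PatternGroup:
    """Subjects whose detection history equals the pattern at relevant days.

    Matching is restricted to complete-case subjects for the taxon so the
    same population underlies a pattern and all of its reductions; relaxing
    a day to irrelevant therefore never shrinks the group.  An empty match
    is a valid group with n = 0, not an error.
    """
    if pattern.taxon is None:
        raise PatternError("pattern must carry a taxon to be matched against a cohort")
    if len(pattern) != cohort.n_timepoints:
        raise PatternError(
            f"pattern length {len(pattern)} != cohort time points {cohort.n_timepoints}"
        )
    j = cohort.taxon_index(pattern.taxon)
    mask = _complete_case_mask(cohort, j)
    det = cohort.detections[:, j, :]
    for t, s in enumerate(pattern.symbols):
        if s == IRR:
            continue
        mask = mask & (det[:, t] == (1.0 if s == DET else 0.0))
    return _group_from_mask(cohort, pattern, mask)


def pattern_codes(detections_jt: np.ndarray) -> np.ndarray:
    """Encode complete (n, T) 0/1 histories as integers in [0, 2^T).

    Bit weights make code 0 the all-detected pattern and follow the
    detected-first lexicographic order of :func:`enumerate_patterns`
    (non-detection at day t sets bit T-1-t).
    """
    T = detections_jt.shape[1]
    weights = 2 ** np.arange(T - 1, -1, -1)
    return ((1.0 - detections_jt) @ weights).astype(np.intp)


def testable_patterns(
    cohort: CohortTable, taxon: str, min_freq: float = 0.15
) -> list[PatternGroup]:
    """Full patterns frequent enough to test for the given taxon.

    The frequency denominator is the number of complete-case subjects for
    the taxon; a pattern is testable when n / n_complete >= ``min_freq``
    (the floor itself is included — only strictly rarer patterns are
    excluded).  Returned in catalogue order.
    """
    if not 0.0 < min_freq < 1.0:
        raise ValueError(f"min_freq must lie in (0, 1), got {min_freq}")
    j = cohort.taxon_index(taxon)
    complete = _complete_case_mask(cohort, j)
    n_complete = int(complete.sum())
    if n_complete == 0:
        logger.warning("taxon %r has no complete-case subjects; nothing testable", taxon)
        return []
    codes = pattern_codes(cohort.detections[complete][:, j, :])
    counts = np.bincount(codes, minlength=2 ** cohort.n_timepoints)
    catalogue = enumerate_patterns(cohort.n_timepoints, taxon=taxon)
    groups = []
    for code, pattern in enumerate(catalogue):
        if counts[code] / n_complete >= min_freq:
            mask = complete.copy()
            mask[complete] = codes == code
            groups.append(_group_from_mask(cohort, pattern, mask))
    return groups
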