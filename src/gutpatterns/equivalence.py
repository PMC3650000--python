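"""Statistical primitives: equivalence-to-zero, one-sample and Welch t-tests.

The equivalence test asks whether a group's mean change in Z-score is close
enough to zero to call the growth "as expected": H0: |mu| >= delta against
H1: |mu| < delta, with delta the expected-growth margin (0.67 ΔZ units by
default).  It is carried out as two one-sided t-tests (an intersection-union
test): the reported p-value is the larger of the two one-sided p-values, so
a small p supports equivalence.

Student's t with n - 1 degrees of freedom is used throughout rather than a
normal reference: testable pattern groups can be as small as ~15% of a
~110-subject stratum, and t is the conservative standard choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EquivalenceTestResult:
    """Outcome of an equivalence-to-zero test on a group mean."""

    estimate: float
    se: float
    n: int
    df: float
    delta: float
    p_value: float


def equivalence_pvalue(estimate, se, df, delta):
    """Vectorised TOST p-value; array in, array out (scalars pass through).

    p = max{ P(T_df <= (estimate - delta)/se), P(T_df >= (estimate + delta)/se) }.
    """
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    df = np.asarray(df, dtype=float)
    p_upper = stats.t.cdf((estimate - delta) / se, df)   # H0: mu >= delta
    p_lower = stats.t.sf((estimate + delta) / se, df)    # H0: mu <= -delta
    return np.maximum(p_upper, p_lower)


def equivalence_to_zero(
    estimate: float, se: float, df: float, delta: float
) -> EquivalenceTestResult:
    """Two one-sided t-tests of H0: |mu| >= delta vs H1: |mu| < delta.

    ``estimate``/``se`` are the group's sample mean and its standard error;
    ``df`` is n - 1 for a one-sample problem.  Symmetric in the sign of the
    estimate; p = 0.5 exactly when |estimate| = delta.
    """
    if se <= 0 or not np.isfinite(se):
        raise ValueError(f"se must be a positive finite number, got {se}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    p = float(equivalence_pvalue(estimate, se, df, delta))
    return EquivalenceTestResult(
        estimate=float(estimate),
        se=float(se),
        n=int(round(df)) + 1,
        df=float(df),
        delta=float(delta),
        p_value=p,
    )


class DegenerateSampleError(ValueError):
    """A sample too small or too constant for the requested test."""


def one_sample_difference(outcomes) -> float:
    """Two-sided one-sample t-test p-value for H0: mean = 0."""
    outcomes = np.asarray(outcomes, dtype=float)
    if outcomes.size < 2:
        raise DegenerateSampleError(
            f"one-sample t-test needs n >= 2, got n = {outcomes.size}"
        )
    if np.ptp(outcomes) == 0:
        raise DegenerateSampleError("one-sample t-test needs nonzero variance")
    return float(stats.ttest_1samp(outcomes, 0.0).pvalue)


def welch_two_sample(group_a, group_b) -> float:
    """Two-sided Welch t-test p-value (Satterthwaite degrees of freedom)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"Welch test needs n >= 2 in both groups, got {a.size} and {b.size}"
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateSampleError("Welch test needs variance in at least one group")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
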