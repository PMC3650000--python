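"""Time-specific analysis: ΔZ regressed on detection, day by day.

For every taxon j and sampling day t, the change in weight-for-age Z-score
is regressed on the 0/1 detection indicator (available-case: subjects with
both that detection and the outcome observed).  With a single binary
predictor, OLS is exactly the two-sample pooled-variance t-test: the slope
is the detected-minus-non-detected difference in mean ΔZ, with the usual
df = n - 2 two-sided p-value.  No covariates enter the model — stepwise
screening of candidate confounders removed them all in the motivating
analysis, so the final model is the crude one.

Each taxon's estimable days form one family for the two-level mixed
directional FDR controller; decisions are recorded at the primary level and
at a relaxed, exploratory level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisConfig, CohortTable, split_strata
from .mdfdr import FamilyPValues, MdfdrDecision, mdfdr_decide

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimepointEffect:
    """One taxon x day regression: the ΔZ shift for detected vs non-detected."""

    taxon: str
    day: int
    beta: float
    se: float
    df: float
    p_value: float
    n_detected: int
    n_nondetected: int

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.p_value)


def fit_timepoint_effect(outcome, detection, taxon: str = "", day: int = 0) -> TimepointEffect:
    """Simple regression of outcome on a 0/1 detection indicator.

    Pairs with a missing value on either side are dropped (available-case).
    Equivalent to the pooled two-sample t-test: beta = mean(detected) -
    mean(non-detected).  If either group is empty (or pooled variance is
    zero) the effect is flagged inestimable (NaN fields) rather than raising,
    so callers can shrink the family.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(detection, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n1 = int((x == 1.0).sum())
    n0 = int((x == 0.0).sum())
    n = n1 + n0
    if n1 == 0 or n0 == 0 or n < 3:
        return TimepointEffect(taxon, day, np.nan, np.nan, np.nan, np.nan, n1, n0)
    y1, y0 = y[x == 1.0], y[x == 0.0]
    beta = float(y1.mean() - y0.mean())
    ss = float(((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum())
    df = n - 2
    if ss <= 0:
        return TimepointEffect(taxon, day, beta, np.nan, float(df), np.nan, n1, n0)
    se = float(np.sqrt(ss / df * (1.0 / n1 + 1.0 / n0)))
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TimepointEffect(taxon, day, beta, se, float(df), p, n1, n0)


def _fit_all_effects(cohort: CohortTable) -> np.ndarray:
    """Vectorised fit of all J x T effects; returns a structured array of
    (beta, se, p, n1, n0) with NaN where inestimable."""
    y = cohort.outcome
    d = cohort.detections  # (n, J, T)
    keep = np.isfinite(d) & np.isfinite(y)[:, None, None]
    dk = np.where(keep, d, np.nan)
    n1 = np.nansum(dk, axis=0)
    n_obs = keep.sum(axis=0)
    n0 = n_obs - n1
    yk = np.where(keep, y[:, None, None], np.nan)
    sum1 = np.nansum(dk * yk, axis=0)
    sumsq1 = np.nansum(dk * yk**2, axis=0)
    sum_all = np.nansum(yk, axis=0)
    sumsq_all = np.nansum(yk**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = sum1 / n1
        m0 = (sum_all - sum1) / n0
        ss1 = sumsq1 - n1 * m1**2
        ss0 = (sumsq_all - sumsq1) - n0 * m0**2
        beta = m1 - m0
        df = n_obs - 2
        se = np.sqrt((ss1 + ss0) / df * (1.0 / n1 + 1.0 / n0))
        p = 2.0 * stats.t.sf(np.abs(beta / se), df)
    ok = (n1 > 0) & (n0 > 0) & (n_obs >= 3) & np.isfinite(se) & (se > 0)
    for arr in (beta, se, p):
        arr[~ok] = np.nan
    out = np.empty(beta.shape, dtype=[("beta", float), ("se", float), ("p", float),
                                      ("n1", int), ("n0", int)])
    out["beta"], out["se"], out["p"] = beta, se, p
    out["n1"], out["n0"] = n1.astype(int), n0.astype(int)
    return out


@dataclass(frozen=True)
class StratumTimeSpecificResult:
    """Effects and two-level decisions for one stratum."""

    stratum: str
    effects: tuple[TimepointEffect, ...]
    decisions: dict[float, MdfdrDecision | None]  # level -> decision


@dataclass(frozen=True)
class TimeSpecificResult:
    strata: tuple[StratumTimeSpecificResult, ...]
    alpha: float
    alpha_relaxed: float

    def table(self) -> pd.DataFrame:
        """Long-format decision table: one row per stratum x taxon x day."""
        rows = []
        for sres in self.strata:
            rejected: dict[float, set] = {}
            for level, dec in sres.decisions.items():
                rejected[level] = (
                    {(f, c) for f, c, _ in dec.rejected_components()} if dec else set()
                )
            for eff in sres.effects:
                key = (eff.taxon, eff.day)
                tier = "none"
                if key in rejected.get(self.alpha, set()):
                    tier = f"{self.alpha:g}"
                elif key in rejected.get(self.alpha_relaxed, set()):
                    tier = f"{self.alpha_relaxed:g}"
                rows.append({
                    "stratum": sres.stratum, "taxon": eff.taxon, "day": eff.day,
                    "beta": eff.beta, "se": eff.se, "p_value": eff.p_value,
                    "n_detected": eff.n_detected, "n_nondetected": eff.n_nondetected,
                    "tier": tier,
                })
        return pd.DataFrame(rows)


def _decide_stratum(
    effects_rec: np.ndarray, cohort: CohortTable, alpha: float
) -> MdfdrDecision | None:
    """Build per-taxon families from the estimable days and run the
    controller; returns None when no taxon has an estimable day."""
    families = []
    for j, taxon in enumerate(cohort.taxon_names):
        ok = np.isfinite(effects_rec["p"][j])
        if not ok.any():
            continue
        families.append(FamilyPValues(
            family_id=taxon,
            component_pvalues=effects_rec["p"][j][ok],
            component_ids=tuple(d for d, o in zip(cohort.timepoint_days, ok) if o),
        ))
    if not families:
        return None
    return mdfdr_decide(families, alpha)


def run_time_specific(
    cohort: CohortTable, config: AnalysisConfig | None = None
) -> TimeSpecificResult:
    """The full time-specific analysis, stratified.

    Per stratum: fit every taxon x day effect, pool the estimable days of a
    taxon into one family, and run the two-level controller at both the
    primary and the relaxed level.  Inestimable days (a detection state
    absent, or zero residual variance) shrink the family rather than
    entering as p = 1.  Strata with fewer than 2 subjects are skipped.
    "No findings" is a normal, empty result.
    """
    config = config or AnalysisConfig()
    strata = split_strata(cohort) if config.stratify else {"all": cohort}
    out = []
    for label, sub in strata.items():
        if sub.n_subjects < 2:
            logger.warning("skip stratum=%s reason=too_few_subjects n=%d",
                           label, sub.n_subjects)
            continue
        rec = _fit_all_effects(sub)
        effects = tuple(
            TimepointEffect(
                taxon, day,
                float(rec["beta"][j, t]), float(rec["se"][j, t]),
                float(rec["n1"][j, t] + rec["n0"][j, t] - 2), float(rec["p"][j, t]),
                int(rec["n1"][j, t]), int(rec["n0"][j, t]),
            )
            for j, taxon in enumerate(sub.taxon_names)
            for t, day in enumerate(sub.timepoint_days)
        )
        decisions = {
            level: _decide_stratum(rec, sub, level)
            for level in (config.alpha, config.alpha_relaxed)
        }
        out.append(StratumTimeSpecificResult(label, effects, decisions))
    return TimeSpecificResult(tuple(out), config.alpha, config.alpha_relaxed)
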