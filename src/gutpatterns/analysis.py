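"""The pattern pipeline: testable patterns -> equivalence -> mdFDR ->
sequential reduction -> post-hoc crude-contrast screening.

Per stratum and taxon, the analysable subjects (complete detection history
for that taxon, outcome observed) are partitioned over the 2^T full
detection patterns.  Patterns reaching the minimum frequency are tested for
equivalence of their mean ΔZ to zero (margin delta): a rejection says the
group grew as expected.  Taxa are families and their testable patterns the
components of the two-level mixed directional FDR controller; every
rejected pattern then enters the halved-level reduction cascade to drop
superfluous late days, and finally the post-hoc screen: the crude
contrast's mean must itself differ from zero (else the finding is
discarded), and if it does, a Welch test compares pattern and contrast
means, reported as a strict / nominal / none tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import AnalysisConfig, CohortTable, split_strata
from .equivalence import (
    DegenerateSampleError,
    equivalence_pvalue,
    one_sample_difference,
    welch_two_sample,
)
from .mdfdr import (
    FamilyPValues,
    MdfdrDecision,
    ReductionTrail,
    mdfdr_decide,
    sequential_reduction,
)
from .patterns import (
    Pattern,
    PatternGroup,
    enumerate_patterns,
    match_subjects,
    pattern_codes,
    _complete_case_mask,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatternFinding:
    """One significant pattern with its full post-hoc provenance."""

    stratum: str
    taxon: str
    entry_pattern: Pattern
    entry_p: float
    alpha_star: float
    reduction_trail: ReductionTrail
    final_pattern: Pattern
    group: PatternGroup
    equivalence_p: float
    contrast_group: PatternGroup | None = None
    contrast_p: float = float("nan")
    welch_p: float = float("nan")
    welch_tier: str = "none"          # strict | nominal | none
    screened_out: bool = True
    screen_reason: str = "unscreened"


@dataclass(frozen=True)
class StratumPatternResult:
    stratum: str
    decision: MdfdrDecision | None
    findings: tuple[PatternFinding, ...]
    audit: tuple[dict, ...]           # every testable pattern, tested or not
    skipped_taxa: tuple[tuple[str, str], ...]  # (taxon, reason)


@dataclass(frozen=True)
class PatternAnalysisResult:
    strata: tuple[StratumPatternResult, ...]
    config: AnalysisConfig

    @property
    def findings(self) -> tuple[PatternFinding, ...]:
        return tuple(f for s in self.strata for f in s.findings)

    def significant_findings(self) -> tuple[PatternFinding, ...]:
        """Findings surviving the post-hoc screen."""
        return tuple(f for f in self.findings if not f.screened_out)

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame([row for s in self.strata for row in s.audit])

    def findings_table(self) -> pd.DataFrame:
        rows = []
        for f in self.findings:
            cg = f.contrast_group
            rows.append({
                "stratum": f.stratum, "taxon": f.taxon,
                "final_pattern": str(f.final_pattern),
                "n": f.group.n, "mean": f.group.mean, "se": f.group.se,
                "equivalence_p": f.equivalence_p, "alpha_star": f.alpha_star,
                "contrast_pattern": str(f.final_pattern.crude_contrast()),
                "contrast_n": cg.n if cg else 0,
                "contrast_mean": cg.mean if cg else float("nan"),
                "contrast_p": f.contrast_p, "welch_p": f.welch_p,
                "welch_tier": f.welch_tier, "screened_out": f.screened_out,
                "screen_reason": f.screen_reason,
                "trail": " -> ".join(str(s.pattern) for s in f.reduction_trail.steps),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def _taxon_pattern_stats(cohort: CohortTable, j: int):
    """Per-full-pattern (count, mean, se) over the taxon's complete cases.

    Returns (n_complete, counts, means, ses) with one slot per catalogue
    code; the bincount path keeps the per-replicate simulation cost low.
    """
    complete = _complete_case_mask(cohort, j)
    n_complete = int(complete.sum())
    n_codes = 2 ** cohort.n_timepoints
    if n_complete == 0:
        z = np.zeros(n_codes)
        return 0, z.astype(int), np.full(n_codes, np.nan), np.full(n_codes, np.nan)
    codes = pattern_codes(cohort.detections[complete][:, j, :])
    y = cohort.outcome[complete]
    counts = np.bincount(codes, minlength=n_codes)
    sums = np.bincount(codes, weights=y, minlength=n_codes)
    sumsq = np.bincount(codes, weights=y * y, minlength=n_codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        var = (sumsq - counts * means**2) / (counts - 1)
        var = np.where(var > 0, var, np.nan)
        ses = np.sqrt(var / counts)
    return n_complete, counts, means, ses


def _equivalence_p_of_group(group: PatternGroup, delta: float) -> float:
    """Equivalence p for a matched group; degenerate groups count as 1."""
    if not group.estimable:
        return 1.0
    return float(equivalence_pvalue(group.mean, group.se, group.n - 1, delta))


def posthoc_screen(
    finding: PatternFinding, cohort: CohortTable, config: AnalysisConfig
) -> PatternFinding:
    """Apply the crude-contrast screen and Welch comparison to one finding.

    The contrast group's mean is tested for difference from zero; a
    non-significant (or inconclusive) contrast discards the finding from
    the significant set.  A significant contrast triggers the Welch
    pattern-vs-contrast test, graded strict (below the contrast level) or
    nominal (below the relaxed Welch level).
    """
    contrast = finding.final_pattern.crude_contrast()
    cgroup = match_subjects(cohort, contrast)
    if cgroup.n < 2:
        return replace(finding, contrast_group=cgroup, screened_out=True,
                       screen_reason="contrast_inconclusive_n<2")
    try:
        contrast_p = one_sample_difference(cgroup.outcomes)
    except DegenerateSampleError:
        return replace(finding, contrast_group=cgroup, screened_out=True,
                       screen_reason="contrast_degenerate")
    if contrast_p > config.screen_alpha_contrast:
        return replace(finding, contrast_group=cgroup, contrast_p=contrast_p,
                       screened_out=True, screen_reason="contrast_not_significant")
    try:
        welch_p = welch_two_sample(finding.group.outcomes, cgroup.outcomes)
    except (ValueError, DegenerateSampleError):
        return replace(finding, contrast_group=cgroup, contrast_p=contrast_p,
                       screened_out=True, screen_reason="welch_inconclusive")
    if welch_p <= config.screen_alpha_contrast:
        tier = "strict"
    elif welch_p <= config.screen_alpha_welch:
        tier = "nominal"
    else:
        tier = "none"
    return replace(finding, contrast_group=cgroup, contrast_p=contrast_p,
                   welch_p=welch_p, welch_tier=tier,
                   screened_out=False, screen_reason="unscreened")


def _analyse_stratum(
    label: str, cohort: CohortTable, config: AnalysisConfig
) -> StratumPatternResult:
    catalogue = enumerate_patterns(cohort.n_timepoints)
    n_codes = len(catalogue)
    families: list[FamilyPValues] = []
    skipped: list[tuple[str, str]] = []
    audit: list[dict] = []
    # (taxon, code) -> (n, mean, se, p)
    stats_by: dict[tuple[str, int], tuple[int, float, float, float]] = {}

    est_list, se_list, df_list, where = [], [], [], []
    per_taxon: dict[str, list[int]] = {}
    for j, taxon in enumerate(cohort.taxon_names):
        n_complete, counts, means, ses = _taxon_pattern_stats(cohort, j)
        if n_complete == 0:
            skipped.append((taxon, "no_complete_cases"))
            continue
        codes = [
            c for c in range(n_codes)
            if counts[c] / n_complete >= config.min_pattern_freq
        ]
        if not codes:
            skipped.append((taxon, "no_testable_patterns"))
            continue
        per_taxon[taxon] = codes
        for c in codes:
            if np.isfinite(ses[c]) and ses[c] > 0 and counts[c] >= 2:
                est_list.append(means[c]); se_list.append(ses[c])
                df_list.append(counts[c] - 1)
                where.append((taxon, c))
            stats_by[(taxon, c)] = (int(counts[c]), float(means[c]), float(ses[c]), 1.0)

    if where:  # one vectorised t call for every estimable pattern in the stratum
        ps = equivalence_pvalue(np.array(est_list), np.array(se_list),
                                np.array(df_list), config.delta)
        for (taxon, c), p in zip(where, np.atleast_1d(ps)):
            n, m, s, _ = stats_by[(taxon, c)]
            stats_by[(taxon, c)] = (n, m, s, float(p))

    for taxon, codes in per_taxon.items():
        families.append(FamilyPValues(
            family_id=taxon,
            component_pvalues=np.array([stats_by[(taxon, c)][3] for c in codes]),
            component_ids=tuple(str(catalogue[c]) for c in codes),
        ))

    if not families:
        return StratumPatternResult(label, None, (), tuple(audit), tuple(skipped))

    decision = mdfdr_decide(families, config.alpha)
    rejected = {(fid, cid) for fid, cid, _ in decision.rejected_components()}
    levels = dict(zip(decision.family_ids, decision.component_levels))

    findings: list[PatternFinding] = []
    for taxon, codes in per_taxon.items():
        for c in codes:
            n, m, s, p = stats_by[(taxon, c)]
            pat_str = str(catalogue[c])
            is_rej = (taxon, pat_str) in rejected
            audit.append({
                "stratum": label, "taxon": taxon, "pattern": pat_str,
                "n": n, "mean": m, "se": s, "equivalence_p": p,
                "alpha_star": levels.get(taxon, 0.0) if decision.R else 0.0,
                "rejected": is_rej,
            })
            if not is_rej:
                continue
            entry = Pattern(tuple(pat_str), taxon=taxon)
            alpha_star = levels[taxon]
            pvalue_fn = lambda q: _equivalence_p_of_group(  # noqa: E731
                match_subjects(cohort, q), config.delta
            )
            trail = sequential_reduction(entry, pvalue_fn, alpha_star)
            final = trail.final_pattern
            fgroup = match_subjects(cohort, final)
            finding = PatternFinding(
                stratum=label, taxon=taxon, entry_pattern=entry, entry_p=p,
                alpha_star=alpha_star, reduction_trail=trail,
                final_pattern=final, group=fgroup,
                equivalence_p=trail.final_step.p_value,
            )
            findings.append(posthoc_screen(finding, cohort, config))

    return StratumPatternResult(label, decision, tuple(findings),
                                tuple(audit), tuple(skipped))


def run_pattern_analysis(
    cohort: CohortTable, config: AnalysisConfig | None = None
) -> PatternAnalysisResult:
    """Run the full pattern pipeline, stratified.

    Deterministic in (cohort, config); an empty cohort or a stratum with no
    testable pattern yields empty results, never an error.
    """
    config = config or AnalysisConfig()
    strata = split_strata(cohort) if config.stratify else {"all": cohort}
    out = []
    for label, sub in strata.items():
        if sub.n_subjects < 2:
            logger.warning("skip stratum=%s reason=too_few_subjects n=%d",
                           label, sub.n_subjects)
            continue
        out.append(_analyse_stratum(label, sub, config))
        for taxon, reason in out[-1].skipped_taxa:
            logger.info("skip stratum=%s taxon=%s reason=%s", label, taxon, reason)
    return PatternAnalysisResult(tuple(out), config)
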