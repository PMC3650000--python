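# Methods

This note documents the statistical model, the procedural choices that were
genuinely open, the synthetic-data generator, and the limits of what the
package's validation can show.

## Data model and missingness

A cohort is n subjects × (stratum, outcome ΔZ, J×T binary detections).
ΔZ is the change in weight-for-age Z-score between birth and ~6 months;
|ΔZ| ≤ 0.67 is the conventional band for growth "as expected", and that
same 0.67 is used as the equivalence margin δ (both configurable).

Missing values are preserved, never imputed. Two analysis populations are
used deliberately:

- **Pattern analysis — complete case per taxon.** A subject contributes to
  a taxon's pattern analysis only with detection observed at *all* T days
  for that taxon (and a non-missing outcome). A four-day pattern is
  otherwise undefined, and this is the only policy under which the 2^T
  full patterns exactly partition the analysable subjects and reduced
  patterns are supersets of their parents.
- **Time-specific analysis — available case.** A subject contributes to
  the (j, t) regression when detection at (j, t) and the outcome are both
  observed.

The frequency floor for testable patterns (default 15%) is evaluated
against the taxon's complete-case count within the stratum — frequencies
must refer to the population actually analysable — and the floor is
inclusive: only strictly rarer patterns are excluded. Intensities exactly
at a detection threshold dichotomise to non-detected ("detected" means
strictly above the limit).

Strata (infant sex by default) are analysed fully independently: separate
complete-case sets, separate frequency filters, separate mdFDR runs. One
stratum-level analysis is therefore the unit of error control, and the
Monte-Carlo harness accounts accordingly (below).

## The two-level mdFDR controller

Families j = 1..n (taxa) each hold m_j component p-values (days, or
testable patterns). The controller: (1) Bonferroni pool,
p̃_j = min(1, m_j min_k p_jk); (2) Benjamini–Hochberg step-up across the n
pooled p-values at level α, rejecting R families; (3) inside each rejected
family, reject components with p_jk ≤ α\*_j = R·α/(n·m_j). With equal
family sizes this is the classical symmetric two-level procedure; the
per-family form keeps the Bonferroni budget exact when inestimable
components shrink a family (a constant detection column reduces m_j rather
than entering as p = 1, which would be needlessly conservative).

The *mixed directional* error being controlled counts a component
rejection as false when the component is truly null or, in the directional
time-specific setting, when the estimated sign of the effect is wrong.

## Sequential reduction

A rejected pattern may carry superfluous late days. Starting from the
entry level L = α\*: if the current pattern's p-value is ≤ L/2, the
right-reduced pattern is tested at level L/2; on success it becomes
current with L ← L/2. The cascade stops at the first failed gate, failed
test, or single-day pattern. Splitting each level into two equal Bonferroni
halves — one retained by the standing rejection, one funding the next
test — guarantees the entry rejection is never revoked and the total spend
stays within α\*. Equal halving is the symmetric choice; the split is
isolated in `mdfdr.sequential_reduction` so alternative allocations can be
swapped in one place. Only right-side reduction is offered: an exposure at
day 120 cannot confound earlier exposures, while an early exposure can
influence later ones.

## Post-hoc screening

A pattern "significantly close to zero" is only interesting if deviating
from it is associated with deviant growth. The crude contrast (all
relevant symbols flipped) of the *final, reduced* pattern is therefore
tested for difference from zero (one-sample t, default level 0.05); a
non-significant or inconclusive (n < 2, zero-variance) contrast discards
the finding. A significant contrast triggers a Welch two-sample test of
pattern vs contrast means, reported at a relaxed level (default 0.10,
reflecting the smaller combined sample) as a tier: strict (≤ 0.05),
nominal (≤ 0.10), none. The Welch tier annotates but never discards.
Discarded findings remain in the audit table; they are only removed from
the significant-findings report.

## Statistical primitives

Equivalence uses two one-sided Student-t tests (intersection–union): with
pattern groups as small as ~15% of a ~110-subject stratum, the t reference
is the conservative standard choice over a normal approximation, and each
group uses its own sample standard error (no pooling across patterns).
p = 0.5 exactly when |μ̂| = δ; the p-value is increasing in |μ̂| and
decreasing in δ. The per-day regression on a 0/1 indicator is computed in
closed form (it is exactly the pooled two-sample t-test); Welch uses
Satterthwaite degrees of freedom via scipy.

## Synthetic cohorts

`generate_cohort` draws, per subject and taxon, detection at the first day
from Bernoulli(q_init) and subsequent days from a first-order Markov chain
that keeps the previous state with probability `persistence` (one scalar
for both 1→1 and 0→0: the single knob keeps null calibrations
interpretable; taxa are mutually independent). The outcome is
Normal(μ(pattern of one designated driver taxon), σ). Defaults:

| parameter | default | rationale |
|---|---|---|
| n_per_stratum | 110 | two sex strata of ~110 infants |
| n_taxa, days | 22; 4, 10, 30, 120 | the motivating design |
| q_init | 0.5 | per-probe prevalences unavailable; maximal-entropy default |
| persistence | 0.8 | colonising microbes persist; stated simulation condition |
| baseline_mean | −0.24 ΔZ | moment-matched to the reported tails (16.7% > 0.67, 32.2% < −0.67) |
| outcome_sd | 0.94 ΔZ | same moment match |
| missing_rate | 0.0 | calibration scenarios have none; MCAR knob for robustness tests |

Replicate seeds are spawned from the master seed with
`numpy.random.SeedSequence.spawn`, so any replicate is reproducible in
isolation.

Ground truth is analytic: pattern probabilities have closed form under the
chain, so each (taxon, pattern) group's true mean — the planted mean for
the driver, the prevalence-weighted marginal for the independent taxa —
and each (taxon, day) true detection effect are computed exactly. With a
planted single-day effect, later days of the driver taxon are correlated
exposures (persistence > 1/2) and are labelled non-null with the effect's
sign, not as nulls.

### Canonical scenarios

- **All-deviant (pattern-pipeline null):** every pattern mean at +1.0 ΔZ,
  outside δ = 0.67, so every equivalence rejection is a false discovery.
  2,000 replicates at full cohort scale (2 × 110 × 22 × 4) run in ~10 s.
- **Global null (time-specific):** outcome independent of all detections;
  1,000 replicates. Empirical mdFDR ≈ 0.04–0.05 at α = 0.05 (Bonferroni
  pooling is slightly conservative under within-family dependence).
- **Recovery:** one stratum of 108, driver q_init = 0.7 (early
  staphylococcal colonisation is common), persistence 0.8; subjects
  detected at day 4 have mean ΔZ 0, all others −1.0. The pipeline should
  reject the frequent day-4-detected full patterns, reduce them to `+XXX`,
  and keep the finding through the contrast screen; recovery is tracked as
  the fraction of replicates reporting `+XXX` unscreened and rises with
  stratum size (near 0 at n = 50 — the entry test lacks power — majority
  at 108, ~1 at 400).

### mdFDR accounting

The harness scores false/total component rejections at the controller
stage (the 4-day testable patterns, or the taxon-day effects); the
reduction cascade only truncates already-rejected patterns and cannot add
rejections. Because strata are controlled independently, one replicate
contributes one false-discovery proportion *per stratum analysis*; pooling
rejections across strata instead would measure the union error of two
separate procedures (≈ 2α under a global null) — an estimand no FDR
procedure claims to control. The reported Monte-Carlo standard error uses
the Bernoulli bound √(p̂(1−p̂)/N), an upper bound for proportions in [0, 1].

## What passing these simulations does and does not show

The generator reproduces the *structure* the analyses assume — strata,
Markov-persistent detection, approximately Normal outcome — but real data
differ in ways the harness does not emulate: taxa are not independent
(cross-feeding, shared ecological niches), detection is an imperfect proxy
for abundance with assay-specific thresholds, ΔZ need not be homoscedastic
across pattern groups, and missingness in real cohorts is rarely MCAR.
Calibration under these simulations therefore validates the procedure's
arithmetic and its error control under its own assumptions, not robustness
to violations of them. The method also cannot adjust for confounding; its
intended use on confounded data is reference-pattern *selection*, followed
by a conventional regression strategy.

## Numerical details

- BH ties are broken by index; this cannot change R or the rejected set of
  p-values.
- Degenerate groups (n < 2 or zero variance) are inestimable: excluded
  from families (time-specific), given p = 1 inside the reduction cascade
  (stopping it), and "inconclusive → discard" in screening.
- All tables are deterministic functions of (cohort, config); the CLI
  writes a manifest (config snapshot, input digests, seed, version) and
  identical manifests yield byte-identical tables.
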