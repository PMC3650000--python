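"""Two-level mixed directional FDR control and the sequential reduction cascade.

Hypotheses are organised into families (one per taxon) of components (time
points, or testable detection patterns).  The controller:

1. pools each family's component p-values by Bonferroni
   (``min(1, m_j * min_k p_jk)``),
2. selects families with the Benjamini-Hochberg step-up at level ``alpha``
   applied to the pooled p-values (R families rejected),
3. tests components inside rejected families at the adjusted level
   ``alpha* = R * alpha / (n * m_j)``, where n is the number of families
   and m_j the family's component count.

With equally sized families this is the classical symmetric two-level
procedure; unequal ``m_j`` keep the per-family Bonferroni budget exact.

A rejected pattern can then enter the *sequential reduction* cascade: an
alpha-recycling scheme that tests progressively right-truncated patterns at
geometrically halved levels.  At each stage the current level L is split in
two Bonferroni halves — one to keep the already-won rejection safe, one to
fund the next test — so the entry rejection can never be revoked, whatever
the cascade does afterwards.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .patterns import Pattern


@dataclass(frozen=True)
class FamilyPValues:
    """One family's component p-values (e.g. one taxon's time points)."""

    family_id: str
    component_pvalues: np.ndarray
    component_ids: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.component_pvalues, dtype=float)
        object.__setattr__(self, "component_pvalues", p)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))
        if p.ndim != 1 or p.size < 1:
            raise ValueError("a family needs at least one component p-value")
        if len(self.component_ids) != p.size:
            raise ValueError("component_ids length mismatch")
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValueError(f"p-values outside [0, 1] in family {self.family_id!r}")

    @property
    def m(self) -> int:
        return int(self.component_pvalues.size)


def bonferroni_pool(family: FamilyPValues) -> float:
    """Family-level p-value: ``min(1, m_j * min_k p_jk)``."""
    return float(min(1.0, family.m * family.component_pvalues.min()))


def bh_select(pooled, alpha: float) -> tuple[int, np.ndarray]:
    """Benjamini-Hochberg step-up on a vector of p-values.

    Returns ``(R, rejected)`` where R = max{k : p_(k) <= k * alpha / n}
    (0 when no k qualifies) and ``rejected`` is a boolean mask selecting
    the R smallest p-values (ties broken by index, which cannot change R).
    """
    p = np.asarray(pooled, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need at least one p-value")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    n = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha * np.arange(1, n + 1) / n
    passing = np.flatnonzero(p[order] <= thresholds)
    R = int(passing[-1] + 1) if passing.size else 0
    rejected = np.zeros(n, dtype=bool)
    rejected[order[:R]] = True
    return R, rejected


@dataclass(frozen=True)
class MdfdrDecision:
    """Full record of one two-level testing pass.

    ``component_levels[j]`` is the adjusted level alpha*_j applied inside
    family j (0 where the family was not rejected or R = 0);
    ``component_rejections[j]`` the per-component flags.
    """

    alpha: float
    family_ids: tuple
    pooled_pvalues: np.ndarray
    R: int
    family_rejections: np.ndarray
    component_levels: tuple
    component_rejections: tuple

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    def n_component_rejections(self) -> int:
        return int(sum(flags.sum() for flags in self.component_rejections))

    def rejected_components(self) -> list[tuple[str, object, float]]:
        """(family_id, component_id, component_level) for every rejection."""
        out = []
        for fid, level, flags, ids in zip(
            self.family_ids, self.component_levels,
            self.component_rejections, self._component_ids,
        ):
            for cid, flag in zip(ids, flags):
                if flag:
                    out.append((fid, cid, level))
        return out

    # stored separately to keep the dataclass fields array-friendly
    _component_ids: tuple = field(default=(), repr=False)


def mdfdr_decide(families: Sequence[FamilyPValues], alpha: float) -> MdfdrDecision:
    """Run the full two-level procedure over a set of families."""
    families = list(families)
    if not families:
        raise ValueError("need at least one family")
    pooled = np.array([bonferroni_pool(f) for f in families])
    R, fam_rej = bh_select(pooled, alpha)
    n = len(families)
    levels: list[float] = []
    comp_rej: list[np.ndarray] = []
    for f, rejected in zip(families, fam_rej):
        if R == 0 or not rejected:
            levels.append(0.0)
            comp_rej.append(np.zeros(f.m, dtype=bool))
        else:
            level = R * alpha / (n * f.m)
            levels.append(level)
            comp_rej.append(f.component_pvalues <= level)
    return MdfdrDecision(
        alpha=float(alpha),
        family_ids=tuple(f.family_id for f in families),
        pooled_pvalues=pooled,
        R=R,
        family_rejections=fam_rej,
        component_levels=tuple(levels),
        component_rejections=tuple(comp_rej),
        _component_ids=tuple(f.component_ids for f in families),
    )


# ---------------------------------------------------------------------------
# Sequential reduction


@dataclass(frozen=True)
class ReductionStep:
    """One stage of the cascade: the pattern held, its p-value, the level it
    was tested at, the gate it had to clear to fund the next test, and
    whether the cascade continued past it."""

    pattern: Pattern
    p_value: float
    level: float
    gate: float
    continued: bool


@dataclass(frozen=True)
class ReductionTrail:
    """The cascade's audit trail; ``final_pattern`` is the reported one."""

    steps: tuple[ReductionStep, ...]
    final_pattern: Pattern

    @property
    def final_step(self) -> ReductionStep:
        return self.steps[-1]


def sequential_reduction(
    pattern: Pattern,
    pvalue_fn: Callable[[Pattern], float],
    alpha_star: float,
) -> ReductionTrail:
    """Right-truncate an already-rejected pattern at halved levels.

    Entry requires ``pvalue_fn(pattern) <= alpha_star``.  With current level
    L (starting at alpha_star): if the current p-value clears the gate L/2,
    the right-reduced pattern is tested at level L/2; on success it becomes
    current with L <- L/2 and the cascade continues.  The cascade stops at
    the first failed gate, failed test, or irreducible (single relevant day)
    pattern.  The entry rejection is never revoked.
    """
    if not 0.0 < alpha_star < 1.0:
        raise ValueError(f"alpha_star must lie in (0, 1), got {alpha_star}")
    p_current = float(pvalue_fn(pattern))
    if not p_current <= alpha_star:
        raise ValueError(
            f"pattern {pattern} enters the cascade only if already rejected: "
            f"p = {p_current} > alpha* = {alpha_star}"
        )
    steps: list[ReductionStep] = []
    current, level = pattern, alpha_star
    while True:
        gate = level / 2.0
        if current.n_relevant < 2:   # irreducible: nothing left to drop
            steps.append(ReductionStep(current, p_current, level, gate, False))
            break
        if p_current > gate:         # not enough alpha left to fund a new test
            steps.append(ReductionStep(current, p_current, level, gate, False))
            break
        reduced = current.reduce_right()
        p_reduced = float(pvalue_fn(reduced))
        if p_reduced <= gate:
            steps.append(ReductionStep(current, p_current, level, gate, True))
            current, p_current, level = reduced, p_reduced, gate
        else:                        # reduced pattern not significant; keep current
            steps.append(ReductionStep(current, p_current, level, gate, False))
            break
    return ReductionTrail(steps=tuple(steps), final_pattern=current)
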