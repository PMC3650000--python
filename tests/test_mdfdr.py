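"""Two-level mdFDR controller and the sequential reduction cascade."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutpatterns import (
    FamilyPValues,
    Pattern,
    bh_select,
    bonferroni_pool,
    mdfdr_decide,
    sequential_reduction,
)


def bh_oracle(pvalues, alpha):
    """Brute force: check every k in the step-up definition."""
    p = sorted(pvalues)
    n = len(p)
    R = 0
    for k in range(1, n + 1):
        if p[k - 1] <= k * alpha / n:
            R = k
    return R


def literal_two_level_oracle(families, alpha):
    """Straight-line restatement of the two-level procedure.

    families: list of lists of p-values.  Returns (R, set of (i, k) rejected
    components).  Written without reusing any package internals.
    """
    n = len(families)
    pooled = [min(1.0, len(f) * min(f)) for f in families]
    R = bh_oracle(pooled, alpha)
    if R == 0:
        return 0, set()
    cutoff = sorted(pooled)[R - 1]
    rejected_fams = [i for i, p in enumerate(pooled) if p <= cutoff][:R]
    out = set()
    for i in rejected_fams:
        level = R * alpha / (n * len(families[i]))
        for k, p in enumerate(families[i]):
            if p <= level:
                out.add((i, k))
    return R, out


class TestBonferroniPool:
    def test_examples(self):
        fam = FamilyPValues("t", [0.01, 0.5, 0.2, 0.8], tuple(range(4)))
        assert bonferroni_pool(fam) == pytest.approx(0.04)
        fam = FamilyPValues("t", [1.0, 1.0, 1.0, 1.0], tuple(range(4)))
        assert bonferroni_pool(fam) == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_dominates_every_subset_bound(self, ps):
        fam = FamilyPValues("t", ps, tuple(range(len(ps))))
        pooled = bonferroni_pool(fam)
        # the pool must be a valid p-value bound for the family intersection:
        # at least as large as the best Bonferroni bound over the family itself
        assert pooled >= min(1.0, len(ps) * min(ps)) - 1e-15
        assert 0.0 <= pooled <= 1.0

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            FamilyPValues("t", [], ())


class TestBhSelect:
    def test_worked_example(self):
        R, rejected = bh_select([0.001, 0.02, 0.04, 0.9], 0.05)
        assert R == 2
        np.testing.assert_array_equal(rejected, [True, True, False, False])

    @pytest.mark.parametrize("p,expected", [([1.0] * 5, 0), ([0.0] * 5, 5)])
    def test_degenerate_vectors(self, p, expected):
        R, rejected = bh_select(p, 0.05)
        assert R == expected
        assert rejected.sum() == expected

    def test_matches_brute_force_on_many_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 11))
            p = rng.random(n) ** rng.uniform(0.5, 3.0)  # vary the p spectrum
            alpha = float(rng.uniform(0.01, 0.3))
            R, rejected = bh_select(p, alpha)
            assert R == bh_oracle(p, alpha)
            assert rejected.sum() == R
            # the rejected set is exactly the R smallest p-values
            if 0 < R < n:
                assert p[rejected].max() <= p[~rejected].min() + 1e-15

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 15)))
            reject_sm = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            _, rejected = bh_select(p, 0.05)
            np.testing.assert_array_equal(rejected, reject_sm)


class TestMdfdrDecide:
    def test_single_trivial_family(self):
        dec = mdfdr_decide([FamilyPValues("a", [0.01], ("x",))], alpha=0.05)
        assert dec.R == 1
        assert dec.component_levels[0] == pytest.approx(0.05)
        assert dec.rejected_components() == [("a", "x", pytest.approx(0.05))]

    def test_all_ones_reject_nothing(self):
        fams = [FamilyPValues(f"f{i}", [1.0, 1.0], ("a", "b")) for i in range(4)]
        dec = mdfdr_decide(fams, 0.05)
        assert dec.R == 0
        assert dec.n_component_rejections() == 0
        assert all(level == 0.0 for level in dec.component_levels)

    def test_matches_literal_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 8))
            fams_raw = [
                list(rng.random(int(rng.integers(1, 6))) ** 2) for _ in range(n)
            ]
            alpha = float(rng.uniform(0.02, 0.2))
            fams = [
                FamilyPValues(f"f{i}", ps, tuple(range(len(ps))))
                for i, ps in enumerate(fams_raw)
            ]
            dec = mdfdr_decide(fams, alpha)
            R_exp, comps_exp = literal_two_level_oracle(fams_raw, alpha)
            assert dec.R == R_exp
            got = {
                (int(fid[1:]), cid) for fid, cid, _ in dec.rejected_components()
            }
            assert got == comps_exp

    @given(
        st.lists(
            st.lists(st.floats(0, 1), min_size=1, max_size=5),
            min_size=1, max_size=6,
        ),
        st.floats(0.01, 0.3),
    )
    def test_no_orphan_components(self, fams_raw, alpha):
        fams = [
            FamilyPValues(f"f{i}", ps, tuple(range(len(ps))))
            for i, ps in enumerate(fams_raw)
        ]
        dec = mdfdr_decide(fams, alpha)
        rejected_fams = set(np.array(dec.family_ids)[dec.family_rejections])
        for fid, _, _ in dec.rejected_components():
            assert fid in rejected_fams
        if dec.R == 0:
            assert dec.n_component_rejections() == 0


class TestSequentialReduction:
    def test_cascade_stops_when_level_budget_runs_out(self):
        # p = 0.004 for every pattern depth, entry level 0.01:
        # 4-day pattern clears the 0.005 gate and the 3-day test (0.004 <=
        # 0.005), but 0.004 > 0.0025 blocks the next stage
        trail = sequential_reduction(
            Pattern.from_string("++++", taxon="t"), lambda q: 0.004, alpha_star=0.01
        )
        assert str(trail.final_pattern) == "+++X"
        assert [s.level for s in trail.steps] == [0.01, 0.005]

    def test_gate_can_fail_immediately(self):
        trail = sequential_reduction(
            Pattern.from_string("++++", taxon="t"), lambda q: 0.004, alpha_star=0.005
        )
        assert str(trail.final_pattern) == "++++"
        assert len(trail.steps) == 1
        assert not trail.steps[0].continued

    def test_all_gates_pass_reduces_to_first_day(self):
        trail = sequential_reduction(
            Pattern.from_string("+-+-", taxon="t"), lambda q: 0.0, alpha_star=0.01
        )
        assert str(trail.final_pattern) == "+XXX"
        assert [s.level for s in trail.steps] == [0.01, 0.005, 0.0025, 0.00125]

    def test_entry_precondition_enforced(self):
        with pytest.raises(ValueError, match="already rejected"):
            sequential_reduction(
                Pattern.from_string("++++", taxon="t"), lambda q: 0.2, alpha_star=0.05
            )

    @given(
        p_by_depth=st.lists(st.floats(0, 0.05), min_size=4, max_size=4),
        alpha_star=st.floats(0.001, 0.05),
    )
    def test_entry_never_revoked_and_levels_halve(self, p_by_depth, alpha_star):
        pvals = {4 - i: p for i, p in enumerate(p_by_depth)}
        if pvals[4] > alpha_star:
            return  # entry precondition not met; nothing to check
        trail = sequential_reduction(
            Pattern.from_string("++++", taxon="t"),
            lambda q: pvals[q.n_relevant],
            alpha_star,
        )
        # the entry pattern heads the trail and stays rejected at alpha*
        assert str(trail.steps[0].pattern) == "++++"
        assert trail.steps[0].p_value <= alpha_star
        for i, step in enumerate(trail.steps):
            assert step.level == pytest.approx(alpha_star / 2**i)
            assert step.p_value <= step.level
        # every reported pattern was significant at the level it was tested
        assert trail.final_step.p_value <= trail.final_step.level
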