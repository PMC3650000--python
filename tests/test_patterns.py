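"""Pattern engine: enumeration, matching, frequency filter, contrast, reduction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gutpatterns as gp
from gutpatterns import Pattern, enumerate_patterns, match_subjects
from gutpatterns import testable_patterns as find_testable
from gutpatterns.patterns import DET, IRR, NON, PatternError, pattern_codes


def full_patterns(max_len=6):
    return st.integers(1, max_len).flatmap(
        lambda n: st.tuples(*([st.sampled_from((DET, NON))] * n))
    ).map(lambda sym: Pattern(sym))


def reduced_patterns(max_len=6):
    def build(draw_len):
        n, k = draw_len
        return st.tuples(*([st.sampled_from((DET, NON))] * k)).map(
            lambda head: Pattern(head + (IRR,) * (n - k))
        )
    return st.tuples(st.integers(1, max_len), st.integers(1, max_len)).filter(
        lambda t: t[1] <= t[0]
    ).flatmap(build)


class TestPatternType:
    def test_parse_render_round_trip(self):
        for text in ("+-+-", "++XX", "+XXX", "-"):
            assert str(Pattern.from_string(text)) == text

    @pytest.mark.parametrize("bad", ["XXXX", "+X+X", "X+++", "", "+0--"])
    def test_invalid_patterns_rejected(self, bad):
        with pytest.raises(PatternError):
            Pattern.from_string(bad)

    @given(reduced_patterns())
    def test_contrast_is_involution_and_moves(self, pattern):
        flipped = pattern.crude_contrast()
        assert flipped.crude_contrast() == pattern
        assert flipped != pattern

    def test_contrast_examples(self):
        assert str(Pattern.from_string("++XX").crude_contrast()) == "--XX"
        assert str(Pattern.from_string("+-+-").crude_contrast()) == "-+-+"

    def test_reduce_right_examples(self):
        assert str(Pattern.from_string("++++").reduce_right()) == "+++X"
        assert str(Pattern.from_string("+-XX").reduce_right()) == "+XXX"
        with pytest.raises(PatternError, match="at least one relevant"):
            Pattern.from_string("+XXX").reduce_right()

    @given(full_patterns())
    def test_full_reduction_chain_ends_at_first_day(self, pattern):
        current = pattern
        for _ in range(len(pattern) - 1):
            current = current.reduce_right()
        assert current.n_relevant == 1
        assert current.symbols[0] == pattern.symbols[0]


class TestEnumeration:
    @pytest.mark.parametrize("T,count", [(1, 2), (3, 8), (4, 16)])
    def test_counts_and_distinctness(self, T, count):
        patterns = enumerate_patterns(T)
        assert len(patterns) == count
        assert len(set(patterns)) == count
        assert all(p.is_full for p in patterns)

    def test_catalogue_order_detected_first(self):
        patterns = [str(p) for p in enumerate_patterns(4)]
        assert patterns[0] == "++++"
        assert patterns[-1] == "----"
        # catalogue number 8 (1-based): detection at day 4 then non-detection
        assert patterns[7] == "+---"

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            enumerate_patterns(0)

    def test_codes_agree_with_catalogue_order(self, rng):
        det = (rng.random((50, 4)) < 0.5).astype(float)
        codes = pattern_codes(det)
        catalogue = enumerate_patterns(4)
        for row, code in zip(det, codes):
            expected = "".join(DET if v else NON for v in row)
            assert str(catalogue[code]) == expected


class TestMatching:
    def test_hand_enumerated_roster(self, tiny_cohort):
        group = match_subjects(tiny_cohort, Pattern.from_string("+++-", taxon="probe1"))
        assert set(group.subject_ids) == {"s1", "s2"}
        assert group.n == 2
        assert group.mean == pytest.approx(np.mean([0.1, -0.2]))

    def test_first_day_only_pattern_matches_all_detected(self, tiny_cohort):
        group = match_subjects(tiny_cohort, Pattern.from_string("+XXX", taxon="probe1"))
        assert set(group.subject_ids) == {"s1", "s2", "s3", "s5"}

    def test_zero_match_is_flagged_not_raised(self, tiny_cohort):
        group = match_subjects(tiny_cohort, Pattern.from_string("-+-+", taxon="probe1"))
        assert group.n == 0
        assert np.isnan(group.mean) and np.isnan(group.se)
        assert not group.estimable

    def test_pattern_without_taxon_rejected(self, tiny_cohort):
        with pytest.raises(PatternError, match="taxon"):
            match_subjects(tiny_cohort, Pattern.from_string("+++-"))

    def test_full_patterns_partition_complete_cases(self, rng):
        cohort = gp.generate_cohort(gp.SimulationConfig(seed=11, missing_rate=0.15))
        taxon = cohort.taxon_names[3]
        groups = [
            match_subjects(cohort, Pattern(p.symbols, taxon=taxon))
            for p in enumerate_patterns(4)
        ]
        from gutpatterns.patterns import _complete_case_mask
        n_complete = int(_complete_case_mask(cohort, 3).sum())
        assert sum(g.n for g in groups) == n_complete

    def test_reduction_never_shrinks_the_group(self):
        cohort = gp.generate_cohort(gp.SimulationConfig(seed=13, missing_rate=0.1))
        taxon = cohort.taxon_names[0]
        pattern = Pattern.from_string("++--", taxon=taxon)
        while True:
            parent = set(match_subjects(cohort, pattern).subject_ids)
            if pattern.n_relevant < 2:
                break
            pattern = pattern.reduce_right()
            child = set(match_subjects(cohort, pattern).subject_ids)
            assert child >= parent


class TestTestablePatterns:
    def _cohort_with_counts(self, counts):
        """One-taxon, 4-day cohort realising exact full-pattern counts."""
        catalogue = enumerate_patterns(4)
        rows, ids = [], []
        for code, k in counts.items():
            sym = catalogue[code].symbols
            for i in range(k):
                ids.append(f"c{code}_{i}")
                rows.append([[1.0 if s == DET else 0.0 for s in sym]])
        n = len(ids)
        rng = np.random.default_rng(0)
        return gp.CohortTable(
            subject_ids=np.array(ids, dtype=object),
            stratum=np.array(["F"] * n, dtype=object),
            outcome=rng.normal(size=n),
            detections=np.array(rows, dtype=float),
            taxon_names=("tax",),
            timepoint_days=(4, 10, 30, 120),
        )

    def test_frequency_floor_is_inclusive(self):
        # 15 / 100 == 15%: testable; 10 / 100: excluded
        cohort = self._cohort_with_counts({0: 15, 1: 10, 2: 40, 3: 35})
        groups = find_testable(cohort, "tax", min_freq=0.15)
        kept = {str(g.pattern) for g in groups}
        assert "++++" in kept          # exactly at the floor
        assert "+++-" not in kept      # strictly below the floor
        assert kept == {"++++", "++-+", "++--"}

    def test_single_shared_pattern(self):
        cohort = self._cohort_with_counts({5: 30})
        groups = find_testable(cohort, "tax", min_freq=0.15)
        assert len(groups) == 1
        assert groups[0].n == 30

    def test_empty_complete_case_set(self, tiny_cohort):
        empty = tiny_cohort.subset(np.zeros(5, dtype=bool))
        assert find_testable(empty, "probe1") == []

    def test_bad_min_freq(self, tiny_cohort):
        with pytest.raises(ValueError):
            find_testable(tiny_cohort, "probe1", min_freq=1.5)
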