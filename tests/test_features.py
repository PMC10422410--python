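"""Feature extraction: the 13 trail-making gaze features and their oracles."""

import itertools
from functools import lru_cache

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etmt import (Fixation, ImpairmentProfile, assemble_features,
                  error_rate, inattentional_blindness, levenshtein,
                  low_level, aoi_level, scanpath_score, scanpath_string,
                  simulate_trial, total_time)
from etmt.features import extract_trial_features, wrong_token_count
from etmt.gaze_io import TrialRecord
from etmt.stimulus import STIMULUS_IDS

# the printed worked-example trail: one stray revisit of target 6 before
# settling into the correct ascending order
WORKED_SCANPATH = "6 1 2 3 4 5 6 7 8".split()


# ---------------------------------------------------------------------------
# Independent oracles

def lev_oracle(a, b):
    """Plain recursive edit distance (memoized), independent of the DP."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(rec(i - 1, j) + 1,
                   rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]))

    return rec(len(a), len(b))


def ib_oracle(seq, min_len=2):
    """Exhaustive repeated-run scan: collects every earlier window of every
    length, then walks the sequence."""
    seq = tuple(seq)
    count = 0
    i = 0
    while i < len(seq):
        found = 0
        for length in range(min_len, min(len(seq) - i, i) + 1):
            earlier = {seq[j:j + length] for j in range(i - length + 1)}
            if seq[i:i + length] in earlier:
                found = length
        if found:
            count += 1
            i += found
        else:
            i += 1
    return count


# ---------------------------------------------------------------------------
# Low level

class TestLowLevel:
    def test_hand_arithmetic(self):
        fx = [Fixation(i * 250, 200, 0, 0) for i in range(3)]
        ll = low_level(fx, 800)
        assert (ll.FL1, ll.FL2, ll.FL3, ll.FL4) == (3, 600, 75.0, 200)

    def test_empty(self):
        ll = low_level([], 1000)
        assert (ll.FL1, ll.FL2, ll.FL3, ll.FL4) == (0, 0, 0.0, 0.0)

    def test_full_trial_fixation(self):
        assert low_level([Fixation(0, 1000, 0, 0)], 1000).FL3 == 100.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            low_level([], 0)


# ---------------------------------------------------------------------------
# Middle level (per AOI)

def fix_at(layout, label, onset, duration):
    a = layout.aoi(label)
    return Fixation(onset, duration, a.cx, a.cy)


class TestAoiLevel:
    def test_revisit_hand_trace(self, tmt_a_simple):
        # AOI 3: 250 ms, elsewhere, then 150 ms back -> two runs, one revisit
        fx = [fix_at(tmt_a_simple, "3", 0, 250),
              fix_at(tmt_a_simple, "1", 300, 200),
              fix_at(tmt_a_simple, "3", 600, 150)]
        by = {a.label: a for a in aoi_level(fx, tmt_a_simple, 1000)}
        a3 = by["3"]
        assert (a3.FM1, a3.FM3, a3.FM4, a3.FM5) == (400, 2, 1, 250)
        assert a3.FM2 == pytest.approx(40.0)

    def test_unvisited_aoi_all_zero(self, tmt_a_simple):
        by = {a.label: a for a in aoi_level([], tmt_a_simple, 1000)}
        assert all((a.FM1, a.FM2, a.FM3, a.FM4, a.FM5) == (0, 0.0, 0, 0, 0.0)
                   for a in by.values())

    def test_consecutive_fixations_one_run(self, tmt_a_simple):
        fx = [fix_at(tmt_a_simple, "2", 0, 100),
              fix_at(tmt_a_simple, "2", 150, 100)]
        a2 = {a.label: a for a in aoi_level(fx, tmt_a_simple, 1000)}["2"]
        assert (a2.FM3, a2.FM4) == (2, 0)

    def test_dwell_bounded_by_total_fixation_time(self, tmt_a_simple):
        trial = simulate_trial(ImpairmentProfile(stray_prob=0.3, revisit_prob=0.3),
                               tmt_a_simple, seed=9)
        tf = extract_trial_features(trial, tmt_a_simple)
        assert sum(a.FM1 for a in tf.aoi) <= tf.low.FL2 + 1e-9


# ---------------------------------------------------------------------------
# Scanpath string

class TestScanpathString:
    def test_visit_order(self, tmt_a_simple):
        labels = WORKED_SCANPATH
        fx = [fix_at(tmt_a_simple, lbl, i * 100, 80) for i, lbl in enumerate(labels)]
        assert scanpath_string(fx, tmt_a_simple) == labels

    def test_out_of_aoi_contributes_nothing(self, tmt_a_simple):
        fx = [Fixation(0, 100, -50, -50)]
        assert scanpath_string(fx, tmt_a_simple) == []

    def test_collapse_of_consecutive_duplicates(self, tmt_a_simple):
        fx = [fix_at(tmt_a_simple, "3", 0, 100),
              fix_at(tmt_a_simple, "3", 150, 100),
              fix_at(tmt_a_simple, "4", 300, 100)]
        assert scanpath_string(fx, tmt_a_simple) == ["3", "4"]
        assert scanpath_string(fx, tmt_a_simple, collapse=False) == ["3", "3", "4"]


# ---------------------------------------------------------------------------
# Levenshtein / scanpath score

class TestLevenshtein:
    def test_identity(self):
        assert levenshtein(list("abc"), list("abc")) == 0

    def test_worked_example(self, tmt_a_simple):
        assert levenshtein(WORKED_SCANPATH, tmt_a_simple.expected_sequence) == 1

    def test_kitten_sitting(self):
        assert levenshtein(list("kitten"), list("sitting")) == lev_oracle("kitten", "sitting") == 3

    def test_multi_character_tokens_are_atomic(self):
        assert levenshtein(["12"], ["1", "2"]) == 2

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from("abcd"), max_size=6),
           st.lists(st.sampled_from("abcd"), max_size=6))
    def test_matches_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == lev_oracle(a, b)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from("abc"), max_size=5),
           st.lists(st.sampled_from("abc"), max_size=5),
           st.lists(st.sampled_from("abc"), max_size=5))
    def test_symmetry_and_triangle(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    def test_cross_check_against_edlib(self):
        import edlib
        pairs = [("kitten", "sitting"), ("abcd", ""), ("aab", "baa"), ("xyz", "xzy")]
        for s1, s2 in pairs:
            assert levenshtein(list(s1), list(s2)) == \
                edlib.align(s1, s2, task="distance")["editDistance"]


class TestScanpathScore:
    def test_perfect_trail(self, tmt_a_simple):
        assert scanpath_score(tmt_a_simple.expected_sequence, tmt_a_simple) == 0

    def test_worked_example(self, tmt_a_simple):
        assert scanpath_score(WORKED_SCANPATH, tmt_a_simple) == 1

    def test_empty_observed_costs_expected_length(self, tmt_a_simple):
        assert scanpath_score([], tmt_a_simple) == 8


# ---------------------------------------------------------------------------
# Total time

class TestTotalTime:
    def test_span(self):
        t = TrialRecord("p", "s", fixations=[Fixation(0, 10, 0, 0)],
                        trial_start=0, trial_end=4042)
        assert total_time(t) == 4042

    def test_empty_trial_rejected(self):
        with pytest.raises(ValueError):
            total_time(TrialRecord("p", "s"))


# ---------------------------------------------------------------------------
# Error rate

class TestErrorRate:
    def test_perfect_trail(self, tmt_a_simple):
        fx = [fix_at(tmt_a_simple, lbl, i * 100, 80)
              for i, lbl in enumerate(tmt_a_simple.expected_sequence)]
        assert error_rate(fx, tmt_a_simple) == 0

    def test_worked_example_single_error(self, tmt_a_simple):
        fx = [fix_at(tmt_a_simple, lbl, i * 100, 80)
              for i, lbl in enumerate(WORKED_SCANPATH)]
        assert error_rate(fx, tmt_a_simple) == 1

    def test_out_of_aoi_fixations_count(self, tmt_a_simple):
        fx = [Fixation(0, 80, -10, -10), Fixation(100, 80, -20, -20)]
        assert error_rate(fx, tmt_a_simple) == 2

    def test_transposition_counts_one_wrong_visit(self):
        # one of the swapped targets is off the in-order traversal; the
        # never-revisited expected "3" is an omission, not a wrong visit
        assert wrong_token_count(["1", "3", "2"], ["1", "2", "3"]) == 1

    def test_missed_target_does_not_cascade(self):
        # skipping one target leaves the rest of the trail in order: no
        # wrong visits (the omission is FH1's business)
        assert wrong_token_count(["1", "3", "4", "5"], ["1", "2", "3", "4", "5"]) == 0


# ---------------------------------------------------------------------------
# Inattentional blindness

class TestInattentionalBlindness:
    def test_worked_example_absent(self):
        # single-token revisit of "6" is below the minimum pattern length
        assert inattentional_blindness(WORKED_SCANPATH) == 0

    def test_replayed_run_detected(self):
        assert inattentional_blindness("1 2 3 6 7 6 7 8".split()) == 1

    def test_empty(self):
        assert inattentional_blindness([]) == 0

    def test_min_len_one_counts_single_repeats(self):
        assert inattentional_blindness(WORKED_SCANPATH, min_pattern_len=1) == 1

    def test_invalid_min_len(self):
        with pytest.raises(ValueError):
            inattentional_blindness([], min_pattern_len=0)

    def test_exhaustive_oracle_small(self):
        # all sequences up to length 6 over a 4-token alphabet
        for n in range(7):
            for seq in itertools.product("abcd", repeat=n):
                assert inattentional_blindness(seq) == ib_oracle(seq), seq


# ---------------------------------------------------------------------------
# Assembly

class TestAssembleFeatures:
    def _ideal_trials(self, layouts, profile):
        return [simulate_trial(profile, layouts[sid], seed=i)
                for i, sid in enumerate(STIMULUS_IDS)]

    def test_zero_impairment_vector(self, layouts, ideal_profile):
        vec = assemble_features(self._ideal_trials(layouts, ideal_profile), layouts)
        assert vec.values["FH1"] == 0
        assert vec.values["FH3"] == 0
        assert vec.values["FH4"] == 0
        assert vec.provenance["complete"]

    def test_counts_sum_percentages_average(self, layouts, ideal_profile):
        trials = self._ideal_trials(layouts, ideal_profile)
        vec = assemble_features(trials, layouts)
        per_trial = [extract_trial_features(t, layouts[t.stimulus_id]) for t in trials]
        assert vec.values["FL1"] == sum(t.low.FL1 for t in per_trial)
        assert vec.values["FH2"] == pytest.approx(sum(t.high.FH2 for t in per_trial))
        assert vec.values["FL3"] == pytest.approx(
            sum(t.low.FL3 for t in per_trial) / 4)

    def test_single_trial_participant_flagged(self, layouts, ideal_profile):
        trial = simulate_trial(ideal_profile, layouts["tmt_a_simple"], seed=0)
        vec = assemble_features([trial], layouts)
        assert not vec.provenance["complete"]
        assert vec.provenance["trials"] == ["tmt_a_simple"]

    def test_no_trials_rejected(self, layouts):
        with pytest.raises(ValueError):
            assemble_features([], layouts)
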