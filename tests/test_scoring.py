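"""Subtest scorers: worked examples, range/monotonicity/ordering properties."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogbattery.battery import ConsonantTrial, LNSItem, SymbolCodeTable, WordList
from cogbattery.scoring import (
    TASK_MAXIMA,
    CompositionError,
    ResponseArityError,
    SubtestScore,
    score_consonant_repetition,
    score_delayed_recall,
    score_list_learning,
    score_lns,
    score_vmt,
    total_score,
)

WORDS = WordList("en", ("machine", "milk", "coffee", "bed", "hat", "garden",
                        "river", "paper", "window", "stone"))
TABLE = SymbolCodeTable({"a": "ooo", "b": "oo*", "c": "o*o", "d": "o**", "e": "*oo", "f": "*o*"})
STREAM = tuple(["ooo", "oo*", "o*o"] * 10)


class TestListLearning:
    def test_full_recall_in_every_trial_scores_thirty(self):
        full = list(WORDS.words)
        assert score_list_learning(WORDS, [full, full, full]).raw == 30

    def test_empty_transcripts_score_zero(self):
        assert score_list_learning(WORDS, [[], [], []]).raw == 0

    def test_partial_recall_sums_distinct_words_per_trial(self):
        trials = [WORDS.words[:7], WORDS.words[:8], WORDS.words[:9]]
        assert score_list_learning(WORDS, trials).raw == 24

    def test_repeated_words_earn_credit_once_per_trial(self):
        assert score_list_learning(WORDS, [["milk", "milk", "milk"], [], []]).raw == 1

    def test_intrusions_are_not_penalized(self):
        assert score_list_learning(WORDS, [["milk", "zebra", "xylophone"], [], []]).raw == 1

    def test_wrong_trial_count_is_an_arity_error(self):
        with pytest.raises(ResponseArityError):
            score_list_learning(WORDS, [[], []])


class TestConsonantRepetition:
    TRIALS = tuple(ConsonantTrial(t) for t in
                   [("t", "k", "s"), ("m", "r", "p"), ("b", "l", "n"), ("d", "f", "g"),
                    ("h", "v", "j"), ("c", "z", "q"), ("w", "x", "b"), ("k", "p", "t")])

    def test_perfect_recall_scores_twenty_four(self):
        responses = [list(t.letters) for t in self.TRIALS]
        assert score_consonant_repetition(self.TRIALS, responses).raw == 24

    def test_empty_responses_score_zero(self):
        assert score_consonant_repetition(self.TRIALS, [[]] * 8).raw == 0

    def test_partial_recall_is_order_insensitive_with_unique_credit(self):
        responses = [["k", "s", "x"]] + [[]] * 7  # target {t,k,s}: k and s credited
        assert score_consonant_repetition(self.TRIALS, responses).raw == 2

    def test_comparison_is_case_insensitive(self):
        responses = [["T", "K", "S"]] + [[]] * 7
        assert score_consonant_repetition(self.TRIALS, responses).raw == 3

    def test_response_count_mismatch_is_an_arity_error(self):
        with pytest.raises(ResponseArityError):
            score_consonant_repetition(self.TRIALS, [[]] * 7)


class TestLetterNumberSequencing:
    ITEMS = tuple(LNSItem(p) for p in [("b", "3", "a", "1"), ("7", "c"), ("2", "9", "d")])

    def test_all_correct_scores_item_count(self):
        responses = [list(i.expected) for i in self.ITEMS]
        assert score_lns(self.ITEMS, responses).raw == 3

    def test_credit_is_all_or_nothing_and_order_sensitive(self):
        assert score_lns(self.ITEMS, [["1", "3", "a", "b"], [], []]).raw == 1
        assert score_lns(self.ITEMS, [["3", "1", "a", "b"], [], []]).raw == 0

    def test_case_insensitive_match(self):
        assert score_lns(self.ITEMS, [["1", "3", "A", "B"], [], []]).raw == 1

    def test_response_count_mismatch_is_an_arity_error(self):
        with pytest.raises(ResponseArityError):
            score_lns(self.ITEMS, [[]])


class TestDelayedRecall:
    def test_full_recall_scores_ten(self):
        assert score_delayed_recall(WORDS, list(WORDS.words)).raw == 10

    def test_empty_transcript_scores_zero(self):
        assert score_delayed_recall(WORDS, []).raw == 0

    def test_unique_credit(self):
        assert score_delayed_recall(WORDS, ["milk", "milk", "coffee"]).raw == 2

    def test_equals_single_trial_list_learning(self):
        """DLL scoring is the one-trial restriction of the LL rule."""
        transcript = ["milk", "garden", "zebra", "milk"]
        dll = score_delayed_recall(WORDS, transcript).raw
        ll = score_list_learning(WORDS, [transcript, [], []]).raw
        assert dll == ll


class TestVisuomotorTracking:
    def test_all_thirty_answered_correctly_scores_thirty(self):
        typed = [TABLE.letter_for(c) for c in STREAM]
        assert score_vmt(TABLE, STREAM, typed).raw == 30

    def test_no_answers_score_zero(self):
        assert score_vmt(TABLE, STREAM, []).raw == 0

    def test_positional_comparison_with_partial_answers(self):
        typed = [TABLE.letter_for(c) for c in STREAM[:12]]
        typed[5] = "f" if typed[5] != "f" else "a"  # one wrong among 12
        assert score_vmt(TABLE, STREAM, typed).raw == 11

    def test_more_answers_than_codes_is_an_arity_error(self):
        with pytest.raises(ResponseArityError):
            score_vmt(TABLE, STREAM, ["a"] * 31)


class TestTotal:
    def test_maxima_sum_to_115(self):
        report = total_score(
            SubtestScore(t, TASK_MAXIMA[t], TASK_MAXIMA[t]) for t in TASK_MAXIMA
        )
        assert report.total == 115

    def test_all_zeros(self):
        report = total_score(SubtestScore(t, 0, TASK_MAXIMA[t]) for t in TASK_MAXIMA)
        assert report.total == 0

    def test_arbitrary_sum(self):
        raws = {"LL": 20, "CR": 12, "LNS": 10, "DLL": 5, "VMT": 15}
        report = total_score(SubtestScore(t, r, TASK_MAXIMA[t]) for t, r in raws.items())
        assert report.total == 62
        assert report["LNS"].raw == 10

    def test_missing_or_duplicate_task_is_a_composition_error(self):
        four = [SubtestScore(t, 0, TASK_MAXIMA[t]) for t in ("LL", "CR", "LNS", "DLL")]
        with pytest.raises(CompositionError, match="missing"):
            total_score(four)
        with pytest.raises(CompositionError, match="duplicate"):
            total_score(four + [SubtestScore("LL", 1, 30), SubtestScore("VMT", 0, 30)])


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

token = st.sampled_from(list(WORDS.words) + ["zebra", "apple", "xx", "milk"])
transcript = st.lists(token, max_size=15)


@given(trials=st.tuples(transcript, transcript, transcript))
def test_list_learning_is_bounded_and_permutation_invariant(trials):
    score = score_list_learning(WORDS, list(trials))
    assert 0 <= score.raw <= 30
    reordered = [list(reversed(t)) for t in trials]
    assert score_list_learning(WORDS, reordered).raw == score.raw


@given(trials=st.tuples(transcript, transcript, transcript), extra=st.sampled_from(WORDS.words))
def test_adding_a_correct_word_never_decreases_the_score(trials, extra):
    base = score_list_learning(WORDS, list(trials)).raw
    grown = [list(trials[0]) + [extra], list(trials[1]), list(trials[2])]
    assert score_list_learning(WORDS, grown).raw >= base


letters = st.lists(st.sampled_from("tksmrpblndfghvjczqwx"), max_size=6)


@given(responses=st.lists(letters, min_size=8, max_size=8))
def test_consonant_score_bounded_and_order_insensitive(responses):
    trials = TestConsonantRepetition.TRIALS
    score = score_consonant_repetition(trials, responses)
    assert 0 <= score.raw <= 24
    shuffled = [list(reversed(r)) for r in responses]
    assert score_consonant_repetition(trials, shuffled).raw == score.raw


@given(st.data())
def test_vmt_is_order_sensitive_but_bounded(data):
    typed = data.draw(st.lists(st.sampled_from("abcdef"), max_size=30))
    score = score_vmt(TABLE, STREAM, typed)
    assert 0 <= score.raw <= 30
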