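"""Simulator: determinism, floor/ceiling behavior, parameter recovery."""

import math

import numpy as np
import pytest

from cogbattery.scoring import score_session
from cogbattery.simulate import (
    DOMAINS,
    CohortConfig,
    ParameterError,
    SimulationError,
    SubjectProfile,
    asr_channel,
    induced_correlation,
    simulate_cohort,
    simulate_subject,
    simulate_validity_cohort,
)
from cogbattery.speech_eval import TokenSequence, align_words, word_error_rate


class TestSubjectProfile:
    def test_rejects_out_of_range_parameters(self):
        with pytest.raises(ParameterError):
            SubjectProfile.uniform(1.2)
        with pytest.raises(ParameterError):
            SubjectProfile.uniform(0.5, learning_gain=0.6)
        with pytest.raises(ParameterError):
            SubjectProfile.uniform(0.5, asr_sub_rate=0.7, asr_del_rate=0.5)
        with pytest.raises(ParameterError):
            SubjectProfile({"verbal_memory": 0.5})


class TestSimulateSubject:
    def test_perfect_abilities_without_noise_reach_every_ceiling(self, en_battery):
        record, _ = simulate_subject(SubjectProfile.uniform(1.0), en_battery, seed=0)
        assert score_session(en_battery, record).as_dict()["total"] == 115

    def test_zero_abilities_score_zero_everywhere(self, en_battery):
        profile = SubjectProfile.uniform(0.0, learning_gain=0.0)
        record, _ = simulate_subject(profile, en_battery, seed=0)
        assert score_session(en_battery, record).as_dict()["total"] == 0

    def test_same_seed_gives_identical_records(self, en_battery):
        profile = SubjectProfile.uniform(0.6, asr_sub_rate=0.1, asr_del_rate=0.05)
        r1, t1 = simulate_subject(profile, en_battery, seed=42)
        r2, t2 = simulate_subject(profile, en_battery, seed=42)
        assert r1 == r2 and t1 == t2
        r3, _ = simulate_subject(profile, en_battery, seed=43)
        assert r1 != r3

    def test_mean_immediate_recall_matches_the_binomial_expectation(self, en_battery):
        """With ability a and gain g the expected LL total is 10 * sum_t clamp(a+(t-1)g)."""
        ability, gain, n_seeds = 0.5, 0.1, 10_000
        profile = SubjectProfile.uniform(ability, learning_gain=gain)
        probs = [min(1.0, ability + t * gain) for t in range(3)]
        expectation = 10 * sum(probs)
        variance = 10 * sum(p * (1 - p) for p in probs)
        totals = []
        for seed in range(n_seeds):
            record, _ = simulate_subject(profile, en_battery, seed=seed)
            totals.append(score_session(en_battery, record)["LL"].raw)
        se = math.sqrt(variance / n_seeds)
        assert abs(np.mean(totals) - expectation) < 3 * se

    def test_truth_record_reports_pre_asr_recall_counts(self, en_battery):
        profile = SubjectProfile.uniform(1.0, asr_del_rate=1.0)
        record, truth = simulate_subject(profile, en_battery, seed=1)
        assert truth["true_ll_recalls"] == [10, 10, 10]  # everything deleted downstream
        assert record.task_responses["LL"]["transcripts"] == [[], [], []]


class TestASRChannel:
    WORDS = TokenSequence("en", ("machine", "milk", "coffee", "bed", "hat"))

    def test_zero_rates_are_the_identity(self):
        out = asr_channel(self.WORDS, 0.0, 0.0, seed=1)
        assert out == self.WORDS
        assert word_error_rate(align_words(self.WORDS, out)) == 0.0

    def test_full_substitution_gives_wer_one(self):
        out = asr_channel(self.WORDS, 1.0, 0.0, seed=1)
        assert len(out) == len(self.WORDS)
        assert word_error_rate(align_words(self.WORDS, out)) == 1.0

    def test_full_deletion_empties_the_sequence(self):
        assert asr_channel(self.WORDS, 0.0, 1.0, seed=1).tokens == ()

    def test_substitutions_never_collide_with_the_word_list(self, en_battery):
        out = asr_channel(TokenSequence("en", en_battery.word_list.words), 1.0, 0.0, seed=5)
        assert not set(out.tokens) & set(en_battery.word_list.words)

    def test_rate_sum_above_one_is_rejected(self):
        with pytest.raises(ParameterError):
            asr_channel(self.WORDS, 0.7, 0.5, seed=1)

    def test_channel_is_deterministic_in_the_seed(self):
        a = asr_channel(self.WORDS, 0.3, 0.2, seed=9)
        assert a == asr_channel(self.WORDS, 0.3, 0.2, seed=9)

    def test_pooled_wer_converges_to_the_error_rate(self):
        """Law of large numbers: WER -> sub_rate + del_rate as tokens grow."""
        sub, dele = 0.1, 0.05
        ref = TokenSequence("en", ("machine", "milk", "coffee", "bed", "hat") * 400)
        alignments = [
            align_words(ref, asr_channel(ref, sub, dele, seed=s)) for s in range(5)
        ]
        n = sum(a.n_ref for a in alignments)
        pooled = sum(a.errors for a in alignments) / n
        p = sub + dele
        assert abs(pooled - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestValidityCohort:
    def test_config_validation(self, en_battery):
        with pytest.raises(SimulationError):
            CohortConfig(n=1)
        with pytest.raises(SimulationError):
            CohortConfig(n=10, shared_ability_weight=1.5)
        with pytest.raises(SimulationError):
            CohortConfig(n=10, observed="weird")

    def test_identical_seed_reproduces_the_table(self, en_battery):
        cfg = CohortConfig(n=50, seed=3)
        t1 = simulate_validity_cohort(cfg, en_battery)
        t2 = simulate_validity_cohort(cfg, en_battery)
        assert t1.equals(t2)

    def test_perfect_coupling_without_noise_gives_r_of_one(self, en_battery):
        cfg = CohortConfig(n=100, shared_ability_weight=1.0, instrument_noise_sd=0.0, seed=1)
        table = simulate_validity_cohort(cfg, en_battery)
        r = np.corrcoef(table["a_LL"], table["b_LL"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_coupling_gives_near_zero_correlation(self, en_battery):
        cfg = CohortConfig(n=4000, shared_ability_weight=0.0, instrument_noise_sd=0.3, seed=2)
        table = simulate_validity_cohort(cfg, en_battery)
        r = np.corrcoef(table["a_LL"], table["b_LL"])[0, 1]
        assert abs(r) < 3 / math.sqrt(4000)

    def test_estimated_r_tracks_the_closed_form(self, en_battery):
        cfg = CohortConfig(n=4000, shared_ability_weight=0.8, instrument_noise_sd=0.3, seed=4)
        table = simulate_validity_cohort(cfg, en_battery)
        r = np.corrcoef(table["a_VMT"], table["b_VMT"])[0, 1]
        assert r == pytest.approx(induced_correlation(0.8, 0.3), abs=0.03)

    def test_binomial_mode_piles_scores_at_the_maximum_near_ceiling(self, en_battery):
        cfg = CohortConfig(
            n=1000, ability_mean=0.97, ability_sd=0.05,
            shared_ability_weight=0.8, instrument_noise_sd=0.3,
            seed=5, observed="binomial",
        )
        table = simulate_validity_cohort(cfg, en_battery)
        assert (table["a_CR"] == 24).mean() > 0.4  # pile-up at the 0-24 ceiling
        latent_r = np.corrcoef(table["z_working_memory"], table["a_CR"])[0, 1]
        assert 0 < latent_r < 1

    def test_ceiling_attenuates_the_observed_correlation(self, en_battery):
        """Score pile-up at the maximum weakens the observed instrument agreement."""
        common = dict(n=2000, shared_ability_weight=0.8, instrument_noise_sd=0.3, seed=6)
        ceiling = simulate_validity_cohort(
            CohortConfig(ability_mean=0.97, ability_sd=0.05, observed="binomial", **common),
            en_battery,
        )
        linear = simulate_validity_cohort(CohortConfig(**common), en_battery)
        observed = np.corrcoef(ceiling["a_CR"], ceiling["b_CR"])[0, 1]
        latent = np.corrcoef(linear["a_CR"], linear["b_CR"])[0, 1]
        assert observed < latent


class TestCohort:
    def test_cohort_has_unique_ids_and_truth_rows(self, en_battery):
        cohort = simulate_cohort(5, en_battery, seed=11)
        ids = [rec.subject_id for rec, _ in cohort]
        assert len(set(ids)) == 5
        for record, truth in cohort:
            assert record.complete
            assert set(DOMAINS) <= set(truth)

    def test_cohort_is_seed_deterministic(self, en_battery):
        a = simulate_cohort(3, en_battery, seed=11)
        b = simulate_cohort(3, en_battery, seed=11)
        assert a == b
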