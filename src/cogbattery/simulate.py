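"""Synthetic subjects, ASR noise, and paired-instrument validity cohorts.

The generative model is deliberately simple — a linear-Gaussian latent
ability per cognitive domain driving Bernoulli item responses:

* Each subject has abilities in [0, 1] for four domains (verbal memory,
  working memory, executive, psychomotor) plus a per-trial verbal learning
  gain. Recall of each list word in immediate-recall trial ``t`` is an
  independent Bernoulli event with probability
  ``clamp(verbal_memory + (t - 1) * learning_gain)``; delayed recall uses
  the level reached after the three learning trials. Consonant, sequencing
  and coding items are independent Bernoulli events with the relevant
  domain ability.
* Spoken recall passes through an ASR corruption channel that substitutes
  each token (with an out-of-list distractor) with probability
  ``asr_sub_rate`` and deletes it with probability ``asr_del_rate``;
  insertions default to rate 0, matching the empirical observation that
  recall-style speech produces essentially no insertion errors.
* For validity studies, two instruments' scores share a latent standard
  normal ability per domain with coupling weight ``w`` plus
  instrument-specific Gaussian noise, so a single task pair has the exact
  induced correlation ``w^2 / sqrt((w^2 + sd_a^2)(w^2 + sd_b^2))``
  (:func:`induced_correlation`). A ``binomial`` observation mode maps the
  latent values through a clamped ability onto bounded Binomial subtest
  scores, which reproduces ceiling effects (score pile-up at the maximum
  and attenuated observed correlations).

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import BatteryDefinition
from .scoring import TASK_IDS, TASK_MAXIMA
from .session import (
    IncompleteSessionError,
    ScriptedResponder,
    SessionRecord,
    StepClock,
    run_session,
)
from .speech_eval import TokenSequence, normalize_transcript

__all__ = [
    "DOMAINS",
    "TASK_DOMAIN",
    "SimulationError",
    "ParameterError",
    "SubjectProfile",
    "CohortConfig",
    "asr_channel",
    "simulate_subject",
    "simulate_cohort",
    "simulate_validity_cohort",
    "induced_correlation",
]

DOMAINS = ("verbal_memory", "working_memory", "executive", "psychomotor")

#: Which latent domain drives each subtest.
TASK_DOMAIN = {
    "LL": "verbal_memory",
    "CR": "working_memory",
    "LNS": "executive",
    "DLL": "verbal_memory",
    "VMT": "psychomotor",
}


class SimulationError(ValueError):
    pass


class ParameterError(SimulationError):
    """A rate or ability parameter is outside its valid range."""


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass(frozen=True)
class SubjectProfile:
    """Latent abilities and noise parameters for one simulated subject."""

    abilities: Mapping[str, float]
    learning_gain: float = 0.1
    asr_sub_rate: float = 0.0
    asr_del_rate: float = 0.0

    def __post_init__(self) -> None:
        abilities = dict(self.abilities)
        object.__setattr__(self, "abilities", abilities)
        missing = set(DOMAINS) - set(abilities)
        if missing:
            raise ParameterError(f"missing abilities for domains: {sorted(missing)}")
        for domain, value in abilities.items():
            if domain not in DOMAINS:
                raise ParameterError(f"unknown ability domain {domain!r}")
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"ability {domain}={value} outside [0, 1]")
        if not 0.0 <= self.learning_gain <= 0.5:
            raise ParameterError(f"learning_gain={self.learning_gain} outside [0, 0.5]")
        for name in ("asr_sub_rate", "asr_del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"{name}={rate} outside [0, 1]")
        if self.asr_sub_rate + self.asr_del_rate > 1.0:
            raise ParameterError("asr_sub_rate + asr_del_rate must not exceed 1")

    @classmethod
    def uniform(cls, ability: float, **kwargs: Any) -> "SubjectProfile":
        """All four domains set to the same ability level."""
        return cls({d: ability for d in DOMAINS}, **kwargs)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a paired-instrument validity cohort.

    ``shared_ability_weight`` couples the two instruments through a common
    latent ability; ``instrument_noise_sd`` is the standard deviation of
    each instrument's idiosyncratic noise. ``observed`` selects the score
    scale: ``"linear"`` keeps the latent Gaussian scale (exact closed-form
    correlation), ``"binomial"`` maps onto bounded integer subtest scores
    with ``ability = clamp(ability_mean + ability_sd * latent)``.
    """

    n: int
    ability_mean: float = 0.7
    ability_sd: float = 0.15
    shared_ability_weight: float = 0.8
    instrument_noise_sd: float = 0.3
    seed: int = 0
    observed: str = "linear"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SimulationError(f"cohort size must be at least 2, got {self.n}")
        if self.ability_sd < 0 or self.instrument_noise_sd < 0:
            raise SimulationError("standard deviations must be non-negative")
        if not 0.0 <= self.shared_ability_weight <= 1.0:
            raise SimulationError("shared_ability_weight must lie in [0, 1]")
        if self.observed not in ("linear", "binomial"):
            raise SimulationError(f"unknown observed mode {self.observed!r}")


# ---------------------------------------------------------------------------
# ASR corruption channel
# ---------------------------------------------------------------------------

# Fixed distractor pools, disjoint from the default word lists so a
# substituted token can never accidentally earn recall credit.
_DISTRACTORS = {
    "en": ("pencil", "cloud", "train", "bottle", "mirror", "ladder",
           "carpet", "engine", "yellow", "basket"),
    "da": ("blyant", "sky", "tog", "flaske", "spejl", "stige",
           "tæppe", "motor", "gul", "kurv"),
}


def _corrupt(tokens: Sequence[str], sub_rate: float, del_rate: float,
             rng: random.Random, language: str) -> list[str]:
    pool = _DISTRACTORS.get(language, _DISTRACTORS["en"])
    out: list[str] = []
    for tok in tokens:
        u = rng.random()
        if u < del_rate:
            continue
        if u < del_rate + sub_rate:
            candidates = [d for d in pool if d != tok]
            out.append(rng.choice(candidates))
        else:
            out.append(tok)
    return out


def asr_channel(
    tokens: TokenSequence, sub_rate: float, del_rate: float, seed: int
) -> TokenSequence:
    """Corrupt a token sequence the way a recall-style ASR system errs.

    Each token is independently substituted (by an out-of-list distractor)
    with probability ``sub_rate``, deleted with probability ``del_rate``,
    and passed through otherwise. No insertions are generated by default.
    """
    if sub_rate < 0 or del_rate < 0 or sub_rate + del_rate > 1.0:
        raise ParameterError(
            f"invalid channel rates sub={sub_rate}, del={del_rate} (sum must be <= 1)"
        )
    rng = random.Random(seed)
    return TokenSequence(
        tokens.language, tuple(_corrupt(tokens.tokens, sub_rate, del_rate, rng, tokens.language))
    )


class _ChannelTranscriber:
    """Transcriber applying the ASR corruption channel to each utterance."""

    def __init__(self, profile: SubjectProfile, rng: random.Random):
        self._profile = profile
        self._rng = rng

    def transcribe(self, utterance: str, language: str) -> TokenSequence:
        clean = normalize_transcript(utterance, language)
        corrupted = _corrupt(
            clean.tokens, self._profile.asr_sub_rate, self._profile.asr_del_rate,
            self._rng, language,
        )
        return TokenSequence(language, tuple(corrupted))


# ---------------------------------------------------------------------------
# Whole-session simulation
# ---------------------------------------------------------------------------


class _SimulatedResponder:
    """Bernoulli item-response process over a battery, with trial-wise learning.

    Remembers the word list it hears during the immediate-recall trials and
    recalls from that memory during delayed recall (the session machinery
    never re-presents the list).
    """

    def __init__(self, profile: SubjectProfile, battery: BatteryDefinition, rng: random.Random):
        self._p = profile
        self._battery = battery
        self._rng = rng
        self._heard: tuple[str, ...] = ()
        self.true_recalls: dict[str, list[int]] = {"LL": [], "DLL": []}

    def _recall_probability(self, task_id: str, trial: int) -> float:
        ability = self._p.abilities["verbal_memory"]
        exposure = trial - 1 if task_id == "LL" else 2
        return _clamp01(ability + exposure * self._p.learning_gain)

    def recall_words(self, task_id, trial, played_words):
        if played_words is not None:
            self._heard = tuple(played_words)
        p = self._recall_probability(task_id, trial)
        recalled = [w for w in self._heard if self._rng.random() < p]
        self.true_recalls[task_id].append(len(recalled))
        return " ".join(recalled)

    def sort_numbers(self, numbers):
        if self._rng.random() < self._p.abilities["executive"]:
            return sorted(numbers, reverse=True)
        return list(numbers)

    def repeat_letters(self, trial, letters):
        wm = self._p.abilities["working_memory"]
        return [c for c in letters if self._rng.random() < wm]

    def sort_sequence(self, index, presented, practice):
        from .battery import lns_expected_answer

        expected = list(lns_expected_answer(presented))
        if self._rng.random() < self._p.abilities["executive"]:
            return expected
        if len(expected) > 1:
            return expected[1:] + expected[:1]  # guaranteed-wrong rotation
        return []

    def code_entry(self, index, code, practice):
        speed = self._p.abilities["psychomotor"]
        correct = self._rng.random() < speed
        letter = self._battery.vmt_table.letter_for(code)
        if not correct:
            others = [l for l in self._battery.vmt_table.codes if l != letter]
            letter = self._rng.choice(others)
        return letter, 1.0  # uniform one-second entry interval


def simulate_subject(
    profile: SubjectProfile, battery: BatteryDefinition, seed: int,
    subject_id: str = "sim",
) -> tuple[SessionRecord, dict[str, Any]]:
    """Simulate one complete session; returns the record and the ground truth.

    The truth record carries the latent abilities, the learning gain, the
    channel rates, and the pre-ASR recall counts per trial — everything a
    recovery analysis needs. Identical seeds give identical records.
    """
    rng = random.Random(seed)
    responder = _SimulatedResponder(profile, battery, rng)
    transcriber = _ChannelTranscriber(profile, rng)
    record = run_session(
        battery, responder, transcriber, StepClock(), subject_id=subject_id
    )
    truth: dict[str, Any] = {"subject_id": subject_id}
    truth.update(profile.abilities)
    truth.update(
        learning_gain=profile.learning_gain,
        asr_sub_rate=profile.asr_sub_rate,
        asr_del_rate=profile.asr_del_rate,
        true_ll_recalls=list(responder.true_recalls["LL"]),
        true_dll_recalls=responder.true_recalls["DLL"][0],
    )
    return record, truth


def simulate_cohort(
    n: int,
    battery: BatteryDefinition,
    seed: int,
    ability_mean: float = 0.7,
    ability_sd: float = 0.15,
    learning_gain: float = 0.1,
    asr_sub_rate: float = 0.05,
    asr_del_rate: float = 0.02,
) -> list[tuple[SessionRecord, dict[str, Any]]]:
    """Simulate ``n`` independent subjects with Gaussian-distributed abilities."""
    if n < 1:
        raise SimulationError("cohort must contain at least one subject")
    rng = random.Random(seed)
    out = []
    for i in range(n):
        abilities = {
            d: _clamp01(rng.gauss(ability_mean, ability_sd)) for d in DOMAINS
        }
        profile = SubjectProfile(
            abilities,
            learning_gain=learning_gain,
            asr_sub_rate=asr_sub_rate,
            asr_del_rate=asr_del_rate,
        )
        out.append(
            simulate_subject(
                profile, battery, seed=rng.randrange(2**31), subject_id=f"sim-{i:04d}"
            )
        )
    return out


# ---------------------------------------------------------------------------
# Paired-instrument validity cohorts
# ---------------------------------------------------------------------------


def induced_correlation(w: float, noise_sd_a: float, noise_sd_b: float | None = None) -> float:
    """Closed-form correlation between two instruments sharing a latent ability.

    For ``X_a = w Z + sd_a E_a`` and ``X_b = w Z + sd_b E_b`` with independent
    standard normal Z, E_a, E_b:

        corr(X_a, X_b) = w^2 / sqrt((w^2 + sd_a^2)(w^2 + sd_b^2))
    """
    if noise_sd_b is None:
        noise_sd_b = noise_sd_a
    if w == 0 and (noise_sd_a == 0 or noise_sd_b == 0):
        raise SimulationError("degenerate model: zero variance on one instrument")
    w2 = w * w
    return w2 / math.sqrt((w2 + noise_sd_a**2) * (w2 + noise_sd_b**2))


def simulate_validity_cohort(
    config: CohortConfig, battery: BatteryDefinition
) -> pd.DataFrame:
    """Generate a paired score table for two instruments over one cohort.

    Each subject draws one shared latent standard normal ability per domain;
    each instrument observes ``w * z + noise_sd * eps`` for the domain
    driving each subtest. Columns: ``subject_id``, ``z_<domain>``,
    ``a_<task>``/``b_<task>`` per subtest, and ``a_total``/``b_total``.
    Identical config (including seed) gives an identical table.
    """
    rng = np.random.default_rng(config.seed)
    w = config.shared_ability_weight
    sd = config.instrument_noise_sd
    z = {d: rng.standard_normal(config.n) for d in DOMAINS}
    latent = {}
    for instrument in ("a", "b"):
        for d in DOMAINS:
            latent[(instrument, d)] = w * z[d] + sd * rng.standard_normal(config.n)
    data: dict[str, Any] = {"subject_id": [f"s{i:04d}" for i in range(config.n)]}
    for d in DOMAINS:
        data[f"z_{d}"] = z[d]
    for instrument in ("a", "b"):
        total = np.zeros(config.n)
        for task in TASK_IDS:
            values = latent[(instrument, TASK_DOMAIN[task])]
            if config.observed == "binomial":
                p = np.clip(config.ability_mean + config.ability_sd * values, 0.0, 1.0)
                scores = rng.binomial(TASK_MAXIMA[task], p).astype(float)
            else:
                scores = values
            data[f"{instrument}_{task}"] = scores
            total = total + scores
        data[f"{instrument}_total"] = total
    return pd.DataFrame(data)
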