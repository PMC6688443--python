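"""Deterministic scorers for the five subtests and the battery total.

Scoring rules, with their maxima:

* LL  — list learning: correctly recalled list words summed over 3 trials,
  each list word credited at most once per trial (max 3 x 10 = 30).
* CR  — consonant repetition: correctly recalled letters per trial,
  order-insensitive, each target letter credited once (max 24).
* LNS — letter-number sequencing: correctly sorted sequences, all-or-nothing
  per item (max 21).
* DLL — delayed list learning: correctly recalled list words, unique credit
  (max 10).
* VMT — visuomotor tracking: positionally correct letters typed against the
  code stream within the time limit (max 30).

All comparisons are case-folded, whitespace-trimmed and Unicode
NFC-normalized (Danish æ/ø/å compare reliably). Tokens outside the target
set never penalize. The total is the plain sum of the five raw scores
(range 0-115).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .battery import ConsonantTrial, LNSItem, SymbolCodeTable, WordList
from .speech_eval import TokenSequence, normalize_token

__all__ = [
    "TASK_IDS",
    "TASK_MAXIMA",
    "ScoringError",
    "ResponseArityError",
    "CompositionError",
    "SubtestScore",
    "ScoreReport",
    "score_list_learning",
    "score_consonant_repetition",
    "score_lns",
    "score_delayed_recall",
    "score_vmt",
    "total_score",
    "score_session",
    "reports_to_frame",
]

TASK_IDS = ("LL", "CR", "LNS", "DLL", "VMT")
TASK_MAXIMA = {"LL": 30, "CR": 24, "LNS": 21, "DLL": 10, "VMT": 30}


class ScoringError(ValueError):
    pass


class ResponseArityError(ScoringError):
    """Number of responses does not match the number of stimuli."""


class CompositionError(ScoringError):
    """A total was requested from an incomplete or duplicated set of subscores."""


@dataclass(frozen=True)
class SubtestScore:
    task_id: str
    raw: int
    max: int

    def __post_init__(self) -> None:
        if self.task_id not in TASK_MAXIMA:
            raise ScoringError(f"unknown task id {self.task_id!r}")
        if self.max != TASK_MAXIMA[self.task_id]:
            raise ScoringError(
                f"{self.task_id} maximum must be {TASK_MAXIMA[self.task_id]}, got {self.max}"
            )
        if not 0 <= self.raw <= self.max:
            raise ScoringError(f"{self.task_id} raw score {self.raw} outside [0, {self.max}]")


@dataclass(frozen=True)
class ScoreReport:
    """Five subtest scores in canonical order plus their total (0-115)."""

    scores: tuple[SubtestScore, ...]
    total: int

    def __post_init__(self) -> None:
        if tuple(s.task_id for s in self.scores) != TASK_IDS:
            raise CompositionError("score report must hold the five tasks in canonical order")
        if self.total != sum(s.raw for s in self.scores):
            raise CompositionError("total must equal the sum of the five raw scores")

    def __getitem__(self, task_id: str) -> SubtestScore:
        for s in self.scores:
            if s.task_id == task_id:
                return s
        raise KeyError(task_id)

    def as_dict(self) -> dict[str, int]:
        out = {s.task_id: s.raw for s in self.scores}
        out["total"] = self.total
        return out


def _tokens(response: TokenSequence | Iterable[str]) -> list[str]:
    if isinstance(response, TokenSequence):
        return list(response.tokens)
    return [normalize_token(str(t)) for t in response]


def score_list_learning(
    word_list: WordList, trial_transcripts: Sequence[TokenSequence | Iterable[str]]
) -> SubtestScore:
    """Sum over 3 trials of distinct list words present in the trial transcript."""
    if len(trial_transcripts) != 3:
        raise ResponseArityError(f"list learning requires exactly 3 trials, got {len(trial_transcripts)}")
    targets = set(word_list.words)
    raw = sum(len(set(_tokens(t)) & targets) for t in trial_transcripts)
    return SubtestScore("LL", raw, TASK_MAXIMA["LL"])


def score_consonant_repetition(
    trials: Sequence[ConsonantTrial], responses: Sequence[Iterable[str]]
) -> SubtestScore:
    """Count correctly recalled letters per trial (order-insensitive, unique credit)."""
    if len(responses) != len(trials):
        raise ResponseArityError(
            f"expected {len(trials)} responses (one per trial), got {len(responses)}"
        )
    raw = 0
    for trial, response in zip(trials, responses):
        raw += sum((Counter(trial.letters) & Counter(_tokens(response))).values())
    return SubtestScore("CR", raw, TASK_MAXIMA["CR"])


def score_lns(
    items: Sequence[LNSItem], responses: Sequence[Iterable[str]]
) -> SubtestScore:
    """Count items answered with exactly the canonical sorted sequence."""
    if len(responses) != len(items):
        raise ResponseArityError(
            f"expected {len(items)} responses (one per item), got {len(responses)}"
        )
    raw = sum(tuple(_tokens(r)) == item.expected for item, r in zip(items, responses))
    return SubtestScore("LNS", raw, TASK_MAXIMA["LNS"])


def score_delayed_recall(
    word_list: WordList, transcript: TokenSequence | Iterable[str]
) -> SubtestScore:
    """Count distinct list words present in the delayed-recall transcript."""
    raw = len(set(_tokens(transcript)) & set(word_list.words))
    return SubtestScore("DLL", raw, TASK_MAXIMA["DLL"])


def score_vmt(
    table: SymbolCodeTable, stream: Sequence[str], typed: Sequence[str]
) -> SubtestScore:
    """Count positions where the typed letter matches the stream code's letter.

    ``typed`` may be shorter than the stream (the subject ran out of time);
    unanswered positions score zero.
    """
    if len(typed) > len(stream):
        raise ResponseArityError(
            f"{len(typed)} answers but only {len(stream)} stream codes"
        )
    raw = sum(
        normalize_token(str(t)) == table.letter_for(code)
        for code, t in zip(stream, typed)
    )
    return SubtestScore("VMT", raw, TASK_MAXIMA["VMT"])


def total_score(subscores: Iterable[SubtestScore]) -> ScoreReport:
    """Compose exactly one score per task into a report with their sum."""
    by_task: dict[str, SubtestScore] = {}
    for s in subscores:
        if s.task_id in by_task:
            raise CompositionError(f"duplicate score for task {s.task_id}")
        by_task[s.task_id] = s
    missing = [t for t in TASK_IDS if t not in by_task]
    if missing:
        raise CompositionError(f"missing scores for tasks: {missing}")
    ordered = tuple(by_task[t] for t in TASK_IDS)
    return ScoreReport(ordered, sum(s.raw for s in ordered))


def score_session(battery, record) -> ScoreReport:
    """Score a complete session record against its battery.

    Practice responses are ignored; only the scored payloads contribute.
    """
    resp = record.task_responses
    missing = [t for t in TASK_IDS if t not in resp]
    if missing:
        raise CompositionError(f"session record is missing tasks: {missing}")
    return total_score(
        [
            score_list_learning(battery.word_list, resp["LL"]["transcripts"]),
            score_consonant_repetition(battery.cr_trials, resp["CR"]["typed"]),
            score_lns(battery.lns_items, resp["LNS"]["responses"]),
            score_delayed_recall(battery.word_list, resp["DLL"]["transcript"]),
            score_vmt(
                battery.vmt_table,
                battery.vmt_stream,
                [e["letter"] for e in resp["VMT"]["entries"]],
            ),
        ]
    )


def reports_to_frame(reports: Mapping[str, ScoreReport]) -> pd.DataFrame:
    """Tabulate score reports keyed by subject id (CSV-export friendly)."""
    rows = []
    for subject_id, report in reports.items():
        row: dict[str, object] = {"subject_id": subject_id}
        row.update(report.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *TASK_IDS, "total"])
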