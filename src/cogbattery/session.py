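"""Headless administration of a battery as a deterministic state machine.

The interactive front end is replaced by a *responder* (supplies the
subject's answers), a *transcriber* (turns spoken recall into token
sequences, standing in for the ASR service), and an injectable *clock*.
Running a session produces a :class:`SessionRecord` — the unit of scoring —
which serializes to a schema-versioned JSON document and parses back
losslessly.

Task order is fixed: LL -> CR -> LNS -> DLL -> VMT. Practice items (the
sequencing practice set and a short coding warm-up) are administered and
recorded but excluded from the scored payloads. The recall word list is
presented to the responder only as the audio stimulus of each immediate
recall trial — never between trials and never before delayed recall, so a
responder cannot "see" the list when it should be remembering it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Protocol, Sequence

from .battery import BatteryDefinition, lns_expected_answer  # noqa: F401  (re-export)

__all__ = [
    "TASK_ORDER",
    "SCHEMA_VERSION",
    "SessionError",
    "ResponderExhausted",
    "IncompleteSessionError",
    "SessionParseError",
    "SessionRecord",
    "Responder",
    "Transcriber",
    "StepClock",
    "ScriptedResponder",
    "NormalizingTranscriber",
    "ScriptedTranscriber",
    "check_descending",
    "lns_expected_answer",
    "run_session",
    "serialize_session",
    "parse_session",
]

TASK_ORDER = ("LL", "CR", "LNS", "DLL", "VMT")
SCHEMA_VERSION = "1.0.0"


class SessionError(ValueError):
    pass


class ResponderExhausted(Exception):
    """A responder ran out of scripted answers mid-session."""


class IncompleteSessionError(SessionError):
    """Session aborted before completion; carries the partial record."""

    def __init__(self, message: str, partial: "SessionRecord"):
        super().__init__(message)
        self.partial = partial


class SessionParseError(SessionError):
    """A session document violates the schema; the message names the field."""


def check_descending(numbers: Sequence[int]) -> bool:
    """True iff the sequence is strictly decreasing (the sorting-filler goal)."""
    if not numbers:
        raise SessionError("check_descending requires a non-empty sequence")
    return all(a > b for a, b in zip(numbers, numbers[1:]))


# ---------------------------------------------------------------------------
# Session record
# ---------------------------------------------------------------------------


@dataclass
class SessionRecord:
    """One subject's responses to the battery, in canonical task order."""

    subject_id: str
    language: str
    started_at: float
    ended_at: float
    task_responses: dict[str, dict[str, Any]]
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        keys = tuple(self.task_responses)
        if keys != TASK_ORDER[: len(keys)]:
            raise SessionError(
                f"tasks must appear in canonical order {TASK_ORDER}, got {keys}"
            )
        vmt = self.task_responses.get("VMT")
        if vmt is not None:
            limit = vmt["time_limit"]
            for entry in vmt["entries"]:
                if not 0 <= entry["t"] <= limit:
                    raise SessionError(
                        f"VMT entry at t={entry['t']} outside the time limit window [0, {limit}]"
                    )

    @property
    def complete(self) -> bool:
        return tuple(self.task_responses) == TASK_ORDER


# ---------------------------------------------------------------------------
# Pluggable collaborators
# ---------------------------------------------------------------------------


class Responder(Protocol):
    """Source of subject responses, one method per stimulus kind.

    ``recall_words`` receives the played word list only during immediate
    recall trials (the audio stimulus); for delayed recall ``played_words``
    is ``None`` — the responder must rely on its own memory.
    """

    def recall_words(self, task_id: str, trial: int, played_words: tuple[str, ...] | None) -> str: ...

    def sort_numbers(self, numbers: tuple[int, ...]) -> Sequence[int]: ...

    def repeat_letters(self, trial: int, letters: tuple[str, ...]) -> Sequence[str]: ...

    def sort_sequence(self, index: int, presented: tuple[str, ...], practice: bool) -> Sequence[str]: ...

    def code_entry(self, index: int, code: str, practice: bool) -> tuple[str, float] | None: ...


class Transcriber(Protocol):
    """Maps a spoken-response event to a token sequence (the ASR contract)."""

    def transcribe(self, utterance: str, language: str): ...


class StepClock:
    """Deterministic monotonic clock; time moves only via :meth:`advance`."""

    def __init__(self, start: float = 0.0):
        self._t = float(start)

    def now(self) -> float:
        return self._t

    def advance(self, seconds: float) -> None:
        if seconds < 0:
            raise SessionError("clock cannot move backwards")
        self._t += seconds


class NormalizingTranscriber:
    """Perfect deterministic 'ASR': normalization only, no recognition errors."""

    def transcribe(self, utterance: str, language: str):
        from .speech_eval import normalize_transcript

        return normalize_transcript(utterance, language)


class ScriptedTranscriber:
    """File/fixture-backed transcriber: returns pre-set hypothesis transcripts.

    Consumes one line per spoken-response event, in session order
    (3 immediate-recall trials, then the delayed recall).
    """

    def __init__(self, lines: Sequence[str]):
        self._lines = list(lines)
        self._i = 0

    @classmethod
    def from_file(cls, path) -> "ScriptedTranscriber":
        text = open(path, encoding="utf-8").read()
        return cls(text.splitlines())

    def transcribe(self, utterance: str, language: str):
        from .speech_eval import normalize_transcript

        if self._i >= len(self._lines):
            raise ResponderExhausted("transcriber has no more scripted lines")
        line = self._lines[self._i]
        self._i += 1
        return normalize_transcript(line, language)


class ScriptedResponder:
    """Data-driven responder holding per-task answer queues.

    ``sorts`` may be the strategy string ``"descending"`` (always sort
    correctly) or an explicit queue of number sequences. Every other field
    is a queue consumed in administration order; exhaustion raises
    :class:`ResponderExhausted`.
    """

    def __init__(
        self,
        recalls: Sequence[str],
        letter_responses: Sequence[Sequence[str]],
        lns_practice: Sequence[Sequence[str]],
        lns_responses: Sequence[Sequence[str]],
        vmt_practice: Sequence[tuple[str, float]],
        vmt_entries: Sequence[tuple[str, float]],
        sorts: str | Sequence[Sequence[int]] = "descending",
    ):
        self._recalls = list(recalls)
        self._letters = [list(r) for r in letter_responses]
        self._lns = {True: [list(r) for r in lns_practice], False: [list(r) for r in lns_responses]}
        self._vmt = {True: list(vmt_practice), False: list(vmt_entries)}
        self._sorts = sorts

    @classmethod
    def perfect(cls, battery: BatteryDefinition, vmt_interval: float = 1.0) -> "ScriptedResponder":
        """A responder that answers every stimulus correctly."""
        recall = " ".join(battery.word_list.words)
        return cls(
            recalls=[recall] * 4,
            letter_responses=[list(t.letters) for t in battery.cr_trials],
            lns_practice=[list(i.expected) for i in battery.lns_practice],
            lns_responses=[list(i.expected) for i in battery.lns_items],
            vmt_practice=[(battery.vmt_table.letter_for(c), vmt_interval) for c in battery.vmt_stream[:3]],
            vmt_entries=[(battery.vmt_table.letter_for(c), vmt_interval) for c in battery.vmt_stream],
        )

    @classmethod
    def from_json(cls, doc: Mapping[str, Any]) -> "ScriptedResponder":
        """Build from a plain JSON mapping (the CLI ``--responses`` format)."""
        return cls(
            recalls=doc["recalls"],
            letter_responses=doc["letter_responses"],
            lns_practice=doc.get("lns_practice", []),
            lns_responses=doc["lns_responses"],
            vmt_practice=[tuple(e) for e in doc.get("vmt_practice", [])],
            vmt_entries=[tuple(e) for e in doc["vmt_entries"]],
            sorts=doc.get("sorts", "descending"),
        )

    def _pop(self, queue: list, what: str):
        if not queue:
            raise ResponderExhausted(f"no scripted response left for {what}")
        return queue.pop(0)

    def recall_words(self, task_id, trial, played_words):
        return self._pop(self._recalls, f"{task_id} recall trial {trial}")

    def sort_numbers(self, numbers):
        if self._sorts == "descending":
            return sorted(numbers, reverse=True)
        return list(self._pop(self._sorts, "sorting filler"))

    def repeat_letters(self, trial, letters):
        return self._pop(self._letters, f"CR trial {trial}")

    def sort_sequence(self, index, presented, practice):
        return self._pop(self._lns[practice], f"LNS item {index} (practice={practice})")

    def code_entry(self, index, code, practice):
        queue = self._vmt[practice]
        if not queue:
            return None  # ran out of answers: subject simply stops, not an error
        return tuple(queue.pop(0))


# ---------------------------------------------------------------------------
# Administration
# ---------------------------------------------------------------------------

_VMT_PRACTICE_CODES = 3


def run_session(
    battery: BatteryDefinition,
    responder: Responder,
    transcriber: Transcriber,
    clock: StepClock | None = None,
    subject_id: str = "anonymous",
    sort_interval: float = 6.0,
) -> SessionRecord:
    """Administer the full battery and return the completed session record.

    The sorting filler of each consonant trial serves sorting sets
    cyclically, one every ``sort_interval`` seconds, until the trial's
    filler period is spent. The coding task stops once the time limit is
    reached or the responder stops answering. If the responder (or a
    scripted transcriber) is exhausted mid-session, an
    :class:`IncompleteSessionError` carrying the partial record is raised.
    """
    clock = clock or StepClock()
    started_at = clock.now()
    responses: dict[str, dict[str, Any]] = {}
    lang = battery.language
    try:
        # Task 1 — list learning: the word list is played at the start of
        # each trial; recall is spoken and passes through the transcriber.
        transcripts = []
        for trial in (1, 2, 3):
            clock.advance(len(battery.word_list.words) * 1.0)  # nominal audio playback
            utterance = responder.recall_words("LL", trial, battery.word_list.words)
            hyp = transcriber.transcribe(utterance, lang)
            transcripts.append(list(hyp.tokens))
            clock.advance(10.0)  # nominal recall window
        responses["LL"] = {"transcripts": transcripts}

        # Task 2 — consonant repetition with descending-sort filler.
        typed, sort_actions = [], []
        set_cursor = 0
        for trial_idx, trial in enumerate(battery.cr_trials, start=1):
            clock.advance(len(trial.letters) * 1.0)
            attempts = max(1, int(trial.filler_duration // sort_interval))
            trial_sorts = []
            for _ in range(attempts):
                sset = battery.sorting_sets[set_cursor % len(battery.sorting_sets)]
                set_cursor += 1
                result = list(responder.sort_numbers(sset.numbers))
                trial_sorts.append(
                    {
                        "presented": list(sset.numbers),
                        "response": result,
                        "correct": bool(
                            sorted(result) == sorted(sset.numbers) and check_descending(result)
                        ),
                    }
                )
                clock.advance(sort_interval)
            typed.append([str(c) for c in responder.repeat_letters(trial_idx, trial.letters)])
            sort_actions.append(trial_sorts)
        responses["CR"] = {"typed": typed, "sort_actions": sort_actions}

        # Task 3 — letter-number sequencing, practice first (unscored).
        practice = [
            [str(t) for t in responder.sort_sequence(i, item.presented, True)]
            for i, item in enumerate(battery.lns_practice)
        ]
        answers = [
            [str(t) for t in responder.sort_sequence(i, item.presented, False)]
            for i, item in enumerate(battery.lns_items)
        ]
        clock.advance(5.0 * (len(battery.lns_practice) + len(battery.lns_items)))
        responses["LNS"] = {"practice_responses": practice, "responses": answers}

        # Task 4 — delayed recall: no audio, the list is NOT shown.
        utterance = responder.recall_words("DLL", 1, None)
        hyp = transcriber.transcribe(utterance, lang)
        clock.advance(10.0)
        responses["DLL"] = {"transcript": list(hyp.tokens)}

        # Task 5 — visuomotor tracking: warm-up, then the timed stream.
        practice_entries = []
        for i, code in enumerate(battery.vmt_stream[:_VMT_PRACTICE_CODES]):
            entry = responder.code_entry(i, code, True)
            if entry is None:
                break
            letter, dt = entry
            clock.advance(dt)
            practice_entries.append({"letter": str(letter), "t": None})
        elapsed = 0.0
        entries = []
        for i, code in enumerate(battery.vmt_stream):
            entry = responder.code_entry(i, code, False)
            if entry is None:
                break
            letter, dt = entry
            if elapsed + dt > battery.vmt_time_limit:
                break  # time is up; this entry is never registered
            elapsed += dt
            clock.advance(dt)
            entries.append({"letter": str(letter), "t": elapsed})
        responses["VMT"] = {
            "practice_entries": practice_entries,
            "entries": entries,
            "time_limit": battery.vmt_time_limit,
        }
    except ResponderExhausted as exc:
        partial = SessionRecord(
            subject_id=subject_id,
            language=lang,
            started_at=started_at,
            ended_at=clock.now(),
            task_responses=responses,
        )
        raise IncompleteSessionError(f"session aborted: {exc}", partial) from exc
    return SessionRecord(
        subject_id=subject_id,
        language=lang,
        started_at=started_at,
        ended_at=clock.now(),
        task_responses=responses,
    )


# ---------------------------------------------------------------------------
# Serialization (strict JSON schema, unknown fields rejected)
# ---------------------------------------------------------------------------

_PAYLOAD_FIELDS = {
    "LL": {"transcripts"},
    "CR": {"typed", "sort_actions"},
    "LNS": {"practice_responses", "responses"},
    "DLL": {"transcript"},
    "VMT": {"practice_entries", "entries", "time_limit"},
}
_TOP_FIELDS = {"schema_version", "subject_id", "language", "started_at", "ended_at", "tasks"}


def serialize_session(record: SessionRecord) -> str:
    """Serialize a complete session record to a JSON document (UTF-8 text)."""
    if not record.complete:
        raise SessionError("only complete session records can be serialized")
    doc = {
        "schema_version": record.schema_version,
        "subject_id": record.subject_id,
        "language": record.language,
        "started_at": record.started_at,
        "ended_at": record.ended_at,
        "tasks": [
            {"task": task, "payload": record.task_responses[task]} for task in TASK_ORDER
        ],
    }
    return json.dumps(doc, ensure_ascii=False, indent=2)


def _require(doc: Mapping[str, Any], fields: set[str], where: str) -> None:
    missing = fields - set(doc)
    if missing:
        raise SessionParseError(f"{where}: missing field(s) {sorted(missing)}")
    unknown = set(doc) - fields
    if unknown:
        raise SessionParseError(f"{where}: unknown field(s) {sorted(unknown)}")


def parse_session(document: str | Mapping[str, Any]) -> SessionRecord:
    """Parse and schema-validate a session JSON document.

    Strict: unknown fields are rejected, every task payload must be present,
    and tasks must appear in canonical order. ``parse(serialize(r)) == r``
    for every valid complete record.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise SessionParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(document, Mapping):
        raise SessionParseError("session document must be a JSON object")
    _require(document, _TOP_FIELDS, "session")
    tasks = document["tasks"]
    if not isinstance(tasks, list):
        raise SessionParseError("tasks: must be a list")
    names = tuple(t.get("task") for t in tasks)
    if names != TASK_ORDER:
        raise SessionParseError(
            f"tasks: must appear exactly once each in canonical order {TASK_ORDER}, got {names}"
        )
    task_responses: dict[str, dict[str, Any]] = {}
    for entry in tasks:
        _require(entry, {"task", "payload"}, f"tasks[{entry.get('task')}]")
        task = entry["task"]
        payload = entry["payload"]
        if not isinstance(payload, Mapping):
            raise SessionParseError(f"tasks[{task}].payload: must be an object")
        _require(payload, _PAYLOAD_FIELDS[task], f"tasks[{task}].payload")
        task_responses[task] = dict(payload)
    try:
        return SessionRecord(
            subject_id=str(document["subject_id"]),
            language=str(document["language"]),
            started_at=float(document["started_at"]),
            ended_at=float(document["ended_at"]),
            task_responses=task_responses,
            schema_version=str(document["schema_version"]),
        )
    except SessionError as exc:
        raise SessionParseError(str(exc)) from exc
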