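"""Battery definitions for the five-subtest digital cognitive screening battery.

The battery digitizes a brief cognitive screen for affective disorders. It
consists of five short tasks, administered in a fixed order:

==== ============================== ========================== ==========
id   task                           measure                    score range
==== ============================== ========================== ==========
LL   list learning (3 trials)       verbal memory (immediate)  0-30
CR   consonant repetition           working memory             0-24
LNS  letter-number sequencing       executive function         0-21
DLL  delayed list learning          verbal memory (delayed)    0-10
VMT  visuomotor tracking            psychomotor speed          0-30
==== ============================== ========================== ==========

This module holds the parameterization of those tasks: the 10-word recall
list, the consonant trials with their descending-number-sorting filler, the
letter-number items, and the symbol-code table (codes over a circle/asterisk
alphabet) with its 30-code stream for the timed coding task. Batteries are
value objects validated at construction and round-trip losslessly through a
YAML/JSON config document.

The default word lists ship with neutral common nouns padding the handful of
canonical words; clinical use requires substituting licensed screening lists.
"""

from __future__ import annotations

import itertools
import random
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "SUPPORTED_LANGUAGES",
    "SYMBOL_ALPHABET",
    "BatteryError",
    "UnsupportedLanguageError",
    "BatteryValidationError",
    "InfeasibleAlphabetError",
    "StimulusError",
    "WordList",
    "ConsonantTrial",
    "LNSItem",
    "SortingSet",
    "SymbolCodeTable",
    "BatteryDefinition",
    "lns_expected_answer",
    "default_battery",
    "generate_vmt_materials",
    "load_battery",
    "battery_to_config",
    "dump_battery",
]

SUPPORTED_LANGUAGES = ("en", "da")

#: Textual rendering of the two-symbol code alphabet: "o" = circle, "*" = asterisk.
SYMBOL_ALPHABET = ("o", "*")

_VOWELS = set("aeiouæøå")


class BatteryError(ValueError):
    """Base class for battery construction and validation failures."""


class UnsupportedLanguageError(BatteryError):
    """Requested language has no bundled battery definition."""


class BatteryValidationError(BatteryError):
    """A battery config document violates a structural invariant."""


class InfeasibleAlphabetError(BatteryError):
    """The symbol alphabet cannot produce enough distinct codes."""


class StimulusError(BatteryError):
    """A stimulus is malformed (e.g. duplicate tokens in a sequencing item)."""


def _norm(token: str) -> str:
    return unicodedata.normalize("NFC", str(token).strip().casefold())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WordList:
    """The 10-word recall list used by both the immediate and delayed recall tasks."""

    language: str
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        words = tuple(_norm(w) for w in self.words)
        object.__setattr__(self, "words", words)
        if len(words) != 10:
            raise BatteryValidationError(
                f"word_list must contain exactly 10 words, got {len(words)}"
            )
        if any(not w for w in words):
            raise BatteryValidationError("word_list entries must be non-empty")
        if len(set(words)) != len(words):
            raise BatteryValidationError("word_list entries must be unique")


@dataclass(frozen=True)
class ConsonantTrial:
    """One consonant-repetition trial: letters played, then a sorting filler period."""

    letters: tuple[str, ...]
    filler_duration: float = 30.0

    def __post_init__(self) -> None:
        letters = tuple(_norm(c) for c in self.letters)
        object.__setattr__(self, "letters", letters)
        if not letters:
            raise BatteryValidationError("consonant trial must contain at least one letter")
        for c in letters:
            if len(c) != 1 or not c.isalpha() or c in _VOWELS:
                raise BatteryValidationError(f"consonant trial letters must be consonants, got {c!r}")
        if self.filler_duration <= 0:
            raise BatteryValidationError("filler_duration must be positive")


def lns_expected_answer(presented: Sequence[str]) -> tuple[str, ...]:
    """Canonical answer to a letter-number sequencing stimulus.

    Digits are reported in ascending order, followed by letters in
    alphabetical order. Duplicate tokens make the answer ambiguous and are
    rejected with :class:`StimulusError`.

    >>> lns_expected_answer(["b", "3", "a", "1"])
    ('1', '3', 'a', 'b')
    """
    tokens = tuple(_norm(t) for t in presented)
    for t in tokens:
        if len(t) != 1 or not (t.isdigit() or t.isalpha()):
            raise StimulusError(f"sequencing tokens must be single digits or letters, got {t!r}")
    if len(set(tokens)) != len(tokens):
        raise StimulusError(f"duplicate tokens in sequencing stimulus {tokens!r}")
    digits = sorted(t for t in tokens if t.isdigit())
    letters = sorted(t for t in tokens if t.isalpha())
    return tuple(digits + letters)


@dataclass(frozen=True)
class LNSItem:
    """A letter-number sequencing item; ``expected`` is derived from ``presented``."""

    presented: tuple[str, ...]
    expected: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        presented = tuple(_norm(t) for t in self.presented)
        object.__setattr__(self, "presented", presented)
        canonical = lns_expected_answer(presented)
        if self.expected:
            given = tuple(_norm(t) for t in self.expected)
            if given != canonical:
                raise BatteryValidationError(
                    f"expected answer {given!r} does not match canonical sort {canonical!r}"
                )
        object.__setattr__(self, "expected", canonical)


@dataclass(frozen=True)
class SortingSet:
    """Five distinct numbers served as a drag-and-drop descending-sort filler."""

    numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        numbers = tuple(int(n) for n in self.numbers)
        object.__setattr__(self, "numbers", numbers)
        if len(numbers) != 5:
            raise BatteryValidationError(f"sorting set must contain exactly 5 numbers, got {len(numbers)}")
        if len(set(numbers)) != 5:
            raise BatteryValidationError("sorting set numbers must be distinct")


@dataclass(frozen=True)
class SymbolCodeTable:
    """Key for the coding task: 6 letters, each paired with a unique symbol code."""

    codes: Mapping[str, str]

    def __post_init__(self) -> None:
        codes = {_norm(k): str(v) for k, v in dict(self.codes).items()}
        object.__setattr__(self, "codes", codes)
        if len(codes) != 6:
            raise BatteryValidationError(f"symbol-code table must map exactly 6 letters, got {len(codes)}")
        for letter in codes:
            if len(letter) != 1 or not letter.isalpha():
                raise BatteryValidationError(f"table keys must be single letters, got {letter!r}")
        values = list(codes.values())
        if len(set(values)) != len(values):
            raise BatteryValidationError("symbol codes must be unique")
        lengths = {len(v) for v in values}
        if len(lengths) != 1:
            raise BatteryValidationError("symbol codes must all have the same length")
        for code in values:
            bad = set(code) - set(SYMBOL_ALPHABET)
            if bad:
                raise BatteryValidationError(
                    f"symbol codes must use only {SYMBOL_ALPHABET}, got {sorted(bad)!r}"
                )
        object.__setattr__(self, "_by_code", {v: k for k, v in codes.items()})

    @property
    def code_length(self) -> int:
        return len(next(iter(self.codes.values())))

    def letter_for(self, code: str) -> str:
        """Return the letter keyed by ``code``."""
        try:
            return self._by_code[code]  # type: ignore[attr-defined]
        except KeyError:
            raise StimulusError(f"code {code!r} is not in the symbol table") from None


@dataclass(frozen=True)
class BatteryDefinition:
    """Complete parameterization of one language's five-task battery."""

    language: str
    word_list: WordList
    cr_trials: tuple[ConsonantTrial, ...]
    lns_items: tuple[LNSItem, ...]
    lns_practice: tuple[LNSItem, ...]
    vmt_table: SymbolCodeTable
    vmt_stream: tuple[str, ...]
    vmt_time_limit: float = 30.0
    sorting_sets: tuple[SortingSet, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "cr_trials", tuple(self.cr_trials))
        object.__setattr__(self, "lns_items", tuple(self.lns_items))
        object.__setattr__(self, "lns_practice", tuple(self.lns_practice))
        object.__setattr__(self, "vmt_stream", tuple(str(c) for c in self.vmt_stream))
        object.__setattr__(self, "sorting_sets", tuple(self.sorting_sets))
        if self.word_list.language != self.language:
            raise BatteryValidationError("word_list language must match battery language")
        n_letters = sum(len(t.letters) for t in self.cr_trials)
        if n_letters != 24:
            raise BatteryValidationError(
                f"consonant trials must total 24 letters (score range 0-24), got {n_letters}"
            )
        if len(self.lns_items) != 21:
            raise BatteryValidationError(
                f"battery must contain 21 sequencing items (score range 0-21), got {len(self.lns_items)}"
            )
        if len(self.vmt_stream) != 30:
            raise BatteryValidationError(
                f"code stream must contain 30 codes (score range 0-30), got {len(self.vmt_stream)}"
            )
        known = set(self.vmt_table.codes.values())
        for code in self.vmt_stream:
            if code not in known:
                raise BatteryValidationError(f"stream code {code!r} does not occur in the symbol table")
        if self.vmt_time_limit <= 0:
            raise BatteryValidationError("vmt_time_limit must be positive")
        if not self.sorting_sets:
            raise BatteryValidationError("battery must provide at least one sorting set")


# ---------------------------------------------------------------------------
# Default batteries
# ---------------------------------------------------------------------------

# 10-word recall lists. The named canonical words are padded with neutral
# common nouns; substitute licensed screening lists for clinical use.
_DEFAULT_WORDS = {
    "en": ("machine", "milk", "coffee", "bed", "hat", "garden",
           "river", "paper", "window", "stone"),
    "da": ("mælk", "sømand", "seng", "brev", "kaffe", "have",
           "vindue", "sten", "papir", "flod"),
}

# 8 trials x 3 consonants = 24 creditable letters.
_DEFAULT_CR_TRIPLETS = (
    ("t", "k", "s"), ("m", "r", "p"), ("b", "l", "n"), ("d", "f", "g"),
    ("h", "v", "j"), ("c", "z", "q"), ("w", "x", "b"), ("k", "p", "t"),
)

_DEFAULT_VMT_LETTERS = ("b", "d", "g", "k", "n", "p")
_LANG_SEED = {"en": 101, "da": 202}

_LNS_DIGITS = "123456789"
_LNS_LETTERS = "abcdefgh"


def _make_lns_items(rng: random.Random, lengths: Iterable[int], per_length: int) -> tuple[LNSItem, ...]:
    items = []
    for length in lengths:
        for _ in range(per_length):
            n_digits = rng.randint(1, length - 1)
            tokens = rng.sample(_LNS_DIGITS, n_digits) + rng.sample(_LNS_LETTERS, length - n_digits)
            rng.shuffle(tokens)
            items.append(LNSItem(tuple(tokens)))
    return tuple(items)


def _make_sorting_sets(rng: random.Random, n_sets: int = 12) -> tuple[SortingSet, ...]:
    sets = []
    for _ in range(n_sets):
        numbers = rng.sample(range(10, 100), 5)
        sets.append(SortingSet(tuple(numbers)))
    return tuple(sets)


def generate_vmt_materials(
    letters: Sequence[str],
    code_length: int,
    stream_length: int,
    seed: int,
) -> tuple[SymbolCodeTable, tuple[str, ...]]:
    """Generate a symbol-code table and a random code stream for the coding task.

    Six unique codes of ``code_length`` symbols over the circle/asterisk
    alphabet are assigned to ``letters``, and ``stream_length`` codes are
    drawn (with replacement) from the table. Deterministic in ``seed``.

    Raises
    ------
    InfeasibleAlphabetError
        If ``2 ** code_length < 6`` (not enough distinct codes).
    """
    letters = tuple(_norm(c) for c in letters)
    if len(letters) != 6 or len(set(letters)) != 6:
        raise BatteryValidationError("exactly 6 distinct letters are required")
    if 2 ** code_length < 6:
        raise InfeasibleAlphabetError(
            f"code_length={code_length} yields only {2 ** code_length} codes; 6 are required"
        )
    if stream_length < 1:
        raise BatteryValidationError("stream_length must be at least 1")
    rng = random.Random(seed)
    universe = ["".join(p) for p in itertools.product(SYMBOL_ALPHABET, repeat=code_length)]
    chosen = rng.sample(universe, 6)
    table = SymbolCodeTable(dict(zip(letters, chosen)))
    stream = tuple(rng.choice(chosen) for _ in range(stream_length))
    return table, stream


def default_battery(language: str) -> BatteryDefinition:
    """Return the bundled battery for ``language`` (``"en"`` or ``"da"``)."""
    if language not in SUPPORTED_LANGUAGES:
        raise UnsupportedLanguageError(
            f"unsupported language {language!r}; supported: {SUPPORTED_LANGUAGES}"
        )
    rng = random.Random(_LANG_SEED[language])
    lns_items = _make_lns_items(rng, lengths=range(2, 9), per_length=3)
    lns_practice = _make_lns_items(rng, lengths=(2, 3, 3, 4, 4), per_length=1)
    table, stream = generate_vmt_materials(
        _DEFAULT_VMT_LETTERS, code_length=3, stream_length=30, seed=_LANG_SEED[language] + 1
    )
    return BatteryDefinition(
        language=language,
        word_list=WordList(language, _DEFAULT_WORDS[language]),
        cr_trials=tuple(ConsonantTrial(t) for t in _DEFAULT_CR_TRIPLETS),
        lns_items=lns_items,
        lns_practice=lns_practice,
        vmt_table=table,
        vmt_stream=stream,
        vmt_time_limit=30.0,
        sorting_sets=_make_sorting_sets(rng),
    )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_REQUIRED_SECTIONS = ("language", "word_list", "cr_trials", "lns_items", "lns_practice", "vmt", "sorting_sets")


def battery_to_config(battery: BatteryDefinition) -> dict[str, Any]:
    """Serialize a battery to a plain config mapping (YAML/JSON friendly)."""
    return {
        "language": battery.language,
        "word_list": list(battery.word_list.words),
        "cr_trials": [
            {"letters": list(t.letters), "filler_duration": t.filler_duration}
            for t in battery.cr_trials
        ],
        "lns_items": [list(i.presented) for i in battery.lns_items],
        "lns_practice": [list(i.presented) for i in battery.lns_practice],
        "vmt": {
            "table": dict(battery.vmt_table.codes),
            "stream": list(battery.vmt_stream),
            "time_limit": battery.vmt_time_limit,
        },
        "sorting_sets": [list(s.numbers) for s in battery.sorting_sets],
    }


def dump_battery(battery: BatteryDefinition) -> str:
    """Serialize a battery to a YAML document (UTF-8 safe, Danish æ/ø/å preserved)."""
    return yaml.safe_dump(battery_to_config(battery), allow_unicode=True, sort_keys=False)


def load_battery(config_document: Mapping[str, Any] | str | Path) -> BatteryDefinition:
    """Build a validated battery from a config mapping, YAML text, or file path.

    The ``vmt`` section accepts either an explicit ``table``/``stream`` pair or
    generator parameters ``letters``/``code_length``/``seed`` (with optional
    ``stream_length``, default 30), which are expanded through
    :func:`generate_vmt_materials`.
    """
    if isinstance(config_document, Path):
        config_document = config_document.read_text(encoding="utf-8")
    if isinstance(config_document, str):
        config_document = yaml.safe_load(config_document)
    if not isinstance(config_document, Mapping):
        raise BatteryValidationError("battery config must be a mapping")
    missing = [s for s in _REQUIRED_SECTIONS if s not in config_document]
    if missing:
        raise BatteryValidationError(f"battery config missing sections: {missing}")
    doc = config_document
    vmt = doc["vmt"]
    if "table" in vmt:
        table = SymbolCodeTable(vmt["table"])
        stream = tuple(str(c) for c in vmt["stream"])
    else:
        table, stream = generate_vmt_materials(
            vmt["letters"],
            code_length=int(vmt["code_length"]),
            stream_length=int(vmt.get("stream_length", 30)),
            seed=int(vmt["seed"]),
        )
    return BatteryDefinition(
        language=str(doc["language"]),
        word_list=WordList(str(doc["language"]), tuple(doc["word_list"])),
        cr_trials=tuple(
            ConsonantTrial(tuple(t["letters"]), float(t.get("filler_duration", 30.0)))
            for t in doc["cr_trials"]
        ),
        lns_items=tuple(LNSItem(tuple(str(t) for t in i)) for i in doc["lns_items"]),
        lns_practice=tuple(LNSItem(tuple(str(t) for t in i)) for i in doc["lns_practice"]),
        vmt_table=table,
        vmt_stream=stream,
        vmt_time_limit=float(vmt.get("time_limit", 30.0)),
        sorting_sets=tuple(SortingSet(tuple(s)) for s in doc["sorting_sets"]),
    )
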