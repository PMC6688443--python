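"""Evaluation of speech-recognition transcripts against manual references.

Verbal recall in the battery is captured by automatic speech recognition
(ASR); its quality is measured by comparing the ASR hypothesis transcript to
a manually generated reference transcript. The canonical metric is the word
error rate

    WER = (S + D + I) / N

where N is the number of reference words and S, D, I count substitutions,
deletions and insertions in a minimal-cost word-level alignment (unit costs).
This module provides transcript normalization, the alignment itself with a
deterministic backtrace, WER, the decomposition of errors into
substitution/deletion/insertion ratios, per-word recognition accuracy
tables, and pooled/macro aggregation across recall sessions.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SpeechEvalError",
    "LanguageMismatchError",
    "UndefinedRateError",
    "UndefinedRatioError",
    "TokenSequence",
    "EditOp",
    "AlignmentResult",
    "normalize_token",
    "normalize_transcript",
    "align_words",
    "word_error_rate",
    "error_ratios",
    "per_word_accuracy",
    "aggregate_wer",
    "wer_report",
]


class SpeechEvalError(ValueError):
    pass


class LanguageMismatchError(SpeechEvalError):
    """Reference and hypothesis are in different languages."""


class UndefinedRateError(SpeechEvalError):
    """WER is undefined (empty reference)."""


class UndefinedRatioError(SpeechEvalError):
    """Error ratios are undefined (no errors to decompose)."""


def normalize_token(token: str) -> str:
    """Casefold, NFC-normalize, and strip punctuation from a single token."""
    token = unicodedata.normalize("NFC", token.casefold().strip())
    return "".join(c for c in token if not unicodedata.category(c).startswith("P"))


@dataclass(frozen=True)
class TokenSequence:
    """A normalized, language-tagged sequence of word tokens."""

    language: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        for t in self.tokens:
            if not t or t != normalize_token(t):
                raise SpeechEvalError(f"token {t!r} is not normalized")

    def __len__(self) -> int:
        return len(self.tokens)


def normalize_transcript(raw_text: str, language: str) -> TokenSequence:
    """Tokenize a raw transcript: split on whitespace, casefold, strip punctuation.

    Total on valid text; empty input yields an empty sequence.

    >>> normalize_transcript("Milk, coffee.", "en").tokens
    ('milk', 'coffee')
    """
    tokens = [normalize_token(t) for t in raw_text.split()]
    return TokenSequence(language, tuple(t for t in tokens if t))


@dataclass(frozen=True)
class EditOp:
    """One step of the alignment trace: op is match/sub/del/ins."""

    op: str
    ref: str | None
    hyp: str | None


@dataclass(frozen=True)
class AlignmentResult:
    """Minimal word-level alignment of a hypothesis against a reference.

    Satisfies ``n_ref = matches + substitutions + deletions`` and
    ``len(hypothesis) = matches + substitutions + insertions``;
    S + D + I is the minimal word edit distance.
    """

    n_ref: int
    substitutions: int
    deletions: int
    insertions: int
    ops: tuple[EditOp, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_ref, self.substitutions, self.deletions, self.insertions) < 0:
            raise SpeechEvalError("alignment counts must be non-negative")
        if self.substitutions + self.deletions > self.n_ref:
            raise SpeechEvalError("S + D cannot exceed the reference length")

    @property
    def matches(self) -> int:
        return self.n_ref - self.substitutions - self.deletions

    @property
    def errors(self) -> int:
        return self.substitutions + self.deletions + self.insertions


def align_words(reference: TokenSequence, hypothesis: TokenSequence) -> AlignmentResult:
    """Minimal-edit-distance word alignment with a deterministic backtrace.

    Dynamic programming with unit costs for substitution, deletion and
    insertion. Ties in the backtrace are resolved match/substitute first,
    then delete, then insert, so the op trace is reproducible; the S/D/I
    counts reported are those of that canonical path.
    """
    if reference.language != hypothesis.language:
        raise LanguageMismatchError(
            f"cannot align {reference.language!r} against {hypothesis.language!r}"
        )
    ref, hyp = reference.tokens, hypothesis.tokens
    m, n = len(ref), len(hyp)
    # dist[i][j] = edit distance between ref[:i] and hyp[:j]
    dist = [list(range(n + 1))] + [[i] + [0] * n for i in range(1, m + 1)]
    for i in range(1, m + 1):
        row, prev = dist[i], dist[i - 1]
        ri = ref[i - 1]
        for j in range(1, n + 1):
            best = prev[j - 1] + (ri != hyp[j - 1])
            up = prev[j] + 1
            if up < best:
                best = up
            left = row[j - 1] + 1
            if left < best:
                best = left
            row[j] = best
    ops: list[EditOp] = []
    i, j = m, n
    while i > 0 or j > 0:
        here = dist[i][j]
        if i > 0 and j > 0 and dist[i - 1][j - 1] + (ref[i - 1] != hyp[j - 1]) == here:
            i, j = i - 1, j - 1
            ops.append(EditOp("match" if ref[i] == hyp[j] else "sub", ref[i], hyp[j]))
        elif i > 0 and dist[i - 1][j] + 1 == here:
            i -= 1
            ops.append(EditOp("del", ref[i], None))
        else:
            j -= 1
            ops.append(EditOp("ins", None, hyp[j]))
    ops.reverse()
    counts = {"match": 0, "sub": 0, "del": 0, "ins": 0}
    for op in ops:
        counts[op.op] += 1
    return AlignmentResult(
        n_ref=m,
        substitutions=counts["sub"],
        deletions=counts["del"],
        insertions=counts["ins"],
        ops=tuple(ops),
    )


def word_error_rate(alignment: AlignmentResult) -> float:
    """WER = (S + D + I) / N; undefined for an empty reference."""
    if alignment.n_ref == 0:
        raise UndefinedRateError("WER is undefined for an empty reference (N = 0)")
    return alignment.errors / alignment.n_ref


def _pool(alignments: AlignmentResult | Iterable[AlignmentResult]) -> tuple[int, int, int, int]:
    if isinstance(alignments, AlignmentResult):
        alignments = [alignments]
    n = s = d = i = 0
    for a in alignments:
        n += a.n_ref
        s += a.substitutions
        d += a.deletions
        i += a.insertions
    return n, s, d, i


def error_ratios(
    alignments: AlignmentResult | Iterable[AlignmentResult],
) -> tuple[float, float, float]:
    """Decompose (possibly pooled) errors into (sub %, del %, ins %) of S+D+I.

    The three percentages sum to 100. Undefined when there are no errors.
    """
    _, s, d, i = _pool(alignments)
    total = s + d + i
    if total == 0:
        raise UndefinedRatioError("error ratios are undefined when S + D + I = 0")
    return (100.0 * s / total, 100.0 * d / total, 100.0 * i / total)


def aggregate_wer(
    sessions: Sequence[AlignmentResult], mode: str = "pooled"
) -> float:
    """Aggregate WER across recall sessions.

    ``pooled`` divides total errors by total reference words; ``macro``
    averages per-session WER over sessions with a non-empty reference.
    The two differ when session lengths are unbalanced.
    """
    sessions = list(sessions)
    if not sessions:
        raise UndefinedRateError("at least one session is required")
    if mode == "pooled":
        n, s, d, i = _pool(sessions)
        if n == 0:
            raise UndefinedRateError("pooled WER undefined: all references empty")
        return (s + d + i) / n
    if mode == "macro":
        rates = [word_error_rate(a) for a in sessions if a.n_ref > 0]
        if not rates:
            raise UndefinedRateError("macro WER undefined: all references empty")
        return sum(rates) / len(rates)
    raise ValueError(f"unknown aggregation mode {mode!r}; use 'pooled' or 'macro'")


def per_word_accuracy(
    observations: Iterable[tuple[str, bool]],
) -> pd.DataFrame:
    """Tabulate recognition accuracy per target word.

    Each observation is ``(target word, recognized-correctly flag)``;
    repeated recalls of the same word are counted individually. Returns a
    DataFrame with columns ``word``, ``recalls``, ``correct``, ``accuracy``
    (percent), sorted by recall count descending then word.
    """
    recalls: dict[str, int] = {}
    correct: dict[str, int] = {}
    for word, flag in observations:
        word = normalize_token(word)
        recalls[word] = recalls.get(word, 0) + 1
        correct[word] = correct.get(word, 0) + bool(flag)
    rows = [
        {
            "word": w,
            "recalls": recalls[w],
            "correct": correct[w],
            "accuracy": 100.0 * correct[w] / recalls[w],
        }
        for w in recalls
    ]
    frame = pd.DataFrame(rows, columns=["word", "recalls", "correct", "accuracy"])
    return frame.sort_values(["recalls", "word"], ascending=[False, True]).reset_index(drop=True)


def wer_report(
    sessions: Sequence[AlignmentResult], language: str, mode: str = "pooled"
) -> pd.DataFrame:
    """One-row summary of ASR performance for a language.

    Columns: language, n_sessions, mode, WER, sub_ratio, del_ratio,
    ins_ratio. Percentages are rounded to 2 decimal places for export.
    """
    wer = aggregate_wer(sessions, mode=mode)
    try:
        sub, dele, ins = error_ratios(sessions)
    except UndefinedRatioError:
        sub = dele = ins = float("nan")
    return pd.DataFrame(
        [
            {
                "language": language,
                "n_sessions": len(sessions),
                "mode": mode,
                "WER": round(wer, 4),
                "sub_ratio": round(sub, 2),
                "del_ratio": round(dele, 2),
                "ins_ratio": round(ins, 2),
            }
        ]
    )
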