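"""Text-complexity scoring for parliamentary speeches.

Converts raw speech text into token counts (words, sentences, syllables,
long words) and the readability scores used as outcomes in the panel
analysis: Flesch Reading Ease, Flesch-Kincaid grade level, and RIX
(long words per sentence). Also applies the sample filters: speeches by
parliamentary chairs and speeches shorter than 25 words are excluded.

Segmentation and syllabification are deterministic, documented heuristics
(see :data:`ABBREVIATIONS` and :func:`count_syllables`); the scoring
formulas themselves are exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "UnscorableSpeechError",
    "TokenCounts",
    "ComplexityScores",
    "SpeechRecord",
    "segment_sentences",
    "count_syllables",
    "tokenize",
    "tokenize_and_count",
    "flesch_score",
    "flesch_kincaid_score",
    "rix_score",
    "score_counts",
    "score_text",
    "filter_speeches",
    "score_table",
    "MIN_WORDS",
]

#: Minimum word count for a speech to enter the estimation sample
#: (strictly shorter speeches are interjections / short questions).
MIN_WORDS = 25

#: Abbreviations whose trailing period never terminates a sentence.
ABBREVIATIONS = frozenset({"dr.", "mr.", "mrs.", "st.", "no.", "etc."})


class UnscorableSpeechError(ValueError):
    """Raised when a speech has no scorable content (no words/sentences)."""


@dataclass(frozen=True)
class TokenCounts:
    """Raw token tallies for one speech.

    ``long_words`` counts words with strictly more than 6 letters
    (letters only -- digits and punctuation are ignored), the numerator
    of the RIX score.
    """

    total_words: int
    total_sentences: int
    total_syllables: int
    long_words: int

    def __post_init__(self) -> None:
        if self.total_words < 0 or self.total_syllables < 0 or self.long_words < 0:
            raise ValueError("token counts must be nonnegative")
        if self.total_sentences < 1:
            raise ValueError("total_sentences must be positive")
        if self.long_words > self.total_words:
            raise ValueError("long_words cannot exceed total_words")
        if self.total_words > 0 and self.total_syllables < self.total_words:
            raise ValueError("every word has at least one syllable")


@dataclass(frozen=True)
class ComplexityScores:
    """Readability scores and their two component averages for one speech."""

    flesch: float
    flesch_kincaid: float
    rix: float
    avg_sentence_length: float
    avg_word_syllables: float


@dataclass
class SpeechRecord:
    """One speech: the unit of observation of the panel.

    At least one of ``text`` / ``counts`` must be present.
    """

    speech_id: str
    speaker_id: str
    city: str
    date: _date
    is_chair: bool = False
    text: str | None = None
    counts: TokenCounts | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.text is None and self.counts is None:
            raise ValueError(f"speech {self.speech_id}: need text or counts")


# ---------------------------------------------------------------------------
# tokenization

# Word = alphabetic run with internal apostrophes/hyphens, or a numeral.
_WORD_RE = re.compile(
    r"[^\W\d_]+(?:['’\-][^\W\d_]+)*|\d+(?:[.,]\d+)*",
    re.UNICODE,
)
_TERMINAL_RE = re.compile(r"[.!?;]")
_VOWEL_GROUP_RE = re.compile(r"[aeiouyäöüàèéùáíóú]+")


def tokenize(text: str) -> list[str]:
    """Split text into word tokens (alphabetic runs and numerals)."""
    return _WORD_RE.findall(text)


def segment_sentences(text: str) -> list[str]:
    """Split text into sentences.

    A sentence ends at '.', '!', '?' or ';' followed by whitespace and a
    capital letter, or at end of text. A trailing period belonging to a
    known abbreviation (``Dr.``, ``Mr.``, ...) does not split. Word
    tokens are preserved: the concatenation of the returned sentences
    contains exactly the tokens of the input.

    Raises
    ------
    UnscorableSpeechError
        If the text is empty or whitespace-only.
    """
    normalized = " ".join(text.split())
    if not normalized:
        raise UnscorableSpeechError("empty or whitespace-only text")

    sentences: list[str] = []
    start = 0
    n = len(normalized)
    for m in _TERMINAL_RE.finditer(normalized):
        end = m.end()
        if end < n:
            # require whitespace then a capital letter to split
            j = end
            if normalized[j] != " ":
                continue
            while j < n and normalized[j] == " ":
                j += 1
            if j >= n:
                pass  # trailing spaces: treat as end of text
            elif not normalized[j].isupper():
                continue
        if m.group() == ".":
            tail = normalized[start:end].rsplit(" ", 1)[-1].lower()
            if tail in ABBREVIATIONS:
                continue
        chunk = normalized[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    residue = normalized[start:].strip()
    if residue:
        sentences.append(residue)
    if not sentences:
        sentences = [normalized]
    return sentences


def count_syllables(word: str) -> int:
    """Count syllables of a single word with a vowel-group heuristic.

    Maximal vowel groups (a, e, i, o, u, y) are counted; a terminal
    silent 'e' is subtracted unless the word ends in consonant+'le';
    the result is floored at 1. Tokens without alphabetic characters
    (numerals etc.) count as one syllable.

    The heuristic is English-oriented; pass a different callable as
    ``syllable_counter`` to :func:`tokenize_and_count` for other
    languages.
    """
    w = word.lower().strip("'’-")
    if not any(c.isalpha() for c in w):
        return 1
    groups = len(_VOWEL_GROUP_RE.findall(w))
    # terminal silent 'e': only when it forms its own vowel group (preceded
    # by a consonant) and the word does not end in consonant+'le'
    if (
        w.endswith("e")
        and groups > 1
        and len(w) >= 2
        and not _VOWEL_GROUP_RE.match(w[-2])
        and not (
            len(w) >= 3
            and w.endswith("le")
            and not _VOWEL_GROUP_RE.match(w[-3])
        )
    ):
        groups -= 1
    return max(groups, 1)


def _letters(word: str) -> int:
    return sum(c.isalpha() for c in word)


def tokenize_and_count(
    text: str,
    syllable_counter: Callable[[str], int] = count_syllables,
) -> TokenCounts:
    """Tokenize a speech and tally words, sentences, syllables, long words.

    Raises
    ------
    UnscorableSpeechError
        If the text contains no word tokens.
    """
    sentences = segment_sentences(text)
    words = tokenize(text)
    if not words:
        raise UnscorableSpeechError("no word tokens")
    return TokenCounts(
        total_words=len(words),
        total_sentences=len(sentences),
        total_syllables=sum(syllable_counter(w) for w in words),
        long_words=sum(_letters(w) > 6 for w in words),
    )


# ---------------------------------------------------------------------------
# scores


def flesch_score(counts: TokenCounts) -> float:
    """Flesch Reading Ease: 206.835 − 1.015·ASL − 84.6·ASW.

    ASL = words per sentence, ASW = syllables per word. Higher is easier.
    """
    if counts.total_words == 0 or counts.total_sentences == 0:
        raise UnscorableSpeechError("zero words or sentences")
    asl = counts.total_words / counts.total_sentences
    asw = counts.total_syllables / counts.total_words
    return 206.835 - 1.015 * asl - 84.6 * asw


def flesch_kincaid_score(counts: TokenCounts) -> float:
    """Flesch-Kincaid grade: 0.39·ASL + 11.8·ASW − 15.59.

    Expressed in US school-grade years; higher means more complex.
    """
    if counts.total_words == 0 or counts.total_sentences == 0:
        raise UnscorableSpeechError("zero words or sentences")
    asl = counts.total_words / counts.total_sentences
    asw = counts.total_syllables / counts.total_words
    return 0.39 * asl + 11.8 * asw - 15.59


def rix_score(counts: TokenCounts) -> float:
    """RIX: long words (more than 6 letters) per sentence."""
    if counts.total_sentences == 0:
        raise UnscorableSpeechError("zero sentences")
    return counts.long_words / counts.total_sentences


def score_counts(counts: TokenCounts) -> ComplexityScores:
    """All complexity scores plus component averages from token counts."""
    if counts.total_words == 0 or counts.total_sentences == 0:
        raise UnscorableSpeechError("zero words or sentences")
    return ComplexityScores(
        flesch=flesch_score(counts),
        flesch_kincaid=flesch_kincaid_score(counts),
        rix=rix_score(counts),
        avg_sentence_length=counts.total_words / counts.total_sentences,
        avg_word_syllables=counts.total_syllables / counts.total_words,
    )


def score_text(
    text: str,
    syllable_counter: Callable[[str], int] = count_syllables,
) -> tuple[TokenCounts, ComplexityScores]:
    counts = tokenize_and_count(text, syllable_counter)
    return counts, score_counts(counts)


# ---------------------------------------------------------------------------
# sample filter


def filter_speeches(
    records: Iterable[SpeechRecord],
    min_words: int = MIN_WORDS,
    syllable_counter: Callable[[str], int] = count_syllables,
) -> tuple[list[SpeechRecord], list[dict]]:
    """Apply the sample filters; return (retained, exclusion log).

    A speech is retained iff its speaker is not a parliamentary chair and
    it has at least ``min_words`` words (the threshold is strict:
    24-word speeches are dropped, 25-word speeches kept). Unscorable
    speeches (no tokens) are excluded with a logged reason, never scored
    as zero. Counting uses precomputed counts when available, otherwise
    the text. Each retained record gets its ``counts`` populated.
    """
    kept: list[SpeechRecord] = []
    log: list[dict] = []
    for rec in records:
        if rec.is_chair:
            log.append({"speech_id": rec.speech_id, "reason": "chair"})
            continue
        counts = rec.counts
        if counts is None:
            try:
                counts = tokenize_and_count(rec.text, syllable_counter)
            except UnscorableSpeechError:
                log.append({"speech_id": rec.speech_id, "reason": "unscorable"})
                continue
        if counts.total_words < min_words:
            log.append({"speech_id": rec.speech_id, "reason": "short"})
            continue
        rec.counts = counts
        kept.append(rec)
    return kept, log


# ---------------------------------------------------------------------------
# tabular interface

_COUNT_COLS = ["total_words", "total_sentences", "total_syllables", "long_words"]
_SCORE_COLS = [
    "flesch",
    "flesch_kincaid",
    "rix",
    "avg_sentence_length",
    "avg_word_syllables",
]


def score_table(
    speeches: pd.DataFrame,
    text_col: str = "text",
    id_col: str = "speech_id",
    chair_col: str = "is_chair",
    min_words: int = MIN_WORDS,
    syllable_counter: Callable[[str], int] = count_syllables,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter and score a speech table.

    Returns the retained rows augmented with token-count and score
    columns, and an exclusion log (speech_id, reason) for dropped rows.
    If all four count columns are already present they are used as-is;
    otherwise ``text_col`` is tokenized.
    """
    has_counts = all(c in speeches.columns for c in _COUNT_COLS)
    rows = []
    log = []
    for _, row in speeches.iterrows():
        sid = row[id_col]
        if chair_col in speeches.columns and bool(row[chair_col]):
            log.append({"speech_id": sid, "reason": "chair"})
            continue
        try:
            if has_counts and pd.notna(row["total_words"]):
                counts = TokenCounts(
                    int(row["total_words"]),
                    int(row["total_sentences"]),
                    int(row["total_syllables"]),
                    int(row["long_words"]),
                )
            else:
                counts = tokenize_and_count(str(row[text_col]), syllable_counter)
        except (UnscorableSpeechError, ValueError):
            log.append({"speech_id": sid, "reason": "unscorable"})
            continue
        if counts.total_words < min_words:
            log.append({"speech_id": sid, "reason": "short"})
            continue
        scores = score_counts(counts)
        out = row.to_dict()
        out.update(
            total_words=counts.total_words,
            total_sentences=counts.total_sentences,
            total_syllables=counts.total_syllables,
            long_words=counts.long_words,
            flesch=scores.flesch,
            flesch_kincaid=scores.flesch_kincaid,
            rix=scores.rix,
            avg_sentence_length=scores.avg_sentence_length,
            avg_word_syllables=scores.avg_word_syllables,
        )
        rows.append(out)
    scored = pd.DataFrame(rows)
    log_df = pd.DataFrame(log, columns=["speech_id", "reason"])
    return scored, log_df
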