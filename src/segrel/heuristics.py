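"""Harmonicity-aided candidate transcription.

For trials where the prompted word sequence is known in advance, the
number of harmonicity peaks in the recording estimates the number of
syllable nuclei (vowels) actually produced.  Since omissions are strongly
suffix-biased — speakers drop words late in the sequence far more often
than early ones — a peak count maps to a word count and the candidate
transcription is simply the prompted-word prefix of that length.

Peak counts are inputs here; the acoustic harmonicity analysis itself is
performed externally (e.g. Praat's autocorrelation method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, TypeVar

T = TypeVar("T")

__all__ = ["TranscriptionRule", "peaks_to_word_count", "candidate_transcription"]


@dataclass(frozen=True)
class TranscriptionRule:
    """Mapping parameters: syllables per prompted word and sequence length."""

    syllables_per_word: int = 2
    max_words: int = 8

    def __post_init__(self) -> None:
        if self.syllables_per_word < 1 or self.max_words < 1:
            raise ValueError("syllables_per_word and max_words must be >= 1")


def peaks_to_word_count(n_peaks: int, rule: TranscriptionRule = TranscriptionRule()) -> int:
    """Number of words inferred from a harmonicity peak count.

    ``ceil(n_peaks / syllables_per_word)`` clamped to ``max_words``: for
    disyllabic words, 13 or 14 peaks imply 7 words, 15 or 16 imply all 8.
    """
    if n_peaks < 0:
        raise ValueError(f"n_peaks must be >= 0, got {n_peaks}")
    return min(rule.max_words, math.ceil(n_peaks / rule.syllables_per_word))


def candidate_transcription(prompted_words: Sequence[T], n_words: int) -> list[T]:
    """The first *n_words* prompted words, order preserved."""
    if not 0 <= n_words <= len(prompted_words):
        raise ValueError(
            f"n_words={n_words} outside [0, {len(prompted_words)}]"
        )
    return list(prompted_words[:n_words])
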