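"""Tokenization, sentence splitting, syllabification, and the non-embedding
feature families: readability-formula features, frequency-bin features, and
length features.

The full feature layout (including the two embedding blocks assembled in
:mod:`readrank.pipeline`) is::

    formula[4] | freq_bins[10] | length[2] | embed_wiki[dim] | embed_ehr[dim]

giving 416 columns under the default 200-dimensional embedding config.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .corpus_io import (
    CorpusError,
    DegenerateDocument,
    Document,
    EasyWordList,
    FrequencyTable,
)

# Tokens are maximal alphanumeric runs, allowing internal apostrophe, hyphen,
# or slash (keeps clinical values like "140/90" and "x-ray" intact).
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['\-/][A-Za-z0-9]+)*")

# Terminal punctuation followed by whitespace and a capital/digit starts a new
# sentence; hard newlines optionally do too (EHR notes are full of lists).
_PUNCT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9“\"'(])")

_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


def tokenize(doc: Document, sentence_split_mode: str = "punct+newline") -> Document:
    """Set ``tokens`` and ``sentences`` on a document (in place, returned).

    ``sentence_split_mode``: ``punct`` splits only at terminal punctuation;
    ``punct+newline`` (default) additionally treats hard newlines as
    boundaries so list-style clinical notes do not collapse into one sentence.
    """
    if sentence_split_mode not in ("punct", "punct+newline"):
        raise ValueError(f"unknown sentence_split_mode {sentence_split_mode!r}")

    if sentence_split_mode == "punct+newline":
        chunks = [c for line in doc.text.splitlines() for c in _PUNCT_SPLIT_RE.split(line)]
    else:
        chunks = _PUNCT_SPLIT_RE.split(doc.text.replace("\n", " "))

    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for chunk in chunks:
        chunk_tokens = _TOKEN_RE.findall(chunk)
        if not chunk_tokens:
            continue
        start = len(tokens)
        tokens.extend(chunk_tokens)
        spans.append((start, len(tokens)))

    if not tokens:
        raise DegenerateDocument(f"document {doc.doc_id!r} has no tokens")
    doc.tokens = tokens
    doc.sentences = spans
    return doc


@lru_cache(maxsize=1)
def _syllable_exceptions() -> dict[str, int]:
    table: dict[str, int] = {}
    path = Path(__file__).parent / "data" / "syllable_exceptions.txt"
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.strip():
            word, count = line.split()
            table[word] = int(count)
    return table


def count_syllables(word: str) -> int:
    """Syllable count: exception-dictionary first, vowel-group heuristic
    otherwise (silent final e handled, floor of one).

    Total on non-empty strings; vowel-free tokens such as clinical
    abbreviations ("HTN") count as one syllable.
    """
    if not word:
        raise ValueError("empty token")
    w = word.lower()
    hit = _syllable_exceptions().get(w)
    if hit is not None:
        return hit
    groups = _VOWEL_GROUP_RE.findall(w)
    n = len(groups)
    if n > 1 and w.endswith("e") and not w.endswith(("le", "ee", "ye", "oe", "ie", "ae", "ue")):
        n -= 1
    return max(n, 1)


_NUMERIC_RE = re.compile(r"[A-Za-z]")


def _is_numeric(token: str) -> bool:
    return _NUMERIC_RE.search(token) is None


@dataclass(frozen=True)
class SurfaceStats:
    """Token/sentence/syllable counts feeding the formula features."""

    n_tokens: int
    n_sentences: int
    n_syllables: int
    n_polysyllabic: int  # words with MORE THAN 3 syllables
    n_difficult: int  # non-numeric words absent from the easy-word list


def surface_stats(doc: Document, easy: EasyWordList) -> SurfaceStats:
    if not doc.is_tokenized:
        raise ValueError(f"document {doc.doc_id!r} not tokenized")
    n_syll = 0
    n_poly = 0
    n_diff = 0
    for tok in doc.tokens:
        s = count_syllables(tok)
        n_syll += s
        if s > 3:
            n_poly += 1
        if not _is_numeric(tok) and tok not in easy:
            n_diff += 1
    return SurfaceStats(
        n_tokens=len(doc.tokens),
        n_sentences=len(doc.sentences),
        n_syllables=n_syll,
        n_polysyllabic=n_poly,
        n_difficult=n_diff,
    )


def formula_features(stats: SurfaceStats) -> np.ndarray:
    """Four readability-formula features.

    ``[avg words/sentence, avg syllables/word, polysyllabic proportion,
    difficult-word percentage]`` — the FKGL inputs, the Gunning-Fog
    polysyllabic share (strictly more than 3 syllables), and the Dale-Chall
    difficult-word percentage in [0, 100].
    """
    if stats.n_sentences == 0 or stats.n_tokens == 0:
        raise DegenerateDocument("zero sentences or tokens")
    return np.array(
        [
            stats.n_tokens / stats.n_sentences,
            stats.n_syllables / stats.n_tokens,
            stats.n_polysyllabic / stats.n_tokens,
            100.0 * stats.n_difficult / stats.n_tokens,
        ]
    )


def fkgl(doc: Document) -> float:
    """Flesch-Kincaid Grade Level, unclipped.

    ``0.39 * words/sentence + 11.8 * syllables/word - 15.59``
    """
    if not doc.is_tokenized:
        raise ValueError(f"document {doc.doc_id!r} not tokenized")
    n_tokens = len(doc.tokens)
    n_sentences = len(doc.sentences)
    if n_tokens == 0 or n_sentences == 0:
        raise DegenerateDocument(f"document {doc.doc_id!r} is degenerate")
    n_syll = sum(count_syllables(t) for t in doc.tokens)
    return 0.39 * (n_tokens / n_sentences) + 11.8 * (n_syll / n_tokens) - 15.59


def build_frequency_table(corpus) -> FrequencyTable:
    """Count lowercased tokens over the whole corpus (all sources combined)
    and place decile-of-log-frequency bin edges."""
    counts: Counter[str] = Counter()
    for doc in corpus:
        if not doc.is_tokenized:
            raise ValueError(f"document {doc.doc_id!r} not tokenized")
        counts.update(t.lower() for t in doc.tokens)
    if not counts:
        raise CorpusError("empty corpus")
    return FrequencyTable.from_counts(dict(counts))


def frequency_bin_features(doc: Document, table: FrequencyTable) -> np.ndarray:
    """Proportion of the document's tokens in each of the 10 frequency bins.

    Out-of-table tokens fall in bin 0 (lowest frequency). Proportions sum to
    one for any non-empty document.
    """
    if not doc.is_tokenized or not doc.tokens:
        raise DegenerateDocument(f"document {doc.doc_id!r} has no tokens")
    if not table.counts:
        raise CorpusError("empty frequency table")
    bins = np.zeros(10)
    for tok in doc.tokens:
        bins[table.bin_of(tok.lower())] += 1
    return bins / len(doc.tokens)


def length_features(doc: Document) -> np.ndarray:
    """Document length in words and in sentences."""
    if not doc.is_tokenized:
        raise ValueError(f"document {doc.doc_id!r} not tokenized")
    return np.array([float(len(doc.tokens)), float(len(doc.sentences))])
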