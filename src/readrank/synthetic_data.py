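"""Synthetic study generator: corpora with planted difficulty plus simulated
crowd raters, so the whole pipeline is testable without any external data.

Documents are assembled from generated pseudo-word lexicons — an "easy"
lexicon of short words and a "hard" lexicon of jargon-like words — with a
per-document jargon density. Two difficulty modes are supported:

``formula``
    hard words are long and polysyllabic; the planted latent difficulty is a
    linear function of the realized polysyllabic proportion and average
    sentence length, i.e. linear in the formula features, so a linear ranker
    can recover it exactly.
``vocab``
    both lexicons share identical word shapes (length and syllable count)
    and sentence structure is held constant, so surface formulas carry no
    signal; the latent difficulty is the realized hard-lexicon fraction and
    can only be picked up through vocabulary-sensitive features.

Raters rate ``pairs_per_rater`` side-by-side pairs (default 20: 5 wiki-wiki,
5 ehr-ehr, 10 mixed) matched within 50 tokens and 0.5 FKGL grade; the rating
is a clipped, rounded affine map of latent-plus-noise, reversed for
"eccentric" raters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import text_features
from .corpus_io import Document, RatingRecord, write_corpus, write_ratings
from .evaluation import stratified_split

logger = logging.getLogger(__name__)

_TOPICS = ("cancer", "diabetes", "hypertension")
_CONSONANTS = list("bcdfghjklmnprstvz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to generate one reproducible study."""

    n_documents_per_cell: int = 20  # per source x topic cell (or see docs_per_cell)
    docs_per_cell: dict | None = None  # optional {(source, topic): n} override
    easy_lexicon_size: int = 120
    hard_lexicon_size: int = 120
    n_abbreviations: int = 20
    jargon_density_range: tuple[float, float] = (0.05, 0.6)
    sentence_length_range: tuple[int, int] = (8, 12)
    n_sentences_range: tuple[int, int] = (8, 12)
    abbrev_rate: float = 0.05  # EHR-source documents only
    difficulty_mode: str = "formula"  # or "vocab"
    latent_w_jargon: float = 8.0
    latent_w_sentlen: float = 0.12
    latent_w_abbrev: float = 0.0
    n_raters: int = 20
    pairs_per_rater: int = 20
    pair_composition: tuple[int, int, int] = (5, 5, 10)  # wiki-wiki, ehr-ehr, mixed
    noise_sd: float = 0.0  # in latent-SD units
    eccentric_fraction: float = 0.0
    match_constraints: bool = True  # enforce |dTokens|<=50 and |dFKGL|<=0.5
    rating_mode: str = "affine"  # or "rank" (tie-free within each rater)
    rating_gain: float = 1.8
    rater_offset_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.pair_composition) != self.pairs_per_rater:
            raise ValueError("pair composition must sum to pairs_per_rater")
        if self.easy_lexicon_size < 10 or self.hard_lexicon_size < 10:
            raise ValueError("lexicon sizes must be >= 10")
        if self.difficulty_mode not in ("formula", "vocab"):
            raise ValueError(f"unknown difficulty_mode {self.difficulty_mode!r}")
        if self.rating_mode not in ("affine", "rank"):
            raise ValueError(f"unknown rating_mode {self.rating_mode!r}")
        if min(self.n_documents_per_cell, self.n_raters, self.pairs_per_rater) <= 0:
            raise ValueError("all counts must be positive")


def preset(name: str, seed: int = 0, **overrides) -> StudyConfig:
    """Named study presets: ``tiny``, ``default``, ``vocab``, ``paper-scale``."""
    presets = {
        "tiny": dict(
            n_documents_per_cell=6, n_raters=6, pairs_per_rater=10, pair_composition=(2, 2, 6),
            easy_lexicon_size=40, hard_lexicon_size=40,
        ),
        "default": dict(),
        # parameter-recovery preset: tie-free rank ratings and unconstrained
        # pairing, so within-rater latent variance equals corpus variance
        # (the side-by-side matching constraints would otherwise make the
        # pair-mates nearly equal in latent difficulty by construction)
        "recovery": dict(
            rating_mode="rank", pairs_per_rater=10, pair_composition=(2, 2, 6),
            n_raters=60, rater_offset_sd=0.0, match_constraints=False,
        ),
        "vocab": dict(
            difficulty_mode="vocab", n_raters=24,
            jargon_density_range=(0.1, 0.9),
            sentence_length_range=(10, 10), n_sentences_range=(10, 10),
            abbrev_rate=0.0,
        ),
        "paper-scale": dict(
            docs_per_cell={
                ("wikipedia", "cancer"): 215, ("wikipedia", "diabetes"): 74,
                ("wikipedia", "hypertension"): 85, ("ehr", "cancer"): 127,
                ("ehr", "diabetes"): 195, ("ehr", "hypertension"): 231,
            },
            n_raters=90,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r} (choose from {sorted(presets)})")
    return StudyConfig(seed=seed, **{**presets[name], **overrides})


# ---------------------------------------------------------------------------
# lexicons


def _make_word(rng, n_syllables: int, coda_p: float = 0.4) -> str:
    parts = []
    for _ in range(n_syllables):
        syl = rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
        if rng.random() < coda_p:
            syl += rng.choice(_CONSONANTS)
        parts.append(syl)
    return "".join(parts)


def _make_lexicon(rng, size: int, syllable_range: tuple[int, int]) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < size:
        n = int(rng.integers(syllable_range[0], syllable_range[1] + 1))
        w = _make_word(rng, n)
        # the vowel-group heuristic must agree with the template, so the
        # planted polysyllabic status is exact
        if w not in seen and text_features.count_syllables(w) == n:
            seen.add(w)
            words.append(w)
    return words


def _make_abbreviations(rng, size: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < size:
        k = int(rng.integers(2, 5))
        w = "".join(rng.choice(_CONSONANTS) for _ in range(k)).upper()
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


# ---------------------------------------------------------------------------
# corpus generation


def generate_corpus(config: StudyConfig):
    """Generate the study corpus.

    Returns ``(documents, latent)`` where documents are tokenized and
    ``latent`` maps doc_id to the hidden difficulty used to drive ratings.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    if config.difficulty_mode == "formula":
        easy_syll, hard_syll = (1, 2), (4, 6)
    else:  # vocab: identical shapes so surface formulas carry nothing
        easy_syll, hard_syll = (2, 2), (2, 2)
    easy_lex = _make_lexicon(rng, config.easy_lexicon_size, easy_syll)
    hard_lex = _make_lexicon(rng, config.hard_lexicon_size, hard_syll)
    if config.difficulty_mode == "vocab":
        # dedupe across the two lexicons; overlap would blur the planted signal
        hard_set = [w for w in hard_lex if w not in set(easy_lex)]
        while len(hard_set) < config.hard_lexicon_size:
            w = _make_word(rng, 2)
            if w not in set(easy_lex) and w not in set(hard_set):
                hard_set.append(w)
        hard_lex = hard_set
    abbrevs = _make_abbreviations(rng, config.n_abbreviations)

    cells = config.docs_per_cell or {
        (src, top): config.n_documents_per_cell
        for src in ("wikipedia", "ehr")
        for top in _TOPICS
    }

    docs: list[Document] = []
    latent: dict[str, float] = {}
    counter = 0
    for (src, top) in sorted(cells):
        for _ in range(cells[(src, top)]):
            doc_id = f"doc{counter:04d}"
            counter += 1
            density = rng.uniform(*config.jargon_density_range)
            doc = _generate_document(
                rng, doc_id, src, top, density, easy_lex, hard_lex, abbrevs, config
            )
            text_features.tokenize(doc)
            latent[doc_id] = _latent_difficulty(doc, hard_lex, config)
            docs.append(doc)
    return docs, latent


def _generate_document(rng, doc_id, source, topic, density, easy_lex, hard_lex, abbrevs, config):
    n_sent = int(rng.integers(config.n_sentences_range[0], config.n_sentences_range[1] + 1))
    mean_len = int(rng.integers(config.sentence_length_range[0], config.sentence_length_range[1] + 1))
    lines = []
    for _ in range(n_sent):
        lo, hi = config.sentence_length_range
        if lo == hi:
            k = lo
        else:
            k = int(np.clip(rng.integers(mean_len - 2, mean_len + 3), 2, None))
        words = []
        for _ in range(k):
            if source == "ehr" and rng.random() < config.abbrev_rate:
                words.append(abbrevs[int(rng.integers(len(abbrevs)))])
            elif rng.random() < density:
                words.append(hard_lex[int(rng.integers(len(hard_lex)))])
            else:
                words.append(easy_lex[int(rng.integers(len(easy_lex)))])
        if source == "ehr":
            lines.append("- " + " ".join(words))
        else:
            lines.append(" ".join(words).capitalize() + ".")
    text = "\n".join(lines) if source == "ehr" else " ".join(lines)
    return Document(doc_id=doc_id, text=text, source=source, topic=topic)


def _latent_difficulty(doc: Document, hard_lex, config: StudyConfig) -> float:
    n = len(doc.tokens)
    wps = n / len(doc.sentences)
    if config.difficulty_mode == "vocab":
        hard = set(hard_lex)
        return sum(1 for t in doc.tokens if t.lower() in hard) / n
    n_poly = sum(1 for t in doc.tokens if text_features.count_syllables(t) > 3)
    n_abbr = sum(1 for t in doc.tokens if t.isupper())
    return (
        config.latent_w_jargon * (n_poly / n)
        + config.latent_w_sentlen * wps
        + config.latent_w_abbrev * (n_abbr / n)
    )


# ---------------------------------------------------------------------------
# rater simulation


def simulate_raters(corpus, latent: dict[str, float], config: StudyConfig) -> list[RatingRecord]:
    """Simulate AMT-style raters over a generated corpus.

    Every emitted pair satisfies the side-by-side matching constraints
    (|delta tokens| <= 50 and |delta FKGL| <= 0.5); ratings are a clipped
    affine map of standardized latent difficulty plus Gaussian noise, with
    the sign reversed for eccentric raters. Documents are drawn with
    replacement across raters, so most receive two or more ratings.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    info = {
        d.doc_id: (len(d.tokens), text_features.fkgl(d), d.source) for d in corpus
    }
    pools = {
        "wikipedia": sorted(d for d, (_, _, s) in info.items() if s == "wikipedia"),
        "ehr": sorted(d for d, (_, _, s) in info.items() if s == "ehr"),
    }
    for src, pool in pools.items():
        if len(pool) < 2:
            raise ValueError(f"need >= 2 documents of source {src!r}")

    vals = np.array([latent[d] for d in sorted(latent)])
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0:
        sd = 1.0
    z = {d: (latent[d] - mu) / sd for d in latent}

    n_ecc = int(round(config.eccentric_fraction * config.n_raters))
    ecc_ids = set(rng.choice(config.n_raters, size=n_ecc, replace=False).tolist()) if n_ecc else set()

    records: list[RatingRecord] = []
    classes = (
        [("wikipedia", "wikipedia")] * config.pair_composition[0]
        + [("ehr", "ehr")] * config.pair_composition[1]
        + [("wikipedia", "ehr")] * config.pair_composition[2]
    )
    for rater_idx in range(config.n_raters):
        rater_id = f"rater{rater_idx:03d}"
        sign = -1.0 if rater_idx in ecc_ids else 1.0
        offset = rng.normal(0.0, config.rater_offset_sd)
        pairs = [
            _draw_pair(rng, pools, info, src_a, src_b, matched=config.match_constraints)
            for src_a, src_b in classes
        ]

        seen_docs = sorted({d for pair in pairs for d in pair})
        perceived = {d: sign * z[d] + rng.normal(0.0, config.noise_sd) for d in seen_docs}
        if config.rating_mode == "rank":
            # spread within-rater ranks over the full 1-10 scale; tie-free
            # whenever the rater sees <= 10 distinct documents
            order = sorted(seen_docs, key=lambda d: perceived[d])
            n = len(order)
            rating_of = {
                d: int(np.rint(1 + 9 * i / (n - 1))) if n > 1 else 5
                for i, d in enumerate(order)
            }
        else:
            rating_of = {
                d: int(np.clip(np.rint(5.5 + config.rating_gain * perceived[d] + offset), 1, 10))
                for d in seen_docs
            }

        for pair_idx, (a, b) in enumerate(pairs):
            pair_id = f"{rater_id}-p{pair_idx:02d}"
            for doc in (a, b):
                records.append(
                    RatingRecord(
                        rater_id=rater_id, pair_id=pair_id, doc_id=doc, rating=rating_of[doc]
                    )
                )
    return records


def _draw_pair(rng, pools, info, src_a, src_b, matched: bool = True, max_tries: int = 500):
    for _ in range(max_tries):
        a = pools[src_a][int(rng.integers(len(pools[src_a])))]
        na, fa, _ = info[a]
        if matched:
            candidates = [
                d
                for d in pools[src_b]
                if d != a and abs(info[d][0] - na) <= 50 and abs(info[d][1] - fa) <= 0.5
            ]
        else:
            candidates = [d for d in pools[src_b] if d != a]
        if candidates:
            return a, candidates[int(rng.integers(len(candidates)))]
    raise ValueError(
        "could not draw a matched document pair within the length/FKGL "
        "constraints; loosen the constraints or enlarge the corpus"
    )


# ---------------------------------------------------------------------------
# fixtures


def generate_study(config: StudyConfig):
    """In-memory study bundle: ``(documents, latent, ratings, split)``."""
    docs, latent = generate_corpus(config)
    ratings = simulate_raters(docs, latent, config)
    split = stratified_split(docs, seed=config.seed)
    return docs, latent, ratings, split


def make_study_fixture(config: StudyConfig, out_dir: str | Path) -> dict:
    """Write a full on-disk study: corpus dir + manifest.csv, ratings.csv,
    latent.csv, split.json. Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs, latent, ratings, split = generate_study(config)

    corpus_dir = out / "corpus"
    write_corpus(docs, corpus_dir)
    write_ratings(ratings, out / "ratings.csv")
    with open(out / "latent.csv", "w", encoding="utf-8") as fh:
        fh.write("doc_id,latent\n")
        for d in sorted(latent):
            fh.write(f"{d},{latent[d]!r}\n")
    (out / "split.json").write_text(json.dumps(split.assignment, indent=0, sort_keys=True))
    return {
        "corpus": corpus_dir,
        "manifest": corpus_dir / "manifest.csv",
        "ratings": out / "ratings.csv",
        "latent": out / "latent.csv",
        "split": out / "split.json",
    }
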