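"""Readers and writers for documents, ratings, frequency tables, easy-word
lists, word vectors, and serialized ranking models.

All downstream modules consume only the types defined here. Documents live as
UTF-8 plain text, one file per document, described by a ``manifest.csv``
(``doc_id,source,topic,filename``); ratings as ``ratings.csv``
(``rater_id,pair_id,doc_id,rating``).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("wikipedia", "ehr")
TOPICS = ("cancer", "diabetes", "hypertension", "other")

MODEL_FORMAT_VERSION = "readrank-model-1"


class CorpusError(ValueError):
    """Structural problem in a corpus, manifest, or ratings file."""


class DegenerateDocument(ValueError):
    """Document has no tokens (or no sentences) after tokenization."""


@dataclass
class Document:
    """A single text with source/topic metadata and derived token structure.

    ``tokens`` and ``sentences`` stay ``None`` until
    :func:`readrank.text_features.tokenize` is applied. ``sentences`` holds
    ``(start, stop)`` token-index spans that partition ``tokens``.
    """

    doc_id: str
    text: str
    source: str
    topic: str
    tokens: list[str] | None = None
    sentences: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise CorpusError(
                f"document {self.doc_id!r}: unknown source {self.source!r} "
                f"(expected one of {SOURCES})"
            )
        if self.topic not in TOPICS:
            raise CorpusError(
                f"document {self.doc_id!r}: unknown topic {self.topic!r} "
                f"(expected one of {TOPICS})"
            )

    @property
    def is_tokenized(self) -> bool:
        return self.tokens is not None and self.sentences is not None


@dataclass(frozen=True)
class RatingRecord:
    """One rater's 1-10 difficulty rating of one document within a pair."""

    rater_id: str
    pair_id: str
    doc_id: str
    rating: int

    def __post_init__(self) -> None:
        if not 1 <= self.rating <= 10:
            raise ValueError(f"rating {self.rating} outside 1-10")


@dataclass
class FrequencyTable:
    """Token counts plus 11 ascending bin edges defining 10 frequency bins.

    Edges are deciles of the log-count distribution over types; tokens absent
    from the table are treated as belonging to the lowest-frequency bin.
    """

    counts: dict[str, int]
    bin_edges: np.ndarray

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "FrequencyTable":
        if len(counts) < 10:
            raise CorpusError(
                f"frequency table needs >= 10 distinct types, got {len(counts)}"
            )
        logc = np.log(np.fromiter(counts.values(), dtype=float, count=len(counts)))
        edges = np.quantile(logc, np.linspace(0.0, 1.0, 11))
        return cls(counts=counts, bin_edges=edges)

    def bin_of(self, token: str) -> int:
        """0-based bin index for a (lowercased) token; OOV -> bin 0."""
        c = self.counts.get(token)
        if c is None:
            return 0
        x = math.log(c)
        # interior edges only: values below edge[1] -> bin 0, above edge[9] -> bin 9
        idx = int(np.searchsorted(self.bin_edges[1:-1], x, side="right"))
        return min(idx, 9)


@dataclass
class EasyWordList:
    """Case-insensitive membership list of 'easy' words."""

    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise CorpusError("easy-word list is empty")
        object.__setattr__(self, "words", frozenset(w.lower() for w in self.words))

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.words


# ---------------------------------------------------------------------------
# corpus


def read_corpus(path: str | Path, manifest: str | Path | pd.DataFrame | None = None):
    """Load a directory of .txt documents described by a manifest.

    Parameters
    ----------
    path : directory containing one plain-text file per document.
    manifest : path to manifest.csv (``doc_id,source,topic,filename``) or a
        pre-loaded DataFrame. Defaults to ``path/manifest.csv``.

    Returns
    -------
    list[Document] in manifest order, text loaded, derived fields unset.
    """
    path = Path(path)
    if manifest is None:
        manifest = path / "manifest.csv"
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, dtype=str)
    required = {"doc_id", "source", "topic", "filename"}
    if not required.issubset(manifest.columns):
        raise CorpusError(f"manifest missing columns {required - set(manifest.columns)}")

    docs: list[Document] = []
    seen: set[str] = set()
    for row in manifest.itertuples(index=False):
        if row.doc_id in seen:
            raise CorpusError(f"duplicate doc_id {row.doc_id!r} in manifest")
        seen.add(row.doc_id)
        fpath = path / row.filename
        if not fpath.is_file():
            raise CorpusError(f"missing file for doc_id {row.doc_id!r}: {fpath}")
        docs.append(
            Document(
                doc_id=row.doc_id,
                text=fpath.read_text(encoding="utf-8"),
                source=row.source,
                topic=row.topic,
            )
        )
    return docs


def write_corpus(docs, path: str | Path) -> None:
    """Write documents as .txt files plus manifest.csv under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in docs:
        fname = f"{doc.doc_id}.txt"
        (path / fname).write_text(doc.text, encoding="utf-8")
        rows.append(
            {"doc_id": doc.doc_id, "source": doc.source, "topic": doc.topic, "filename": fname}
        )
    pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# ratings


def read_ratings(path: str | Path) -> list[RatingRecord]:
    """Read and validate a ratings.csv.

    Rows whose rating falls outside 1-10 (or is non-integer) are dropped with
    a logged warning; a (rater_id, pair_id) group not containing exactly 2
    distinct documents is a hard error.
    """
    df = pd.read_csv(path, dtype={"rater_id": str, "pair_id": str, "doc_id": str})
    required = {"rater_id", "pair_id", "doc_id", "rating"}
    if not required.issubset(df.columns):
        raise CorpusError(f"ratings file missing columns {required - set(df.columns)}")

    records: list[RatingRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            rating = int(row.rating)
            if rating != float(row.rating):
                raise ValueError
            rec = RatingRecord(
                rater_id=row.rater_id, pair_id=row.pair_id, doc_id=row.doc_id, rating=rating
            )
        except (ValueError, TypeError):
            n_rejected += 1
            logger.warning(
                "rejecting rating row (rater=%s pair=%s doc=%s rating=%r)",
                row.rater_id, row.pair_id, row.doc_id, row.rating,
            )
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("rejected %d invalid rating rows", n_rejected)

    _validate_pairs(records)
    return records


def _validate_pairs(records) -> None:
    groups: dict[tuple[str, str], set[str]] = {}
    for r in records:
        groups.setdefault((r.rater_id, r.pair_id), set()).add(r.doc_id)
    for (rater, pair), docs in groups.items():
        if len(docs) != 2:
            raise CorpusError(
                f"pair {pair!r} of rater {rater!r} has {len(docs)} distinct "
                f"documents, expected 2"
            )


def write_ratings(records, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"rater_id": r.rater_id, "pair_id": r.pair_id, "doc_id": r.doc_id, "rating": r.rating}
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# frequency table / easy words / word vectors


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a ``token<TAB>count`` table and derive decile bin edges."""
    counts: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        token, _, count = line.partition("\t")
        counts[token] = int(count)
    return FrequencyTable.from_counts(counts)


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for token, count in sorted(table.counts.items()):
            fh.write(f"{token}\t{count}\n")


def read_easy_words(path: str | Path) -> EasyWordList:
    words = {w.strip() for w in Path(path).read_text(encoding="utf-8").splitlines() if w.strip()}
    return EasyWordList(words=frozenset(words))


def default_easy_words() -> EasyWordList:
    """The bundled easy-word list (common-word approximation, overridable)."""
    return read_easy_words(Path(__file__).parent / "data" / "easy_words.txt")


def read_word_vectors(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Read word vectors in the standard text format.

    First line: ``<vocab_size> <dim>``; then one ``token v1 .. vdim`` per line.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusError(f"bad word-vector header in {path}")
        n, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise CorpusError(f"bad vector row for token {parts[0]!r}")
            vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
    if len(vectors) != n:
        raise CorpusError(f"header promised {n} vectors, found {len(vectors)}")
    return vectors, dim


def write_word_vectors(vectors: dict[str, np.ndarray], path: str | Path) -> None:
    dims = {len(v) for v in vectors.values()}
    if len(dims) != 1:
        raise CorpusError("inconsistent vector dimensions")
    dim = dims.pop()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(vectors)} {dim}\n")
        for token, vec in vectors.items():
            fh.write(token + " " + " ".join(repr(float(x)) for x in vec) + "\n")


# ---------------------------------------------------------------------------
# model serialization


def write_model(model, path: str | Path) -> None:
    """Serialize a RankModel to a single JSON file (bit-exact floats)."""
    payload = {
        "format": MODEL_FORMAT_VERSION,
        "layout_version": model.layout_version,
        "weights": [float(w) for w in model.weights],
        "c_tradeoff": float(model.c_tradeoff),
        "scaler_mean": [float(x) for x in model.scaler_mean],
        "scaler_scale": [float(x) for x in model.scaler_scale],
        "training_diagnostics": model.training_diagnostics,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_model(path: str | Path, expected_layout: str | None = None):
    from .ranker import RankModel  # deferred to avoid an import cycle

    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise CorpusError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT_VERSION:
        raise CorpusError(f"{path} is not a {MODEL_FORMAT_VERSION} file")
    if expected_layout is not None and payload["layout_version"] != expected_layout:
        raise CorpusError(
            f"model layout {payload['layout_version']!r} does not match "
            f"expected {expected_layout!r}"
        )
    return RankModel(
        weights=np.asarray(payload["weights"], dtype=np.float64),
        c_tradeoff=payload["c_tradeoff"],
        layout_version=payload["layout_version"],
        scaler_mean=np.asarray(payload["scaler_mean"], dtype=np.float64),
        scaler_scale=np.asarray(payload["scaler_scale"], dtype=np.float64),
        training_diagnostics=payload["training_diagnostics"],
    )
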