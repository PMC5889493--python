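"""Source-specific skip-gram embeddings and document-level mean pooling.

Two embeddings are trained — one on the wikipedia-source documents, one on
the EHR-source documents — and BOTH are applied to every document at feature
time, so the model can score documents of unknown source.

The trainer is a self-contained skip-gram with negative sampling (SGNS)
implemented on numpy: single-threaded, fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import CorpusError, Document


@dataclass
class EmbeddingConfig:
    dim: int = 200
    window: int = 5
    min_count: int = 2
    epochs: int = 10
    negatives: int = 5
    learning_rate: float = 0.025
    seed: int = 0


@dataclass
class EmbeddingModel:
    """Token -> vector map for one source, all vectors of length ``dim``."""

    source_tag: str
    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for tok, vec in self.vectors.items():
            if len(vec) != self.dim:
                raise CorpusError(f"vector for {tok!r} has length {len(vec)}, expected {self.dim}")


def train_embedding(corpus, source_tag: str, config: EmbeddingConfig | None = None) -> EmbeddingModel:
    """Train a skip-gram embedding on the documents of one source.

    ``corpus`` is filtered to ``source_tag`` here; passing an already-filtered
    corpus is fine. Deterministic given ``config.seed``.
    """
    if config is None:
        config = EmbeddingConfig()
    docs = [d for d in corpus if d.source == source_tag]
    if not docs:
        raise CorpusError(f"no documents with source {source_tag!r}")
    sentences = []
    for doc in docs:
        if not doc.is_tokenized:
            raise ValueError(f"document {doc.doc_id!r} not tokenized")
        for start, stop in doc.sentences:
            sentences.append([t.lower() for t in doc.tokens[start:stop]])
    vectors = _train_sgns(sentences, config)
    return EmbeddingModel(source_tag=source_tag, dim=config.dim, vectors=vectors)


def _train_sgns(sentences: list[list[str]], cfg: EmbeddingConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)

    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= cfg.min_count)
    if not vocab:
        raise CorpusError("no token meets min_count; corpus too small")
    index = {t: i for i, t in enumerate(vocab)}
    v = len(vocab)

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    neg_p = freq / freq.sum()

    # (center, context) pairs within the window, restricted to in-vocab tokens
    centers: list[int] = []
    contexts: list[int] = []
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        for i, c in enumerate(ids):
            lo = max(0, i - cfg.window)
            hi = min(len(ids), i + cfg.window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers:
        raise CorpusError("corpus yields no skip-gram pairs")
    centers_arr = np.asarray(centers, dtype=np.int64)
    contexts_arr = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers_arr)

    w_in = (rng.random((v, cfg.dim)) - 0.5) / cfg.dim
    w_out = np.zeros((v, cfg.dim))

    batch = 1024
    total_steps = cfg.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            sel = order[lo : lo + batch]
            lr = cfg.learning_rate * max(1.0 - step / total_steps, 1e-4)
            step += 1
            c_idx = centers_arr[sel]
            o_idx = contexts_arr[sel]
            neg_idx = rng.choice(v, size=(len(sel), cfg.negatives), p=neg_p)

            c_vec = w_in[c_idx]  # (b, d)
            o_vec = w_out[o_idx]  # (b, d)
            n_vec = w_out[neg_idx]  # (b, k, d)

            pos_score = _sigmoid(np.einsum("bd,bd->b", c_vec, o_vec))
            neg_score = _sigmoid(np.einsum("bd,bkd->bk", c_vec, n_vec))

            g_pos = (pos_score - 1.0)[:, None]  # (b, 1)
            g_neg = neg_score[:, :, None]  # (b, k, 1)

            grad_c = g_pos * o_vec + np.einsum("bkd->bd", g_neg * n_vec)
            np.add.at(w_in, c_idx, -lr * grad_c)
            np.add.at(w_out, o_idx, -lr * (g_pos * c_vec))
            np.add.at(
                w_out,
                neg_idx.ravel(),
                (-lr * (g_neg * c_vec[:, None, :])).reshape(-1, cfg.dim),
            )

    return {t: w_in[i].copy() for t, i in index.items()}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def embed_document(doc: Document, model: EmbeddingModel) -> np.ndarray:
    """Unweighted mean of in-vocabulary token vectors; zeros if none."""
    if not doc.is_tokenized:
        raise ValueError(f"document {doc.doc_id!r} not tokenized")
    vecs = [model.vectors[t.lower()] for t in doc.tokens if t.lower() in model.vectors]
    if not vecs:
        return np.zeros(model.dim)
    return np.mean(vecs, axis=0)
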