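"""Feature assembly: combine the formula, frequency-bin, length, and the two
embedding blocks into one fixed-layout vector per document."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import text_features
from .corpus_io import Document, EasyWordList, FrequencyTable, default_easy_words
from .embeddings import EmbeddingModel, embed_document

GROUP_NAMES = ("formula", "frequency", "length", "embedding")


@dataclass(frozen=True)
class FeatureLayout:
    """Named blocks of the feature vector, in order."""

    blocks: tuple[tuple[str, int], ...]

    @classmethod
    def default(cls, embed_dim: int = 200) -> "FeatureLayout":
        return cls(
            blocks=(
                ("formula", 4),
                ("freq_bins", 10),
                ("length", 2),
                ("embed_wiki", embed_dim),
                ("embed_ehr", embed_dim),
            )
        )

    @property
    def length(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def version(self) -> str:
        return "v1:" + "+".join(f"{name}{n}" for name, n in self.blocks)

    def block_slice(self, name: str) -> slice:
        offset = 0
        for bname, n in self.blocks:
            if bname == name:
                return slice(offset, offset + n)
            offset += n
        raise KeyError(name)

    def columns_of_group(self, group: str) -> np.ndarray:
        """Column indices belonging to an ablation group.

        Groups: formula -> formula block; frequency -> freq_bins; length ->
        length; embedding -> both embedding blocks.
        """
        mapping = {
            "formula": ("formula",),
            "frequency": ("freq_bins",),
            "length": ("length",),
            "embedding": ("embed_wiki", "embed_ehr"),
        }
        if group not in mapping:
            raise KeyError(f"unknown feature group {group!r}")
        idx: list[int] = []
        for bname in mapping[group]:
            s = self.block_slice(bname)
            idx.extend(range(s.start, s.stop))
        return np.asarray(idx, dtype=int)

    def drop_groups(self, groups) -> "FeatureLayout":
        dropped = set()
        for g in groups:
            self.columns_of_group(g)  # validates the name
            dropped.update(
                {"formula": ["formula"], "frequency": ["freq_bins"],
                 "length": ["length"], "embedding": ["embed_wiki", "embed_ehr"]}[g]
            )
        kept = tuple(b for b in self.blocks if b[0] not in dropped)
        if not kept:
            raise ValueError("cannot drop every feature group")
        return FeatureLayout(blocks=kept)


@dataclass
class FeaturePipeline:
    """Featurizes tokenized documents into fixed-layout vectors."""

    freq_table: FrequencyTable
    easy_words: EasyWordList = field(default_factory=default_easy_words)
    embed_wiki: EmbeddingModel | None = None
    embed_ehr: EmbeddingModel | None = None
    drop: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        dims = [m.dim for m in (self.embed_wiki, self.embed_ehr) if m is not None]
        if self.embed_wiki is not None and self.embed_ehr is not None:
            if self.embed_wiki.dim != self.embed_ehr.dim:
                raise ValueError("embedding dims differ between sources")
        embed_dim = dims[0] if dims else 200
        self.layout = FeatureLayout.default(embed_dim).drop_groups(self.drop)

    def featurize(self, doc: Document) -> np.ndarray:
        if not doc.is_tokenized:
            raise ValueError(f"document {doc.doc_id!r} not tokenized")
        parts: list[np.ndarray] = []
        names = {name for name, _ in self.layout.blocks}
        if "formula" in names:
            stats = text_features.surface_stats(doc, self.easy_words)
            parts.append(text_features.formula_features(stats))
        if "freq_bins" in names:
            parts.append(text_features.frequency_bin_features(doc, self.freq_table))
        if "length" in names:
            parts.append(text_features.length_features(doc))
        if "embed_wiki" in names:
            parts.append(self._embed_block(doc, self.embed_wiki))
        if "embed_ehr" in names:
            parts.append(self._embed_block(doc, self.embed_ehr))
        x = np.concatenate(parts)
        if len(x) != self.layout.length:
            raise AssertionError("feature vector length mismatch with layout")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite feature for document {doc.doc_id!r}")
        return x

    def _embed_block(self, doc: Document, model: EmbeddingModel | None) -> np.ndarray:
        dim = self.layout.block_slice("embed_wiki").stop - self.layout.block_slice("embed_wiki").start
        if model is None:
            return np.zeros(dim)
        return embed_document(doc, model)

    def featurize_corpus(self, docs) -> dict[str, np.ndarray]:
        return {d.doc_id: self.featurize(d) for d in docs}
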