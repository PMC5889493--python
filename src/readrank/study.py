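"""End-to-end orchestration: featurize a corpus, train on the train split
with C tuned on dev, and evaluate concordance on the test split.

Used by the CLI, the evaluation/ablation harness, and the acceptance script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import ranker
from .corpus_io import default_easy_words
from .embeddings import EmbeddingConfig, train_embedding
from .evaluation import (
    ConcordanceReport,
    SplitAssignment,
    fkgl_baseline_concordance,
    per_rater_concordance,
)
from .pipeline import FeatureLayout, FeaturePipeline
from .text_features import build_frequency_table

logger = logging.getLogger(__name__)


def restrict_ratings(ratings, docs_in_part: set[str]):
    """Keep only ratings of documents inside one split partition."""
    return [r for r in ratings if r.doc_id in docs_in_part]


@dataclass
class StudyRunner:
    """Caches featurization so repeated runs (C sweep, ablation) are cheap.

    The frequency table and both embeddings are built from the full corpus
    (they are unsupervised); the ranking weights only ever see train-split
    ratings, and C is chosen on the dev split.
    """

    documents: list
    ratings: list
    split: SplitAssignment
    embed_config: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    c_grid: tuple = ranker.DEFAULT_C_GRID
    standardize: bool = True
    _features: dict | None = None
    _layout: FeatureLayout | None = None

    def prepare(self) -> None:
        if self._features is not None:
            return
        freq = build_frequency_table(self.documents)
        emb_wiki = train_embedding(self.documents, "wikipedia", self.embed_config)
        emb_ehr = train_embedding(self.documents, "ehr", self.embed_config)
        pipe = FeaturePipeline(
            freq_table=freq,
            easy_words=default_easy_words(),
            embed_wiki=emb_wiki,
            embed_ehr=emb_ehr,
        )
        self._layout = pipe.layout
        self._features = pipe.featurize_corpus(self.documents)

    @property
    def features(self) -> dict:
        self.prepare()
        return self._features

    @property
    def layout(self) -> FeatureLayout:
        self.prepare()
        return self._layout

    def _sliced(self, drop: tuple) -> tuple[dict, FeatureLayout]:
        """Features with the dropped groups' columns removed."""
        self.prepare()
        if not drop:
            return self._features, self._layout
        layout = self._layout.drop_groups(drop)
        keep = np.ones(self._layout.length, dtype=bool)
        for g in drop:
            keep[self._layout.columns_of_group(g)] = False
        feats = {d: x[keep] for d, x in self._features.items()}
        return feats, layout

    def train_model(self, drop: tuple = ()) -> "tuple":
        """Tune C on dev, train at the best C on the train split.

        Returns ``(model, features, best_c, dev_sweep)``.
        """
        feats, layout = self._sliced(drop)
        train_ratings = restrict_ratings(self.ratings, self.split.docs_in("train"))
        dev_ratings = restrict_ratings(self.ratings, self.split.docs_in("dev"))
        examples = ranker.generate_pairwise_examples(train_ratings, feats)
        train_matrix = np.asarray([feats[d] for d in sorted(self.split.docs_in("train"))])
        best_c, sweep = ranker.tune_c(
            examples,
            dev_ratings,
            feats,
            c_grid=self.c_grid,
            layout_version=layout.version,
            feature_matrix=train_matrix,
            standardize=self.standardize,
        )
        model = ranker.train(
            examples,
            c_tradeoff=best_c,
            layout_version=layout.version,
            feature_matrix=train_matrix,
            standardize=self.standardize,
        )
        return model, feats, best_c, sweep

    def run(self, drop: tuple = ()) -> ConcordanceReport:
        """Full train/tune cycle, evaluated on the test split."""
        model, feats, _, _ = self.train_model(drop)
        test_ratings = restrict_ratings(self.ratings, self.split.docs_in("test"))
        scores = ranker.score_many(model, feats)
        return per_rater_concordance(scores, test_ratings)

    def run_baseline(self) -> ConcordanceReport:
        """FKGL-formula concordance on the same test ratings."""
        test_ratings = restrict_ratings(self.ratings, self.split.docs_in("test"))
        return fkgl_baseline_concordance(test_ratings, self.documents)


def split_raters(ratings, proportions=(0.6, 0.2, 0.2), seed: int = 0):
    """Deterministic rater-level train/dev/test partition.

    Used by the parameter-recovery protocol, where held-out raters (rather
    than held-out documents) are scored on their full document sets.
    """
    raters = sorted({r.rater_id for r in ratings})
    rng = np.random.default_rng(seed)
    rng.shuffle(raters)
    n = len(raters)
    n_train = int(round(n * proportions[0]))
    n_dev = int(round(n * proportions[1]))
    groups = {
        "train": set(raters[:n_train]),
        "dev": set(raters[n_train : n_train + n_dev]),
        "test": set(raters[n_train + n_dev :]),
    }
    return groups


def rater_holdout_run(
    documents,
    ratings,
    rater_groups: dict,
    embed_config: EmbeddingConfig | None = None,
    c_grid=ranker.DEFAULT_C_GRID,
    features: dict | None = None,
) -> ConcordanceReport:
    """Train on the train raters, tune C on the dev raters, and report mean
    per-rater W over the test raters (each scored on their own documents).

    Pass precomputed ``features`` to amortize featurization across runs.
    """
    if features is None:
        runner = StudyRunner(
            documents, ratings, split=None, embed_config=embed_config or EmbeddingConfig()
        )
        runner.split = None
        runner.prepare()
        features = runner.features

    by_part = {
        part: [r for r in ratings if r.rater_id in rater_groups[part]]
        for part in ("train", "dev", "test")
    }
    examples = ranker.generate_pairwise_examples(by_part["train"], features)
    matrix = np.asarray([features[d] for d in sorted({r.doc_id for r in by_part["train"]})])
    best_c, _ = ranker.tune_c(
        examples, by_part["dev"], features, c_grid=c_grid, feature_matrix=matrix
    )
    model = ranker.train(examples, c_tradeoff=best_c, feature_matrix=matrix)
    scores = ranker.score_many(model, features)
    return per_rater_concordance(scores, by_part["test"])
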