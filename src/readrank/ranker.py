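"""Pairwise reduction of per-rater difficulty ratings and the linear
max-margin ranking model.

From each rater we build one example per unordered document pair with unequal
ratings, oriented so that ``diff = x(harder) - x(easier)`` carries label +1;
no example ever crosses raters. Training solves::

    min_w  1/2 ||w||^2 + C * sum_ij xi_ij
    s.t.   w . (x_i - x_j) >= 1 - xi_ij,   xi_ij >= 0

which is a no-intercept binary SVM on the difference vectors. We realize it
by mirroring each difference with label -1 and fitting a hinge-loss SVM
without intercept; since the mirrored set doubles every slack term, the
solver is handed ``C/2`` so the solution matches the single-orientation
objective at ``C`` exactly.

Features are z-scored with training-set statistics before differencing; the
scaler is stored in the model so scoring sees the same transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


@dataclass(frozen=True)
class PairwiseExample:
    """One oriented difference vector from a single rater.

    ``diff = x(harder) - x(easier)``; the implied label is always +1.
    """

    diff: np.ndarray
    rater_id: str
    harder_doc: str
    easier_doc: str


@dataclass
class RankModel:
    """Linear ranking function ``score(x) = w . z(x)`` (z = stored z-score)."""

    weights: np.ndarray
    c_tradeoff: float
    layout_version: str
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    training_diagnostics: dict = field(default_factory=dict)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.scaler_mean) / self.scaler_scale


def generate_pairwise_examples(ratings, features: dict[str, np.ndarray]) -> list[PairwiseExample]:
    """All same-rater unordered pairs with unequal ratings, one example each.

    A document rated several times by the same rater contributes its mean
    rating. Missing features for any rated document are a hard error.
    """
    per_rater: dict[str, dict[str, list[int]]] = {}
    for r in ratings:
        if r.doc_id not in features:
            raise KeyError(f"no feature vector for rated document {r.doc_id!r}")
        per_rater.setdefault(r.rater_id, {}).setdefault(r.doc_id, []).append(r.rating)

    examples: list[PairwiseExample] = []
    for rater_id in sorted(per_rater):
        doc_ratings = {d: float(np.mean(v)) for d, v in per_rater[rater_id].items()}
        docs = sorted(doc_ratings)
        for i, a in enumerate(docs):
            for b in docs[i + 1 :]:
                ra, rb = doc_ratings[a], doc_ratings[b]
                if ra == rb:
                    continue
                harder, easier = (a, b) if ra > rb else (b, a)
                examples.append(
                    PairwiseExample(
                        diff=features[harder] - features[easier],
                        rater_id=rater_id,
                        harder_doc=harder,
                        easier_doc=easier,
                    )
                )
    return examples


def _fit_scaler(features: dict[str, np.ndarray] | np.ndarray):
    mat = np.asarray(list(features.values())) if isinstance(features, dict) else np.asarray(features)
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns pass through unscaled
    return mean, scale


def train(
    examples,
    c_tradeoff: float = 1.0,
    layout_version: str = "adhoc",
    feature_matrix: np.ndarray | None = None,
    standardize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 20_000,
) -> RankModel:
    """Fit the max-margin ranking weights on pairwise examples.

    ``feature_matrix`` (documents x features) supplies the statistics for the
    z-score transform; when absent (or ``standardize=False``) the identity
    transform is stored.
    """
    if not examples:
        raise ValueError("no training examples")
    diffs = np.asarray([e.diff for e in examples], dtype=np.float64)
    if diffs.ndim != 2 or len({len(e.diff) for e in examples}) != 1:
        raise ValueError("inconsistent example layouts")

    n_features = diffs.shape[1]
    if standardize and feature_matrix is not None:
        mean, scale = _fit_scaler(feature_matrix)
        if len(mean) != n_features:
            raise ValueError("feature_matrix width does not match examples")
    else:
        mean = np.zeros(n_features)
        scale = np.ones(n_features)
    z = diffs / scale  # means cancel in differences

    if not np.any(np.abs(z) > 0):
        raise ValueError("all difference vectors are zero; nothing to learn")

    x = np.vstack([z, -z])
    y = np.concatenate([np.ones(len(z)), -np.ones(len(z))])
    svc = LinearSVC(
        C=c_tradeoff / 2.0,  # mirrored set doubles each slack term
        loss="hinge",
        fit_intercept=False,
        tol=tol,
        max_iter=max_iter,
        random_state=0,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(x, y)
    if svc.n_iter_ >= max_iter:
        logger.warning("LinearSVC hit max_iter=%d (tol=%g); solution may be loose", max_iter, tol)
    w = svc.coef_.ravel().copy()

    margins = z @ w
    diagnostics = {
        "n_examples": int(len(z)),
        "n_discordant_on_train": int(np.sum(margins <= 0)),
        "total_slack": float(np.sum(np.maximum(0.0, 1.0 - margins))),
        "solver_iterations": int(svc.n_iter_),
    }
    return RankModel(
        weights=w,
        c_tradeoff=c_tradeoff,
        layout_version=layout_version,
        scaler_mean=mean,
        scaler_scale=scale,
        training_diagnostics=diagnostics,
    )


def score(model: RankModel, features: np.ndarray) -> float:
    """Linear score ``w . z(x)``; higher = predicted more difficult."""
    x = np.asarray(features, dtype=np.float64)
    if x.shape != model.weights.shape:
        raise ValueError(
            f"feature vector of length {x.shape} does not match model layout "
            f"({model.weights.shape})"
        )
    return float(model.weights @ model.transform(x))


def score_many(model: RankModel, features: dict[str, np.ndarray]) -> dict[str, float]:
    return {doc_id: score(model, x) for doc_id, x in features.items()}


def rank_documents(model: RankModel, features: dict[str, np.ndarray]) -> list[str]:
    """doc_ids most-difficult first; ties broken lexicographically."""
    scores = score_many(model, features)
    return sorted(scores, key=lambda d: (-scores[d], d))


def tune_c(
    train_examples,
    dev_ratings,
    features: dict[str, np.ndarray],
    c_grid=DEFAULT_C_GRID,
    layout_version: str = "adhoc",
    feature_matrix: np.ndarray | None = None,
    standardize: bool = True,
):
    """Pick the C maximizing mean per-rater Kendall W on the dev ratings.

    Returns ``(best_c, {C: mean_w})``. Ties go to the smallest C.
    """
    from .evaluation import system_vs_rater_concordance  # lazy: avoids cycle

    if not c_grid:
        raise ValueError("empty C grid")
    if not dev_ratings:
        raise ValueError("empty dev set")
    results: dict[float, float] = {}
    for c in sorted(c_grid):
        model = train(
            train_examples,
            c_tradeoff=c,
            layout_version=layout_version,
            feature_matrix=feature_matrix,
            standardize=standardize,
        )
        report = system_vs_rater_concordance(
            lambda feats, m=model: score_many(m, feats), dev_ratings, features
        )
        results[c] = report.mean_w
    best_c = max(sorted(results), key=lambda c: (results[c], -c))
    return best_c, results
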