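"""Concordance-based evaluation: the tie-corrected Kendall coefficient of
concordance (W), the per-rater system-vs-rater protocol, the
readability-formula baseline, Wilcoxon paired comparison, stratified
splitting, and the feature-ablation harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import text_features
from .corpus_io import Document

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceReport:
    per_rater_w: dict[str, float]
    mean_w: float
    comparison: dict | None = None


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # doc_id -> {train, dev, test}
    proportions: tuple[float, float, float]
    stratum_key: str

    def docs_in(self, part: str) -> set[str]:
        return {d for d, p in self.assignment.items() if p == part}


def kendall_w(rankings) -> float:
    """Tie-corrected Kendall coefficient of concordance over m rank lists.

    ``rankings`` is an (m, n) array-like of ranks (or any scores; they are
    converted to average ranks per rater). Requires m >= 2 raters and n >= 2
    items, every rater covering the same item set.

        W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j)

    with S the squared deviation of rank sums about their mean and
    T_j = sum over tie groups of (t^3 - t) for rater j.
    """
    mat = np.asarray(rankings, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError("rankings must be a 2-D (raters x items) structure")
    m, n = mat.shape
    if m < 2:
        raise ValueError(f"need >= 2 raters, got {m}")
    if n < 2:
        raise ValueError(f"need >= 2 items, got {n}")

    ranks = np.vstack([stats.rankdata(row) for row in mat])
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))

    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        # every rater ties every item: zero variance available, define W = 0
        return 0.0
    return s * 12.0 / denom


def _rater_doc_scores(ratings) -> dict[str, dict[str, float]]:
    """rater -> {doc -> mean rating} (a rater may rate a document twice)."""
    acc: dict[str, dict[str, list[int]]] = {}
    for r in ratings:
        acc.setdefault(r.rater_id, {}).setdefault(r.doc_id, []).append(r.rating)
    return {
        rater: {d: float(np.mean(v)) for d, v in docs.items()} for rater, docs in acc.items()
    }


def per_rater_concordance(score_by_doc: dict[str, float], ratings) -> ConcordanceReport:
    """Per rater: m=2 Kendall W between the rater's difficulty order and the
    given system scores, restricted to that rater's documents.

    Raters with fewer than 2 documents, all-equal ratings, or documents
    missing from ``score_by_doc`` entirely are excluded with a warning.
    """
    per_rater: dict[str, float] = {}
    for rater, doc_scores in sorted(_rater_doc_scores(ratings).items()):
        docs = sorted(d for d in doc_scores if d in score_by_doc)
        if len(docs) < 2:
            logger.warning("rater %s: fewer than 2 scorable documents, excluded", rater)
            continue
        rater_vals = [doc_scores[d] for d in docs]
        if len(set(rater_vals)) < 2:
            logger.warning("rater %s: all ratings equal, excluded", rater)
            continue
        sys_vals = [score_by_doc[d] for d in docs]
        per_rater[rater] = kendall_w([rater_vals, sys_vals])
    if not per_rater:
        raise ValueError("no rater had enough distinctly-rated documents")
    return ConcordanceReport(per_rater_w=per_rater, mean_w=float(np.mean(list(per_rater.values()))))


def system_vs_rater_concordance(model_ranking_fn, ratings, features) -> ConcordanceReport:
    """Concordance of a scoring function with every rater.

    ``model_ranking_fn(features) -> {doc_id: score}`` (higher = harder);
    ``features`` maps doc_id -> feature vector for at least the rated docs.
    """
    scores = model_ranking_fn(features)
    return per_rater_concordance(scores, ratings)


def fkgl_baseline_concordance(ratings, corpus) -> ConcordanceReport:
    """Identical protocol with the FKGL grade as the difficulty score."""
    scores = {}
    for doc in corpus:
        scores[doc.doc_id] = text_features.fkgl(doc)
    return per_rater_concordance(scores, ratings)


def wilcoxon_compare(per_rater_w_system, per_rater_w_baseline, alpha: float = 0.05) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-rater W values.

    Pairs over the common rater set. All-zero differences report p = 1.
    Exact null distribution for <= 25 pairs, normal approximation with
    continuity correction above.
    """
    raters = sorted(set(per_rater_w_system) & set(per_rater_w_baseline))
    if len(raters) < 6:
        logger.warning("only %d paired raters; the signed-rank test is weak", len(raters))
    a = np.array([per_rater_w_system[r] for r in raters])
    b = np.array([per_rater_w_baseline[r] for r in raters])
    diffs = a - b
    if np.all(diffs == 0):
        return {"statistic": 0.0, "p_value": 1.0, "significant": False, "alpha": alpha, "n": len(raters)}
    method = "exact" if len(raters) <= 25 and not np.any(diffs == 0) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method, correction=True)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "alpha": alpha,
        "n": len(raters),
    }


def stratified_split(
    documents,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    stratum_key: str = "topic",
    seed: int = 0,
) -> SplitAssignment:
    """Shuffled per-stratum 60/20/20 (default) assignment, deterministic in
    ``seed``. Counts use largest-remainder rounding within each stratum."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    parts = ("train", "dev", "test")

    strata: dict[str, list[str]] = {}
    for doc in documents:
        strata.setdefault(getattr(doc, stratum_key), []).append(doc.doc_id)

    assignment: dict[str, str] = {}
    for stratum in sorted(strata):
        ids = sorted(strata[stratum])
        if len(ids) < 3:
            logger.warning("stratum %r has %d documents (< 3); best-effort split", stratum, len(ids))
        rng.shuffle(ids)
        counts = _largest_remainder(len(ids), proportions)
        pos = 0
        for part, k in zip(parts, counts):
            for d in ids[pos : pos + k]:
                assignment[d] = part
            pos += k
    return SplitAssignment(assignment=assignment, proportions=tuple(proportions), stratum_key=stratum_key)


def _largest_remainder(n: int, proportions) -> list[int]:
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def ablation_run(study, feature_groups=("frequency", "formula", "length", "embedding")) -> dict:
    """Retrain with each feature group removed and report test mean W.

    ``study`` is a :class:`readrank.study.StudyRunner`-compatible object with
    ``run(drop=...) -> ConcordanceReport``. Each entry of ``feature_groups``
    is one configuration: a group name or a tuple of group names to drop
    together. Dropping every group at once is an error (raised by the
    layout). Returns ``{"full": w, "-<group>": w, ...}``.
    """
    results = {"full": study.run(drop=()).mean_w}
    for entry in feature_groups:
        drop = (entry,) if isinstance(entry, str) else tuple(entry)
        if set(drop) >= {"frequency", "formula", "length", "embedding"}:
            raise ValueError("cannot drop all feature groups")
        results["-" + "+".join(drop)] = study.run(drop=drop).mean_w
    return results
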