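"""Rater-behavior analytics: pairwise rater concordance, conformity,
eccentric-rater flagging, controversial-document screening, and study
filtering for retraining."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .evaluation import kendall_w

logger = logging.getLogger(__name__)

ECCENTRIC_THRESHOLD = 0.5
HIGHLY_CONFORMING_THRESHOLD = 0.7
CONTROVERSIAL_MAX_DIFF = 5


@dataclass
class ConformityReport:
    """Pairwise rater W over shared documents plus per-rater conformity."""

    pairwise_w: dict[tuple[str, str], float]
    conformity: dict[str, float] = field(default_factory=dict)
    correlation: float | None = None  # optional Spearman rho vs a model's per-rater W


def _rater_doc_means(ratings) -> dict[str, dict[str, float]]:
    acc: dict[str, dict[str, list[int]]] = {}
    for r in ratings:
        acc.setdefault(r.rater_id, {}).setdefault(r.doc_id, []).append(r.rating)
    return {k: {d: float(np.mean(v)) for d, v in docs.items()} for k, docs in acc.items()}


def pairwise_rater_concordance(ratings) -> ConformityReport:
    """Kendall W (m=2) for every rater pair over their shared documents.

    A pair is included when the raters share >= 2 documents and each rater
    assigns at least two distinct values on the shared set; other pairs are
    omitted (not an error). Entries are stored once per unordered pair, keyed
    with the two ids in sorted order.
    """
    per_rater = _rater_doc_means(ratings)
    if len(per_rater) < 2:
        raise ValueError("need >= 2 raters")
    pairwise: dict[tuple[str, str], float] = {}
    for ra, rb in combinations(sorted(per_rater), 2):
        shared = sorted(set(per_rater[ra]) & set(per_rater[rb]))
        if len(shared) < 2:
            continue
        va = [per_rater[ra][d] for d in shared]
        vb = [per_rater[rb][d] for d in shared]
        if len(set(va)) < 2 or len(set(vb)) < 2:
            continue
        pairwise[(ra, rb)] = kendall_w([va, vb])
    return ConformityReport(pairwise_w=pairwise)


def conformity(report: ConformityReport) -> dict[str, float]:
    """Per-rater mean W against all peers with a usable shared set.

    Raters appearing in no pair are excluded with a warning. The result is
    also stored on the report.
    """
    per_rater: dict[str, list[float]] = {}
    for (ra, rb), w in report.pairwise_w.items():
        per_rater.setdefault(ra, []).append(w)
        per_rater.setdefault(rb, []).append(w)
    report.conformity = {r: float(np.mean(ws)) for r, ws in sorted(per_rater.items())}
    return report.conformity


def conformity_correlation(report: ConformityReport, per_rater_w: dict[str, float]) -> float:
    """Spearman rho between a model's per-rater W and rater conformity."""
    if not report.conformity:
        conformity(report)
    raters = sorted(set(report.conformity) & set(per_rater_w))
    if len(raters) < 3:
        raise ValueError("need >= 3 raters common to both maps")
    rho = stats.spearmanr(
        [per_rater_w[r] for r in raters], [report.conformity[r] for r in raters]
    ).statistic
    report.correlation = float(rho)
    return report.correlation


def flag_eccentric(report: ConformityReport, threshold: float = ECCENTRIC_THRESHOLD) -> set[str]:
    """Raters whose conformity falls strictly below ``threshold``."""
    if not report.conformity:
        conformity(report)
    return {r for r, c in report.conformity.items() if c < threshold}


def flag_controversial(
    ratings, min_raters: int = 2, max_diff_threshold: int = CONTROVERSIAL_MAX_DIFF
):
    """Documents rated by >= ``min_raters`` distinct raters whose maximum
    rating difference strictly exceeds ``max_diff_threshold``.

    Returns ``(flagged_doc_ids, max_diff_by_doc)`` where the second map
    covers every document meeting the ``min_raters`` screen (its mean is the
    statistic reported alongside the flagged set).
    """
    by_doc: dict[str, dict[str, list[int]]] = {}
    for r in ratings:
        by_doc.setdefault(r.doc_id, {}).setdefault(r.rater_id, []).append(r.rating)

    max_diff: dict[str, int] = {}
    for doc, by_rater in by_doc.items():
        if len(by_rater) < min_raters:
            continue
        vals = [v for ratings_ in by_rater.values() for v in ratings_]
        max_diff[doc] = max(vals) - min(vals)
    flagged = {d for d, diff in max_diff.items() if diff > max_diff_threshold}
    return flagged, max_diff


def filter_study(ratings, drop_raters=frozenset(), drop_documents=frozenset()):
    """Remove records touching dropped raters/documents, preserving pair
    integrity: a pair reduced to one document is dropped entirely.

    Raises if the filtered study is untrainable (< 2 raters or < 4 docs).
    """
    drop_raters = set(drop_raters)
    drop_documents = set(drop_documents)
    kept = [
        r for r in ratings if r.rater_id not in drop_raters and r.doc_id not in drop_documents
    ]
    # pair integrity: both members of a (rater, pair) must survive
    pair_docs: dict[tuple[str, str], set[str]] = {}
    for r in kept:
        pair_docs.setdefault((r.rater_id, r.pair_id), set()).add(r.doc_id)
    result = [r for r in kept if len(pair_docs[(r.rater_id, r.pair_id)]) == 2]

    raters = {r.rater_id for r in result}
    docs = {r.doc_id for r in result}
    if len(raters) < 2 or len(docs) < 4:
        raise ValueError(
            f"filtering left {len(raters)} raters and {len(docs)} documents; untrainable"
        )
    return result
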