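"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: the concordance
oracle is pure-Python over exact fractions, and the max-margin oracle solves
the primal quadratic program directly with SLSQP.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.optimize import minimize


def average_ranks(values):
    """Ranks 1..n with ties averaged, computed by explicit sorting."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [Fraction(0)] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = Fraction(sum(range(i + 1, j + 2)), j - i + 1)
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_kendall_w(score_lists) -> float:
    """Tie-corrected W from the rank-sum variance definition, exact arithmetic."""
    m = len(score_lists)
    n = len(score_lists[0])
    rank_lists = [average_ranks(row) for row in score_lists]
    rank_sums = [sum(rl[i] for rl in rank_lists) for i in range(n)]
    mean = Fraction(sum(rank_sums), n)
    s = sum((r - mean) ** 2 for r in rank_sums)
    tie = Fraction(0)
    for rl in rank_lists:
        groups: dict = {}
        for r in rl:
            groups[r] = groups.get(r, 0) + 1
        tie += sum(Fraction(t**3 - t) for t in groups.values())
    denom = Fraction(m**2 * (n**3 - n)) - m * tie
    if denom <= 0:
        return 0.0
    return float(12 * s / denom)


def qp_rank_svm(diffs, c_tradeoff, tol=1e-12):
    """Solve  min 1/2||w||^2 + C sum xi  s.t.  w.d_i >= 1 - xi_i, xi >= 0
    directly as a constrained QP. Returns the weight vector."""
    diffs = np.asarray(diffs, dtype=float)
    n, p = diffs.shape

    def obj(v):
        w, xi = v[:p], v[p:]
        return 0.5 * w @ w + c_tradeoff * xi.sum()

    def jac(v):
        w, xi = v[:p], v[p:]
        return np.concatenate([w, np.full(n, c_tradeoff)])

    constraints = [
        {
            "type": "ineq",
            "fun": lambda v, i=i: v[p:][i] - (1.0 - diffs[i] @ v[:p]),
            "jac": lambda v, i=i: np.concatenate([diffs[i], np.eye(n)[i]]),
        }
        for i in range(n)
    ]
    bounds = [(None, None)] * p + [(0.0, None)] * n
    x0 = np.zeros(p + n)
    x0[p:] = 1.0
    res = minimize(
        obj, x0, jac=jac, bounds=bounds, constraints=constraints, method="SLSQP",
        options={"maxiter": 2000, "ftol": tol},
    )
    assert res.success, res.message
    return res.x[:p]
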