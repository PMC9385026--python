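"""Independent textbook/brute-force oracles used to cross-check the
package's statistics. Kept deliberately naive and separate from the
implementation paths they verify."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as _stats


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p by the textbook formula
    (Welch-Satterthwaite degrees of freedom)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * _stats.t.sf(abs(t), df)


def pearson_p_from_t(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t-transform with
    n - 2 degrees of freedom."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * _stats.t.sf(abs(t), n - 2)


def hypergeom_upper_tail(k: int, n_universe: int, n_set: int,
                         n_query: int) -> float:
    """P(X >= k) by explicit enumeration with binomial coefficients."""
    total = math.comb(n_universe, n_query)
    upper = min(n_set, n_query)
    acc = 0
    for j in range(k, upper + 1):
        acc += math.comb(n_set, j) * math.comb(n_universe - n_set,
                                               n_query - j)
    return acc / total


def bh_stepup(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up by hand: q_(i) = min_{j>=i} m p_(j)/j,
    capped at 1, returned in the original order."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for idx in range(m - 1, -1, -1):
        rank = idx + 1
        running = min(running, m * p[order[idx]] / rank)
        q_sorted[idx] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def cv_by_hand(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample SD and |SD/mean| written out longhand."""
    vals = list(map(float, values))
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, abs(sd / mean)


def select_panel_bruteforce(table, n_up: int, n_down: int, top_k: int,
                            alpha: float, fc_threshold: float,
                            expression_floor: float):
    """Exhaustive filter-sort-slice panel selection over a list of dicts
    with keys gene, av, cv, cv_defined, p, mean_control_fpkm.

    Returns (up genes, down genes, top_k genes) with the same ordering
    rule as the implementation: ascending cv, then larger |av|, then gene.
    """
    candidates = [row for row in table
                  if row["cv_defined"]
                  and row["p"] < alpha
                  and abs(row["av"]) >= fc_threshold
                  and row["mean_control_fpkm"] >= expression_floor]
    key = lambda row: (row["cv"], -abs(row["av"]), row["gene"])
    ups = sorted((r for r in candidates if r["av"] > 0), key=key)[:n_up]
    downs = sorted((r for r in candidates if r["av"] < 0), key=key)[:n_down]
    union = sorted(ups + downs, key=key)[:top_k]
    return ([r["gene"] for r in ups], [r["gene"] for r in downs],
            [r["gene"] for r in union])
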