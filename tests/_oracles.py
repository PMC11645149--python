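"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle is a literal, definition-level implementation (combinatorial
counting, step-up recursion, pair enumeration, exhaustive split search,
observed-minus-expected accumulation) kept deliberately separate from the
package's code paths.
"""

import itertools
import math

import numpy as np


def hypergeom_upper_tail(universe, k1, n2, k):
    """Exact P(X >= k) by direct combinatorial counting."""
    total = math.comb(universe, n2)
    acc = 0
    for j in range(k, min(k1, n2) + 1):
        acc += math.comb(k1, j) * math.comb(universe - k1, n2 - j)
    return acc / total


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = running
    return q


def auc_pair_counting(pos, neg):
    """ROC AUC by exhaustive pair enumeration; ties count one half."""
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        wins += p > n
        ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def step_fit_brute_force(values):
    """Best one-step fit by trying every split of the sorted vector.

    Returns (sse, split_index, low_mean, high_mean)."""
    v = np.sort(np.asarray(values, dtype=float))
    best = None
    for k in range(1, len(v)):
        lo, hi = v[:k], v[k:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k, lo.mean(), hi.mean())
    return best


def logrank_chi2(ta, ea, tb, eb):
    """Two-group log-rank chi-square by direct accumulation over event times."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, int), np.asarray(eb, int)
    events = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = var = 0.0
    for t in events:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        d2 = ((tb == t) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
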