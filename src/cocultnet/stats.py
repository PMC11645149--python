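"""Shared statistical primitives used by more than one pipeline stage."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def hypergeom_upper_tail(universe_n: int, layer1_k: int, layer2_n: int, overlap_k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap_k).

    X counts successes when ``layer2_n`` items are drawn without replacement
    from a universe of ``universe_n`` items of which ``layer1_k`` are
    successes. Computed by exact summation of the hypergeometric pmf in log
    space (scipy's survival function).
    """
    if not 0 <= layer1_k <= universe_n or not 0 <= layer2_n <= universe_n:
        raise ValueError("layer sizes must lie within the universe")
    if overlap_k > min(layer1_k, layer2_n):
        raise ValueError(
            f"overlap {overlap_k} exceeds min(layer sizes) "
            f"{min(layer1_k, layer2_n)}"
        )
    if overlap_k < 0:
        raise ValueError("overlap must be non-negative")
    if overlap_k == 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap_k - 1, universe_n, layer1_k, layer2_n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(values_pos, values_neg) -> float:
    """ROC area under the curve via the rank-sum (Mann-Whitney U) identity.

    AUC = P(pos > neg) + 0.5 * P(pos == neg), i.e. ties count one half.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both value lists must be non-empty")
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)  # midranks handle ties as 0.5
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
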