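"""Two-group differential expression on log2-CPM values.

The DEG engine is deliberately simple: library-size normalization to
log2(CPM + pseudocount), per-gene Welch's unequal-variance t-test, and
Benjamini-Hochberg adjustment. Genes are then filtered at a signed
log2-fold-change threshold (default |log2FC| >= 2) and an adjusted-p
ceiling (default 0.05) and rank-ordered by effect size. The ranking
statistic is pluggable at the pipeline level; Welch-on-log2CPM is the
default because it is transparent and adequate for set triage with
replicated groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from cocultnet.io import ExpressionMatrix, GeneSet
from cocultnet.stats import benjamini_hochberg

#: smallest p-value reported for degenerate (zero-variance) separations
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class DEResult:
    """Per-gene differential-expression records plus the thresholds used.

    ``table`` columns: gene (index), log2_fc, p_value, adj_p, mean_a,
    mean_b, degenerate (True when both groups had zero variance but
    different means, where p is reported as the smallest positive float).
    """

    table: pd.DataFrame
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    lfc_min: float = 2.0
    adj_p_max: float = 0.05

    def ranked(self) -> pd.DataFrame:
        """Records sorted by |log2_fc| (desc) then adj_p (asc)."""
        df = self.table.copy()
        df["_abs"] = df["log2_fc"].abs()
        df = df.sort_values(["_abs", "adj_p"], ascending=[False, True]).drop(columns="_abs")
        return df

    def write_tsv(self, path, lfc_min: float | None = None, adj_p_max: float | None = None):
        lfc_min = self.lfc_min if lfc_min is None else lfc_min
        adj_p_max = self.adj_p_max if adj_p_max is None else adj_p_max
        df = self.ranked()
        df["passed_filter"] = (df["log2_fc"].abs() >= lfc_min) & (df["adj_p"] < adj_p_max)
        df.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


def size_factors(mat: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (composition-robust normalization).

    For each sample, the median over genes of count / geometric-mean-count,
    computed on genes expressed in every sample. Scaled so the factors
    average 1; multiplied by the mean raw library size they give effective
    library sizes for CPM.
    """
    if mat.scale != "counts":
        raise ValueError("size_factors expects a counts-scale matrix")
    counts = mat.values.to_numpy()
    pos = (counts > 0).all(axis=1)
    if pos.sum() < 10:
        raise ValueError("too few genes expressed in all samples for size factors")
    logc = np.log(counts[pos])
    ratios = logc - logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / sf.mean()
    return pd.Series(sf, index=mat.sample_ids)


def effective_library_sizes(mat: ExpressionMatrix) -> pd.Series:
    """Mean raw library size scaled per-sample by median-of-ratios factors."""
    raw = mat.values.sum(axis=0)
    return size_factors(mat) * float(raw.mean())


def normalize_log2cpm(
    mat: ExpressionMatrix, pseudocount: float = 1.0, library_sizes: pd.Series | None = None
) -> ExpressionMatrix:
    """Counts -> log2(count / library_size * 1e6 + pseudocount).

    By default library size is the raw column sum; passing
    :func:`effective_library_sizes` instead makes the normalization robust
    to composition shifts (many strongly induced genes inflating one
    group's totals). A zero-library-size sample is a hard error.
    """
    if mat.scale != "counts":
        raise ValueError("normalize_log2cpm expects a counts-scale matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    libsize = mat.values.sum(axis=0) if library_sizes is None else library_sizes.loc[mat.sample_ids]
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = mat.values.div(libsize, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + pseudocount), "log2cpm", mat.annotations)


def _fit_scaled_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene variances.

    Assumes s^2 ~ s0^2 * F(df, d0) and matches the first two moments of
    log(s^2) (the classic closed-form fit): the excess spread of log
    variances beyond what chi^2_df noise explains determines the prior
    degrees of freedom d0; the location determines s0^2. Returns
    (inf, mean prior) when gene variances are no more spread than chi^2
    noise allows (complete shrinkage).
    """
    from scipy.special import digamma, polygamma

    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e_z, var_z = z.mean(), z.var(ddof=1)
    excess = var_z - polygamma(1, df / 2.0)
    if excess <= 1e-8:
        d0 = np.inf
        log_s0 = e_z - digamma(df / 2.0) + np.log(df / 2.0)
        return d0, float(np.exp(log_s0))
    # invert trigamma by Newton iteration (polygamma(1, d0/2) = excess)
    x = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = polygamma(1, x)
        delta = tri * (1.0 - tri / excess) / polygamma(2, x)
        x = max(x - delta, 1e-8)
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    log_s0 = e_z - digamma(df / 2.0) + digamma(d0 / 2.0) + np.log(df / d0)
    return float(d0), float(np.exp(log_s0))


def de_test(mat: ExpressionMatrix, group_a, group_b, engine: str = "welch") -> DEResult:
    """Per-gene two-group test on log2-scale expression.

    log2_fc = mean(group_b) - mean(group_a) on the log2 scale, so positive
    values mean *up in b*.

    ``engine='welch'`` is the plain unequal-variance t-test.
    ``engine='moderated'`` is an empirical-Bayes moderated t: per-gene
    pooled variances are shrunk toward a prior fitted across all genes
    (scaled-F model), and the t-statistic uses the posterior variance with
    augmented degrees of freedom — the standard remedy for the unstable
    variance estimates of small replicate groups.

    With a single sample per group only the fold change is meaningful and
    p is set to 1. Zero-variance separations (both groups constant but
    different) get p = smallest positive float and a ``degenerate`` flag;
    identical constant groups get log2_fc 0, p 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    unknown = (set(group_a) | set(group_b)) - set(mat.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample(s): {sorted(unknown)}")
    if mat.scale != "log2cpm":
        raise ValueError("de_test expects log2-scale expression")
    if engine not in ("welch", "moderated"):
        raise ValueError(f"unknown engine {engine!r}")

    a = mat.values[group_a].to_numpy(dtype=float)
    b = mat.values[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_b - mean_a

    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        p = np.ones_like(lfc)
        degen = np.zeros_like(lfc, dtype=bool)
    else:
        var_a = a.var(axis=1, ddof=1)
        var_b = b.var(axis=1, ddof=1)
        zero_var = (var_a == 0) & (var_b == 0)
        if engine == "welch":
            with np.errstate(divide="ignore", invalid="ignore"):
                p = sps.ttest_ind(b, a, axis=1, equal_var=False).pvalue
        else:
            df = n_a + n_b - 2
            s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
            d0, s0_sq = _fit_scaled_f_prior(s2, df)
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0_sq)
                df_post = np.inf
            else:
                s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
                df_post = d0 + df
            se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = lfc / se
            if np.isinf(df_post):
                p = 2.0 * sps.norm.sf(np.abs(t))
            else:
                p = 2.0 * sps.t.sf(np.abs(t), df_post)
        degen = zero_var & (lfc != 0)
        p = np.where(zero_var, np.where(lfc == 0, 1.0, P_FLOOR), p)
        p = np.nan_to_num(p, nan=1.0)
    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": p,
            "adj_p": benjamini_hochberg(p),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "degenerate": degen,
        },
        index=mat.values.index,
    )
    return DEResult(table, tuple(group_a), tuple(group_b))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    return benjamini_hochberg(p_values)


def filter_deg(
    res: DEResult,
    lfc_min: float = 2.0,
    adj_p_max: float = 0.05,
    direction: str = "both",
    name: str = "DEG",
) -> GeneSet:
    """Genes passing |log2FC| >= lfc_min and adj_p < adj_p_max in the
    requested direction (up = higher in group_b)."""
    if lfc_min < 0 or adj_p_max < 0:
        raise ValueError("thresholds must be non-negative")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    df = res.table
    keep = (df["log2_fc"].abs() >= lfc_min) & (df["adj_p"] < adj_p_max)
    if direction == "up":
        keep &= df["log2_fc"] > 0
    elif direction == "down":
        keep &= df["log2_fc"] < 0
    return GeneSet(name, frozenset(df.index[keep]))
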