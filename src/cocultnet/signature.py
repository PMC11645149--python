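"""Composite signature scoring, clustering, group statistics, ROC-AUC
refinement and over-representation analysis.

A composite score is the per-sample mean of per-gene z-scores (sample
standard deviation, ddof=1) over a signature's genes — unweighted by
default, with optional per-gene weights. Per-gene ROC-AUC (the rank-sum
identity, ties 0.5) drives both the cross-dataset refinement filter (a gene
survives only if its AUC exceeds the threshold in *every* validation
dataset) and the perturbation-recapitulation analysis (genes whose AUC
separating perturbed from control samples reaches a threshold, default
exactly 1.0 = perfect classification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from cocultnet.io import ExpressionMatrix, GeneSet
from cocultnet.stats import benjamini_hochberg, hypergeom_upper_tail, roc_auc
from cocultnet.triage import TriagePartition

logger = logging.getLogger(__name__)


@dataclass
class SignatureScoreSet:
    """Per-sample composite scores for one named signature.

    ``table``: sample-indexed DataFrame with columns ``score`` and ``group``.
    """

    signature_name: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample in score set")
        if not np.isfinite(self.table["score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite composite score")

    def scores(self) -> pd.Series:
        return self.table["score"]

    def by_group(self) -> dict[str, np.ndarray]:
        return {
            str(g): sub["score"].to_numpy(dtype=float)
            for g, sub in self.table.groupby("group", sort=True)
        }


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples; zero-variance genes become all-zero."""
    sd = values.std(axis=1, ddof=1)
    centered = values.sub(values.mean(axis=1), axis=0)
    z = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


def composite_score(
    mat: ExpressionMatrix,
    sig: GeneSet,
    weights: dict[str, float] | None = None,
    group_by: str = "condition",
) -> SignatureScoreSet:
    """Mean per-gene z-score over the signature, per sample.

    Signature genes absent from the matrix are logged and skipped; it is an
    error if none are present. With ``weights`` the mean is weighted.
    """
    present = [g for g in sorted(sig.genes) if g in mat.values.index]
    missing = sig.genes - set(present)
    if missing:
        logger.info("%d signature gene(s) absent from matrix, skipped", len(missing))
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    z = _zscore_rows(mat.values.loc[present])
    if weights:
        w = np.array([weights.get(g, 1.0) for g in present], dtype=float)
        scores = (z.to_numpy() * w[:, None]).sum(axis=0) / w.sum()
    else:
        scores = z.mean(axis=0).to_numpy()
    groups = (
        mat.annotations.loc[mat.sample_ids, group_by]
        if group_by in mat.annotations.columns
        else pd.Series("all", index=mat.sample_ids)
    )
    table = pd.DataFrame({"score": scores, "group": groups.to_numpy()}, index=mat.sample_ids)
    return SignatureScoreSet(sig.name, table)


# ---------------------------------------------------------------------------
# clustering


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.get_left()), rec(node.get_right())
        return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

    return rec(tree) + ";"


def hierarchical_cluster(mat: ExpressionMatrix, sig: GeneSet, metric: str = "euclidean") -> dict:
    """Agglomerative clustering of samples on signature-gene z-scores.

    Average linkage over either Euclidean distance between z-score
    profiles (default: level-sensitive, the convention of standard
    expression heatmaps) or 1 - Pearson correlation (pattern-only;
    blind to shared elevation level, which standardized group-structured
    data collapses). Ties break deterministically by sample order
    (scipy's stable ordering over the condensed distance matrix).
    Returns the linkage matrix, a Newick string, the dendrogram leaf
    order and the flat 2-cluster labels, keyed by sample.
    """
    if len(mat.sample_ids) < 2:
        raise ValueError("clustering needs >= 2 samples")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    present = [g for g in sorted(sig.genes) if g in mat.values.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    z = _zscore_rows(mat.values.loc[present]).to_numpy()
    if metric == "correlation":
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(z.T)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(z.T, metric="euclidean")
    link = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(link, t=2, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    samples = mat.sample_ids
    return {
        "linkage": link,
        "newick": _linkage_to_newick(link, samples),
        "leaf_order": [samples[i] for i in order],
        "labels": {samples[i]: int(flat[i]) for i in range(len(samples))},
    }


# ---------------------------------------------------------------------------
# group statistics


def anova_tukey(scores: SignatureScoreSet) -> dict:
    """One-way ANOVA over score groups plus Tukey HSD pairwise adjusted p.

    Degenerate inputs (zero within-group variance everywhere) are handled
    explicitly: identical groups give F=0, p=1; perfectly separated
    constant groups give infinite F with p reported as the smallest
    positive float.
    """
    groups = scores.by_group()
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has < 2 samples")
    names = sorted(groups)
    arrays = [groups[n] for n in names]

    grand = np.concatenate(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    tiny = np.finfo(float).tiny
    if ss_between <= 1e-12 * max(ss_within, 1.0):
        f_stat, p = 0.0, 1.0
        pairwise = {
            (a, b): 1.0 for i, a in enumerate(names) for b in names[i + 1 :]
        }
        return {"F": f_stat, "p": p, "pairwise": pairwise, "groups": names}
    if ss_within == 0.0:
        pairwise = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                same = np.array_equal(np.sort(groups[a]), np.sort(groups[b]))
                pairwise[(a, b)] = 1.0 if same else tiny
        return {"F": np.inf, "p": tiny, "pairwise": pairwise, "groups": names}

    f_stat, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairwise = {
        (names[i], names[j]): float(hsd.pvalue[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return {"F": float(f_stat), "p": float(p), "pairwise": pairwise, "groups": names}


# ---------------------------------------------------------------------------
# ROC-AUC refinement


def auc_table(
    mat: ExpressionMatrix, candidates: GeneSet, pos_samples, neg_samples, dataset: str = ""
) -> pd.DataFrame:
    """Per-gene ROC-AUC (positive group scores higher) for each candidate
    present in the matrix. Columns: gene, auc, dataset."""
    pos, neg = list(pos_samples), list(neg_samples)
    rows = []
    for gene in sorted(candidates.genes):
        if gene not in mat.values.index:
            continue
        rows.append(
            {
                "gene": gene,
                "auc": roc_auc(mat.values.loc[gene, pos], mat.values.loc[gene, neg]),
                "dataset": dataset,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "auc", "dataset"])


def refine_by_auc(
    candidates: GeneSet,
    datasets: list[tuple[ExpressionMatrix, list, list]],
    threshold: float = 0.85,
    name: str = "refined",
) -> tuple[GeneSet, pd.DataFrame]:
    """Keep candidates whose contact-vs-mono AUC exceeds ``threshold`` in
    EVERY dataset.

    ``datasets`` is a list of (matrix, positive samples, negative samples).
    Candidates absent from any dataset are excluded with a warning. Returns
    the refined gene set and the full AUC table.
    """
    if not datasets:
        raise ValueError("at least one validation dataset required")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    tables = []
    surviving = set(candidates.genes)
    for i, (mat, pos, neg) in enumerate(datasets):
        tab = auc_table(mat, candidates, pos, neg, dataset=f"dataset_{i + 1}")
        tables.append(tab)
        seen = set(tab["gene"])
        absent = surviving - seen
        if absent:
            logger.warning("%d candidate(s) absent from dataset %d, excluded", len(absent), i + 1)
        passed = set(tab.loc[tab["auc"] > threshold, "gene"])
        surviving &= passed
    return GeneSet(name, frozenset(surviving)), pd.concat(tables, ignore_index=True)


def recapitulation_fraction(
    mat: ExpressionMatrix,
    perturbed_samples,
    control_samples,
    partition: TriagePartition,
    auc_threshold: float = 1.0,
) -> dict:
    """Fraction of each triage bin recapitulated by a perturbation.

    A bin gene is *recapitulated* when its per-gene AUC separating
    perturbed from control samples reaches ``auc_threshold`` (default 1.0,
    perfect classification). Empty bins report a missing (None) fraction.
    """
    pos, neg = list(perturbed_samples), list(control_samples)
    out: dict[str, object] = {}
    for bin_name, gs in (("borrowed", partition.borrowed), ("intrinsic", partition.intrinsic)):
        recap = set()
        for gene in gs.genes:
            if gene not in mat.values.index:
                continue
            if roc_auc(mat.values.loc[gene, pos], mat.values.loc[gene, neg]) >= auc_threshold:
                recap.add(gene)
        out[f"recap_{bin_name}"] = GeneSet(f"recap_{bin_name}", frozenset(recap))
        out[f"fraction_{bin_name}"] = len(recap) / len(gs) if len(gs) else None
    return out


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_enrichment(
    query: GeneSet, collections: list[GeneSet], universe: GeneSet
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection
    set, within ``universe``; BH adjustment across the collections.

    Query genes outside the universe are dropped with a warning. Columns:
    set, set_n, overlap_k, p, adj_p.
    """
    if not universe.genes:
        raise ValueError("empty universe")
    q = query.genes & universe.genes
    dropped = query.genes - universe.genes
    if dropped:
        logger.warning("%d query gene(s) outside the universe, dropped", len(dropped))
    rows = []
    for gs in collections:
        members = gs.genes & universe.genes
        overlap = len(q & members)
        p = hypergeom_upper_tail(len(universe.genes), len(members), len(q), overlap)
        rows.append({"set": gs.name, "set_n": len(members), "overlap_k": overlap, "p": p})
    df = pd.DataFrame(rows, columns=["set", "set_n", "overlap_k", "p"])
    df["adj_p"] = benjamini_hochberg(df["p"]) if len(df) else []
    return df.sort_values("p", ignore_index=True)
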