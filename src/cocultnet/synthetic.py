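"""Synthetic fixtures with planted ground truth.

The generators emulate the study design the pipeline targets: a stromal
donor line co-cultured with an ER+ tumor recipient line in four arms
(donor monoculture, recipient monoculture, recipient in direct-contact
co-culture, recipient in conditioned media), with

* a planted *transfer* gene set expressed highly by the donor, low in the
  recipient, and elevated in the recipient only under direct contact;
* a planted *intrinsic* gene set elevated in contact-cultured recipients
  but not highly expressed by the donor;
* a planted *conditioned-media* gene set elevated in both the CM and the
  contact arms (soluble-factor response);
* negative-binomial count noise with gene-wise dispersion;
* a proteome whose per-gene detection probability is logistic in mean
  abundance (the low-abundance dropout of isobaric-tag proteomics);
* an interaction network with excess wiring planted between the transfer
  and intrinsic neighborhoods, plus a degree-matched rewired control;
* a patient cohort whose hazard doubles (configurable) with a latent
  high-signature state, under independent exponential censoring.

Every generator is a pure function of (truth, size parameters, seed); the
planted truth is emitted alongside each fixture in a machine-readable
sidecar and no pipeline stage reads it.

Planted genes are drawn from a lower-abundance baseline than background
genes (median ~40 vs ~150 counts): borrowed molecules are characteristically
low-abundance, and this also keeps the composition shift of the contact
libraries small so that CPM normalization stays meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from cocultnet.io import EdgeTable, ExpressionMatrix, GeneSet, CohortTable
from cocultnet.stats import benjamini_hochberg

CONDITIONS = ("donor_mono", "recipient_mono", "recipient_cc", "recipient_cm")

#: extra log2 elevation of transfer genes in the donor, on top of lfc_transfer
#: (stromal genes a tumor line lacks sit far above the recipient baseline)
DONOR_EXTRA_LFC = 2.0


@dataclass
class SimulationTruth:
    """Planted ground truth for one synthetic study."""

    transfer_genes: GeneSet
    intrinsic_genes: GeneSet
    cm_genes: GeneSet
    lfc_transfer: float = 2.5
    lfc_intrinsic: float = 2.5
    lfc_cm: float = 2.5
    #: right-skewed per-gene heterogeneity of the planted log2 fold changes
    #: (exponential scale, gene-intrinsic, drawn once from the truth seed):
    #: the lfc_* values are guaranteed minimum inductions, with a tail of
    #: strongly induced genes as in real DEG tables
    lfc_gene_scale: float = 0.4
    #: per-gene scatter of the donor's extra elevation of transfer genes
    donor_lfc_sd: float = 1.0
    #: log2-sd of donor-vs-recipient cell-line differences on background genes
    line_effect_sd: float = 1.0
    #: residual stromal fraction in contact-culture recipient samples
    #: (imperfect tumor-cell enrichment from the 1:9 co-culture); off by
    #: default — it dilutes the recipient's intrinsic induction
    cc_admixture: float = 0.0
    nb_dispersion: float = 0.1
    proteome_detection: dict = field(
        default_factory=lambda: {"midpoint": 7.0, "slope": 1.0}
    )  # logistic on mean log2-CPM abundance
    cohort: dict = field(
        default_factory=lambda: {
            "hazard_ratio": 2.0,
            "censoring_rate": np.log(2) / 60.0,  # exponential rate, per month
            "baseline_hazard": np.log(2) / 60.0,  # median 60 months in low group
        }
    )
    seed: int = 7

    def __post_init__(self) -> None:
        sets = [self.transfer_genes.genes, self.intrinsic_genes.genes, self.cm_genes.genes]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("planted gene sets must be pairwise disjoint")
        if self.lfc_transfer <= 0 or self.lfc_intrinsic <= 0 or self.lfc_cm <= 0:
            raise ValueError("planted log2 fold changes must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "transfer_genes": sorted(self.transfer_genes.genes),
            "intrinsic_genes": sorted(self.intrinsic_genes.genes),
            "cm_genes": sorted(self.cm_genes.genes),
            "lfc_transfer": self.lfc_transfer,
            "lfc_intrinsic": self.lfc_intrinsic,
            "lfc_cm": self.lfc_cm,
            "nb_dispersion": self.nb_dispersion,
            "proteome_detection": self.proteome_detection,
            "cohort": self.cohort,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def default_truth(
    n_genes: int = 2000,
    n_transfer: int = 150,
    n_intrinsic: int = 80,
    n_cm: int = 10,
    seed: int = 7,
    **kwargs,
) -> SimulationTruth:
    """The default study: 2000 genes, 150 transfer / 80 intrinsic / 10 CM
    planted, log2FC 2.5, NB dispersion 0.1."""
    genes = gene_universe(n_genes)
    rng = np.random.default_rng(seed)
    picked = rng.permutation(n_genes)[: n_transfer + n_intrinsic + n_cm]
    t = frozenset(genes[i] for i in picked[:n_transfer])
    i_ = frozenset(genes[i] for i in picked[n_transfer : n_transfer + n_intrinsic])
    c = frozenset(genes[i] for i in picked[n_transfer + n_intrinsic :])
    return SimulationTruth(
        GeneSet("transfer_truth", t),
        GeneSet("intrinsic_truth", i_),
        GeneSet("cm_truth", c),
        seed=seed,
        **kwargs,
    )


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n_genes + 1)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def group_mean_matrix(truth: SimulationTruth, n_genes: int) -> pd.DataFrame:
    """Expected NB mean per gene and condition (the generator's backbone).

    Background genes share one baseline across all four arms; planted genes
    get a lower baseline plus the elevations described in the module
    docstring. Gene-intrinsic quantities (baselines and the per-gene fold
    change scatter) depend only on the truth seed, so replicate datasets of
    the same truth share them and only the count noise differs.
    """
    genes = gene_universe(n_genes)
    planted = truth.transfer_genes.genes | truth.intrinsic_genes.genes | truth.cm_genes.genes
    if not planted <= set(genes):
        raise ValueError("planted gene sets exceed the gene universe")
    if n_genes < len(planted) + 100:
        raise ValueError("n_genes must exceed the planted sets by >= 100")
    rng = np.random.default_rng(truth.seed)
    base = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n_genes)
    low = rng.lognormal(mean=np.log(40.0), sigma=0.5, size=n_genes)
    is_planted = np.array([g in planted for g in genes])
    baseline = np.where(is_planted, low, base)

    def gene_lfc(center: float) -> np.ndarray:
        return center + rng.exponential(truth.lfc_gene_scale, size=n_genes)

    lfc_t = gene_lfc(truth.lfc_transfer)
    lfc_i = gene_lfc(truth.lfc_intrinsic)
    lfc_c = gene_lfc(truth.lfc_cm)
    donor_extra = DONOR_EXTRA_LFC + rng.normal(0.0, truth.donor_lfc_sd, size=n_genes)
    line_effect = rng.normal(0.0, truth.line_effect_sd, size=n_genes)

    means = pd.DataFrame(
        {cond: baseline.copy() for cond in CONDITIONS}, index=genes, dtype=float
    )
    t_mask = means.index.isin(truth.transfer_genes.genes).astype(float)
    i_mask = means.index.isin(truth.intrinsic_genes.genes).astype(float)
    c_mask = means.index.isin(truth.cm_genes.genes).astype(float)
    # donor cell-line identity: background genes differ between the lines;
    # planted genes carry their designed elevations instead
    means["donor_mono"] *= 2.0 ** (
        t_mask * (lfc_t + donor_extra) + (1.0 - t_mask - i_mask - c_mask) * line_effect
    )
    means["recipient_cc"] *= 2.0 ** (t_mask * lfc_t + i_mask * lfc_i + c_mask * lfc_c)
    means["recipient_cm"] *= 2.0 ** (c_mask * lfc_c)
    # residual stromal cells in the sorted contact-culture samples
    alpha = truth.cc_admixture
    means["recipient_cc"] = (1.0 - alpha) * means["recipient_cc"] + alpha * means["donor_mono"]
    return means


def simulate_coculture(
    truth: SimulationTruth,
    n_genes: int = 2000,
    reps_per_group: int = 3,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Four-arm co-culture counts matrix with planted effects and NB noise."""
    if reps_per_group < 2:
        raise ValueError("reps_per_group must be >= 2")
    seed = truth.seed if seed is None else seed
    means = group_mean_matrix(truth, n_genes)
    rng = np.random.default_rng(seed)
    short = {"donor_mono": "DM", "recipient_mono": "RM", "recipient_cc": "CC", "recipient_cm": "CM"}
    cols, names, conds = [], [], []
    for cond in CONDITIONS:
        mu = means[cond].to_numpy()
        for r in range(1, reps_per_group + 1):
            cols.append(_nb_draw(rng, mu, truth.nb_dispersion))
            names.append(f"{short[cond]}{r}")
            conds.append(cond)
    values = pd.DataFrame(
        np.column_stack(cols).astype(float), index=means.index, columns=names
    )
    ann = pd.DataFrame(
        {
            "condition": conds,
            "cell_line": ["donor" if c == "donor_mono" else "recipient" for c in conds],
            "batch": 1,
        },
        index=names,
    )
    return ExpressionMatrix(values, "counts", ann)


def simulate_proteome(
    expr: ExpressionMatrix,
    truth: SimulationTruth,
    noise_sd: float = 0.3,
    seed: int | None = None,
) -> pd.DataFrame:
    """TMT-like protein differential table for contact vs recipient
    monoculture.

    Detection is Bernoulli with probability logistic in the gene's mean
    log2-CPM abundance over the compared recipient samples (low-abundance
    dropout). Detected genes inherit the RNA-level fold change of the
    generator's mean structure (contact vs monoculture, per gene) with
    independent Gaussian platform noise; the p-value is a z-test of the
    noisy fold change against that noise. Undetected genes are absent
    from the table.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    cc = expr.samples_where(condition="recipient_cc")
    rm = expr.samples_where(condition="recipient_mono")
    libsize = expr.values.sum(axis=0)
    log2cpm = np.log2(expr.values.div(libsize, axis=1) * 1e6 + 1.0)
    abundance = log2cpm[cc + rm].mean(axis=1).to_numpy()
    mid = truth.proteome_detection["midpoint"]
    slope = truth.proteome_detection["slope"]
    p_detect = 1.0 / (1.0 + np.exp(-slope * (abundance - mid)))
    detected = rng.random(len(abundance)) < p_detect

    means = group_mean_matrix(truth, len(expr.gene_ids))
    true_lfc = np.log2(means["recipient_cc"] / means["recipient_mono"]).to_numpy()
    lfc = true_lfc + rng.normal(0.0, noise_sd, size=len(true_lfc))

    from scipy import stats as sps

    z = lfc / noise_sd
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {"gene": expr.gene_ids, "log2_fc": lfc, "p_value": pvals, "abundance": abundance}
    )[detected]
    out["adj_p"] = benjamini_hochberg(out["p_value"])
    return out.reset_index(drop=True)


def simulate_network(
    truth: SimulationTruth,
    n_extra_nodes: int = 500,
    wiring: str = "planted",
    inter_layer_edges: int = 300,
    seed: int | None = None,
) -> EdgeTable:
    """Scale-free interaction network over planted genes plus extras.

    ``planted`` wiring adds ``inter_layer_edges`` excess edges between the
    transfer and intrinsic gene sets; ``rewired_control`` applies
    degree-preserving double-edge swaps to the planted graph, scattering
    the excess wiring while keeping every node's degree.
    """
    if wiring not in ("planted", "rewired_control"):
        raise ValueError(f"unknown wiring {wiring!r}")
    seed = truth.seed if seed is None else seed
    t_nodes = sorted(truth.transfer_genes.genes)
    i_nodes = sorted(truth.intrinsic_genes.genes)
    extras = [f"X{i:05d}" for i in range(1, n_extra_nodes + 1)]
    nodes = t_nodes + i_nodes + extras
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(len(nodes))
    g0 = nx.barabasi_albert_graph(len(nodes), m=2, seed=int(rng.integers(2**31 - 1)))
    relabel = {i: nodes[order[i]] for i in range(len(nodes))}
    g = nx.relabel_nodes(g0, relabel)

    added = 0
    while added < inter_layer_edges:
        a = t_nodes[rng.integers(len(t_nodes))]
        b = i_nodes[rng.integers(len(i_nodes))]
        if not g.has_edge(a, b):
            g.add_edge(a, b)
            added += 1
    if wiring == "rewired_control":
        nswap = 5 * g.number_of_edges()
        nx.double_edge_swap(g, nswap=nswap, max_tries=50 * nswap, seed=int(rng.integers(2**31 - 1)))

    conf = rng.uniform(0.4, 1.0, size=g.number_of_edges())
    rows = [
        {"node_a": a, "node_b": b, "confidence": c}
        for (a, b), c in zip(sorted(map(lambda e: tuple(sorted(e)), g.edges())), conf)
    ]
    return EdgeTable(pd.DataFrame(rows))


def simulate_cohort(
    truth: SimulationTruth,
    sig: GeneSet,
    n_patients: int = 200,
    effect_size: float = 1.5,
    n_noise_genes: int = 20,
    seed: int | None = None,
) -> tuple[CohortTable, np.ndarray]:
    """Patient cohort whose hazard rises with a latent high-signature state.

    Half the patients (Bernoulli 1/2) are in the latent high state, which
    shifts every signature gene up by ``effect_size`` standard units.
    Survival is exponential at the baseline hazard (low state) or baseline
    x hazard_ratio (high state); censoring is independent exponential at
    ``censoring_rate`` (rate 0 = no censoring). Returns the cohort and the
    latent state vector (ground truth; not part of the cohort table).
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed + 3)
    state = rng.random(n_patients) < 0.5
    sig_genes = sorted(sig.genes)
    expr = rng.normal(0.0, 1.0, size=(n_patients, len(sig_genes)))
    expr[state] += effect_size
    noise = rng.normal(0.0, 1.0, size=(n_patients, n_noise_genes))

    lam0 = truth.cohort["baseline_hazard"]
    hr = truth.cohort["hazard_ratio"]
    lam = np.where(state, lam0 * hr, lam0)
    t_event = rng.exponential(1.0 / lam)
    c_rate = truth.cohort["censoring_rate"]
    t_cens = rng.exponential(1.0 / c_rate, size=n_patients) if c_rate > 0 else np.full(n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    table = pd.DataFrame(
        np.column_stack([time, event, expr, noise]),
        columns=["time", "event", *sig_genes, *[f"NOISE{i:03d}" for i in range(n_noise_genes)]],
        index=[f"P{i:04d}" for i in range(1, n_patients + 1)],
    )
    table["event"] = table["event"].astype(int)
    return CohortTable(table), state


def simulate_validation_dataset(
    truth: SimulationTruth,
    n_genes: int = 2000,
    reps_per_group: int = 3,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """A 3D-culture-style validation dataset: the same planted mean
    structure under an independent seed, returned with its contact (pos)
    and monoculture (neg) sample lists."""
    expr = simulate_coculture(truth, n_genes=n_genes, reps_per_group=reps_per_group, seed=seed)
    libsize = expr.values.sum(axis=0)
    log2 = ExpressionMatrix(
        np.log2(expr.values.div(libsize, axis=1) * 1e6 + 1.0), "log2cpm", expr.annotations
    )
    return (
        log2,
        expr.samples_where(condition="recipient_cc"),
        expr.samples_where(condition="recipient_mono"),
    )


def simulate_perturbation(
    bin_genes: GeneSet,
    recap_fraction: float = 0.2,
    other_genes: GeneSet | None = None,
    reps_per_group: int = 4,
    lfc: float = 3.0,
    noise_sd: float = 0.4,
    seed: int = 7,
) -> tuple[ExpressionMatrix, GeneSet]:
    """Perturbed-vs-control expression in which a planted fraction of
    ``bin_genes`` responds to the perturbation; returns the matrix and the
    planted responder set."""
    rng = np.random.default_rng(seed + 4)
    genes = sorted(bin_genes.genes | (other_genes.genes if other_genes else set()))
    bin_sorted = sorted(bin_genes.genes)
    n_resp = int(round(recap_fraction * len(bin_sorted)))
    responders = frozenset(
        bin_sorted[i] for i in rng.permutation(len(bin_sorted))[:n_resp]
    )
    n = len(genes)
    base = rng.normal(8.0, 1.0, size=n)
    cols, names, conds = [], [], []
    for cond, shift in (("control", 0.0), ("perturbed", lfc)):
        for r in range(1, reps_per_group + 1):
            delta = np.where(np.isin(genes, sorted(responders)), shift, 0.0)
            cols.append(base + delta + rng.normal(0.0, noise_sd, size=n))
            names.append(f"{cond[:4].upper()}{r}")
            conds.append(cond)
    values = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    ann = pd.DataFrame({"condition": conds, "cell_line": "recipient", "batch": 1}, index=names)
    return ExpressionMatrix(values, "log2cpm", ann), GeneSet("planted_responders", responders)
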